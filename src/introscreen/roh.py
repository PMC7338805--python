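"""Runs of homozygosity (ROH) and regions shared under a recessive model.

Homozygosity mapping in a consanguineous family: each affected child is
expected to be autozygous (homozygous by descent) across the disease
locus, while unaffected sibs are not. ROH are called per individual as
maximal stretches of consecutive homozygous array calls; the candidate
locus is the intersection of all affecteds' ROH with any part overlapped
by an unaffected individual's ROH removed.

Conventions
-----------
* A run is a maximal stretch of markers in which every non-missing call
  is homozygous and at most ``max_missing_in_run`` no-calls occur; it
  must contain at least ``min_markers`` homozygous calls (the classical
  "longer than 25 adjacent SNPs" rule, read boundary-inclusive).
* A heterozygous call always terminates a run.
* Region boundaries are the outermost *homozygous* markers of the run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable, HET, MISSING
from .pedigree import Pedigree


@dataclass(frozen=True)
class RohConfig:
    min_markers: int = 25
    max_missing_in_run: int = 2

    def __post_init__(self) -> None:
        if self.min_markers < 2:
            raise ValueError("min_markers must be >= 2")
        if self.max_missing_in_run < 0:
            raise ValueError("max_missing_in_run must be >= 0")


@dataclass(frozen=True)
class RohRegion:
    sample_id: str
    chrom: str
    start_bp: int  # 1-based inclusive, position of first homozygous marker
    end_bp: int  # 1-based inclusive, position of last homozygous marker
    n_markers: int  # homozygous markers in the run

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")


@dataclass(frozen=True)
class SharedRohRegion:
    chrom: str
    start_bp: int
    end_bp: int
    present_in: frozenset[str]

    @property
    def span_mb(self) -> float:
        return round((self.end_bp - self.start_bp) / 1e6, 1)


def _maximal_homozygous_windows(
    is_missing: np.ndarray, k: int
) -> list[tuple[int, int]]:
    """Maximal [i, j] index windows of a het-free stretch with <= k missing."""
    n = len(is_missing)
    miss = np.flatnonzero(is_missing)
    if len(miss) <= k:
        return [(0, n - 1)]
    windows = []
    # window i spans from just after the i-th bounding no-call to just
    # before the (i+k+1)-th; it holds exactly k interior no-calls
    for i in range(-1, len(miss) - k):
        lo = 0 if i < 0 else miss[i] + 1
        j = i + k + 1
        hi = n - 1 if j >= len(miss) else miss[j] - 1
        if lo <= hi:
            windows.append((lo, hi))
    return windows


def call_roh(
    table: GenotypeTable, sample_id: str, config: RohConfig = RohConfig()
) -> list[RohRegion]:
    """Call per-chromosome runs of homozygosity for one sample.

    Returns maximal runs in coordinate order. Runs are trimmed to their
    outermost homozygous markers; two maximal windows trimming to the
    same span are reported once.
    """
    if sample_id not in table.calls:
        raise KeyError(f"sample {sample_id!r} not present in genotype table")
    calls = table.calls[sample_id]
    regions: list[RohRegion] = []
    for chrom in table.chromosomes():
        idx = table.chromosome_index(chrom)
        c = calls[idx]
        pos = table.pos[idx]
        # split at heterozygous calls: a het always terminates a run
        het_at = np.flatnonzero(c == HET)
        bounds = np.concatenate([[-1], het_at, [len(c)]])
        spans: list[tuple[int, int]] = []
        for b in range(len(bounds) - 1):
            lo, hi = bounds[b] + 1, bounds[b + 1] - 1
            if hi - lo + 1 < config.min_markers:
                continue
            stretch_missing = c[lo : hi + 1] == MISSING
            for wlo, whi in _maximal_homozygous_windows(
                stretch_missing, config.max_missing_in_run
            ):
                a, z = lo + wlo, lo + whi
                hom = np.flatnonzero(c[a : z + 1] != MISSING)
                if len(hom) < config.min_markers:
                    continue
                spans.append((a + hom[0], a + hom[-1]))
        for a, z in sorted(set(spans)):
            # drop spans nested inside another reported span
            if any(
                (oa <= a and z <= oz) and (oa, oz) != (a, z) for oa, oz in spans
            ):
                continue
            n_hom = int(np.sum(c[a : z + 1] != MISSING))
            regions.append(
                RohRegion(
                    sample_id=sample_id,
                    chrom=chrom,
                    start_bp=int(pos[a]),
                    end_bp=int(pos[z]),
                    n_markers=n_hom,
                )
            )
    return regions


# -- interval algebra on 1-based inclusive intervals ------------------------


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for a, z in sorted(intervals):
        if out and a <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], z))
        else:
            out.append((a, z))
    return out


def _intersect(xs: list[tuple[int, int]], ys: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(xs) and j < len(ys):
        a = max(xs[i][0], ys[j][0])
        z = min(xs[i][1], ys[j][1])
        if a <= z:
            out.append((a, z))
        if xs[i][1] < ys[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract(xs: list[tuple[int, int]], ys: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for a, z in xs:
        pieces = [(a, z)]
        for ya, yz in ys:
            nxt = []
            for pa, pz in pieces:
                if yz < pa or ya > pz:
                    nxt.append((pa, pz))
                    continue
                if pa < ya:
                    nxt.append((pa, ya - 1))
                if yz < pz:
                    nxt.append((yz + 1, pz))
            pieces = nxt
        out.extend(pieces)
    return sorted(out)


def shared_roh(
    regions_by_sample: dict[str, list[RohRegion]],
    pedigree: Pedigree,
    table: GenotypeTable | None = None,
    config: RohConfig = RohConfig(),
) -> list[SharedRohRegion]:
    """Intersect affected individuals' ROH and remove unaffected overlap.

    ``regions_by_sample`` must hold ROH for every genotyped individual;
    affection status is taken from the pedigree. When the genotype table
    is supplied, each candidate interval must retain at least
    ``config.min_markers`` homozygous markers in every affected.
    """
    affected = [s for s in regions_by_sample if pedigree.individuals[s].status == "affected"]
    unaffected = [s for s in regions_by_sample if pedigree.individuals[s].status == "unaffected"]
    if not affected:
        raise ValueError("no affected individuals among the ROH samples")

    chroms: list[str] = []
    for regs in regions_by_sample.values():
        for r in regs:
            if r.chrom not in chroms:
                chroms.append(r.chrom)

    shared: list[SharedRohRegion] = []
    for chrom in chroms:
        inter: list[tuple[int, int]] | None = None
        for s in affected:
            ivs = _merge(
                [(r.start_bp, r.end_bp) for r in regions_by_sample[s] if r.chrom == chrom]
            )
            inter = ivs if inter is None else _intersect(inter, ivs)
            if not inter:
                break
        if not inter:
            continue
        removed = _merge(
            [
                (r.start_bp, r.end_bp)
                for s in unaffected
                for r in regions_by_sample[s]
                if r.chrom == chrom
            ]
        )
        pieces = _subtract(inter, removed)
        for a, z in pieces:
            if table is not None and not _retains_markers(table, chrom, a, z, affected, config):
                continue
            shared.append(
                SharedRohRegion(
                    chrom=chrom, start_bp=a, end_bp=z, present_in=frozenset(affected)
                )
            )
    shared.sort(key=lambda r: (chroms.index(r.chrom), r.start_bp))
    return shared


def _retains_markers(
    table: GenotypeTable,
    chrom: str,
    start: int,
    end: int,
    affected: list[str],
    config: RohConfig,
) -> bool:
    idx = table.chromosome_index(chrom)
    inside = idx[(table.pos[idx] >= start) & (table.pos[idx] <= end)]
    if len(inside) < config.min_markers:
        return False
    for s in affected:
        c = table.calls[s][inside]
        if int(np.sum((c != MISSING) & (c != HET))) < config.min_markers:
            return False
    return True


# -- reporting ---------------------------------------------------------------


def write_roh_bed(regions: list[RohRegion], path: str | Path) -> None:
    """BED (0-based half-open), name=sample, score=n_markers."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.sample_id}\t{r.n_markers}\n")


def write_shared_bed(regions: list[SharedRohRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\tshared\t0\n")


def read_shared_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Shared-ROH BED rows as (chrom, start_bp, end_bp), 1-based inclusive."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, start, end = line.split("\t")[:3]
        out.append((chrom, int(start) + 1, int(end)))
    return out


def shared_report(regions: list[SharedRohRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start_bp": [r.start_bp for r in regions],
            "end_bp": [r.end_bp for r in regions],
            "span_mb": [r.span_mb for r in regions],
            "present_in": [",".join(sorted(r.present_in)) for r in regions],
        }
    )
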