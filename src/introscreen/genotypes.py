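"""Ordered biallelic array genotypes.

Calls are encoded as alt-allele counts: ``0`` hom-ref, ``1`` het,
``2`` hom-alt, ``-1`` missing (no-call). Homozygosity mapping only
distinguishes homozygous / heterozygous / missing, so this minimal
encoding carries everything the pipeline needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1


@dataclass
class GenotypeTable:
    """Markers (chrom, 1-based pos, id) with aligned per-sample call vectors."""

    chrom: np.ndarray  # object/str array, one entry per marker
    pos: np.ndarray  # int64, 1-based, strictly increasing within chromosome
    marker_id: np.ndarray
    calls: dict[str, np.ndarray] = field(default_factory=dict)  # int8 vectors

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        n = len(self.pos)
        if not (len(self.chrom) == len(self.marker_id) == n):
            raise ValueError("marker arrays have inconsistent lengths")
        for chrom in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == chrom]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"marker positions not strictly increasing on chromosome {chrom}"
                )
        for sample, vec in self.calls.items():
            vec = np.asarray(vec, dtype=np.int8)
            if len(vec) != n:
                raise ValueError(f"call vector for {sample!r} has length {len(vec)} != {n}")
            bad = ~np.isin(vec, [HOM_REF, HET, HOM_ALT, MISSING])
            if bad.any():
                raise ValueError(f"invalid genotype codes for {sample!r}")
            self.calls[sample] = vec

    @property
    def samples(self) -> list[str]:
        return list(self.calls)

    @property
    def n_markers(self) -> int:
        return len(self.pos)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.chrom))

    def chromosome_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"marker_id": self.marker_id, "chrom": self.chrom, "pos": self.pos}
        )
        for sample, vec in self.calls.items():
            df[sample] = vec
        return df


def write_genotype_tsv(table: GenotypeTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str | Path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = ["marker_id", "chrom", "pos"]
    missing_cols = [c for c in meta if c not in df.columns]
    if missing_cols:
        raise ValueError(f"genotype TSV is missing columns {missing_cols}")
    calls = {
        c: df[c].to_numpy(dtype=np.int8) for c in df.columns if c not in meta
    }
    return GenotypeTable(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        marker_id=df["marker_id"].to_numpy(dtype=object),
        calls=calls,
    )
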