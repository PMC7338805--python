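"""Recessive-variant filter cascade and interactome prioritization.

The cascade reduces a genome-wide variant set under a homozygous
recessive model: (1) rare in population databases, (2) compatible with
recessive segregation in the family, (3) inside a shared run of
homozygosity, (4) of a consequence class that can damage the protein,
where otherwise-discarded non-coding variants are rescued when splice
scanning predicts a created or strengthened splice site. A final
guilt-by-association step keeps survivors whose gene belongs to the
interactome neighbourhood of known disease genes.

The four filters commute (each is a pure predicate on one variant), so
the stage order only shapes the reported funnel counts, not the final
set; the order used here is frequency, segregation, ROH, consequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .pedigree import Pedigree
from .roh import SharedRohRegion
from .splice import SpliceSiteModel, scan_created_sites
from .variants import VariantRecord

# consequence classes discarded unless a splice effect is predicted
NONFUNCTIONAL_CLASSES = {
    "utr5",
    "utr3",
    "deep_intronic",
    "intergenic",
    "synonymous",
    "near_splice",
}

STAGES = ("frequency", "segregation", "roh", "consequence")


@dataclass(frozen=True)
class FilterConfig:
    max_af: float | None = 0.01  # None disables the frequency filter
    recessive_model: bool = True
    require_roh: bool = True
    consequence_filter: bool = True
    rescue_splice_flagged: bool = True

    def __post_init__(self) -> None:
        if self.max_af is not None and not 0 < self.max_af < 1:
            raise ValueError("max_af must lie in (0, 1)")


@dataclass
class GeneNetwork:
    """Undirected gene-interaction graph with named seed-gene sets."""

    nodes: set[str]
    edges: set[frozenset[str]]
    seed_sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2 or not e <= self.nodes:
                raise ValueError(f"edge {set(e)} references unknown nodes")
        for name, seeds in self.seed_sets.items():
            if not seeds:
                raise ValueError(f"seed set {name!r} is empty")

    def neighbours(self, gene: str) -> set[str]:
        return {g for e in self.edges if gene in e for g in e if g != gene}

    @classmethod
    def from_files(
        cls, edges_path: str | Path, seed_paths: dict[str, str | Path]
    ) -> "GeneNetwork":
        edges: set[frozenset[str]] = set()
        nodes: set[str] = set()
        for line in Path(edges_path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split()[:2]
            nodes |= {a, b}
            if a != b:
                edges.add(frozenset((a, b)))
        seed_sets = {}
        for name, p in seed_paths.items():
            seed_sets[name] = {
                s.strip() for s in Path(p).read_text().split() if s.strip()
            }
        nodes |= set().union(*seed_sets.values()) if seed_sets else set()
        return cls(nodes=nodes, edges=edges, seed_sets=seed_sets)


@dataclass
class PrioritizationResult:
    funnel: list[tuple[str, int]]
    survivors_by_stage: dict[str, list[VariantRecord]]

    @property
    def survivors(self) -> list[VariantRecord]:
        return self.survivors_by_stage[self.funnel[-1][0]] if self.funnel else []

    @property
    def final_genes(self) -> list[str]:
        return sorted({v.gene for v in self.survivors})


def check_segregation(v: VariantRecord, ped: Pedigree) -> bool:
    """Homozygous-recessive co-segregation; missing genotypes are neutral.

    True iff every affected is homozygous-alt, every genotyped parent of
    an affected is heterozygous (obligate carrier) and no unaffected is
    homozygous-alt.
    """
    for a in ped.affected:
        gt = v.genotypes.get(a)
        if gt is not None and gt != 2:
            return False
    for p in ped.parents_of_affected():
        gt = v.genotypes.get(p)
        if gt is not None and gt != 1:
            return False
    for u in ped.unaffected:
        gt = v.genotypes.get(u)
        if gt is not None and gt == 2:
            return False
    return True


def _in_shared_roh(
    v: VariantRecord, shared: list[SharedRohRegion] | list[tuple[str, int, int]]
) -> bool:
    for region in shared:
        if isinstance(region, SharedRohRegion):
            chrom, a, z = region.chrom, region.start_bp, region.end_bp
        else:
            chrom, a, z = region
        if v.chrom == chrom and a <= v.pos <= z:
            return True
    return False


def _splice_rescued(v: VariantRecord, splice_model: SpliceSiteModel | None) -> bool:
    if v.context is not None and splice_model is not None:
        ref_seq, alt_seq, pos = v.context
        return bool(scan_created_sites(ref_seq, alt_seq, pos, splice_model))
    return v.splice_flag is not None


def filter_cascade(
    variants: list[VariantRecord],
    ped: Pedigree,
    shared_roh: list[SharedRohRegion] | list[tuple[str, int, int]] | None,
    cfg: FilterConfig = FilterConfig(),
    splice_model: SpliceSiteModel | None = None,
) -> PrioritizationResult:
    """Run the four filters in order, recording a survivor funnel.

    Stages only ever remove variants; a disabled stage is the identity
    and still appears in the funnel.
    """
    if cfg.require_roh and shared_roh is None:
        raise ValueError("require_roh is set but no shared-ROH regions were supplied")

    current = list(variants)
    funnel: list[tuple[str, int]] = [("input", len(current))]
    survivors: dict[str, list[VariantRecord]] = {"input": list(current)}

    def apply(stage: str, keep) -> None:
        nonlocal current
        current = [v for v in current if keep(v)]
        funnel.append((stage, len(current)))
        survivors[stage] = list(current)

    apply("frequency", lambda v: cfg.max_af is None or v.population_af <= cfg.max_af)
    apply(
        "segregation",
        lambda v: not cfg.recessive_model or check_segregation(v, ped),
    )
    apply(
        "roh",
        lambda v: not cfg.require_roh or _in_shared_roh(v, shared_roh or []),
    )
    apply(
        "consequence",
        lambda v: not cfg.consequence_filter
        or v.region_class not in NONFUNCTIONAL_CLASSES
        or (cfg.rescue_splice_flagged and _splice_rescued(v, splice_model)),
    )
    return PrioritizationResult(funnel=funnel, survivors_by_stage=survivors)


def candidate_gene_set(net: GeneNetwork, depth: int = 1) -> set[str]:
    """Seed genes plus their interactome neighbourhood (default depth 1)."""
    frontier: set[str] = set()
    for name, seeds in net.seed_sets.items():
        for s in seeds:
            if s not in net.nodes:
                warnings.warn(f"seed gene {s!r} ({name}) not in network; skipped")
                continue
            frontier.add(s)
    out = set(frontier)
    for _ in range(depth):
        frontier = {n for g in frontier for n in net.neighbours(g)} - out
        out |= frontier
    return out


def rank_candidates(
    result: PrioritizationResult, candidates: set[str]
) -> list[VariantRecord]:
    """Survivors in candidate genes, splice-flagged first, then rarest."""
    kept = [v for v in result.survivors if v.gene in candidates]
    kept.sort(key=lambda v: (v.splice_flag is None, v.population_af))
    return kept


def funnel_frame(result: PrioritizationResult):
    import pandas as pd

    return pd.DataFrame(result.funnel, columns=["stage", "surviving"])
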