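"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators emulate the data shapes of a consanguineous-family
discovery study so every stage runs without any download:

* ``simulate_pedigree_array`` — 250K-style SNP-array genotypes with
  autozygous intervals planted in the affected sibs;
* ``simulate_variant_cohort`` — an annotated variant cohort containing
  one causal deep-intronic allele plus decoys engineered to fail the
  filter cascade at known stages, with a truth table of those stages;
* ``simulate_spectral_counts`` — overdispersed (negative-binomial)
  bait-vs-control spectral counts with planted fold changes on chosen
  proteasome subunits.

All generators are deterministic for a fixed scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable, HET, HOM_ALT, HOM_REF, MISSING
from .locus import LocusFixture, build_psmc3_fixture
from .pedigree import ARRAY_SAMPLES, Pedigree, family_pedigree
from .splice import default_donor_model, scan_created_sites
from .variants import VariantRecord

# the three shared-homozygosity intervals of the worked example (chr11)
STUDY_ROH_INTERVALS: tuple[tuple[str, int, int], ...] = (
    ("11", 44_396_024, 44_668_374),
    ("11", 45_574_574, 47_684_908),
    ("11", 66_066_993, 67_349_899),
)

DECOY_CLASSES = (
    "fails-frequency",
    "fails-segregation",
    "outside-ROH",
    "passes-all-but-network",
)

# the study-funnel preset: decoys at every stage plus five candidates that
# only the interactome step can separate from the causal gene
STUDY_FUNNEL_DECOYS: tuple[str, ...] = (
    ("fails-frequency",) * 3
    + ("fails-segregation",) * 3
    + ("outside-ROH",) * 3
    + ("passes-all-but-network",) * 5
)


@dataclass(frozen=True)
class CountsDesign:
    """Bait/control replicate layout and per-protein count model."""

    samples: tuple[tuple[str, str], ...] = (
        ("Ctrl1", "bait_control"),
        ("Ctrl2", "bait_control"),
        ("Ctrl3", "bait_control"),
        ("Pat1", "bait_patient"),
        ("Pat2", "bait_patient"),
        ("Pat3", "bait_patient"),
        ("Neg1", "negative_control"),
        ("Neg2", "negative_control"),
        ("Neg3", "negative_control"),
    )
    baseline_means: dict[str, float] = field(default_factory=dict)  # bait-level means
    fold_changes: dict[str, float] = field(default_factory=dict)  # applied to bait_patient
    bait_specificity: float = 8.0  # bait/negative-control mean ratio for specific preys
    dispersion: float = 0.05  # NB variance = mu + dispersion * mu^2

    def __post_init__(self) -> None:
        groups = [g for _, g in self.samples]
        if groups.count("bait_patient") < 2 or groups.count("bait_control") < 2:
            raise ValueError("need >= 2 bait and >= 2 control replicates")

    def resolved_means(self) -> dict[str, float]:
        return dict(self.baseline_means) if self.baseline_means else default_protein_means()


def default_protein_means(n_background: int = 166) -> dict[str, float]:
    """Spectral-count means for the proteasome interactome plus background."""
    means: dict[str, float] = {}
    for i in range(1, 8):
        means[f"PSMA{i}"] = 55.0 + 4 * i
    for i in range(1, 8):
        means[f"PSMB{i}"] = 45.0 + 3 * i
    for i in range(1, 7):
        means[f"PSMC{i}"] = 70.0 + 5 * i
    for i in range(1, 15):
        means[f"PSMD{i}"] = 30.0 + 2 * i
    means["PSME1"] = 25.0
    means["PSME2"] = 20.0
    for i in range(n_background):
        means[f"OTHER{i + 1:03d}"] = 5.0 + (i % 26)
    return means


def study_fold_changes() -> dict[str, float]:
    """The planted truth of the worked example: 20S core up, 19S unchanged."""
    fc = {f"PSMA{i}": 1.5 for i in range(1, 8)}
    fc.update({f"PSMB{i}": 1.5 for i in (1, 3, 5, 7)})
    fc.update({f"PSMB{i}": 2.0 for i in (2, 4, 6)})
    return fc


@dataclass(frozen=True)
class SimScenario:
    """One fully specified synthetic study."""

    seed: int = 0
    pedigree: Pedigree = field(default_factory=family_pedigree)
    planted_roh: tuple[tuple[str, int, int], ...] = STUDY_ROH_INTERVALS
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"11": 135_000_000}
    )
    marker_spacing_bp: float = 10_000.0
    het_rate: float = 0.30
    missing_rate: float = 0.005
    min_roh_markers: int = 25
    array_samples: tuple[str, ...] = ARRAY_SAMPLES
    n_background_variants: int = 2_000
    decoy_spec: tuple[str, ...] = STUDY_FUNNEL_DECOYS
    causal_gene: str = "PSMC3"
    causal_position: tuple[str, int] = ("11", 47_440_000)
    causal_gene_in_network: bool = True
    counts_design: CountsDesign = field(
        default_factory=lambda: CountsDesign(fold_changes=study_fold_changes())
    )

    def __post_init__(self) -> None:
        for p in (self.het_rate, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, a, z in self.planted_roh:
            if a >= z:
                raise ValueError(f"empty interval {chrom}:{a}-{z}")
            by_chrom.setdefault(chrom, []).append((a, z))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (a1, z1), (a2, z2) in zip(ivs, ivs[1:]):
                if a2 <= z1:
                    raise ValueError(f"planted intervals overlap on chromosome {chrom}")
        for cls in self.decoy_spec:
            if cls not in DECOY_CLASSES:
                raise ValueError(f"unknown decoy class {cls!r}")

    def with_seed(self, seed: int) -> "SimScenario":
        return replace(self, seed=seed)


# -- SNP-array genotypes -----------------------------------------------------


def _marker_positions(scenario: SimScenario, rng: np.random.Generator, chrom: str) -> np.ndarray:
    """Exponential inter-marker gaps, with a regular grid inside planted
    intervals so each holds its deterministic complement of markers."""
    length = scenario.chromosome_lengths[chrom]
    spacing = scenario.marker_spacing_bp
    gaps = rng.exponential(spacing, size=int(length / spacing * 1.5) + 10)
    pos = np.cumsum(gaps).astype(np.int64) + 1
    pos = pos[pos <= length]
    planted = [iv for iv in scenario.planted_roh if iv[0] == chrom]
    keep = np.ones(len(pos), dtype=bool)
    grids = []
    for _, a, z in planted:
        n = int((z - a) / spacing) + 1
        if n < scenario.min_roh_markers:
            raise ValueError(
                f"planted interval {chrom}:{a}-{z} is too short to hold "
                f"{scenario.min_roh_markers} markers at {spacing:.0f} bp spacing"
            )
        keep &= (pos < a) | (pos > z)
        grids.append(np.linspace(a, z, n).round().astype(np.int64))
    pos = np.unique(np.concatenate([pos[keep], *grids])) if grids else pos
    return pos


def simulate_pedigree_array(scenario: SimScenario) -> GenotypeTable:
    """Array genotypes with planted autozygosity in the affected sibs.

    Affected individuals are homozygous at every marker inside planted
    intervals (a shared allele, as for an IBD haplotype); everywhere
    else, and for unaffected individuals, markers are heterozygous with
    probability ``het_rate``, otherwise homozygous for a random allele,
    with no-calls at ``missing_rate``.
    """
    rng = np.random.default_rng(scenario.seed)
    ped = scenario.pedigree
    affected = set(ped.affected)
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for chrom in scenario.chromosome_lengths:
        p = _marker_positions(scenario, rng, chrom)
        chroms.extend([chrom] * len(p))
        positions.append(p)
    pos = np.concatenate(positions)
    chrom_arr = np.array(chroms, dtype=object)
    n = len(pos)

    in_planted = np.zeros(n, dtype=bool)
    for chrom, a, z in scenario.planted_roh:
        in_planted |= (chrom_arr == chrom) & (pos >= a) & (pos <= z)
    shared_allele = rng.choice([HOM_REF, HOM_ALT], size=n).astype(np.int8)

    calls: dict[str, np.ndarray] = {}
    for sample in scenario.array_samples:
        is_het = rng.random(n) < scenario.het_rate
        hom_allele = rng.choice([HOM_REF, HOM_ALT], size=n)
        vec = np.where(is_het, HET, hom_allele).astype(np.int8)
        is_missing = rng.random(n) < scenario.missing_rate
        vec[is_missing] = MISSING
        if sample in affected:
            vec[in_planted] = shared_allele[in_planted]
        calls[sample] = vec

    marker_id = np.array([f"snp{i + 1:06d}" for i in range(n)], dtype=object)
    return GenotypeTable(chrom=chrom_arr, pos=pos, marker_id=marker_id, calls=calls)


# -- variant cohort ----------------------------------------------------------


def _segregating_genotypes(ped: Pedigree) -> dict[str, int]:
    """The recessive pattern: affecteds hom-alt, carrier parents het,
    unaffected sibs het or ref."""
    gts: dict[str, int] = {}
    for a in ped.affected:
        gts[a] = 2
    for p in ped.parents_of_affected():
        gts[p] = 1
    for i, u in enumerate(sorted(set(ped.unaffected) - set(ped.parents_of_affected()))):
        gts[u] = i % 2  # alternate het / ref among unaffected sibs
    return gts


def _first_failing_stage(
    v: VariantRecord, ped: Pedigree, scenario: SimScenario, max_af: float = 0.01
) -> str | None:
    """Generator-side label: first cascade stage the variant must fail."""
    from .prioritize import NONFUNCTIONAL_CLASSES, check_segregation

    if v.population_af > max_af:
        return "frequency"
    if not check_segregation(v, ped):
        return "segregation"
    in_roh = any(
        v.chrom == c and a <= v.pos <= z for c, a, z in scenario.planted_roh
    )
    if not in_roh:
        return "roh"
    if v.region_class in NONFUNCTIONAL_CLASSES and v.splice_flag is None:
        return "consequence"
    return None


def simulate_variant_cohort(
    scenario: SimScenario, fixture: LocusFixture | None = None
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """An annotated cohort with one causal deep-intronic allele.

    The causal variant sits in a planted shared-ROH interval, >100 bp
    from any exon, segregates recessively and carries a created-donor
    splice flag established by actually scanning the packaged locus
    cassette. Decoys are planted per ``scenario.decoy_spec``; background
    variants fill the cohort. The truth table records, per variant, the
    first cascade stage it must fail ("network" for survivors outside
    the interactome, "none" for the causal variant).
    """
    rng = np.random.default_rng(scenario.seed + 1)
    ped = scenario.pedigree
    fixture = fixture or build_psmc3_fixture()

    causal_chrom, causal_pos = scenario.causal_position
    if not any(
        causal_chrom == c and a <= causal_pos <= z for c, a, z in scenario.planted_roh
    ):
        raise ValueError(
            f"causal position {causal_chrom}:{causal_pos} lies outside every planted interval"
        )

    donor = default_donor_model()
    created = scan_created_sites(
        fixture.genomic_sequence, fixture.alt_sequence, fixture.variant[0], donor
    )
    splice_flag = "donor_created" if created else None

    causal_gts: dict[str, int] = {a: 2 for a in ped.affected}
    causal_gts.update({p: 1 for p in ped.parents_of_affected()})
    for i, u in enumerate(sorted(set(ped.unaffected) - set(ped.parents_of_affected()))):
        causal_gts[u] = i % 2

    variants: list[VariantRecord] = []
    labels: list[tuple[str, str, str]] = []  # (variant_id, class, fail_stage)

    def add(v: VariantRecord, cls: str, stage: str) -> None:
        variants.append(v)
        labels.append((v.variant_id, cls, stage))

    vid = iter(f"v{i + 1:06d}" for i in range(10**6))
    add(
        VariantRecord(
            chrom=causal_chrom,
            pos=causal_pos,
            ref=fixture.variant[1],
            alt=fixture.variant[2],
            gene=scenario.causal_gene,
            region_class="deep_intronic",
            dist_to_nearest_exon=337,
            population_af=0.0,
            genotypes=dict(causal_gts),
            splice_flag=splice_flag,
            variant_id=next(vid),
            context=(fixture.genomic_sequence, fixture.alt_sequence, fixture.variant[0]),
        ),
        "causal",
        "none",
    )

    roh_intervals = [iv for iv in scenario.planted_roh]

    def pos_inside_roh() -> tuple[str, int]:
        c, a, z = roh_intervals[rng.integers(len(roh_intervals))]
        return c, int(rng.integers(a, z + 1))

    def pos_outside_roh() -> tuple[str, int]:
        chrom = list(scenario.chromosome_lengths)[0]
        while True:
            p = int(rng.integers(1, scenario.chromosome_lengths[chrom]))
            if not any(
                chrom == c and a <= p <= z for c, a, z in scenario.planted_roh
            ):
                return chrom, p

    for k, cls in enumerate(scenario.decoy_spec):
        seg = _segregating_genotypes(ped)
        if cls == "fails-frequency":
            chrom, p = pos_inside_roh()
            v = VariantRecord(
                chrom=chrom, pos=p, ref="C", alt="T", gene=f"FRQ{k}",
                region_class="coding", population_af=float(rng.uniform(0.02, 0.08)),
                genotypes=seg, variant_id=next(vid),
            )
        elif cls == "fails-segregation":
            chrom, p = pos_inside_roh()
            bad = dict(seg)
            bad[ped.affected[k % len(ped.affected)]] = 1  # an affected is only het
            v = VariantRecord(
                chrom=chrom, pos=p, ref="G", alt="A", gene=f"SEG{k}",
                region_class="coding", population_af=float(rng.uniform(0.0, 0.005)),
                genotypes=bad, variant_id=next(vid),
            )
        elif cls == "outside-ROH":
            chrom, p = pos_outside_roh()
            v = VariantRecord(
                chrom=chrom, pos=p, ref="A", alt="C", gene=f"OUT{k}",
                region_class="coding", population_af=float(rng.uniform(0.0, 0.005)),
                genotypes=seg, variant_id=next(vid),
            )
        else:  # passes-all-but-network
            chrom, p = pos_inside_roh()
            v = VariantRecord(
                chrom=chrom, pos=p, ref="T", alt="G", gene=f"CAND{k}",
                region_class="coding", population_af=float(rng.uniform(0.0, 0.005)),
                genotypes=seg, variant_id=next(vid),
            )
        stage = "network" if cls == "passes-all-but-network" else cls.split("fails-")[-1]
        if cls == "outside-ROH":
            stage = "roh"
        add(v, cls, stage)

    classes = np.array(
        ["coding", "synonymous", "utr5", "utr3", "deep_intronic", "intergenic", "near_splice"]
    )
    class_p = np.array([0.25, 0.15, 0.1, 0.1, 0.15, 0.15, 0.1])
    chrom = list(scenario.chromosome_lengths)[0]
    for _ in range(scenario.n_background_variants):
        af = float(rng.uniform(0.02, 0.5)) if rng.random() < 0.8 else float(
            rng.uniform(0.0, 0.01)
        )
        region = str(rng.choice(classes, p=class_p))
        dist = int(rng.integers(101, 50_000)) if region == "deep_intronic" else (
            int(rng.integers(1, 100)) if region == "near_splice" else 0
        )
        gts = {
            s: int(rng.binomial(2, af))
            for s in scenario.pedigree.individuals
        }
        v = VariantRecord(
            chrom=chrom, pos=int(rng.integers(1, scenario.chromosome_lengths[chrom])),
            ref="A", alt="G", gene=f"BG{rng.integers(1, 10_000)}",
            region_class=region, dist_to_nearest_exon=dist,
            population_af=af, genotypes=gts, variant_id=next(vid),
        )
        stage = _first_failing_stage(v, ped, scenario)
        if stage is None:
            # a background variant slipping through every filter would be a
            # second "causal" candidate; break its segregation instead
            v.genotypes[ped.affected[0]] = 1
            stage = "segregation"
        add(v, "background", stage)

    truth = pd.DataFrame(labels, columns=["variant_id", "class", "fail_stage"])
    return variants, truth


# -- spectral counts ---------------------------------------------------------


def simulate_spectral_counts(scenario: SimScenario):
    """Negative-binomial spectral counts for the co-IP design.

    Bait samples draw from each protein's bait-level mean (patient bait
    means multiplied by any planted fold change); negative controls draw
    from the mean divided by ``bait_specificity`` for proteasome preys.
    Variance is mu + dispersion * mu^2.
    """
    from .coip import SpectralCountMatrix, infer_subcomplex

    design = scenario.counts_design
    if design.dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(scenario.seed + 2)
    means = design.resolved_means()
    proteins = list(means)

    data = {}
    for sample, group in design.samples:
        col = np.empty(len(proteins), dtype=np.int64)
        for i, prot in enumerate(proteins):
            mu = means[prot]
            if group == "negative_control" and infer_subcomplex(prot) != "other":
                mu = mu / design.bait_specificity
            if group == "bait_patient":
                mu = mu * design.fold_changes.get(prot, 1.0)
            n_param = 1.0 / design.dispersion
            col[i] = rng.negative_binomial(n_param, n_param / (n_param + mu))
        data[sample] = col
    counts = pd.DataFrame(data, index=proteins)
    groups = pd.Series({s: g for s, g in design.samples})
    return SpectralCountMatrix(counts=counts, groups=groups)
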