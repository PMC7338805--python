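"""Annotated variant records and VCF 4.2 input/output.

Each record carries per-sample genotypes (alt-allele counts), a
population allele frequency, a gene symbol and a coarse region class.
Region classes follow the filtering vocabulary of recessive-disease
pipelines; ``deep_intronic`` means more than 100 bp from any exon-intron
boundary (and therefore invisible to exome capture).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

REGION_CLASSES = {
    "coding",
    "splice_site",
    "near_splice",
    "utr5",
    "utr3",
    "deep_intronic",
    "intergenic",
    "synonymous",
}

DEEP_INTRONIC_MIN_DIST = 100


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = "."
    region_class: str = "coding"
    dist_to_nearest_exon: int = 0
    population_af: float = 0.0
    genotypes: dict[str, int | None] = field(default_factory=dict)
    splice_flag: str | None = None  # e.g. "donor_created"
    variant_id: str = "."
    # optional live-scanning context: (ref_seq, alt_seq, variant position in seq)
    context: tuple[str, str, int] | None = None

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        if not 0.0 <= self.population_af <= 1.0:
            raise ValueError("population_af must be within [0, 1]")
        if self.region_class == "deep_intronic" and self.dist_to_nearest_exon <= DEEP_INTRONIC_MIN_DIST:
            raise ValueError(
                "deep_intronic requires dist_to_nearest_exon > "
                f"{DEEP_INTRONIC_MIN_DIST} (got {self.dist_to_nearest_exon})"
            )
        if self.region_class == "near_splice" and self.dist_to_nearest_exon > DEEP_INTRONIC_MIN_DIST:
            raise ValueError("near_splice variants must lie within 100 bp of an exon")


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}


def write_vcf(variants: list[VariantRecord], samples: list[str], path: str | Path) -> None:
    """Emit a VCF 4.2 with AF/GENE/REGION/DIST/SPLICE INFO and GT genotypes."""
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Population allele frequency (max over databases)">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=REGION,Number=1,Type=String,Description="Region class">',
        '##INFO=<ID=DIST,Number=1,Type=Integer,Description="Distance to nearest exon (bp)">',
        '##INFO=<ID=SPLICE,Number=1,Type=String,Description="Created/strengthened splice-site annotation">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    lines = list(header)
    for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
        info = (
            f"AF={v.population_af:g};GENE={v.gene};REGION={v.region_class};"
            f"DIST={v.dist_to_nearest_exon}"
        )
        if v.splice_flag:
            info += f";SPLICE={v.splice_flag}"
        gts = "\t".join(_GT_STRING[v.genotypes.get(s)] for s in samples)
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t{info}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read an annotated VCF via cyvcf2 into VariantRecord objects."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: list[VariantRecord] = []
    for rec in vcf:
        genotypes: dict[str, int | None] = {}
        for sample, gt in zip(samples, rec.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            genotypes[sample] = sum(alleles) if alleles else None
        out.append(
            VariantRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0] if rec.ALT else ".",
                gene=rec.INFO.get("GENE", "."),
                region_class=rec.INFO.get("REGION", "coding"),
                dist_to_nearest_exon=int(rec.INFO.get("DIST", 0)),
                population_af=float(rec.INFO.get("AF", 0.0)),
                genotypes=genotypes,
                splice_flag=rec.INFO.get("SPLICE"),
                variant_id=rec.ID or ".",
            )
        )
    return out
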