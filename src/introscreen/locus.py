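"""The packaged PSMC3 intron-10 locus fixture.

The worked example of the whole splice pipeline: an exon10-intron10-exon11
cassette of the PSMC3 (Rpt5) transcript in which a deep-intronic A>G
substitution at c.1127+337 creates a new donor splice site. Paired with
an intronic acceptor, it activates a 114-nt pseudoexon whose inclusion
shifts the reading frame after codon 376 (p.(Ser376Argfs*15)).

Only the 114-nt pseudoexon body is the experimentally determined
sequence; the exons, the remaining intron and the acceptor/donor flanks
are synthetic constructs (consensus-like where a splice signal is
intended, splice-signal-free elsewhere) because the surrounding genomic
sequence is not part of the packaged example. The reference CDS is
likewise a synthetic 439-codon coding sequence pinned at the positions
the consequence prediction depends on (codon 376 = AGC, CDS 1126-1127 =
A,G).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

# the pseudoexon body as observed in the patient mRNA; its final base is
# the variant position (reference A, alternate G)
PSEUDOEXON_114NT = (
    "ACTCCACCCCTCATCTGAAGGCACAGAGGCTGGAGGCACTTAGTTTCCTGGCCTCACACCTCAGCCCATT"
    "AACACACGCCAGGAATGGCCGGGACCAGATGGACTTGAGTTCAG"
)

CDS_PHASE_ANCHOR = 1127  # CDS coordinate of the last nucleotide of exon 10

# acceptor contexts: 18 intronic bases + the invariant AG
_STRONG_TRACT = "TTTTCTTTCTTTCTTCCCAG"  # immediately 5' of the pseudoexon
_WEAK_TRACT = "TACTTCATCGTTACTTTTAG"  # a weaker decoy acceptor further 5'

_N_CODONS = 439
_EXON10_CASSETTE_NT = 200  # CDS 928..1127
_EXON11_CASSETTE_NT = 150  # CDS 1128..1277


@dataclass(frozen=True)
class LocusFixture:
    """Reference cassette, exon layout and variant of the worked example."""

    genomic_sequence: str  # reference allele cassette
    exon_table: tuple[tuple[int, int], ...]  # 1-based inclusive cassette intervals
    cds_phase_anchor: int
    insert_sequence: str  # the 114-nt pseudoexon body (alternate allele)
    variant: tuple[int, str, str]  # (cassette position, ref, alt)
    reference_cds: str
    cassette_cds_start: int  # CDS coordinate of the cassette's first base

    @property
    def alt_sequence(self) -> str:
        pos, ref, alt = self.variant
        assert self.genomic_sequence[pos - 1] == ref
        return self.genomic_sequence[: pos - 1] + alt + self.genomic_sequence[pos:]

    def spliced_reference(self) -> str:
        """Cassette exons concatenated; equals the matching CDS slice."""
        return "".join(
            self.genomic_sequence[a - 1 : z] for a, z in self.exon_table
        )


def _no_ag_sequence(rng: np.random.Generator, n: int) -> str:
    """Random intronic filler containing no AG dinucleotide (no stray acceptors)."""
    out: list[str] = []
    while len(out) < n:
        b = "ACGT"[rng.integers(4)]
        if out and out[-1] == "A" and b == "G":
            continue
        out.append(b)
    return "".join(out)


def _reference_cds() -> str:
    """Synthetic 439-codon CDS with the worked example's anchor positions."""
    rng = np.random.default_rng(11)
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    for i in range(1, _N_CODONS + 1):
        while True:
            codon = "".join("ACGT"[j] for j in rng.integers(0, 4, 3))
            if codon not in stops:
                break
        codons.append(codon)
    codons[0] = "ATG"
    codons[374] = "CTC"  # codon 375 ends in C: exon 10 donor context reads CAG|GT
    codons[375] = "AGC"  # Ser376; CDS 1126-1128 = A,G,C with 1127|1128 at the junction
    codons.append("TAA")
    return "".join(codons)


@lru_cache(maxsize=None)
def build_psmc3_fixture() -> LocusFixture:
    cds = _reference_cds()
    exon10 = cds[927:1127]
    exon11 = cds[1127 : 1127 + _EXON11_CASSETTE_NT]

    rng = np.random.default_rng(29)
    pad_a = _no_ag_sequence(rng, 96)
    spacer_b = _no_ag_sequence(rng, 81)
    pad_c = _no_ag_sequence(rng, 84)

    reference_insert = PSEUDOEXON_114NT[:-1] + "A"  # variant base is reference A
    intron = (
        "GTAAGT"  # exon 10 donor
        + pad_a
        + _WEAK_TRACT  # decoy acceptor (pairs into a 215-nt candidate)
        + spacer_b
        + _STRONG_TRACT  # pseudoexon acceptor
        + reference_insert
        + "GTCGAG"  # weak donor context: a site only on the alternate allele
        + pad_c
        + _STRONG_TRACT  # exon 11 acceptor
    )
    cassette = exon10 + intron + exon11

    variant_pos = _EXON10_CASSETTE_NT + 6 + 96 + 20 + 81 + 20 + 114  # c.1127+337
    assert cassette[variant_pos - 1] == "A"
    exon2_start = _EXON10_CASSETTE_NT + len(intron) + 1
    return LocusFixture(
        genomic_sequence=cassette,
        exon_table=(
            (1, _EXON10_CASSETTE_NT),
            (exon2_start, exon2_start + _EXON11_CASSETTE_NT - 1),
        ),
        cds_phase_anchor=CDS_PHASE_ANCHOR,
        insert_sequence=PSEUDOEXON_114NT,
        variant=(variant_pos, "A", "G"),
        reference_cds=cds,
        cassette_cds_start=928,
    )


def write_fixture_fasta(fixture: LocusFixture, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(fixture.genomic_sequence), id="cassette_ref", description="reference allele"),
        SeqRecord(Seq(fixture.alt_sequence), id="cassette_alt", description="alternate allele"),
        SeqRecord(Seq(fixture.reference_cds), id="reference_cds", description="synthetic CDS"),
    ]
    SeqIO.write(records, str(path), "fasta")
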