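"""Splice-site scoring, pseudoexon reconstruction and protein consequence.

A deep-intronic substitution can create a new donor splice site; paired
with a pre-existing intronic acceptor it activates a pseudoexon (cryptic
exon) that is spliced into the mature mRNA. This module detects
variant-created sites with position weight matrices (PWMs), enumerates
candidate pseudoexons, splices them into the coding sequence and
predicts the protein-level outcome (HGVS p. description, ordinal of the
premature stop, average mass of the truncated protein).

Scoring model
-------------
Order-0 PWMs with log2-odds against a uniform base background, estimated
(with a 0.5 pseudocount) from a bundled list of canonical human-like
splice-site examples. Donor sites are scored on the 9-mer spanning
exon positions -3..-1 and intron positions +1..+6 (consensus CAG|GTAAGT);
acceptor sites on the 23-mer spanning intron -20..-1 and exon +1..+3
(polypyrimidine tract + AG). A window lacking the invariant GT (donor)
or AG (acceptor) dinucleotide is not a site at any score; otherwise a
site is called when the summed log-odds reaches the model threshold
(default 0, i.e. better than background).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

# average (isotope-abundance weighted) residue masses in daltons
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}


@dataclass
class SpliceSiteModel:
    """Log-odds weight matrix for donor or acceptor sites."""

    kind: str  # "donor" | "acceptor"
    log_odds: np.ndarray  # (window_length, 4), columns A C G T
    threshold: float = 0.0

    # window geometry: (required dinucleotide indices, required letters,
    # index of the exon-side boundary base)
    _GEOMETRY = {
        "donor": ((3, 4), "GT", 2),  # boundary base = last exonic (-1)
        "acceptor": ((18, 19), "AG", 20),  # boundary base = first exonic (+1)
    }

    def __post_init__(self) -> None:
        if self.kind not in self._GEOMETRY:
            raise ValueError(f"unknown model kind {self.kind!r}")
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        expected = 9 if self.kind == "donor" else 23
        if self.log_odds.shape != (expected, 4):
            raise ValueError(
                f"{self.kind} matrix must be ({expected}, 4), got {self.log_odds.shape}"
            )

    @property
    def window(self) -> int:
        return self.log_odds.shape[0]

    @property
    def required_indices(self) -> tuple[int, int]:
        return self._GEOMETRY[self.kind][0]

    @property
    def required_letters(self) -> str:
        return self._GEOMETRY[self.kind][1]

    @property
    def boundary_index(self) -> int:
        """0-based index, within the window, of the exon-side boundary base."""
        return self._GEOMETRY[self.kind][2]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.log_odds, axis=1))

    @classmethod
    def from_examples(
        cls, kind: str, examples: list[str], threshold: float = 0.0, pseudocount: float = 0.5
    ) -> "SpliceSiteModel":
        """Estimate the matrix from aligned example site sequences."""
        window = 9 if kind == "donor" else 23
        req_idx, req = cls._GEOMETRY[kind][:2]
        counts = np.zeros((window, 4))
        for seq in examples:
            seq = seq.upper()
            if len(seq) != window:
                raise ValueError(f"example {seq!r} is not a {window}-mer")
            if seq[req_idx[0]] != req[0] or seq[req_idx[1]] != req[1]:
                raise ValueError(f"example {seq!r} lacks the invariant {req} dinucleotide")
            for i, b in enumerate(seq):
                counts[i, _BASE_INDEX[b]] += 1
        freqs = (counts + pseudocount) / (len(examples) + 4 * pseudocount)
        return cls(kind=kind, log_odds=np.log2(freqs / 0.25), threshold=threshold)

    def score(self, kmer: str) -> float | None:
        """Summed log-odds, or None (no-site) if the invariant GT/AG is absent."""
        kmer = kmer.upper()
        if len(kmer) != self.window:
            raise ValueError(f"k-mer length {len(kmer)} != model window {self.window}")
        if any(b not in _BASE_INDEX for b in kmer):
            raise ValueError(f"k-mer {kmer!r} contains non-ACGT letters")
        i, j = self.required_indices
        if kmer[i] != self.required_letters[0] or kmer[j] != self.required_letters[1]:
            return None
        return float(sum(self.log_odds[p, _BASE_INDEX[b]] for p, b in enumerate(kmer)))

    def is_site(self, kmer: str) -> bool:
        s = self.score(kmer)
        return s is not None and s >= self.threshold


def score_site(model: SpliceSiteModel, kmer: str) -> float | None:
    return model.score(kmer)


def _read_examples(name: str) -> list[str]:
    text = resources.files("introscreen.data").joinpath(name).read_text()
    return [
        line.strip().upper()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


@lru_cache(maxsize=None)
def default_donor_model(threshold: float = 0.0) -> SpliceSiteModel:
    return SpliceSiteModel.from_examples("donor", _read_examples("donor_sites.txt"), threshold)


@lru_cache(maxsize=None)
def default_acceptor_model(threshold: float = 0.0) -> SpliceSiteModel:
    return SpliceSiteModel.from_examples(
        "acceptor", _read_examples("acceptor_sites.txt"), threshold
    )


# -- created-site scanning ---------------------------------------------------


@dataclass(frozen=True)
class CreatedSite:
    """A window that becomes a splice site on the alternate allele.

    ``position`` is the 1-based cassette coordinate of the exon-side
    boundary base of the site (last exonic base for a donor, first
    exonic base for an acceptor).
    """

    position: int
    ref_score: float | None
    alt_score: float


def scan_created_sites(
    ref_seq: str,
    alt_seq: str,
    variant_pos: int,
    model: SpliceSiteModel,
) -> list[CreatedSite]:
    """Find windows overlapping a substitution that gain a splice site.

    A site is "created" when the alternate window reaches the model
    threshold while the reference window is below it (or lacks the
    invariant dinucleotide altogether).
    """
    if len(ref_seq) != len(alt_seq):
        raise ValueError("ref and alt sequences must have equal length (substitution)")
    diffs = [i for i, (a, b) in enumerate(zip(ref_seq, alt_seq)) if a != b]
    if diffs and diffs != [variant_pos - 1]:
        raise ValueError("sequences must differ only at variant_pos")
    v0 = variant_pos - 1
    w = model.window
    out: list[CreatedSite] = []
    for start in range(max(0, v0 - w + 1), min(v0, len(ref_seq) - w) + 1):
        ref_k = ref_seq[start : start + w]
        alt_k = alt_seq[start : start + w]
        alt_score = model.score(alt_k)
        if alt_score is None or alt_score < model.threshold:
            continue
        ref_score = model.score(ref_k)
        if ref_score is None or ref_score < model.threshold:
            out.append(
                CreatedSite(
                    position=start + model.boundary_index + 1,
                    ref_score=ref_score,
                    alt_score=alt_score,
                )
            )
    return out


# -- pseudoexon enumeration --------------------------------------------------


@dataclass(frozen=True)
class CrypticExon:
    acceptor_pos: int  # 1-based cassette coordinate of first exonic base
    donor_pos: int  # 1-based cassette coordinate of last exonic base
    sequence: str
    acceptor_score: float
    donor_score: float

    @property
    def length(self) -> int:
        return self.donor_pos - self.acceptor_pos + 1


def find_cryptic_exons(
    cassette: str,
    created_donor: CreatedSite | int,
    acceptor_model: SpliceSiteModel,
    *,
    donor_score: float | None = None,
    exons: list[tuple[int, int]] | None = None,
    min_len: int = 30,
    max_len: int = 500,
) -> list[CrypticExon]:
    """Enumerate acceptor sites pairing with a created donor.

    Candidate pseudoexons run from a scoring acceptor's first exonic
    base up to the donor position, with length within [min_len, max_len];
    they are returned sorted by acceptor + donor score, best first.
    """
    if isinstance(created_donor, CreatedSite):
        donor_pos = created_donor.position
        donor_score = created_donor.alt_score if donor_score is None else donor_score
    else:
        donor_pos = int(created_donor)
        donor_score = 0.0 if donor_score is None else donor_score
    if exons is not None and any(a <= donor_pos <= z for a, z in exons):
        raise ValueError(f"created donor at {donor_pos} lies inside an annotated exon")

    out: list[CrypticExon] = []
    for exon_start in range(max(21, donor_pos - max_len + 1), donor_pos - min_len + 2):
        window = cassette[exon_start - 21 : exon_start + 2]
        if len(window) < acceptor_model.window:
            continue
        score = acceptor_model.score(window)
        if score is None or score < acceptor_model.threshold:
            continue
        out.append(
            CrypticExon(
                acceptor_pos=exon_start,
                donor_pos=donor_pos,
                sequence=cassette[exon_start - 1 : donor_pos],
                acceptor_score=score,
                donor_score=donor_score,
            )
        )
    out.sort(key=lambda e: e.acceptor_score + e.donor_score, reverse=True)
    return out


# -- splicing the pseudoexon into the CDS ------------------------------------


def splice_in(
    ref_cds: str, cryptic: CrypticExon | str, cds_anchor: int
) -> tuple[str, str]:
    """Insert a pseudoexon between CDS positions cds_anchor and cds_anchor+1.

    Returns the mutant CDS and the HGVS r.-style description
    (``r.<anchor>_<anchor>+1ins<sequence>``). A zero-length insert is the
    identity and described as ``r.=``.
    """
    insert = cryptic.sequence if isinstance(cryptic, CrypticExon) else cryptic
    if not 0 < cds_anchor <= len(ref_cds):
        raise ValueError(f"cds_anchor {cds_anchor} outside the CDS (length {len(ref_cds)})")
    if not insert:
        return ref_cds, "r.="
    mutant = ref_cds[:cds_anchor] + insert + ref_cds[cds_anchor:]
    return mutant, f"r.{cds_anchor}_{cds_anchor}+1ins{insert}"


# -- protein consequence -----------------------------------------------------


@dataclass(frozen=True)
class ProteinConsequence:
    kind: str  # "frameshift_truncation" | "immediate_stop" | "extension" | "no_change"
    first_changed_residue_index: int  # 1-based, CDS codon numbering
    ref_residue: str
    new_residues: str  # altered residues up to (excluding) the stop
    stop_ordinal: int | None  # stop position counting the first changed residue as 1
    hgvs_p: str
    truncated_mass_da: float | None


def translate(cds: str) -> str:
    """Standard-code translation, stops rendered as '*'."""
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate())


def predict_consequence(
    ref_cds: str, mutant_cds: str, insertion_point: int
) -> ProteinConsequence:
    """Protein outcome of an intra-codon (or codon-boundary) insertion.

    The first potentially changed residue is the codon containing CDS
    position ``insertion_point`` (ceil(insertion_point / 3)); the mutant
    is translated from that codon and the new residue run is reported up
    to the first stop, whose ordinal counts the first changed residue
    as 1 (the HGVS fs*N convention).
    """
    ref_protein = translate(ref_cds)
    if "*" in ref_protein[:-1]:
        raise ValueError("reference CDS contains an internal stop codon")
    idx = math.ceil(insertion_point / 3)
    if not 1 <= idx <= len(ref_protein):
        raise ValueError(f"insertion point {insertion_point} outside the reference CDS")
    ref_aa = ref_protein[idx - 1]
    mutant_protein = translate(mutant_cds)
    tail = mutant_protein[idx - 1 :]

    if tail == ref_protein[idx - 1 :]:
        return ProteinConsequence(
            kind="no_change",
            first_changed_residue_index=idx,
            ref_residue=ref_aa,
            new_residues="",
            stop_ordinal=None,
            hgvs_p="p.(=)",
            truncated_mass_da=None,
        )
    stop_at = tail.find("*")
    if stop_at == -1:
        return ProteinConsequence(
            kind="extension",
            first_changed_residue_index=idx,
            ref_residue=ref_aa,
            new_residues=tail,
            stop_ordinal=None,
            hgvs_p=f"p.({AA3[ref_aa]}{idx}{AA3[tail[0]]}fs*?)",
            truncated_mass_da=None,
        )
    new_residues = tail[:stop_at]
    stop_ordinal = stop_at + 1
    truncated = ref_protein[: idx - 1] + new_residues
    if not new_residues:
        hgvs = f"p.({AA3[ref_aa]}{idx}Ter)"
        kind = "immediate_stop"
    else:
        hgvs = f"p.({AA3[ref_aa]}{idx}{AA3[new_residues[0]]}fs*{stop_ordinal})"
        kind = "frameshift_truncation"
    return ProteinConsequence(
        kind=kind,
        first_changed_residue_index=idx,
        ref_residue=ref_aa,
        new_residues=new_residues,
        stop_ordinal=stop_ordinal,
        hgvs_p=hgvs,
        truncated_mass_da=protein_mass(truncated),
    )


def protein_mass(aa_sequence: str) -> float:
    """Average molecular mass in daltons: residue masses plus one water."""
    total = WATER_MASS
    for aa in aa_sequence.upper():
        try:
            total += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown amino-acid letter {aa!r}") from None
    return total


def consequence_report(
    hgvs_r: str, consequence: ProteinConsequence, exon: CrypticExon
) -> dict:
    """JSON-serialisable summary of a pseudoexon consequence call."""
    return {
        "hgvs_r": hgvs_r,
        "hgvs_p": consequence.hgvs_p,
        "kind": consequence.kind,
        "first_changed_residue_index": consequence.first_changed_residue_index,
        "new_residues": consequence.new_residues,
        "stop_ordinal": consequence.stop_ordinal,
        "truncated_mass_da": consequence.truncated_mass_da,
        "pseudoexon": {
            "acceptor_pos": exon.acceptor_pos,
            "donor_pos": exon.donor_pos,
            "length": exon.length,
            "acceptor_score": exon.acceptor_score,
            "donor_score": exon.donor_score,
        },
    }
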