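"""Weight-matrix scoring, created-site scanning, pseudoexon assembly and
protein consequence, each against an independent oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from introscreen.splice import (
    AVERAGE_RESIDUE_MASS,
    CreatedSite,
    SpliceSiteModel,
    WATER_MASS,
    default_acceptor_model,
    default_donor_model,
    find_cryptic_exons,
    predict_consequence,
    protein_mass,
    scan_created_sites,
    score_site,
    splice_in,
    translate,
)

# independent codon table for the translation oracle
_CODONS = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate((a, b, c) for a in _BASES for b in _BASES for c in _BASES):
    _CODONS[_a + _b + _c] = _AA[_i]


def oracle_translate(cds: str) -> str:
    return "".join(_CODONS[cds[i : i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3))


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# -- score_site --------------------------------------------------------------


def test_consensus_donor_maximises_the_matrix(donor_model):
    consensus = donor_model.consensus
    assert consensus == "CAGGTAAGT"
    best = donor_model.score(consensus)
    for i in range(9):
        for b in "ACGT":
            if b == consensus[i]:
                continue
            mutant = consensus[:i] + b + consensus[i + 1 :]
            s = donor_model.score(mutant)
            if s is not None:
                assert s <= best


def test_missing_invariant_dinucleotide_is_no_site(donor_model, acceptor_model):
    assert score_site(donor_model, "CAGCCAAGT") is None  # CC at +1/+2
    assert score_site(acceptor_model, "T" * 18 + "CC" + "GAA") is None


def test_score_equals_independent_recount_of_bundled_examples(donor_model, rng):
    """Recompute the matrix from the packaged example list with separate code
    and hand-sum the per-position log-odds."""
    from importlib import resources

    lines = [
        l.strip()
        for l in resources.files("introscreen.data").joinpath("donor_sites.txt").read_text().splitlines()
        if l.strip() and not l.startswith("#")
    ]
    n = len(lines)
    for _ in range(50):
        kmer = _random_seq(rng, 3) + "GT" + _random_seq(rng, 4)
        expected = 0.0
        for i, base in enumerate(kmer):
            count = sum(1 for l in lines if l[i] == base)
            expected += math.log2(((count + 0.5) / (n + 2.0)) / 0.25)
        assert donor_model.score(kmer) == pytest.approx(expected)


def test_score_input_validation(donor_model):
    with pytest.raises(ValueError, match="length"):
        donor_model.score("CAGGT")
    with pytest.raises(ValueError, match="ACGT"):
        donor_model.score("CAGGTANGT")


# -- scan_created_sites ------------------------------------------------------


def test_fixture_has_exactly_one_created_donor(fixture, donor_model):
    sites = scan_created_sites(
        fixture.genomic_sequence, fixture.alt_sequence, fixture.variant[0], donor_model
    )
    assert len(sites) == 1
    assert sites[0].position == fixture.variant[0]  # final base of the insert
    assert sites[0].alt_score >= donor_model.threshold
    assert sites[0].ref_score is None or sites[0].ref_score < donor_model.threshold


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.text(alphabet="ACGT", min_size=9, max_size=60), st.data())
def test_null_variant_scan_is_empty(seq, data):
    pos = data.draw(st.integers(1, len(seq)))
    assert scan_created_sites(seq, seq, pos, default_donor_model()) == []


def test_scan_matches_exhaustive_window_scoring(donor_model, rng):
    for _ in range(30):
        n = 120
        ref = _random_seq(rng, n)
        v0 = int(rng.integers(0, n))
        alts = [b for b in "ACGT" if b != ref[v0]]
        alt = ref[:v0] + alts[int(rng.integers(3))] + ref[v0 + 1 :]
        got = scan_created_sites(ref, alt, v0 + 1, donor_model)
        expected = []
        for s in range(n - 9 + 1):
            rs = donor_model.score(ref[s : s + 9])
            as_ = donor_model.score(alt[s : s + 9])
            if as_ is not None and as_ >= donor_model.threshold and (
                rs is None or rs < donor_model.threshold
            ):
                expected.append((s + 3, rs, as_))
        assert [(c.position, c.ref_score, c.alt_score) for c in got] == expected


def test_scan_rejects_multi_substitution():
    with pytest.raises(ValueError):
        scan_created_sites("AAAA", "TTAA", 1, default_donor_model())


# -- find_cryptic_exons ------------------------------------------------------


def test_fixture_top_candidate_is_the_114nt_pseudoexon(fixture, donor_model, acceptor_model):
    sites = scan_created_sites(
        fixture.genomic_sequence, fixture.alt_sequence, fixture.variant[0], donor_model
    )
    exons = find_cryptic_exons(
        fixture.alt_sequence, sites[0], acceptor_model, exons=list(fixture.exon_table)
    )
    assert exons, "no candidate pseudoexon found"
    top = exons[0]
    assert top.length == 114
    assert top.sequence == fixture.insert_sequence
    # the donor can pair with several intronic acceptors; ranking separates them
    assert len(exons) > 1
    scores = [e.acceptor_score + e.donor_score for e in exons]
    assert scores == sorted(scores, reverse=True)


def test_no_qualifying_acceptor_gives_empty_list(acceptor_model):
    cassette = "C" * 400  # no AG anywhere
    donor = CreatedSite(position=390, ref_score=None, alt_score=5.0)
    assert find_cryptic_exons(cassette, donor, acceptor_model) == []


def test_exonic_donor_position_rejected(acceptor_model):
    donor = CreatedSite(position=50, ref_score=None, alt_score=5.0)
    with pytest.raises(ValueError, match="exon"):
        find_cryptic_exons("A" * 200, donor, acceptor_model, exons=[(1, 100)])


def test_candidates_match_pair_enumeration_oracle(acceptor_model, rng):
    """Toy intron with planted acceptor tracts equals brute-force enumeration."""
    tract = "TTTTCTTTCTTTCTTCCCAG"
    filler = lambda n: "".join(
        b for b in _random_seq(rng, 3 * n) if True
    )[:n].replace("AG", "AC")
    cassette = filler(80) + tract + filler(50) + tract + filler(60) + tract + filler(40)
    donor_pos = len(cassette)
    cassette += "A"  # donor boundary base
    donor = CreatedSite(position=donor_pos + 1, ref_score=None, alt_score=4.0)
    got = find_cryptic_exons(cassette, donor, acceptor_model, min_len=30, max_len=300)
    expected = []
    for exon_start in range(max(21, donor.position - 300 + 1), donor.position - 30 + 2):
        window = cassette[exon_start - 21 : exon_start + 2]
        s = acceptor_model.score(window)
        if s is not None and s >= acceptor_model.threshold:
            expected.append((exon_start, s))
    assert sorted((e.acceptor_pos, e.acceptor_score) for e in got) == sorted(expected)
    assert len(got) >= 3


# -- splice_in ---------------------------------------------------------------


def test_fixture_r_description(fixture, donor_model, acceptor_model):
    sites = scan_created_sites(
        fixture.genomic_sequence, fixture.alt_sequence, fixture.variant[0], donor_model
    )
    exon = find_cryptic_exons(
        fixture.alt_sequence, sites[0], acceptor_model, exons=list(fixture.exon_table)
    )[0]
    mutant, hgvs_r = splice_in(fixture.reference_cds, exon, fixture.cds_phase_anchor)
    assert hgvs_r == "r.1127_1127+1ins" + fixture.insert_sequence
    assert len(mutant) == len(fixture.reference_cds) + 114


def test_zero_length_insert_is_identity():
    cds, r = splice_in("ATGAAATAA", "", 3)
    assert cds == "ATGAAATAA" and r == "r.="


def test_splice_in_length_conservation(rng):
    cds = "ATG" + _random_seq(rng, 60) + "TAA"
    ins = _random_seq(rng, 17)
    mutant, _ = splice_in(cds, ins, 10)
    assert len(mutant) == len(cds) + 17
    with pytest.raises(ValueError, match="cds_anchor"):
        splice_in(cds, ins, len(cds) + 1)


# -- predict_consequence -----------------------------------------------------


def test_fixture_consequence(fixture, donor_model, acceptor_model):
    sites = scan_created_sites(
        fixture.genomic_sequence, fixture.alt_sequence, fixture.variant[0], donor_model
    )
    exon = find_cryptic_exons(
        fixture.alt_sequence, sites[0], acceptor_model, exons=list(fixture.exon_table)
    )[0]
    mutant, _ = splice_in(fixture.reference_cds, exon, fixture.cds_phase_anchor)
    pc = predict_consequence(fixture.reference_cds, mutant, fixture.cds_phase_anchor)
    assert pc.kind == "frameshift_truncation"
    assert pc.first_changed_residue_index == 376
    assert pc.ref_residue == "S"
    assert pc.new_residues == "RLHPSSEGTEAGGT"  # Arg then the 13 listed residues
    assert pc.stop_ordinal == 15 == len(pc.new_residues) + 1
    assert pc.hgvs_p == "p.(Ser376Argfs*15)"


def test_insert_creating_immediate_stop():
    ref = "ATGTCCTAA"  # Met Ser stop
    mutant, _ = splice_in(ref, "AAGGG", 4)  # codon 2 becomes TAA
    pc = predict_consequence(ref, mutant, 4)
    assert pc.kind == "immediate_stop"
    assert pc.stop_ordinal == 1 and pc.new_residues == ""
    assert pc.hgvs_p == "p.(Ser2Ter)"


def test_extension_reported_when_no_stop_reached():
    ref = "ATGGAATAA"
    mutant, _ = splice_in(ref, "GC", 4)  # frameshift consumes the stop
    pc = predict_consequence(ref, mutant, 4)
    assert pc.kind == "extension"
    assert pc.stop_ordinal is None
    assert pc.hgvs_p.endswith("fs*?)")


def test_random_inserts_match_codon_table_oracle(rng):
    for _ in range(40):
        n_codons = int(rng.integers(10, 40))
        while True:
            body = _random_seq(rng, 3 * n_codons)
            if "*" not in oracle_translate(body):
                break
        ref = "ATG" + body + "TAA"
        anchor = int(rng.integers(1, len(ref) - 3))
        ins = _random_seq(rng, int(rng.integers(1, 30)))
        mutant, _ = splice_in(ref, ins, anchor)
        pc = predict_consequence(ref, mutant, anchor)
        mut_prot = oracle_translate(mutant)
        idx = math.ceil(anchor / 3)
        tail = mut_prot[idx - 1 :]
        if tail == oracle_translate(ref)[idx - 1 :]:
            assert pc.kind == "no_change"
        elif "*" in tail:
            assert pc.new_residues == tail[: tail.index("*")]
            assert pc.stop_ordinal == tail.index("*") + 1
        else:
            assert pc.kind == "extension"


def test_in_frame_insert_at_codon_boundary_preserves_downstream(rng):
    for _ in range(20):
        ref = "ATG" + _random_seq(rng, 90) + "TAA"
        while "*" in translate(ref)[:-1]:
            ref = "ATG" + _random_seq(rng, 90) + "TAA"
        k = int(rng.integers(1, 30))
        ins = ""
        while len(ins) == 0 or "*" in oracle_translate(ins):
            ins = _random_seq(rng, 3 * int(rng.integers(1, 8)))
        mutant, _ = splice_in(ref, ins, 3 * k)
        ref_prot = translate(ref)
        mut_prot = translate(mutant)
        assert mut_prot[k + len(ins) // 3 :] == ref_prot[k:]


def test_reference_insertion_point_validation():
    with pytest.raises(ValueError, match="internal stop"):
        predict_consequence("ATGTAAAAATAA", "ATGTAAAAATAA", 3)


# -- protein mass ------------------------------------------------------------


def test_glycine_and_empty_peptide_masses():
    assert protein_mass("G") == pytest.approx(75.07, abs=0.01)
    assert protein_mass("") == pytest.approx(18.02, abs=0.01)


def test_mass_matches_biopython_table(rng):
    from Bio.SeqUtils import molecular_weight

    letters = list(AVERAGE_RESIDUE_MASS)
    for _ in range(10):
        seq = "".join(rng.choice(letters, size=50))
        ref = molecular_weight(seq, seq_type="protein", monoisotopic=False)
        assert protein_mass(seq) == pytest.approx(ref, abs=0.5)


def test_unknown_residue_letter_rejected():
    with pytest.raises(ValueError, match="unknown"):
        protein_mass("GAVX")


def test_mass_is_additive():
    assert protein_mass("GAV") == pytest.approx(
        sum(AVERAGE_RESIDUE_MASS[a] for a in "GAV") + WATER_MASS
    )
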