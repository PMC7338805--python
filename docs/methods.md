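# Methods

This note documents the models and numerical choices behind each module,
what the synthetic-data generators emulate (and do not), and the known
limitations.

## Homozygosity mapping (`roh`)

**Model.** In a consanguineous family, an autosomal-recessive locus is
expected to be autozygous — homozygous by descent — in every affected
child, so each affected shows a long run of homozygosity (ROH) over the
locus that unaffected sibs lack.

**Run definition.** A run is a maximal stretch of consecutive array
markers in which every non-missing call is homozygous, at most
`max_missing_in_run` no-calls occur, and at least `min_markers`
homozygous calls are present. Choices, all configurable:

* `min_markers = 25`, boundary-inclusive (a run of exactly 25 qualifies).
  The classical "25 adjacent SNPs" rule on a 250K array corresponds to
  roughly 250 kb, long enough to exclude chance homozygosity at typical
  array heterozygosity (0.7²⁵ ≈ 10⁻⁴ per window).
* `max_missing_in_run = 2`: arrays have ~1 % no-call rates; a no-call
  neither breaks a run nor counts toward its 25 homozygous markers.
  When a het-free stretch holds more no-calls than the budget, all
  maximal sub-windows within budget are enumerated (they may overlap),
  trimmed to their outermost homozygous markers, and de-duplicated.
* A heterozygous call always terminates a run — no het tolerance, the
  strict reading appropriate to autozygosity in a consanguineous design.
* Region boundaries are the outermost homozygous markers, not midpoints
  to the flanking heterozygous calls, so reported coordinates are always
  genotyped positions.

**Shared regions** are the interval intersection of all affecteds' ROH
with any sub-interval overlapping an unaffected individual's ROH
removed; when genotypes are available, each retained piece must keep
≥ `min_markers` homozygous markers in every affected. The caller is
verified against a quadratic brute-force window enumerator, and the
intersector against a per-basepair membership scan.

## Variant prioritization (`prioritize`)

Four filters, applied in the order frequency → segregation → ROH →
consequence. Each filter is a pure predicate on a single variant, so the
filters commute: order changes only the funnel counts, never the final
survivor set (covered by a permutation test).

* **Frequency**: population allele frequency ≤ `max_af` (default 0.01).
  When several database frequencies are annotated upstream, the maximum
  is written to `AF` — presence above 1 % in any one database excludes.
* **Segregation** (homozygous-recessive): every affected homozygous-alt,
  every genotyped parent of an affected heterozygous (obligate carrier),
  no unaffected homozygous-alt. Missing genotypes are non-informative —
  they never fail a variant, which keeps partially genotyped pedigrees
  usable.
* **ROH**: position inside a shared ROH region.
* **Consequence**: UTR, intronic, intergenic, synonymous and near-splice
  variants are dropped *unless* splice scanning (or an upstream
  `SPLICE` annotation) flags a created/strengthened site — the rescue
  that makes deep-intronic discovery possible.

**Interactome step.** Candidate genes are the seed genes (e.g. known
cataract and deafness genes) plus their depth-1 neighbours in a supplied
interaction edge list. Depth-1 is the default because "potentially
interacting" lists are built from direct interactions; deeper expansion
is a parameter (`candidate_gene_set(net, depth=k)`), default off, since
each extra hop dilutes specificity rapidly. Survivors are ranked
splice-flagged first, then by ascending population frequency.

## Splice-site model and pseudoexon reconstruction (`splice`)

**Scoring.** Order-0 position weight matrices with log₂-odds against a
uniform background, estimated with a 0.5 pseudocount from a bundled,
aligned list of 32 canonical-like examples per site type
(`data/donor_sites.txt`, `data/acceptor_sites.txt`; column base
frequencies follow the classical human donor/acceptor frequency tables).
Windows are the conventional donor 9-mer (exon −3..−1 | intron +1..+6,
consensus CAG|GTAAGT) and acceptor 23-mer (intron −20..−1 | exon +1..+3,
polypyrimidine tract + AG). The invariant GT / AG dinucleotide is a hard
requirement — without it a window is "no site" at any score. The default
call threshold is 0 (better than background); it is a model parameter,
not a calibrated cutoff. Full dependency modelling between positions
(maximum-entropy style) is deliberately out of scope: created-site
*detection* needs a sharp reference/alternate contrast at the variant
column, not calibrated site strengths.

**Created sites** are windows overlapping a substitution where the
alternate allele reaches the threshold and the reference allele does not
(or lacks GT/AG). **Pseudoexon candidates** pair a created donor with
every scoring acceptor within [30, 500] nt upstream and are ranked by
summed donor + acceptor score.

**Consequence.** The pseudoexon is inserted between CDS positions
`anchor` and `anchor+1`; translation uses the standard code (Biopython).
The first potentially changed residue is codon ⌈anchor/3⌉; the reported
stop ordinal counts that residue as 1 (the HGVS `fs*N` convention), so
`stop_ordinal = len(new_residues) + 1`. On the packaged fixture this
yields Arg376 + 13 further residues + stop = `p.(Ser376Argfs*15)` — note
that a naive "adds 15 aa" reading over-counts by one: 14 altered
residues precede the stop at ordinal 15. An insertion whose frameshift
never reaches a stop is reported as a distinct `extension` kind.

**Masses** are average (isotope-abundance-weighted) residue masses plus
one water, cross-checked in tests against Biopython's independent table.
Average rather than monoisotopic masses are used because truncated-
protein sizes on blots are average-mass-scale quantities.

## The packaged PSMC3 fixture (`locus`)

The worked example embeds the experimentally determined 114-nt
pseudoexon body in a synthetic cassette:

* A synthetic 439-codon reference CDS pinned at the positions the
  consequence depends on: codon 376 = AGC (so CDS 1126–1127 = A,G end
  exon 10) and no internal stops. The true *PSMC3* exon sequences are
  not bundled; only these anchor constraints matter to the computation.
* Intron 10 places, in order: the exon-10 donor (GTAAGT), AG-free filler,
  a weak decoy acceptor, more filler, a strong polypyrimidine acceptor
  immediately 5′ of the insert, the 114-nt insert whose final base is the
  variant position (reference A, alternate G at cassette position 537 =
  c.1127+337), then a donor context (GTCGAG) chosen so the window scores
  below threshold with the reference A and above it with the alternate
  G, filler, and the exon-11 acceptor.
* Filler sequence is AG-free by construction so the only scoring
  acceptors are the intended ones; the decoy acceptor demonstrates that
  the created donor can pair with multiple acceptors and that ranking
  separates them (the 114-nt candidate scores ~17.6 vs ~7.7).

The fixture's flanks are synthetic constructs, not reconstructions of
the real intron; conclusions about the real locus rest only on the
insert sequence, the anchor geometry and the splice arithmetic.

## Co-IP spectral-count statistics (`coip`)

**Normalization** is strict median-of-ratios: reference proteins are
those detected (count > 0) in every sample; sample j's size factor is
the median over reference proteins of count/geometric-mean. Proteins
with any zero are normalized but never shape the factors (a pseudocount
option exists for matrices with no all-detected protein). The identity
"median ratio of normalized counts = 1 per sample" is asserted in tests,
and factors are cross-checked against an independent implementation.

**Testing.** Per protein: log₂ fold change of group means of normalized
counts with pseudocount 1, and a two-sample t-test on log₂(normalized+1)
with empirical-Bayes variance moderation: per-protein pooled variances
are shrunk toward a common prior fitted by the method of moments on log
variances (a scaled-F model), and the residual degrees of freedom gain
the prior degrees of freedom. At 3-vs-3 replicates a raw per-protein
t-test has 2–4 degrees of freedom and essentially no power after FDR
correction across hundreds of proteins; moderation is the standard
small-replicate remedy and matches the DESeq-flavoured character of the
normalization. A plain Welch test remains available
(`enrich(..., moderate=False)`). BH adjustment is applied across tested
proteins; proteins detected in fewer than 2 samples of the test group
are excluded from testing and reported separately. On simulated null
designs the pooled q<0.05 rate is ~0.0004 (conservative, as expected of
BH with discrete-ish small-sample p-values); planted 4× effects on
20/200 proteins are recovered essentially completely.

**Subcomplex ratios** (20S α = PSMA, 20S β = PSMB, 19S ATPase = PSMC,
19S non-ATPase = PSMD, PA28 = PSME) are patient/control ratios of mean
normalized counts per protein, averaged per subcomplex; proteins with a
zero control mean are excluded from the average. DESeq factors are used
for *all* normalized quantities, including these ratios and the
scatter-style output, for internal consistency.

## Densitometry (`densitometry`)

Lane signal = band sum / stain-free total protein; percent = 100 ×
signal / mean(reference lanes); the statistic is a pooled-variance
Student's t (equal-n blot designs; Welch switchable). Identical
zero-variance groups return p = 1 by convention. The quantity is
invariant to common rescaling of bands and loading, which is asserted.

## Synthetic data (`simulate`): what it emulates and what it does not

* **Array genotypes**: marker positions with exponential spacing (mean
  10 kb, emulating a 250K chip) except inside planted intervals, where a
  regular 10 kb grid guarantees the deterministic marker complement the
  run definition needs; background heterozygosity 0.30; no-call rate
  0.005 (call rate > 99 %). Affected individuals share one homozygous
  allele per marker across planted intervals, as an IBD haplotype would.
  No linkage disequilibrium, allele-frequency structure or genotyping
  error model — passing tests show the *mapping logic* is correct, not
  that real-array artefacts are handled.
* **Variant cohort**: one causal deep-intronic allele inside a planted
  interval (its splice flag set by actually scanning the packaged
  cassette), decoys engineered to fail at each labelled stage
  (frequency > 1 %, broken segregation, outside ROH, outside the
  interactome), and 2,000 background variants by default — a desk-scale
  stand-in for the millions of variants of a real genome; the funnel's
  *shape* (monotone collapse to a handful of candidates, one in the
  interactome) is the tested object, not its absolute counts. A
  background variant that would survive every filter by chance is
  re-drawn to break segregation, so the planted causal is the unique
  survivor by construction.
* **Spectral counts**: negative-binomial with variance μ + αμ²,
  α = 0.05 by default; bait-specific preys are attenuated 8× in
  negative-control IPs; planted fold changes multiply patient-bait
  means. Default design: 3 control IPs, 3 patient IPs, 3 negative
  controls; the planted truth is 1.5× on PSMA, 1.5× on PSMB1/3/5/7,
  2.0× on PSMB2/4/6, and 1.0× on PSMC/PSMD — the 20S-core signature.
  No peptide-level structure, shared-peptide ambiguity or batch effects.

All generators are deterministic given `SimScenario.seed`.

## Degenerate inputs and tie-breaks

* Empty variant sets flow through the cascade as empty results, not
  errors; disabled filters are identities and still appear in funnels.
* Zero-length pseudoexon insertion is the identity (`r.=`).
* Scoring ties in pseudoexon ranking preserve enumeration order
  (upstream-most acceptor first).
* `shared_roh` boundaries come from interval algebra, so a subtraction
  can produce pieces whose edges are not marker positions; the
  marker-recount step prunes pieces too thin to be credible.

## Known limitations

* The splice model is order-0: no branch point, no polypyrimidine-tract
  strength beyond the acceptor window, no splicing-efficiency
  quantification; it detects created sites, it does not rank real ones
  genome-wide.
* The prioritization assumes full-penetrance homozygous recessive
  inheritance; compound heterozygosity and structural variants are out
  of scope.
* Spectral-count enrichment treats counts as given; protein inference
  and PSM-level FDR are upstream concerns.
* The truncated-mass worked example requires the canonical Rpt5
  sequence, which is not bundled (see README).
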