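# Methods

## Scope and data model

`codonscope` analyses a set of validated coding sequences (ORFs) together
with a per-ORF expression matrix over four named culture conditions (G18,
S18, G72, S72). An ORF is accepted when it is at least 300 nt (a floor
that keeps codon statistics stable on short sequences), a multiple of 3,
free of ambiguous bases, and free of in-frame stop codons before the final
codon. A terminal stop is optional — public ORF collections differ on
whether they keep it — but its absence is logged so mixed conventions
surface. Records containing N are rejected outright rather than having
N-codons skipped, which keeps every downstream count an exact function of
the sequence. All codon-level reporting uses the RNA alphabet (AUG, GCU,
…); DNA FASTA input is transliterated on ingestion.

## Expression grouping

RPKM = 10⁹·C/(N·L). Four grouping schemes stratify ORFs: per-condition
value (EC), highest value across the four conditions (HV), average value
(AV), and the ribosomal reference set (R), which overrides the numbered
bins. Ribosomal membership is caller-supplied (a flags TSV or id set); a
helper matches "ribosomal" in free-text annotations for convenience, since
the set is a curation decision, not something derivable from expression.

The printed integer bin labels (1–30, 31–70, 71–100, 101–999, ≥1000) are
realised as half-open real intervals [1,31), [31,71), [71,101), [101,1000),
[1000,∞): RPKM is continuous and every value ≥ 1 must land in exactly one
bin. ORFs whose statistic is below 1 RPKM are left unassigned (and logged)
rather than forced into the lowest bin. The coarse summary (1–30 / 31–100 /
>100) uses the same convention, so ">100" is exactly the union of the
101–999 and ≥1000 fine bins; summary percentages are reported over assigned
ORFs by default, with an "all" denominator switch because the treatment of
sub-1-RPKM ORFs in a denominator is a reporting choice, not a fact.
Fold-change bins (1–2, 2.1–5, 5.1–10, 10.1–50, >50) are upper-inclusive —
(2,5] etc. — matching their decimal labels. Argmax/argmin condition labels
break ties by the fixed condition order G18, S18, G72, S72.

## RSCU

RSCU_ij = x_ij·n_i/Σ_j x_ij on counts pooled over the whole group
(concatenation, not a per-gene average), the dataset-level convention of
CodonW. Stop codons are treated as a three-codon TER family and included;
start codons are counted (they only affect Met, whose RSCU is identically
1). Both choices are switchable by excluding codons from the input counts.
A family with zero total has *undefined* (NaN) RSCU, never 0, so that ratio
maps over small groups cannot manufacture spurious dissimilarity. Ratio
maps flag codons with RSCU ratio in [0.9, 1.1] as similar; the display
classes ("most common" = family argmax including ties, "less frequent" =
RSCU < 0.5, else "intermediate") are a reporting convention — the 0.5
cutoff is a package choice with no statistical content.

## 3′ codon context

Adjacent in-frame codon pairs within each ORF (an ORF of k codons yields
k−1 ordered pairs; pairs never span ORFs) fill a 64×64 contingency table
with the 5′ codon on rows. The first codon participates only as a 5′
member and the terminal stop only as a 3′ member; stop-containing pairs are
counted by default with a switch to exclude them. Expected counts use the
independence model e_pq = row_p·col_q/N, and each cell is scored by the
adjusted residual r = (o−e)/√(e(1−p)(1−q)), which is approximately N(0,1)
under independence. Cells with e = 0 are undefined (NaN) and excluded from
calls. The significance rule is the plain two-sided band: |r| ≤ 3 is
"no bias", r > 3 "preferred", r < −3 "avoided", with no multiplicity
correction — a Bonferroni-adjusted threshold helper (≈ 4.4 for 4096 cells
at α = 0.05) and a Pearson-residual mode ((o−e)/√e) are provided for
sensitivity analysis but are off by default. Top-k rankings break residual
ties lexicographically on (5′ codon, 3′ codon). Differential maps compare
two groups cell-wise as Δr = r_a − r_b with |Δr| ≤ 3 flagged similar; this
treats the two residuals as independent unit-variance scores and is a
display heuristic, not a formal two-sample test. Residuals are stored at
full precision and only rounded in report output.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume —
in-frame ORF sets with controllable codon usage and pair coupling, plus
four-condition expression with controllable fold-changes — not any real
genome. Each ORF starts AUG, ends with a stop drawn from the TER frequency
vector, and draws internal codons from a first-order Markov chain: the base
emission is amino_acid_frequencies × within-family codon_frequencies
(uniform by default), and the transition weight into codon q from codon p
is multiplied by an optional coupling factor for (p,q) and renormalised.
First-order generation was chosen over i.i.d. precisely so pair coupling is
expressible; with an empty coupling map the chain *is* i.i.d., which the
null-calibration tests rely on (and which the implementation exploits as a
vectorised fast path). Coupling may target a stop at the 3′ position (it
is applied when the terminal stop is drawn) but never a stop at 5′, since
internal stops cannot occur.

GC% targeting tilts each synonymous family's frequencies by exp(t·gc(c))
with a single parameter t solved numerically (Brent) so the expected GC of
internal codons matches the target; start/stop codons are ignored in the
solve as a negligible share of a ≥100-codon ORF. Exact per-sequence GC
matching is out of scope. Unreachable targets raise rather than clamp.

Lengths are a discretised log-normal over codon counts (default median 400
codons, log-sd 0.35, floor 100 codons = 300 nt) or fixed. Expression is
rpkm = base × multiplier × noise with base = 10^N(2.6, 0.5) — putting
~88% of ORFs above 100 RPKM, the "mostly highly expressed" regime the
analyses are aimed at — per-ORF per-condition log-normal multipliers with
σ = 0.5 (typical max/min fold-changes in the 2–5× range), and log-normal
noise with σ = 0.1, small enough that bin assignments are stable at
default sizes. Fixed per-condition multipliers can replace the random ones
to force a deterministic fold-change structure. All draws flow from a
single integer seed; a fixed seed reproduces FASTA and TSV outputs byte for
byte.

What the generator does **not** emulate: real amino-acid composition,
genome-scale GC heterogeneity, correlated expression between conditions,
read-level sampling noise (RPKM is drawn directly, not from simulated
reads), intron structure, or viral genome composition. Tests passing on
synthetic data therefore validate the statistics and their calibration, not
claims about any particular organism.

## Numerical and calibration choices

- Adjusted residuals are validated against a loop-level computation from
  the definition on random 6×6 tables at 1e-10 relative tolerance, and the
  independence expectations against `scipy.stats.contingency.expected_freq`.
- Null calibration: on i.i.d. synthetic codons at ≥10⁶ pairs, the fraction
  of cells with |r| > 3 is asserted below 2% — far above the Gaussian
  0.27% to absorb count discreteness and the mild dependence introduced by
  overlapping pairs and the fixed start codon.
- Power: a single pair enriched ×2 in the generator must exceed r = +3 at
  ≥10⁵ pairs, with a compensating negative residual elsewhere in its 5′ row.
- Parameter recovery: RSCU recovers n·p of the generating frequencies
  within 0.05 absolute at ≥10⁵ codons per family. At smaller sizes the
  tolerance scales with the estimator's sampling sd (a 6-codon family at
  ~8×10⁴ total codons has sd ≈ 0.025 per codon, so unit tests at that size
  use a 4-sd bound).
- GC rounding for GC-bins is half-away-from-zero to the nearest integer
  percent; fold-change and expression bin edges are as above; ties
  everywhere break on fixed lexicographic or condition order so reruns are
  deterministic.
- Report problem sizes: the test suite exercises the calibration
  properties at 10⁶ pairs / 2×10⁶ codons, which keeps the full suite under
  a minute on one CPU while leaving every asserted bound several sd wide.

## Known limitations

- The ±3 band treats each cell marginally; with 4096 cells it implies a
  nonzero family-wise false-positive count by design (the published
  convention it follows). Use the Bonferroni helper when a family-wise
  guarantee matters.
- Differential maps difference two residuals without pooling their
  variances; near-empty groups produce noisy deltas, mitigated only by the
  undefined-cell propagation.
- RSCU on very small groups is dominated by sampling noise; the package
  reports counts alongside RSCU so users can judge support, but applies no
  shrinkage.
- Expression handling assumes the four fixed condition labels; generalising
  the condition set would touch the grouping schemes and display labels.
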