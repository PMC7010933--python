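# Methods

## Promoter definition and extraction

A gene's promoter is the up-to-2,000 bp of sequence immediately
upstream of the first base of its start codon, read 5'→3' on the coding
strand. The anchor is the CDS start (the ATG), not an experimentally
defined TSS; genes whose representative CDS does not begin with ATG are
excluded from analysis, and promoters running off a contig edge keep
whatever upstream sequence exists. When a gene has several mRNAs the
representative transcript is the one with the longest total CDS, ties
broken by the lexicographically smallest transcript ID — the choice is
arbitrary but must be deterministic. Internally all coordinates are
0-based half-open; GFF3 is read 1-based inclusive and BED is written
0-based half-open. Non-ACGT characters are uppercased to `N`; `N`
matches at the unconstrained pentamer positions and counts as a
mismatch at constrained ones.

## Scanner semantics

Each alternation frame of a promoter (5 phases × 2 starting
orientations) is walked in 5-bp slots; a slot either matches its
expected pentamer with 0 or 1 deviations at positions 2–4, or breaks
the run. Within each break-free stretch, the scanner enumerates every
*maximal* interval carrying at most one total mismatch, applies the
three-subunit key rule, and emits each surviving interval once. Two
policies matter and are deliberate:

* **Longest-first maximality** (default). A window is never reported
  if an admissible window in the same frame properly contains it —
  extension that spends the mismatch budget is always taken. Two
  overlapping maximal runs in the same frame (budget exhausted at
  opposite ends) are both reported. `exact-only` mode instead reports
  every admissible window.
* **Cap at 8 subunits.** Observed HSEs range over 3–8 subunits; a
  longer perfect run is reported once, capped at 8 subunits anchored at
  the run's 5' end (if the capped window excludes the run's single
  mismatch, the reported HSE is typical).

A key-position mismatch is classified gapped wherever it occurs; for
3-subunit runs the admission rules force it into the middle subunit, so
the classical "middle subunit" definition and the key⇒gapped rule
coincide there. For longer runs a terminal key mismatch is still
gapped — the trichotomy (typical/gapped/varied) then partitions every
admitted HSE.

Promoters are scanned on the coding strand only: the motif family is
closed under reverse complement (revcomp of `nGAAn` is `nTTCn`), so a
second pass would duplicate every match. The test suite asserts this
duality explicitly.

The brute-force oracle used in tests re-derives the same output by
enumerating every window at every offset and orientation by direct
string comparison, then filtering by explicit pairwise containment; it
shares no code path with the production scanner beyond the emit record.

## Response calling and MFH

A (gene, organ) pair is heat-responsive when any of the five stress
time points (5, 10, 30 min, 1 h, 4 h) shows fold change ≥ 2.0 with
FDR-adjusted p < 0.05 (the FC bound inclusive, the p bound strict). By
default fold change enters as the directional magnitude max(FC, 1/FC),
so two-fold repression also qualifies; `direction="up"` restricts to
induction. The response magnitude MFH is the maximal (directional)
fold change over the five time points, z-standardized within the
organ's responsive set — so MFH is a *relative* magnitude, invariant to
affine rescaling of the maxima, with mean 0 and sd 1 per organ by
construction. Standardization is undefined for fewer than two
responsive genes or zero spread; both raise errors rather than return
NaN. BH adjustment is provided for tables carrying raw p; tables that
already carry adjusted p are used as-is.

## Statistical battery

* **Contingency**: Pearson chi-squared without continuity correction on
  the class × {responsive, non-responsive} table.
* **MANOVA**: (position, subunit count) as dependent variables against
  response status, Pillai's trace with the standard F approximation
  (robust default among the four classical statistics); univariate
  one-way F per variable is reported alongside. Exactly-zero
  between-group scatter is returned as F = 0, p = 1.
* **ANCOVA**: `mfh ~ factor + position`, with nested-model F tests for
  the factor and the position slope.
* **Position convention**: bp upstream of the ATG measured to the HSE's
  3' end, always positive; "closer to the start codon" = smaller value.
  A negative slope/correlation therefore means proximal HSEs confer
  larger magnitudes.
* **Mismatch groups**: labels like `G 2-3` (first subunit `nGAAn`,
  mismatch in subunit 2 at pentamer position 3). Group contrasts are
  one-way ANCOVAs of each group pooled with the typical baseline,
  restricted to 3-subunit HSEs so subunit-number effects cannot
  confound the comparison.
* **Pairwise nucleotide comparison**: contrasts on the covariate-
  adjusted level means of `mfh ~ C(base) + position` (the position
  covariate is included in the comparison model), adjusted single-step
  Tukey via the studentized range (Tukey–Kramer for unbalanced groups;
  `bonferroni`/`holm` available). The compact letter display assigns
  one letter per maximal clique of the non-significance graph, so two
  groups share a letter iff they are not significantly different at
  0.05.

Significance conventions: 0.05 (*) and 0.01 (**).

## GO enrichment

Hypergeometric upper tail P(X ≥ k) per term, BH across all tested
terms, retention at q < 0.01, fold enrichment (k/n)/(K/N). The default
universe is the annotated gene set of the supplied term map; no
propagation up the GO graph is performed — the map is used as provided.
Ties are broken by q, then p, then term id for deterministic output.

## Synthetic data: what it emulates and what it does not

`simulate_genome` lays genes out in cassettes (promoter, ATG-initiated
CDS, spacer) round-robin over three wheat-style chromosomes
(`chr1A/1B/1D`), alternating strands, and plants at most one HSE per
promoter at a uniform position. Defaults: 2 kb promoters, class mix
5% typical / 25% gapped / 70% varied and a sharply decreasing
subunit-count distribution (55/25/11/5/3/1% for k = 3..8), mirroring
the heavily non-canonical composition and the decreasing subunit
histogram seen in real promoter scans. Background sequence is uniform
ACGT; at that composition a 2 kb promoter spontaneously contains a
matching HSE reasonably often, so the ledger is always re-verified by
rescanning (`rescan_n`, `rescan_exact`) rather than assumed.
`motif_free_background=True` rejection-samples promoters until the
planted HSE is the scanner's only match — used for strict recovery
tests.

`simulate_expression` draws the response flag from
Bernoulli(logistic(baseline + class offset + position slope · position
+ subunit offset)) with a null effect structure by default and baseline
log-odds −2.2 (≈ 10% responsive, the order of magnitude of leaf-scale
response rates). The log2 maximal fold change is Normal(2.0 + effect
terms, 0.6) truncated below at 1, exponentiated; 20% of responsive
genes are down-regulated (entering as the reciprocal). The DE table is
then written to respect the calling thresholds exactly: the peak time
point carries the maximal fold change with adjusted p < 0.05, all other
values stay strictly inside (1/2, 2) — so threshold calling recovers
the true flags exactly, and recovery tests are sharp. Effect sizes
used in power experiments: +1.0 log-odds for the typical class at
20,000 genes (contingency), a log2-scale position slope of
−0.00015/bp at n = 1,000 — chosen to realize a position–magnitude
correlation near −0.15, the magnitude reported at study scale — and a
+0.5 sd magnitude boost for one mismatch group at ≈ 200 genes/group.
Magnitude-model experiments set the baseline log-odds high so that all
genes are responsive, since the magnitude model is only defined on the
responsive set.

What the generator does **not** emulate: linkage between the three
subgenomes (homoeologous triplets), realistic GC content or repeat
structure, multiple HSEs per promoter, p-value/fold-change correlation
structure from a real DE caller, or count-level noise. Passing tests
therefore demonstrate correctness of the scanning, classification,
calling, and inference machinery under the stated generative model —
not robustness to annotation errors or DE-caller artifacts in real
data.

## Numerical choices and scale

Adjusted p-values in the generator are written directly (DE calling
from reads is upstream of this pipeline). OLS fits in the contrast
machinery use plain least squares with rank checks (collinear designs
raise). Calibration experiments use 1,000 replicates at 2,000 genes
(the null rejection band checked is 5% ± 2%); power experiments use
100 replicates at the sizes above; the acceptance script uses 500/50
replicates for the same quantities. Planted-HSE recovery runs 1,000
plants cycling through every class × subunit-count combination in
clean-background 2 kb promoters, and scanner/oracle equivalence uses
200 random 1 kb sequences. These sizes make the whole suite run in a
few minutes on one core while keeping Monte-Carlo error well inside
every asserted band.

## Known limitations

* The "middle subunit" gapped definition is generalized to key⇒gapped
  for runs longer than three subunits; a scanner that classifies
  terminal key mismatches as varied would shift gapped/varied counts.
* Overlapping HSEs in different alternation frames are all reported;
  reporting policies that deduplicate across frames would lower totals.
* MFH compares magnitudes only within an organ's responsive set;
  cross-organ magnitude comparisons are not meaningful under this
  standardization.
* The GO module treats terms as flat sets; enrichment of parent terms
  via the ontology graph is out of scope.
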