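# Methods

## The procedure

`spongenet` models the standard circRNA-centred ceRNA workflow as a fixed
sequence of operations over three classes of evidence:

1. **Differential-expression screening.**  Each RNA class (circRNA, miRNA,
   mRNA) is screened with |log₂FC| ≥ 1 and *p* < 0.05.  The fold-change
   threshold is read on the log₂ scale (fold ≥ 2 or ≤ 0.5): every record in
   the packaged reference tables satisfies |log₂FC| ≥ 1.03, whereas a
   literal linear |FC| ≥ 1 would exclude nothing, so the log₂ reading is the
   only one consistent with the tables.  The ≥ on fold change and strict <
   on *p* are kept exactly as stated.  Raw *p*-values are thresholded by
   default; a Benjamini–Hochberg mode exists but is off, matching the
   single-study convention of screening on unadjusted *p* at n = 3.
2. **Sponge-network construction.**  Predicted circRNA–miRNA edges for the
   screened circRNAs form an undirected bipartite graph; miRNA nodes are
   then intersected with the DE miRNAs.  circRNA nodes are kept even when
   isolated so the loss is reportable.
3. **Centrality and hub selection.**  Degree, betweenness and closeness are
   computed on the DE-restricted graph (networkx: Brandes betweenness with
   2/((n−1)(n−2)) pair normalisation; Wasserman–Faust closeness, which
   scales by the reachable fraction and is well defined on disconnected
   graphs; isolated nodes score 0 on both).  *Key miRNAs* are miRNA nodes
   with degree strictly greater than 3× the median — the median is taken
   over miRNA-node degrees only, since miRNAs are the selection population;
   a flag switches to all-node degrees.  *Hub circRNAs* are the top k
   (default 5) by the mean of their betweenness-rank and closeness-rank
   (average ranks on ties; ties broken by higher degree, then id).  A
   user-supplied exclusion list removes literature-known candidates from
   eligibility; that curation is never inferred automatically.
4. **Triad assembly.**  Hub-circRNA edges to DE miRNAs are expanded through
   the consensus miRNA→mRNA map.  A triad is retained when its mRNA is DE
   with direction opposite to the miRNA (the ceRNA expectation: sponge and
   target move together, opposite the shared miRNA).  circRNA–miRNA
   opposition is recorded but *not* required by default — validated sponge
   tables contain same-direction pairs (4 of the 6 packaged interactions
   are opposite, 2 are not) — and a strict mode enforces it.  The exported
   network keeps all consensus target mRNAs, including non-DE ones; only
   triad statistics are restricted to DE mRNAs.  The per-miRNA target sets
   are merged by union for the export, with the per-miRNA map retained.

## Seed-match target prediction

The predictor stands in for database lookups and uses only canonical seed
pairing.  On a target read 5′→3′, the 6mer core is the reverse complement
of miRNA positions 2–7; 7mer-m8 adds pairing at position 8 (one nt 5′ of
the core on the target), 7mer-A1 adds an adenosine opposite position 1 (one
nt 3′ of the core), and 8mer has both.  U and T are interchangeable;
ambiguity codes are rejected.  Coordinates are 0-based half-open on the
target as stored.  Circular targets are additionally scanned across the
back-splice junction (the last 7 nt joined to the first 7); a
junction-spanning site keeps linearised coordinates, so its end may exceed
the sequence length.

Duplex scoring is deliberately minimal: a seed-type weight
(8mer 4 > 7mer-m8 3 > 7mer-A1 2 > 6mer 1) plus one point per Watson–Crick
pair between miRNA positions 13–16 and the antiparallel-aligned target
flank.  No conservation, context, or free-energy terms — those belong to
the external databases this package does not reproduce.

Two deterministic evidence sources emulate a two-database consensus: a
site-count call (≥ `min_sites`, default 1) and a score call (best duplex
score ≥ `min_score`, default 2.0 — the 7mer-A1 weight, i.e. anything
stronger than a bare 6mer; the threshold is exposed because no principled
default exists).  miRNA→mRNA edges use **intersection** of the two sources
(consensus of two predictors); circRNA→miRNA edges default to **union**
(sponge discovery favours sensitivity).  Both are configurable.

## The two-group test

For simulated counts the per-feature test is a two-sided, pooled-variance
Student *t*-test on log₂(count + 0.5), with
log₂FC = log₂((mean_case + 0.5)/(mean_control + 0.5)).  The pseudocount
stabilises zeros; pooling mirrors the shared-variance assumption of
standard RNA-seq GLMs.  The Welch–Satterthwaite alternative was measured
and rejected: at n = 3 per group its effective df can fall to 2, giving an
empirical type-I error of ≈ 0.033 at nominal 0.05 on the null simulation,
while the pooled test is calibrated (≈ 0.048–0.053 across seeds).  A
feature that is all-zero, or constant-and-equal, in both groups is reported
as (log₂FC = 0, p = 1).  Screening of externally computed DE tables — the
usual analysis path — bypasses this test entirely.  No normalisation
factors, shrinkage, or multi-factor designs are attempted.

## Synthetic-data generator

The generator emulates the two-group study design: n = 3 samples per group
per class.  Counts are negative-binomial with variance μ + φμ² around
per-feature baselines `baseline_mean · 2^N(0,1)` (log-normal jitter, sd 1 on
the log₂ scale — a conventional marginal model for sequencing counts).
Defaults: baseline mean 500, dispersion φ = 0.1, planted effects
|log₂FC| = 2 for 20 features per class, 10 planted triads, 150/100/400
features per class.  Feature counts are scaled well below a
whole-transcriptome survey so simulation-heavy tests stay fast while
leaving enough null features (≥ 85% per class) to measure false-positive
behaviour.  φ = 0 falls back to Poisson.

Planted triads are direction-consistent by construction: the circRNA and
mRNA share a direction drawn uniformly at random, the miRNA opposes it —
the dominant pattern among validated sponge pairs.  One exact 8mer site per
planted (miRNA, target) pair is written into both the circRNA and the mRNA
sequence at a recorded coordinate; miRNA seed cores are kept mutually
distinct so planted sites are attributable.  Background is uniform random
sequence.  Because chance 6mer matches are common (≈ (L−5)·4⁻⁶ per pair),
the generator by default *scrubs* them: it rescans all pairs, mutates one
base inside each unplanted site, and repeats until clean (≤ 25 rounds).  A
chance site overlapping a planted region cannot be mutated without
destroying the planted signal; such survivors are recorded in the ground
truth as `chance_sites`, so tests can reason about them exactly.  The Ct
generator draws reference-gene CTs from Normal(20, 0.2) per sample and
offsets each target gene by a constant plus −log₂FC in case samples, so the
expected 2^−ΔΔCT equals the planted fold; measurement noise (default sd
0.25, the order of typical technical replicate scatter) is added on top.

One integer seed governs everything: `simulate_all` threads a single
generator stream through counts → sequences → Ct table in that order;
stage functions called standalone derive their own stream from the seed.

What the generator does **not** emulate: library-size differences between
samples, count correlation structure, GC/length biases, isoform overlap,
non-canonical (seedless or bulged) miRNA binding, and amplification-
efficiency variation in qPCR.  Passing recovery tests therefore show the
pipeline's logic is sound under its own model assumptions, not that the
screening thresholds have any particular operating characteristics on real
sequencing data.

## Recovery benchmark

With the default configuration, 50 replicate simulations give pooled
screening sensitivity ≈ 0.95 and precision ≈ 0.94 (pooled over the three
classes: total true positives over total planted, and over total called),
and mean planted-triad recall ≈ 0.91, where a triad counts as recovered
when its circRNA and miRNA survive screening and both of its edges are
predicted — the condition for appearing in the exported ceRNA network,
which retains non-DE target mRNAs.  The acceptance surface asserts
sensitivity ≥ 0.7, precision ≥ 0.9 and recall ≥ 0.8.

## qPCR quantification

ΔCT = CT(gene) − CT(reference) per sample; the calibrator is the **mean
control-group ΔCT** (not a designated calibrator sample), so control ΔΔCT
averages exactly 0 and the geometric mean of control folds is exactly 1.
Fold = 2^−ΔΔCT.  Reference genes travel as data (GAPDH for circRNA/mRNA,
U6 for miRNA in the synthetic tables), never hard-coded.  Group comparison
is a two-sided equal-variance Student *t*-test, on folds by default (as
typically plotted) with a ΔCT mode available, since which scale was tested
is often unstated in publications.  No amplification-efficiency (Pfaffl)
correction.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) for k query genes in a term of size K, n query genes, universe N,
with BH correction applied within each namespace (BP/MF/CC/pathway),
mirroring per-panel top-10 reporting.  The universe defaults to the union
of all annotation-set members because no background list is generally
given; query genes outside the universe are dropped with a warning and the
effective n is reported.  No GO-graph propagation and no live database
queries; reproducing any specific published term list is out of scope
(database-version dependent).

## Numerical and degenerate-input choices

* Table parsing uses round-trip float precision, so written and re-read
  tables are bit-identical; GraphML/edge-TSV round-trips are exact,
  SIF (which has no attribute slots) recovers node classes from the
  interaction labels.
* log₂FC = 0 is rejected as directionless at the record level and silently
  dropped by the matrix-level test wrapper (such a feature can never be
  called DE).
* Median of an even-length degree list is the mean of the middle two; the
  key-miRNA rule uses strict >, so "all degrees equal" selects nothing.
* Hub ranking ties: average rank positions, then higher degree, then
  lexicographic id — fully deterministic.
* `hub_top_k=None` ranks every eligible circRNA; recovery benchmarks use it
  because hub ranking is a reporting choice, not part of planted-signal
  recovery.
* Degenerate t-tests (zero variance in both groups) return p = 1 when the
  group means are equal and p ≈ 0 otherwise, rather than NaN.

## Known limitations

* The seed-match predictor is a transparent stand-in, not a re-derivation
  of any database's scores; consensus behaviour, not score values, is the
  tested contract.
* The two-group test is a log-scale t-test, not a negative-binomial GLM;
  at very low counts its power profile differs from dedicated DE tools.
* Centrality-based hub selection inherits the usual caveats of small,
  star-like bipartite graphs: closeness and betweenness are nearly
  collinear there, and ranks can be tie-heavy.
* The enrichment module assumes flat, disjoint annotation namespaces.
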