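# Methods

## The matching model

`ligrec` treats cell–cell communication inference as set intersection with
expression evidence. Inputs are (i) a curated pair database — gene pairs
(A, B) with optional role annotations (receptor / ligand / adhesion) — and
(ii) two gene-level expression profiles, a *population* and a *stroma*,
assumed RMA-normalized on the linear scale with P/M/A detection calls.

For every database pair and both orientations (A on the population side, B on
the stroma side, and vice versa), a row is emitted when:

1. the population-side gene passes the population's differential-expression
   gate (see below), or the gate is bypassed for presence-only matching;
2. the population-side gene is *present* in the population profile;
3. the stroma-side gene is *present* in the stroma profile.

The population side carries both the gate and the presence requirement; the
stroma side needs presence only. This asymmetry encodes the screening logic:
the gate selects genes that distinguish the population from the stroma (so a
stromal growth factor is not also made by the target cell), while the stromal
side is taken as expressed-or-not. Pairs satisfying both sides in both
orientations are emitted twice and flagged as autocrine candidates rather
than suppressed — the gate, not the matcher, is the place to exclude them.

Rows are keyed uniquely on (population gene, stroma gene, direction) and
sorted by (stroma symbol, population symbol, direction), so output files are
byte-deterministic and diffable. Direction is derived from role annotations
when both are informative; otherwise rows are labelled `adhesion_pair`.

### Gene keys

The canonical gene key is the numeric Entrez (locus link) identifier as a
string; when a record carries only a symbol, the case-folded symbol is the
key (logged at debug level). Case-folding matters in practice: printed gene
names vary in capitalisation between tables ("Integrin alpha 4" vs "integrin
alpha 4"), and the fold makes them one gene.

## Differential-expression gate

Tests run on log2(intensity + 1); the pseudo-count keeps near-zero linear
values finite. Defaults: Welch t, alpha 0.01, no multiple-testing
correction — the gate is a screen, not an inference, and its nominal level is
part of the method. A Benjamini–Hochberg switch exists but is off.
Within-group variances are floored at 1e-8 so replicate-identical groups do
not divide by zero.

The alternative `moderated_t` shrinks per-gene pooled variances toward a
scaled inverse-chi-square prior fitted by method of moments on log(s²)
(digamma/trigamma inversion, Newton iteration); the posterior-variance t uses
d0 + d_resid degrees of freedom. At 2–3 replicates this buys power and
protects against freak tiny variances; the test suite checks both the
shrinkage behaviour and agreement of the Welch path with an independent
implementation.

Profiles built from printed per-gene means have one "replicate"; replicate
tests refuse them with an instructive error and the fold-change-only gate
(`fold_change_gate`, ratio in either direction ≥ min_fold, denominators
floored at 1.0, p recorded as 1.0) stands in.

## Probe-set aggregation and presence

Expression tables are probe-set level. Default aggregation is `max_mean`:
the probe set with the largest mean intensity represents the gene (its
replicate values and calls carry over); `mean_of_means` is available. A gene
is *present* when its representing probe set is called P in at least one
replicate — the most permissive reading of presence-in-at-least-one, and the
one used throughout; a config switch requires P in all replicates. Marginal
(M) calls count as absent by default.

## Stage dynamics

Pairs are keyed unordered and direction-collapsed for staging: the question
"is this pair used at every stage?" is about the partners, not about which
cell carries the receptor. A pair is *ubiquitous* iff its occurrence set
equals the full series; everything else is *restricted* — the only split the
data support without an arbitrary k-of-n cutoff. The default series (LT-HSC,
MPP, LMPP, CLP, GMP, proB, preB, matureB) is flattened although the true
lineage branches at GMP; the transition report is therefore only computed
along a user-declared linear path.

## Candidate screen

For each stroma-side gene of a matched table: nominate iff supportive
intensity ≥ min_intensity and supportive / max(non-supportive, 1.0) ≥
min_fold. Defaults min_fold = 5, min_intensity = 100 sit well below the
contrasts of the positive controls in the bundled data (CXCL12 ≈ 531×,
BMP4 ≈ 20×) while excluding ~2× differences such as IL-7 — the screen finds
stroma-*distinguishing* factors, not every biologically important one. A
single fold threshold covers both the "exclusively expressed" and the
"expressed to a higher level" cases; no separate presence dichotomy is
applied. Candidates are ranked by descending fold, ties broken by symbol.

## Co-culture response filter and ΔΔCt

The response filter retains genes with max(level across the two conditions) >
min_level (default 100), fold ≥ min_fold (default 5, floored denominators)
and, when both profiles have ≥ 2 replicates, Welch p < alpha (default 0.05).
Applying the level rule to the *maximum* keeps strongly induced genes that
start near zero; the p clause is skipped with a logged notice for
single-replicate inputs.

ΔΔCt = (Ct_goi − Ct_ref)_control − (Ct_goi − Ct_ref)_sample; fold = 2^ΔΔCt.
Each gene-of-interest Ct is normalized against the reference gene (HPRT by
default) measured in the *same* cDNA — the standard reading where the
notation leaves the reference's sample subscript implicit. Identity
(all-equal Cts → fold exactly 1), antisymmetry (swapping sample and control
inverts the fold) and strict monotonicity in each Ct follow from the formula
and are property-tested.

## Synthetic data

The generator emulates a small two-population microarray experiment:
per-gene log2 means ~ N(7, 1) (linear ≈ 128), replicate noise N(0, 0.5) on
the log2 scale, 3 replicate arrays, detection threshold 50 linear units,
planted effect +5 log2 units (32-fold). Each planted pair boosts its
population partner in the population only (making it differentially
expressed) and its stroma partner in the stroma only; each decoy pair has one
partner forced ~4 log2 units below the detection threshold in *both*
profiles, so it cannot match in either orientation and ground truth is exact
by construction rather than statistical. Calls follow the threshold rule,
optionally flipped at a configurable rate. Everything is reproducible from a
single integer seed (NumPy default_rng).

Because pairs draw distinct genes, the generator requires 2·n_pairs ≤
n_genes. What the simulation does *not* emulate: probe-level structure,
batch effects, correlated genes, or intensity-dependent variance — passing
recovery tests therefore certifies the pipeline's logic (gating, presence,
orientation handling), not robustness to real-array artifacts.

Default study conditions for recovery runs: 200 genes, 40 pairs, 20 planted,
20 seeds — small enough to run in seconds on one CPU, large enough that mean
recall and false-discovery proportion are stable to well under the 0.95/0.05
acceptance bounds.

## Bundled reference data

`ligrec/data/interaction_tables.tsv` transcribes the interaction tables of
eight hematopoietic populations against OP9 stroma with NIH3T3/osteoblast
comparators (117 rows, 37 distinct pairs). Two facts shape the API: the
printed stroma-side intensity of a few genes differs between tables (e.g.
BMPR1A 497 vs 327), so stroma and comparator profiles are constructed *per
population table* and never merged; and the tables print no replicates, so
matching them runs presence-only (the printed rows are already the product of
the original differential-expression selection). Role annotations in the
derived pair database are standard biology for these well-characterised
partners and affect only the direction label; the one ambiguous partner
("Similar to Ornithine decarboxylase") is annotated unknown.

## Numerical conventions

* Intensities stay linear end-to-end; only tests transform to log2(x+1).
* All ratio denominators are floored at 1.0 linear units.
* Ties in fold-change direction (log2FC = 0) are labelled up_in_population.
* TSV writers render integral floats as integers so printed tables round-trip
  byte-for-byte; readers accept `#` comment headers.

## Known limitations

* A curated pair database bounds sensitivity: pathways absent from it are
  invisible, and the bundled 37-pair database is a reconstruction of the
  printed tables, not a full curation (~400 pairs in the original resource).
* Presence calls and the DE gate are hard thresholds; no expression-magnitude
  interaction score is computed beyond reporting intensities.
* The restricted/ubiquitous split is binary by design; with noisy inputs a
  single missed call flips a pair to restricted.
* The moderated t approximates the full linear-model treatment (no design
  matrices, contrasts, or array weights).
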