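# Methods

## Problem and model

The package classifies matched molecular pairs (MMPs) into activity cliffs
(AC, ΔpKi > 2 log units) and non-cliffs (ΔpKi < 1); pairs in the ambiguous
band [1, 2] are discarded everywhere.  The thresholds are read as strict
inequalities, so deltas of exactly 1.0 or 2.0 are ambiguous; on real potency
data exact boundary values are vanishingly rare, so this choice is
inconsequential in practice but makes the partition unambiguous.

The classifier is a C-SVM over a precomputed Gram matrix of the MMP kernel,
the product of core-wise and substituent-wise Tanimoto kernels on binary
substructure fingerprints.  The decision convention is
`f(x) = sign(Σ αᵢyᵢ K(svᵢ, x) − b)`; the backing solver
(`sklearn.svm.SVC(kernel="precomputed")`) reports an intercept with the
opposite sign, reconciled at fit time so that the stored `bias_` is the `b`
of this convention.

## Fragmentation and pair generation

Single cuts only: every acyclic single bond between two heavy atoms is a
candidate; each cut yields core/substituent orientations whose substituent
has 1–13 heavy atoms.  Bare-hydrogen substituents are not enumerated
(an H fragment carries no substructure features, and heavy-atom counting
governs all size rules).  The attachment point is a mapped dummy atom
(`[*:1]`) kept in canonical fragment SMILES, so cores differing only in
attachment position stay distinct, and reattachment (`rdkit.Chem.molzip`)
reconstructs the parent exactly — a property-checked invariant.

Pair constraints: each substituent ≤ 13 heavy atoms, substituent difference
≤ 8 heavy atoms, substituents distinct as canonical strings.  When a
compound pair shares several valid cores, exactly one MMP is retained — the
maximum-heavy-atom core, ties broken by the lexicographically smallest core
string.  Retaining all fragmentations would let the same compound pair
appear in several matched molecular series and leak compounds across the
series-wise train/test split; the maximum-core rule is the smallest-surprise
deduplication and both size bounds are configurable.

Series (MMS) are the partition of MMPs by core; series containing only one
class are dropped since they contribute nothing to either side of a
discriminative evaluation.

## Fingerprints

Features are unfolded Morgan environment identifiers of bond radius 1 and 2
(bond diameters 2 and 4).  Radius-0 (atom-type) features are excluded so
that every feature describes a multi-atom environment whose contribution can
be meaningfully drawn on the structure.  Identifiers are sorted ascending
and assigned consecutive bits per segment — no folding, hence no bit
collisions within a universe; identifier-level 32-bit hash collisions are
accepted as in standard ECFP practice.  Presence (not count) semantics
throughout: the XOR/AND construction and the Tanimoto kernel operate on
sets.  The attachment dummy participates in environments, making substituent
features attachment-aware.

The substituent segment concatenates an XOR channel (features in exactly one
substituent) and an AND channel (features in both), sharing one sorted
identifier table with distinct offsets.  Both channels are symmetric under
swapping the substituents, so the fingerprint is invariant to pair
orientation.

Kernels are evaluated directly on identifier sets rather than on
materialized bit vectors.  This is algebraically identical to the vector
formula over the union universe and has one practical consequence handled
explicitly: a test-only feature (unseen in training) enlarges the test
instance's self-similarity denominator but can never overlap a support
vector, so it depresses the kernel without ever receiving a contribution.
Such features are tracked and reported (`MMPFingerprint.unmapped`,
explanation `remainder`), never silently dropped.

Degenerate inputs: an empty feature segment is legal (warned); the
empty-vs-anything Tanimoto case, including 0/0, is defined as 0 —
similarity is not asserted from the absence of evidence.

## Training and evaluation

`C` is selected from a grid (default {0.01, 0.1, 1, 10, 100, 1000}) by
stratified 5-fold cross-validation maximizing MCC, ties going to the
smaller (more regularized) C; folds shuffle under the run seed, so training
is deterministic given (data, grid, seed).  When a class has fewer members
than folds the search is skipped and the grid midpoint is used with a
warning.  MCC is the selection metric because it is the headline evaluation
statistic and is robust to the class imbalance typical of cliff data.

Series-wise leave-one-out: each MMS in turn is the test set; test MMPs
containing any compound present in a training MMP are eliminated; the
feature universe and the model are rebuilt per fold from training data
only.  Metrics (recall and ROC AUC on raw decision values with AC positive,
MCC) are computed on predictions pooled over folds.  MCC is defined as 0
when a confusion-matrix margin vanishes; AUC is NaN if the pooled truth is
single-class.

## Exact decomposition

For the plain Tanimoto kernel, the denominator of each kernel evaluation is
a constant of that (support vector, instance) pair, so the kernel splits
into one additive term per shared feature.  For the product kernel the
expansion produces cross-terms over shared (core, substituent) feature
pairs; each cross-term is split 50/50 between its two features, per support
vector, before aggregation.  The split ratio never varies, so aggregation
order does not affect per-feature values.  The bias is reported separately
and never spread over features (it is instance-independent).  Exactness —
Σ contributions − b = decision value — is enforced in tests at 1e−9
relative tolerance and holds at machine precision.

A consequence worth knowing: when every pair shares an identical core
(core factor ≡ 1), the per-feature substituent contributions are exactly
half of the plain-Tanimoto contributions on the substituent segment — the
other half sits on the shared core features; the totals agree.

Atom/bond mapping: a feature's contribution is divided evenly over the
atom and bond slots of all its recorded environment occurrences (duplicate
occurrences count separately) and accumulated across overlapping features.
AND-channel features occur in both substituent fragments; their contribution
is first halved between the two fragments, then spread within each — the
even split is a package choice where no canonical apportionment exists.
Conservation (mapped weights + remainder = contribution total) is exact by
construction and asserted at 1e−9 relative.

Depictions normalize weights by the maximum absolute atom/bond weight per
MMP; positive weights render warm (orange-red by default), negative cool
(blue), zero white.  Color names are configurable constants.

## Kernel SHAP control

The control explainer implements standard Kernel SHAP: coalition vectors
over presence/absence bits, the Shapley kernel weight
`(N−1)/(C(N,z)·z·(N−z))`, off-coalition bits replaced by background
(training fingerprint) values with the model output averaged over the
background, baseline φ₀ = mean decision value over the background, and a
weighted least squares with the empty/full coalitions as hard constraints
(sum of φ equals the explained output minus φ₀ exactly).  Coalitions are
enumerated exhaustively when `2^N − 2 ≤ K` (K default 2048), else sampled
proportionally to the kernel weight; sampling requires `K ≥ N + 2`.  The
feature space for an MMP explanation is the union of instance and
support-vector features, deterministically ordered and capped (default 64,
instance features kept preferentially, warned).  N, K, the background and
the cap are explicit knobs; under sampling the values are estimates, not
exact Shapley values.

## Synthetic data

The planted-cliff generator emulates the label structure of a lead-
optimization SAR table: `n_series` scaffolds (default 8, drawn from a
built-in list of drug-like ring systems with one marked attachment point),
`series_size` analogs each (default 6) decorated with substituents from a
neutral pool plus one potency-boosting substituent (tert-butyl by default).
Potency is `base + delta_strong·[cliff sub] + N(0, sigma)` with defaults
base 6.0, delta_strong 2.5, sigma 0.15; the constraint
`delta_strong > 2 + 3σ` keeps planted pairs above the cliff threshold with
near-certainty.  Generation is byte-deterministic under the seed.

What it does *not* emulate: real potency distributions, assay noise
structure, chemical diversity, or series of uneven size.  Passing the
recovery benchmark shows the pipeline can learn and explain a
transformation-driven cliff signal under clean conditions; it says nothing
about performance on curated bioactivity extracts, which flow through the
same entry points (`read_compound_table` with a column mapping) but are not
benchmarked here.

Note that single-cut fragmentation on these series also produces
cross-series MMPs whose "core" is a shared substituent and whose exchanged
fragments are the two scaffolds; these are chemically legitimate and are
kept.  They make the generated MMP count (~400–500 at the defaults)
considerably larger than the within-series pair count alone.

## Benchmark sizes and determinism

The end-to-end recovery benchmark (`mmpcliff.benchmark`) uses the generator
defaults (8 series × 6 analogs, ≈470 MMPs after labeling), a reduced C grid
{0.1, 1, 10, 100} and 25 seeded runs; each run fits one model per
leave-one-out fold plus one per explained series, about 1.5 s per run.  All
randomness in an entry point derives from a single integer seed; feature
extraction is cached (pure in the canonical fragment SMILES), which changes
no results.

## Known limitations

- Identifier hash collisions (32-bit) can merge unrelated environments;
  unfolded sorted assignment removes only universe-level collisions.
- One MMP per compound pair discards alternative fragmentations that a
  transformation-centric analysis might want.
- No probability calibration, class weighting, applicability-domain
  scoring, or multi-cut cores.
- The SHAP explainer is a reference implementation tuned for correctness
  (exhaustive where feasible), not for large-N throughput.
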