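# Methods

## Problem and data model

Each observation is one pre-miRNA hairpin with one or more annotated
mature products and a binary label (1 = essential: knockout shows an
abnormal phenotype; 0 = non-essential). Sequences are normalised to the
RNA alphabet on input (uppercase, T→U); records containing N are
excluded from feature extraction with a warning. All coordinates are
0-based, half-open. Matures are attached to precursors by exact id
match, then by case-insensitive stem match with the mir/miR token and
arm suffixes (-5p/-3p/*) stripped, then — because hairpin copies such as
mir-1a-1/mir-1a-2 share mature names — with a trailing "-digits" copy
suffix stripped from the precursor stem; a mature matching several
copies is attached to all of them.

## Feature set

38 features per record, in three blocks (canonical order in
`miress.features.FEATURE_NAMES`):

1. *Legacy block (14)* — U/C/G contents of precursor, mature and
   non-mature regions; mature and non-mature lengths; MFE and
   nMFE = MFE/L; cleavage-site class. The cleavage site is taken as the
   5′-terminal base of each mature (Drosha/Dicer cleave immediately 5′ of
   the mature): class 1 when every mature starts with U, −1 when none
   does, 0 otherwise. With several matures, mature-derived features use
   the 5′→3′ concatenation of the located windows, so every record maps
   to one fixed-length vector. For inexactly-located matures the
   precursor window (not the annotated string) is used.
2. *Dinucleotide block (18)* — frequencies of the nine A-free pairs SZ,
   S,Z ∈ {U,C,G}, in the precursor and in the mature concatenation. The
   denominator is L−1, i.e. all overlapping windows count, including
   windows containing A; only the nine A-free pairs are reported, so the
   block sums to ≤ 1.
3. *Structure block (6)* — from one fold of the precursor:
   P = N_bp/L (pairs in the MFE structure), Shannon entropy
   Q = −(1/L) Σ_{i<j} p_ij log₂ p_ij (0·log 0 := 0), expected pair
   distance D = (1/L) Σ_{i<j} p_ij (1 − p_ij), and nP, nQ, nD dividing
   each once more by L. P, Q, D are already per-length statistics; the
   n-variants implement the additional "divided by its length" reading,
   the only one consistent with both variants being listed side by side.

Mature location is leftmost exact substring match, falling back to the
leftmost maximal-identity ungapped window, accepted only at identity
≥ 0.9; mature intervals may not overlap.

## Folding backends

`simple` (default in tests) is a deliberately minimal, exactly checkable
model: admissible pairs are Watson–Crick plus G·U wobble, every pair
contributes energy −1, unpaired bases 0, hairpin loops enclose ≥ 3
bases, no pseudoknots, Boltzmann factor e^(−E) at unit temperature. MFE
is computed by interval dynamic programming; co-optimal traceback ties
resolve toward the pair with the smallest 5′ index, then the smallest 3′
index, making the structure deterministic. Pair probabilities come from
the exact inside/outside partition-function recursion; the outside pass
conditions on the innermost enclosing pair, giving exact Boltzmann
marginals (verified to < 1e−9 against full structure enumeration; the
enumeration oracle itself lives in `miress.folding.exhaustive_oracle`
and is quadratic-exponential, capped at 26 nt by default).

`turner` adapts ViennaRNA (nearest-neighbour parameters, 37 °C,
default model settings) behind the same `FoldResult` interface and is
the backend to use when mirroring thermodynamic MFE/P/Q/D statistics on
real pre-miRNAs. The folding temperature and parameter set of the
original benchmark numbers are not documented anywhere we know of, so
ViennaRNA defaults are the assumed reproduction setting.

## Learner

Newton (second-order) boosting of binary regression trees on the
logistic loss, implemented from scratch in `miress.gbm`:

* round t computes g_i = p_i − y_i, h_i = p_i(1 − p_i) at the current
  raw scores (base score 0);
* one tree is grown depth-first; each node runs an exact greedy split
  search over every feature and every midpoint between consecutive
  distinct sorted values, maximising the regularized gain
  ½[G_L²/(H_L+λ) + G_R²/(H_R+λ) − (G_L+G_R)²/(H_L+H_R+λ)] − γ, subject
  to both children holding summed Hessian ≥ `min_child_hessian`; no
  split with non-positive gain is accepted;
* leaves take w* = −G/(H+λ); raw scores advance by η·w.

Ties in the split search resolve to the lowest feature index, then the
lowest threshold, so training is bit-for-bit deterministic; the `seed`
hyperparameter is reserved for subsampling variants and unused on the
default path (no row/column subsampling). Thresholds are midpoints
clamped to the lower value when floating-point rounding would make the
midpoint collide with the upper value, keeping the routed partition
identical to the prefix the gain was computed for.

Defaults are the settings the method was tuned to: γ = 0, λ = 1.0,
K = 6 (max depth), T = 1000 rounds. The learning rate of the original
experiments is unstated; η = 0.3, the conventional default of this model
family, is used and configurable. Gain-based importance sums each
feature's accepted split gains over all trees and normalises to 1.
Models serialize to versioned JSON and round-trip exactly.

## Evaluation protocol

Stratified k-fold (default k = 5): within each class, indices are
shuffled by the seed and dealt round-robin, so per-class fold sizes
differ by at most 1. The protocol repeats the whole partition
`repeats` times (default 50) with seed + r for repeat r. Metrics per
repeat are computed on the pooled held-out scores of that repeat (one
ROC per repeat) and then averaged; whether the original protocol pooled
or averaged per-fold is unstated, and pooling was chosen because a
single 154-sample benchmark gives ~15-sample folds whose individual
ROCs are noisy. Per-fold metrics are also reported. AUC is the
rank-sum statistic with midranks for ties (identical to trapezoidal ROC
area); ACC/precision/recall/F use threshold 0.5, with F = 2PR/(P+R) and
F = 0 when P + R = 0. `scan` grid-evaluates exactly one of
{γ, λ, K, T} while the others stay at their defaults.

## Synthetic data

The generator emulates the benchmark's geometry: by default 77 + 77
records, stems of 24–30 bp, loops of 4–12 nt, matures of 20–23 nt — a
~52–72 nt precursor, the small end of real pre-miRNA sizes, chosen so
partition-function folding of whole datasets stays cheap. The 3′ arm is
the reverse complement of the 5′ arm with a 5% per-base mismatch rate
(real stems are imperfect); the mature is an exact substring of one arm.
Class signal enters only through two knobs: GC probability of arm bases
(0.8 essential vs 0.4 non-essential by default) and the probability that
the mature's first base is forced to U (0.9 vs 0.1), i.e. through the
composition/MFE-linked features and the cleavage-site class — the
feature groups the gain-importance analysis is expected to surface.
`null_spec` sets both knobs equal (GC 0.5, U-start 0.25), making the
labels exactly uninformative.

What the simulation does *not* emulate: miRBase-like sequence motifs,
conservation, expression, multi-mature hairpins, bulge/loop geometry
beyond random mismatches. Passing the planted-signal tests therefore
shows that the pipeline recovers class signal that is present in its
feature space — not that real essentiality is this easy; on the real
benchmark the published numbers sit near AUC 0.91, far from the ~0.99 of
the strong-signal simulation.

## Numerical and design choices

* Built-in folding uses e as the per-pair Boltzmann weight; partition
  sums for ≤ ~120 nt stay far below double-precision overflow.
* Q uses log base 2; empty structure ⇒ all structure features 0.
* Degenerate feature inputs: an empty non-mature region scores length 0
  and contents 0; dinucleotide frequencies require length ≥ 2.
* `max_depth = 0` is allowed and yields a single-leaf tree whose weight
  is the closed form at the root — useful for verifying the leaf-weight
  formula in isolation.
* Label files are TSV or CSV, auto-detected, optional header;
  duplicate ids and labels outside {0, 1} are errors.
* CV aggregates report mean and standard deviation over repeats.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` size their computations to
what the verification needs: oracle equivalence on 200 random 8–26 nt
sequences; split-search brute-force equivalence on 50 random fixtures
(N ≤ 200, d ≤ 10); pipeline recovery on 77+77-record datasets with
30–100 boosting rounds of depth-3–6 trees and 5–10 CV repeats, which
keeps each run in seconds-to-minutes while leaving the full
T = 1000 × 50-repeat protocol available through configuration.

## Known limitations

* The `simple` energy model is for verification and simulation, not for
  thermodynamic realism; use `turner` for real sequences.
* Exact greedy split search is O(n·d·log n) per node and targets
  hundreds-of-samples benchmarks, not large-scale data; there is no
  histogram approximation, missing-value handling, or multiclass
  objective.
* The fuzzy mature locator is ungapped; matures that align to their
  precursor only with indels are rejected.
* Feature importance is gain-based only; correlated features (e.g. the
  composition block) share credit in ways that depend on tie-breaking.
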