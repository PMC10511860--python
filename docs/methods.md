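# Methods

## Model

`ntfcv` approximates a third-order non-negative tensor
X ∈ ℝ^{I×J×K}_{≥0} (e.g., subjects × symptoms × days of adverse-event
severity scores) by a rank-R CANDECOMP/PARAFAC (CP) model

    X[i,j,k] ≈ Σ_{r=1..R} A[i,r] · B[j,r] · C[k,r],   A, B, C ≥ 0,

with factor matrices A (I×R, subject loadings), B (J×R, symptom
loadings), C (K×R, temporal profiles). No separate component-weight
vector is kept: component scale stays absorbed in the factor columns,
exactly as multiplicative-update solvers emit them, and columns are not
reordered or normalized before reporting — any normalization is a
presentation choice left to the user.

Missing data are carried as an element-wise binary weight tensor W
(1 = observed, 0 = missing); values at weight-0 cells are NaN sentinels
and never enter any objective or metric.

## Fitting with element-wise weights

The solver minimizes the weighted least-squares objective
f(A,B,C) = Σ_{w=1} (X − X̂)² by an EM / multiplicative-update scheme.
Each outer iteration:

1. **E step** — fill unweighted cells with the current reconstruction:
   X_fill = W∘X + (1−W)∘X̂.
2. **M step** — one Lee–Seung multiplicative update per mode on the
   filled (fully observed) tensor, e.g. for mode 1
   A ← A ∘ [X_fill(1)(C⊙B)] / [A((CᵀC)∗(BᵀB)) + ε],
   where X_fill(1) is the mode-1 unfolding, ⊙ the Khatri–Rao product and
   ∗ the Hadamard product (the Gram form of the denominator is
   algebraically equal to A(C⊙B)ᵀ(C⊙B) but cheaper).

Because the filled objective majorizes the masked objective (they agree
at the current iterate and differ by a non-negative term on unweighted
cells), every iteration is guaranteed not to increase f; the test suite
verifies this to 1e-9 relative slack on random instances. Factors stay
non-negative by construction.

Numerical choices:

- ε = 1e-12 is added to denominators only; numerators are left exact so
  that exact zeros remain fixed points.
- Convergence is declared when |f_t − f_{t−1}| / max(f_{t−1}, ε) < tol,
  with tol = 1e-8 by default and a cap of n_iter_max = 1000 iterations.
  `FitResult.n_iter_used` and `converged` let users detect cap-limited
  runs.
- Initial factors are i.i.d. uniform(0,1), drawn from a generator seeded
  per (rank, trial), so grids are reproducible and independent of
  execution order (serial and parallel runs agree exactly).
- Cells missing from the data and cells hidden for cross-validation are
  treated identically during fitting (both imputed), but data-missing
  cells are never counted in any reported error.

## Rank selection by masked cross-validation

For each CV trial, floor(ratio/100 × n_observed) observed cells are
drawn uniformly without replacement and their fit weight set to 0. Each
candidate rank in [rank_min, rank_max] is fitted on the remaining cells
and scored by the **test error** — the MSE of the reconstruction on the
hidden cells; the **reconstruction error** (MSE over all observed
cells) is recorded alongside for elbow-style inspection. The selected
rank minimizes the *median* test error over trials; ties break toward
the smaller rank (parsimony). The median of an even number of trials is
the midpoint of the two central order statistics.

Design choices made where the procedure was genuinely open:

- **One mask per trial, shared across ranks.** Each trial's mask is
  drawn once and reused for every rank, making the between-rank
  comparison paired and reducing its Monte-Carlo variance. An
  independent mask per (rank, trial) would leave the selection rule
  unchanged in expectation.
- **Floor for the mask size**, so the requested masking percentage is
  never exceeded.
- ratio > 40% warns (masking that much tends to blur local structure
  and underestimate the rank) and ratio = 0 warns (nothing is held
  out, so CV degenerates); neither is an error.
- The final reported model is refitted *without* any CV mask (all
  observed cells carry weight 1), over the same number of random
  restarts; the restart with the smallest reconstruction error is kept.
  Masked fits serve rank selection only.

When rank_min == rank_max the CV scan is skipped entirely and the
decomposition runs directly at that rank; with a single-rank grid both
modes agree.

The grid costs O(R·T·I_iter) fits; `cores` parallelizes grid cells with
identical results to a serial run.

## Data ingestion

Three spreadsheet layouts map onto the (subject, symptom, day) tensor:
wide (one column per day-label + symptom-name concatenation), tidy
long (one row per observation; subjects ordered by sorted unique ID),
and one-sheet-per-day. Wide-layout columns are matched by *exact*
concatenated name rather than substring containment — a deliberate
tightening that prevents a symptom name that prefixes another (e.g.
"pain" / "pain2") from matching multiple columns. The same toy dataset
expressed in all three layouts yields bit-identical tensors.

The subject-completeness filter keeps subject i iff its missing-cell
count is **strictly below** max_missing_fraction × J × K (default
0.3). The fraction is exposed as a parameter because the filter can be
read in two directions (drop subjects with under 30% observed vs. keep
subjects with under 30% missing); the default implements the latter,
and users can reproduce either reading.

Tensors interchange as .npy files of float64 with NaN encoding missing
cells; loading rejects non-3-dimensional arrays and any finite negative
entry (with a message naming the negative-element problem), before any
fitting starts.

## Synthetic data generator

`synthetic.generate` plants a ground-truth CP model with i.i.d.
uniform(0,1) factor entries, adds Gaussian noise scaled to a fraction
σ of the signal root-mean-square, clips at zero to preserve
non-negativity, and knocks out a fixed fraction of cells — uniformly at
random, or whole-subject blocks to exercise the completeness filter.
Defaults used throughout the tests and the acceptance script emulate a
mid-sized adverse-event study: dims (40, 12, 14) — 40 subjects, 12
symptoms, 7 days after each of 2 doses — planted rank 3, σ = 0.05,
10% missing. These sizes keep a full CV grid scan (ranks 1–6, 10
trials) to roughly twenty seconds while remaining large enough for the
planted rank to be identifiable.

What the generator does *not* emulate: the empirical marginals of real
severity scores (integer scales, zero inflation), correlated symptom
co-occurrence beyond what low rank induces, or informative (non-random)
missingness. Passing recovery tests therefore demonstrate that the
estimator finds planted low-rank structure under benign noise, not that
any particular real dataset is low-rank.

## Known limitations

- The multiplicative-update solver converges linearly at best and can
  stall near zero entries; random restarts (`trials`) are the intended
  mitigation, as in the original workflow.
- Only third-order dense tensors are supported; no sparsity
  regularization, no Tucker models, no beta-divergence objectives.
- CP factors are identifiable only up to permutation and scaling of
  components; tests assert reconstruction quality, never factor-wise
  equality to the planted truth.
- The test-error curve is typically flat above the true rank, so the
  median over few trials can tip to a neighboring rank on small or very
  noisy tensors; the defaults (10+ trials, ≤30% masking) keep this rare
  in the regimes exercised here.
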