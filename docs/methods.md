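# Methods

## Signal model

The experiment is an inversion-recovery/CPMG sequence: a 180° inversion,
a variable recovery time t1, then an echo train read out at multiples of
the echo time. For a set of discrete relaxation reservoirs k with
fractions A_k summing to 1, the noiseless signal is

    M(t1_i, t2_j) = Σ_k A_k (1 − 2β e^(−t1_i/T1_k)) e^(−t2_j/T2_k)

with inversion efficiency β = 1 by default (a perfect 180° pulse; real
hardware needs β < 1, exposed as `efficiency`). Noise is i.i.d. Gaussian
per (t1, echo) point after averaging, in units of the equilibrium
magnetization. The default `noise_sd = 0.002` corresponds to peak-signal
SNR 500, a realistic figure for a benchtop magnet after four averages;
the standard acquisition is echo time 200 µs, 2000 or 4000 echoes and 32
logarithmic t1 steps. The t1 ladder spans 1–3000 ms so that the
zero-crossing t1 = T1·ln 2 of every modelled reservoir (T1 between
2.4 and 640 ms) falls strictly inside it.

## Phenotype presets

Presets carry the published reservoir coordinates of packed red blood
cells: three (T1, T2) peaks per state — bulk water R, hydration layer S,
protein-bound water T — for the oxygenated, oxidized, deoxygenated,
wild-type, HbE, HbD and rare beta-thalassemia states. The oxidized state
additionally carries a "relaxation tail" from (T1 = 50.3, T2 = 1.34) ms
down to (2.43, 0.78) ms, realized as 8 equal-amplitude sub-components
log-linearly interpolated between the anchors; this reproduces the
stretched protein-bound T1 distribution caused by distance-dependent
paramagnetic relaxation around ferric iron.

Signal fractions are not part of the published decomposition, so they
are a modelling choice, fixed once: **R = 0.70, S = 0.20, T = 0.10**
(oxidized: R = 0.70, S = 0.20, T-residue = 0.06, tail = 0.04). The
rationale is compositional: packed cells hold roughly 33 g/dL hemoglobin
binding ~0.3–0.4 g water per g protein, so hydration-layer water is tens
of percent of the water signal, not a trace. The choice also matters
numerically: with hydration/bound fractions of only a few percent the
regularized inversion cannot separate the S and T reservoirs at any
smoothing weight (their misfit contribution is quadratic in the
amplitude), whereas at 0.20/0.10 all three reservoirs resolve. Amplitudes
are overridable per preset (`preset_phenotype(name, amplitudes=...)`).

Several printed A-ratio table entries do not follow from their own
T1/T2 pair under half-up rounding (deoxygenated R: 4.54 computed vs 4.53
printed; HbE S: 79.38 vs 79.39; HbD T: 80.25 at two decimals vs the
printed integer 80). Presets always store the raw relaxation times and
never force a printed ratio; the tests pin both values.

## Cohort generator

The default cohort emulates a 32-subject study: 10 wild type
(non-disease), 8 oxidized and 6 partially oxidized (disease), and 8
variants (3 HbE, 3 HbD, 2 rare beta-thalassemia). Every subject derives
a stable seed from the global seed and its subject id (CRC32 hashing, so
cohorts extend without reshuffling), jitters every preset parameter by a
multiplicative log-normal factor (σ = 5%), and simulates one decay
matrix at SNR 500 with 2000 echoes. Partial oxidation scales the tail
amplitude by a uniform factor in (0.2, 0.8), giving a subtype gradient:
the protein-bound T1 stretch grows from ≈ 0.5 decades (wild type)
through ≈ 0.6–0.9 (partial) to ≥ 1.3 (fully oxidized).

What the generator does **not** emulate: hematocrit and cell-packing
variation, plasma compartments, chemical-exchange kinetics between
reservoirs, B0/B1 inhomogeneity, receiver drift, or structured (non-white)
noise. Passing tests therefore demonstrate correctness of the analysis
chain under the stated signal model, not robustness to every artifact of
bench data.

## Inversion

The map F ≥ 0 on a 100×100 log grid (T1 ∈ [1, 10⁴] ms, T2 ∈ [0.05, 10³]
ms — enclosing every preset coordinate with margin) minimizes

    ‖M − K1 F K2ᵀ‖²_F + α ‖F‖²_F ,   F ≥ 0

with K1, K2 the inversion-recovery and echo-decay kernels. The smoothing
weight is the zeroth-order Tikhonov form (a norm penalty, the common
choice in FISTA-based inversion tools), default α = 1 with 5000
iterations.

Both kernels are compressed by truncated SVD at 1e-4 of the leading
singular value (numerical ranks ~15 at the default sizes); the data are
projected onto the retained singular directions, which preserves the
objective up to truncation error.

The solver is an accelerated projected-gradient (FISTA) iteration from a
zero start with Nesterov momentum restarted whenever the objective would
rise, making the objective trace monotone. Two step rules are available:

- `diagonal` (default): a per-cell majorizer
  D_pq = 2 (Σ_p'|K1ᵀK1|_pp' · Σ_q'|K2ᵀK2|_qq' + α), the Gershgorin
  row-sum bound of the Kronecker-structured Hessian. The non-negativity
  projection is unchanged under a diagonal metric.
- `scalar`: the classical 1/L step with L = 2((σ1σ2)² + α).

The diagonal rule exists because the exponential kernels are severely
ill-conditioned: with the scalar step, 5000 iterations leave the
low-singular-value structure (the small protein-bound peak) several grid
cells from its converged position, while the diagonal step localizes it
within a cell. On problems small enough for a dense active-set QP solve,
both rules reach the constrained optimum to 1e-6 relative objective.

Stopping at 5000 iterations is part of the method definition, not an
approximation to be removed: like all iterative regularization, the
not-fully-converged solution is slightly sharper than the α = 1 fixed
point and recovers peak positions marginally better.

## Peak analysis

Local maxima above 2% of the global maximum are merged when closer than
3 cells (Chebyshev; larger apex wins); above-threshold cells are
assigned to apexes by steepest ascent; regions smaller than 2 cells are
dropped as inversion speckle, as are regions whose T1/T2 falls below 0.5
— relaxation physics requires T1 ≥ T2 for this sequence, and the only
structures that far below the diagonal are grid-edge artifacts of the
inversion. The reported coordinate is the apex with parabolic sub-cell
refinement in log space (amplitude-weighted centroids over the full
region or its above-half-max core are available via `centroid=`; they
skew toward the shoulders that neighbouring reservoirs imprint on a
region and are less accurate here). R is the largest-volume peak (volume
ties break toward larger T2), T the smallest-T2 peak of the rest, S the
intermediate.

The tail metric measures, within the protein-bound T2 window (default
0.3–3 ms), the T1 span in decades of the contiguous above-threshold row
run containing the band maximum; rows whose full-row maximum lies
outside the window (shoulders of higher-T2 reservoirs) are excluded from
anchoring the scale. Contiguity matters: the tail is physically a
connected stretch originating at the T-peak, and a disconnected
grid-edge ripple must not inflate the span.

Measured resolution at the default settings (noiseless): R and S peaks
recover within ~0.5 grid cell in both axes on all presets; T-peaks
within ~1 cell for the oxygenated/wild-type state, ~1.2–1.5 cells for
the variants, and ~2.3 cells in T2 for the deoxygenated state (its
T2 = 0.565 ms is sampled by fewer than three echo times). The oxidized
protein-bound region is deliberately a continuous stretch — its tail is
quantified by the extent metric, not by a discrete peak position.

## Classification

The default featurizer is deterministic: the log-intensity map above its
dynamic-range floor (log10(F + ε) − log10(ε), ε = 1e-6·max), block-
averaged to 32×32, flattened and L2-normalized. A `peaks` featurizer
(raw R/S/T log-coordinates, A-ratios, volumes and tail extent) and a
pluggable external `embedding` callable (for CNN image embeddings) share
the interface; a trained CNN is deliberately not the default, since it
would tie results to external weights.

Dimension reduction defaults to metric MDS initialized with the
classical Torgersen solution (eigendecomposition of the double-centered
squared-distance matrix) and refined by stress majorization capped at
300 iterations; t-SNE and Isomap are available behind the same call.
Hierarchical clustering is average-linkage on Euclidean distances, with
the leaf-ordered distance matrix returned for heat-map rendering. Group
separation uses the two-tailed two-sample t test (Welch variant by
default; the pooled classic form behind `equal_var=True`).

Supervised evaluation pools out-of-fold predictions of stratified
k-fold (k ∈ {2, 3, 5}, seeded shuffling) or leave-one-out CV into one
confusion table. Metrics: CA, sensitivity, specificity, precision, F1
(harmonic mean of precision and sensitivity), each reported as missing —
never as 0 — when its denominator vanishes, and AUC from the pooled
positive-class scores via the Mann–Whitney rank-sum identity with
midranks. Models are scikit-learn's logistic regression (L2, C = 1),
3-NN, Gaussian naive Bayes, and a one-hidden-layer perceptron (32
logistic units, L2 1e-3, ≤ 500 epochs, seeded); the epoch cap is part of
the configuration, so convergence warnings from the optimizer are
silenced. On the binary disease/non-disease task (variants grouped with
disease, wild type as control) the default synthetic cohort is almost
perfectly separable: LOO accuracies are 1.00/0.94/1.00/0.94 for
LR/kNN/NN/NB, and mean accuracy is non-decreasing from k = 2 through
LOO.

## Numerical and interface choices

- All randomness flows through `numpy.random.default_rng` seeds;
  identical (config, seed) pairs give bit-identical outputs. The solver
  itself is deterministic.
- Data travel as plain CSV matrices with JSON sidecars; a legacy
  "embedded" dialect (axes in the first row/column) is read-only.
- CLI exit codes: 0 success, 2 config error, 3 data-format error,
  4 numerical failure.
- A-ratio presentation uses half-up rounding to match printed tables
  (Python's built-in `round` is banker's rounding).

## Known limitations

- No L-curve or discrepancy-principle selection of α; the weight is a
  fixed default and sweeps are manual.
- No uncertainty quantification on the spectrum, no lineshape fitting,
  no exchange modelling between reservoirs.
- The tail-extent metric depends on the detection threshold and window;
  at SNR 500 it fluctuates by a few tenths of a decade between noise
  realizations (class separation survives, single values should be
  read with that spread in mind).
- The cohort's class separability reflects the stated generator: real
  inter-subject variability is richer than 5% log-normal jitter, and
  classifier accuracies on real cohorts will be lower.
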