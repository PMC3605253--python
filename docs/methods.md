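# Methods

This note documents the modelling assumptions, numerical choices and
limitations of `grnode`.  It is the authoritative description of *why* the
package behaves as it does; the README shows *how* to use it.

## Model class

Gene regulation is modelled as a sparse linear time-invariant (LTI) system
`dx/dt = A x + B u` over standardised expression levels.  The linearity
assumption is pragmatic: over the moderate excursions of a standardised
time course ([−1, 1]), transcriptional response curves are well approximated
by their linear part, and linearity is what makes the per-sub-model
regression initialiser and the exact trajectory propagation possible.  Three
structural conventions follow the biology:

* **Diagonal elements are strictly negative.**  a_ii aggregates
  self-regulation and first-order mRNA decay; a non-negative diagonal would
  make a sub-model non-decaying, which standardised expression data cannot
  support.  The bound is configurable (`diag_upper`, default −10⁻³).
* **Interactions do not conserve material.**  An edge j → i changes x_i but
  not x_j (transcriptional signalling, not conversion).
* **Integrator chains.**  A sub-model of order r consists of r states
  sharing one diagonal coefficient, coupled in series with unit gain;
  incoming connections enter the first state, the last state is compared to
  data.  This adds dynamic flexibility (S-shaped, delayed responses)
  without adding parameters.  When an order is raised, the first-order
  coefficients are adapted so that static gain and total time constant are
  preserved: a_r = r·a₁ and all other coefficients scaled by
  (−a_r)^r / (−a₁).

The optional non-linearity wraps each sub-model's driven-row linear
combination in f(z) = tanh(g·z)/g (odd, saturating, unit slope at 0, so the
linear model is recovered for small signals).  Only the driven row is
wrapped: transforming the intermediate chain rows would destroy the unit
coupling pattern that makes a chain a chain.  The default is linear
modelling; the sigmoid costs an ODE solve per objective evaluation.

## Pre-processing

* **Standardisation.**  Per gene and experiment the initial value is
  subtracted (every series starts at 0, matching x₀ = 0); then the gene's
  series in *all* experiments are divided by one common scalar, the maximum
  absolute centred value across experiments.  The common scalar is essential
  in the multi-experiment setting: per-experiment scaling would assign the
  same gene different units in different experiments and break the shared
  model.  A gene that is constant after centering in every experiment has no
  dynamics to model and is rejected (`DegenerateSeriesError`).
  Standardisation is idempotent.
* **Interpolation.**  `k_per_interval` (default 3) artificial points per
  measured interval, from a natural cubic spline fitted per gene and
  experiment; fewer than 4 measured points fall back to piecewise-linear.
  Interpolated points carry weight 0.25 versus 1.0 for measured points
  (both configurable).  The artificial points stabilise the
  derivative-based regression on sparse grids and damp over-fitting, at the
  price of a small bias: the spline is only an approximation of the true
  trajectory, so even noise-free parameters are recovered only to ≈1%
  accuracy on a six-point grid.  Noise-free consistency checks therefore run
  with `k_per_interval = 0`, where recovery is exact to optimiser tolerance.
* Standardisation precedes interpolation, so artificial points inherit the
  scale.

## Parameter identification

For sub-model i with input set M_i and state set N_i (always containing i),
initial parameters come from weighted linear regression of the numeric
derivative (central differences per experiment, one-sided at boundaries)
on the concatenated experiment data:
θ_init = ([U X]ᵀ W [U X])⁻¹ [U X]ᵀ W ẋ.  Concatenation treats data points
as dynamically independent, which is exactly the assumption the subsequent
simulation-based refinement repairs.  A rank-deficient weighted design
(e.g. duplicated regressors, a never-applied stimulus) rejects the
candidate structure.

Refinement minimises the weighted squared deviation between the *simulated*
sub-model trajectory and the measured+interpolated series, summed over
experiments, with L-BFGS-B under box bounds (all coefficients within ±50,
diagonal within [−50, −10⁻³]; iteration cap 200, projected-gradient
tolerance 10⁻⁸).  If the optimiser ends worse than its start, the start is
returned (`converged=False`), so refinement never loses ground.

During sub-model fitting, incoming signals are fixed time courses: stimulus
steps, simulated trajectories of already-included genes, and the data of
not-yet-included genes (proxy connections).  The sub-model is therefore a
driven integrator chain, which the inner loop propagates **exactly** per
grid interval (piecewise-linear drivers; matrix-exponential step for
chains, closed form for first order).  This is both faster and more
accurate than a generic ODE solver and is the package's main performance
device; the full coupled model is simulated with LSODA
(rtol 10⁻⁶, atol 10⁻⁸) for reporting and oracle tests.

One shared weight vector serves both the regression matrix W and the
objective weights w(t_k).

## The structure heuristic

The outer loop adds one gene at a time: basic candidates (self-regulation +
one stimulus each + fix prior edges) are fitted for every remaining gene,
the best-reproduced gene (lowest penalised error; ties broken by fewer
parameters, then input order) is improved and frozen.  Improvement phases,
in order: growing, order raising (orders 2..`maxOrder`), pruning.

The per-series error compared against `allowedError` is the
*weight-normalised* objective J/Σw — a per-point squared error.  The raw
double sum would grow with the number of time points and experiments,
making one threshold meaningless across datasets; on the benchmark noise
level (σ = 0.05) the normalised error lands in the 10⁻³–10⁻² range that the
`allowedError` sweep spans.

* **Growing** runs while the error exceeds `allowedError` and the number of
  non-self connections is below `maxConnections`; an addition must improve
  the penalised error by at least `growing_threshold` (default 5%).
  Candidates include stimuli, modelled genes and the data of unmodelled
  genes; proxy edges to later-modelled genes are rewired to their states at
  the end and appear above the diagonal of A as global feedbacks (their
  coefficients are kept; the rewiring is topological).
* **Order raising** is attempted only while the error target is unmet
  (raising the order does not add parameters, but it does add states, and an
  already-adequate fit does not justify them); the best order must clear the
  same relative-improvement threshold.
* **Pruning** tentatively removes every non-fix connection and keeps a
  removal if the refitted error worsens by at most `pruning_threshold`
  (5%), **or** if the reduced sub-model still meets `allowedError`.  The
  second clause is deliberate: a near-perfectly fitted sub-model (J ~ 10⁻⁶)
  can never lose a spurious edge under a purely relative rule, because any
  removal is a huge relative change of a negligible error.  Anchoring
  "significant worsening" at the user's own error demand makes
  `allowedError` govern sparsity symmetrically in both directions.  A
  corollary: a very lax `allowedError` prunes aggressively, down to bare
  self-decay models.

Already-included sub-models are not re-optimised when later genes arrive
(configurable via `refit_included`, off by default and deliberately
untested territory): freezing keeps the cost linear in N and the audit
trail interpretable.

## Prior knowledge

Connection codes: 0 (no connection), 1 (connection, unknown sign),
10 (activation), −10 (inhibition).  **Fix** knowledge is structural: forced
edges appear in every candidate of the gene (sign-constrained coefficients
for ±10, with a magnitude floor of 10⁻⁵ so the edge always encodes as
present) and code 0 is a hard exclusion.  **Flexible** knowledge adds
λ·Σ s·d to the objective, with s the reliability score and d the binary
sign distance between the model's edge code and the prior code.  d is
summed over *every* position of the row carrying a flexible entry — an
absent edge against a "connection" prior counts as a disagreement — so
flexible knowledge can both discourage contradictions and encourage
inclusion during growing.  d does not distinguish a sign flip from a
missing edge; the graphical classification (red vs grey-dashed) does.

## Benchmarks and evaluation

The generator produces stable sparse LTI systems in three cross-talk
classes — FCT (every gene reachable from every stimulus; default 5 genes),
LCT (some but not all genes reachable from more than one stimulus; 4), NCT
(stimulus-disjoint sub-networks; 7) — with two stimuli by default.
Adjacency is fixed per class; coefficients are seeded random draws with
off-diagonal and input magnitudes in [0.3, 1.5] and diagonals within
[−2, −0.2].

Two generator choices are identifiability-driven and worth stating:

* **Time constants are graded by depth** (roots τ ≈ 4, downstream genes
  faster, jittered to stay distinct).  A *fast* upstream gene saturates like
  the stimulus step itself, making its outgoing edges indistinguishable
  from direct stimulus edges on a six-point grid — no inference method can
  recover what the data do not encode.
* **Cross-talk sits at leaf genes**, realised in the LCT class as one gene
  lineage plus one direct stimulus.  A leaf fed by two slow disjoint-lineage
  parents creates a greedy trap: each single-edge addition must share the
  sub-model's one diagonal coefficient across experiments, and the
  step-input substitute then beats each true parent individually.  The
  greedy, one-edge-at-a-time search cannot cross that barrier; the
  benchmark is designed to test recovery, not that particular
  non-identifiability.

Artificial data mimic sparse microarray time courses: six points at
t = 0, 1, 2, 4, 8, 16 (exponentially increasing intervals), i.i.d. Gaussian
noise N(0, 0.05²) added to the simulated trajectories, then
standardisation.  Scenario "M" holds one experiment per stimulus and reuses
the single-stimulus scenarios' noise realisations, so comparisons isolate
the effect of data integration.

Structure evaluation classifies all N² + M·N candidate positions
(self-loops included) into TP / TN / FN and the sign-aware split of false
positives (FPs wrong sign, FPn non-existent interaction), with
SE = TP/(TP+FN+FPs), SP = TN/(TN+FPn), PR = TP/(TP+FPn+FPs),
FM = 2·PR·SE/(PR+SE); zero denominators yield 0.  Edge presence uses a zero
tolerance of 10⁻⁶ on the coefficients.

Resampling validation perturbs the standardised series with N(0, σ²)
(default σ = 0.05, default 100 runs; tests and examples use 20 to stay
fast), re-standardises, re-infers, and reports the fraction of runs in
which each nominal connection reappears with the same sign.

## What the synthetic benchmarks do and do not show

The generator reproduces the data *geometry* of real stimulation
time-courses (few points, exponential spacing, additive noise, step
stimuli) but not their biology: no unmodelled confounders, no replicate
structure, noise is homoscedastic and Gaussian, the true system really is
LTI, and every relevant gene is observed.  Passing benchmarks therefore
demonstrates correctness of the machinery and behaviour under the stated
noise — not that a real transcriptome yields the true network.  On real
data the resampling frequencies, not single point estimates, are the
quantity to interpret.

## Numerical and degenerate-case choices

* Ties in gene selection: lower penalised error, then fewer parameters,
  then file order.  Growing candidates are scanned stimuli-first, then
  genes, in index order; the first strict improvement wins ties.
* A gene for which no candidate structure is identifiable is included as a
  best-effort basic sub-model and flagged in the run report.
* An empty dataset yields an empty model, not an error.
* All randomness (benchmark coefficients, noise, resampling) flows from
  explicit seeds; inference itself is deterministic, so identical inputs
  and configuration give bit-identical structures.

## Known limitations

* Greedy structure search finds local optima; there is no guarantee of the
  global solution (resampling mitigates, and the benchmark section above
  documents one concrete trap).
* Proxy (global-feedback) coefficients are not refitted after rewiring, and
  included sub-models are never revisited; strongly coupled feedback systems
  may end with a coupled simulation that fits worse than the per-sub-model
  errors suggest (the coupled trajectory is exported precisely so this is
  visible).
* Highly correlated regressors (near-identical time courses) defeat the
  rank check only approximately; the bounded refinement keeps coefficients
  finite but attribution between near-collinear parents is arbitrary.
* The evaluation measures compare gene-level adjacency; chain orders are
  not scored.
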