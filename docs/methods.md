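# Methods

## Coarse-graining of traces

Each lineage branch spans three cell cycles (8-, 16-, 32-cell). Raw time in
every cycle is linearly warped to (0, 1], rounded to the nearest multiple of
0.05 and shifted by the cycle index, giving at most 20 grid points per cycle
on (0, 3]; samples colliding on a grid point are averaged. The grid is
(0, 1] rather than [0, 1): the 20-point count forces one endpoint out, and
we keep the cycle end so division times land exactly on the integers 1
and 2. A sample exactly at a division ends its previous cycle. Stages are
8 = (0, 1], 16E = (1, 1.5), 16L = [1.5, 2], 32E = (2, 2.5), 32L = [2.5, 3];
a point exactly at a half-cycle boundary is late.

Intensities are smoothed with a centred moving average of 2.5 h within each
cycle (the window shrinks at cycle edges and never crosses a division).
Normalisation happens on the smoothed, untrimmed series — per-time-point
z-scoring across an embryo's distinct cells for YAP (sister branches share
their ancestors' samples and are de-duplicated, so pre-division cells are
not over-weighted), and per-time-point embryo-minimum background
subtraction followed by per-embryo min-max over the 16- and 32-cell stages
for CDX2/SOX2. Only then is the first 2 h after every division excluded,
before stage summarisation; running the exclusion before normalisation
would thin the cell set per time point around divisions for no benefit.
Summaries are the stage mean (YAP, stages 1–4) and the end-of-stage value
(targets, stages 2–4); SOX2 additionally subtracts the branch's value at
the start of the 16-cell stage to absorb branch-specific offsets.

A time point where the embryo presents a single cell gets z = 0 with a
warning; a stage with no retained samples yields a missing summary that
propagates as NA through binarization and excludes the branch from class
assignment (fitting handles NA by complete-family counting).

## Thresholding

Binarization is `v = 1 iff summary ≥ θ` (ties positive — "above" versus
"at" the threshold is otherwise ambiguous, and the choice only matters on
sets of measure zero for continuous summaries). Shipped fixed thresholds:
YAP θ₁…θ₄ = (−0.59, −0.82, −0.61, −0.58) and CDX2 θ = 0.088, the values
derived on the original imaging cohorts; they are defaults, not magic — the
derivation procedures re-derive thresholds on any new data:

* **YAP, derive mode** — per stage, a Gaussian KDE (Scott's rule, 512-point
  grid) local minimum between the two highest modes; if the density has no
  such minimum (no clear bimodal structure), fall back to the CDX2-style
  3-component Gaussian mixture with the top two components positive. The
  fallback order is shape-driven on purpose: a 3-component mixture forced
  onto clearly bimodal data splits one mode and places the bottom/next
  boundary inside it, which mis-thresholds every value in the split mode.
* **CDX2** — one pooled 3-component mixture over stages 2–4, bottom
  component negative, θ at the weighted-density crossing between the bottom
  and middle components (EM with 10 restarts and a fixed seed, so θ is
  bit-reproducible given data).
* **SOX2** — a 2-component mixture per batch (backgrounds are batch
  specific). A split log-likelihood diagnostic (`sox2_split_loglik`: fit one
  Gaussian per side, sum log-likelihoods) is provided for threshold
  inspection; it is an interpretation of a sketched procedure, flagged as
  such in its docstring.

Induction classes follow the first stage at which a target is on: G2+,
G3+, G4+ or G⁻; re-silencing after induction does not change the class.
These classes correspond exactly to the evidence sets {G₂=1},
{G₂=0, G₃=1}, {G₂=0, G₃=0, G₄=1} used for inference.

## The DBN engine

CPDs are Bernoulli tables indexed by parent configuration, with parents
ordered by (stage, name). MLE is `(n₁ + α)/(n + 2α)` with pseudocount
α = 0 by default; unseen configurations are NaN at α = 0 and must be
explicitly filled (0.5) before enumeration or variable elimination —
entries unreachable under the boundary conditions (e.g. conditioning on
G₁ = 1) carry zero probability mass regardless of the fill. The
log-likelihood is the sum of log CPD entries over fully observed families;
for a record missing an entire channel this equals the exact marginal
likelihood, because the missing chain marginalises out of the
factorisation. BIC counts one free parameter per parent configuration per
node, roots included (k = 26 for pairwise M3), and n is the number of
trajectory records — the branch decomposition, matching the n = 288 usage
for 9 embryos.

Variable elimination uses factors over binary scopes, eliminating hidden
variables in (stage, Y-first, name) order; exactness is order-independent
and the fixed order makes intermediate factors deterministic. Enumeration
(2¹⁰ pairwise, 2¹⁵ fused) is retained as the independent oracle; the test
suite requires VE ≡ renormalised enumeration to 1e-12 on all
induction-class evidence sets and on double-positive conditioning.

## Simulation

A lineage is 13 cells over 5 stages (1+2+2+4+4), divisions after stages 0
and 2, cells coded by {a, b} strings; daughters are sampled independently
conditional on their mother. This independence caps the achievable
asymmetric-division rate at 2q(1−q) ≤ 50%, so a reported 64% asymmetric
rate is encoded per daughter: q = p(Yᵢ₊₁=0 | Yᵢ=1) = 0.32 at division
steps. An embryo is 8 independent lineages (32 final branches). One cohort
seed expands into per-embryo `SeedSequence` substreams, so growing a cohort
never reshuffles earlier embryos; within an embryo the draw order is fixed
and vectorised across lineages (a per-embryo substream with fixed draw
order gives the same stability guarantee as per-branch substreams at a
fraction of the RNG overhead).

## Reference fixtures

`F1` (Y, S), `F2` (Y, C) and `F3` (fused) are fully specified M3 networks.
Entries printed for the fitted model are used verbatim and tagged `reported`
in the serialised fixture: the boundary conditions p(Y₀=1) = 1,
p(G₀=0) = p(G₁=0) = 1, the stage-4 SOX2 induction p(S₄=1|S₃=0,Y₃=0) = 0.43
and its stage-2 counterpart p(S₂=1|S₁=0,Y₁=0) = 0.66 (the complement of the
reported 0.34 failure-to-induce probability; S₁ = 0 is forced, so the
conditional is the CPD entry). All other entries are round, documented
defaults tagged `default`: target persistence 0.98 once expressed ("close
to 1"), YAP within-cycle persistence 0.95, YAP return 0.05, per-daughter
YAP loss 0.32 at divisions, CDX2 induction 0.85 at 16L under nuclear YAP
(so the early class dominates, as observed), mid-pipeline induction values
0.4–0.5, and leak rates 0.02 (SOX2) / 0.05 (CDX2). Only reported-tagged
entries are ever used as reference values in acceptance checks.

## Synthetic traces

The trace generator emulates extracted per-nucleus intensities, not images.
Per embryo: every cell's cycle length is Normal(12 h, 0.75 h) (normality is
the documented property of cleavage timing; the mean and SD are this
package's defaults), clipped at a quarter of the mean for safety; the
observation window runs from the 8-cell stage to the embryo's first 32→64
division, so every retained time point sees all 32 branches — the condition
the per-time-point normalisations rely on. Each branch's own cycle ends are
recorded for warping. YAP is sampled every 15 min as
`100 + 40·state − 1.5t + ε`, a baseline plus the state separation (bimodal
at the 16-cell stage), a slow downward trend that exercises the per-time-
point z-scoring, and i.i.d. Gaussian noise (σ = 3 by default); targets are
sampled every 30 min as logistic ramps (halftime 1.5 h after stage entry)
that follow the hidden binary state, amplitude 50 over a baseline of 5,
SOX2 with a batch-specific additive background (2·k for batch k). Noise is
drawn per cell, so sister branches share their pre-division samples
exactly. Hidden binary states come from the same lineage sampler as the
trajectory-level generator, so the two levels share one law by
construction; a chi-squared test on induction-class frequencies of
discretised noiseless traces (150 embryos, one branch per lineage to keep
draws independent) confirms it against the exact class probabilities.

What the generator does not emulate: segmentation/tracking errors, photo-
bleaching, spatial position, cell death, and any coupling between YAP state
and division timing. Passing tests therefore validate the pipeline's
statistical machinery on data with the assumed structure, not robustness to
imaging artefacts.

### The noiseless limit

End-to-end exactness (100% ground-truth recovery through
preprocess + discretize) is asserted in the limit where both intensity
noise and cleavage-timing jitter vanish. Timing jitter is itself a noise
source with a structural consequence: with the observation truncated at the
first 32→64 division, a branch whose 32L half-cycle is barely observed has
a partially risen induction ramp (or no 32L grid point at all), and no
threshold can recover its state. Under the default noisy configuration
(σ = 3, cycle SD 0.75 h, 12 embryos) full-trajectory recovery is asserted
at ≥ 95% over three seeds.

## Evaluation

Train/test robustness uses size-6 training splits — exhaustive over all
C(9,6) = 84 subsets for 9-embryo cohorts, or a seeded random sample (100
splits) for larger ones. Calibration uses the expected calibration error
with M = 10 equal-width bins (boundary values to the lower bin, 1.0 to the
top bin) on a one-step-ahead node-prediction task: for every non-root node
of every held-out trajectory, predict p(node = 1 | observed parents) from
the trained model and compare with the observed value, pooled. The
calibrated classification task is a declared choice (the quantity being
calibrated is otherwise unspecified); it is isolated behind
`one_step_predictions` so an induction-class variant can be swapped in.
Persistence probabilities "close to 1" are reported numerically, never
asserted against a threshold.

Cohort-level statistics (class-frequency mean ± SD over embryos, per-stage
C/S cell-state counts on the fused model) are computed on simulated cohorts
of 3000 embryos by default. Monte-Carlo checks against exact VE values use
3 standard errors widened by a design-effect factor √4 for within-lineage
correlation of branch values.

## Numerical conventions

* Warped times are stored to 2 decimals; probabilities at full double
  precision in JSON.
* GMM: 10 EM restarts, fixed seed 20250905, `reg_covar = 1e-10` (tolerates
  zero-variance clusters on noiseless data).
* Threshold derivation requires ≥ 30 pooled values.
* Ties in BIC selection are reported, never silently broken.
* Statistical round-trip checks (parameter recovery within 3 binomial SEs)
  divide branch-table counts by the shared-ancestor duplication factor
  (×4 at stage 0, ×2 at stages 1–2): branch rows duplicate each ancestral
  cell's single draw, and the binomial SE is only valid on unique draws.

## Known limitations

* Only the five coarse stages and binary states are modelled; no
  continuous-valued expression modelling, no 64-cell follow-up.
* No structure learning beyond the four named candidates; no approximate
  inference (exact VE is cheap at this scale).
* The geometric (cell-position) model is out of scope; the fused network
  exposes the YAP chain as the fusion hook for a third CPD block.
* Fixture entries not printed for the fitted model are defaults; analyses
  that depend on them characterise the package's reference conditions, not
  measured biology.
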