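# Methods

## Occupancy model

Cell encapsulation is modelled as Poisson: the count of cells in a droplet
has mean *a* = cell concentration (cells/mL) × droplet volume (nL) × 10⁻⁶.
The packaged default volume of 0.8 nL is back-inferred from the canonical
concentration → occupancy pairings used in multi-cell experiments
(2.5×10⁶ cells/mL ↔ ~2 cells/droplet up to 15×10⁶ ↔ ~12) and is
overridable everywhere. Model sums truncate the occupancy at kmax = 30;
simulation draws from the untruncated Poisson, because the physical loading
process is untruncated — the truncation belongs to the formula, not the
physics. Both raw (truncated, summing to ≤ 1) and renormalized probability
masses are exposed, since an expected-frequency curve can legitimately be
drawn either way; `compare_occupancy` accepts both via `renormalize`.
Probability masses are evaluated through `scipy.stats.poisson` (log-space),
overflow-safe far beyond k = 170 where naive factorials fail.

The occupancy goodness-of-fit statistic is Pearson's Σ(obs−exp)²/exp with
high-k bins pooled into a tail bin until the pooled expectation reaches a
configurable floor (default 1 count) — the standard small-expected-count
safeguard. Degrees of freedom are bins − 1 (mean known, not fitted).

## Sharing model

A fraction *b* of cells are IL-10 producers; a producer renders every cell
in its droplet IL-10 positive (binary positivity — partial transfer is out
of scope). Two analytic predictions are implemented side by side:

* **Quadratic weight** (`fraction_positive_quadratic`): droplets of size k
  contribute weight b·k² positive cells against k total, i.e. each of the
  b·k expected producers converts all k occupants. Untruncated, this is
  100·b·(1+a). Multi-producer droplets are double-counted, so the value
  can exceed 100%; a cap at 100% is applied by default and the uncapped
  value is always reported alongside. The formula is kept verbatim because
  it is the prediction whose divergence from measurement is the scientific
  point; the cap reflects the prediction "increasing to maximum".
* **Exact expectation** (`fraction_positive_exact`): the expected positive
  cells in a size-k droplet is k·(1−(1−b)ᵏ) — all k cells iff at least one
  producer — which never exceeds 100% and is the true mean of the
  mechanism. Since b·k ≥ 1−(1−b)ᵏ, the quadratic formula is an upper bound,
  strict whenever multi-cell droplets occur and 0 < b < 1, and the two
  agree in the b → 0 limit (relative gap O(b)).

The Monte-Carlo simulator draws occupancy ~ Poisson(a) and producers ~
Binomial(k, b) per droplet and applies the ≥1-producer rule. Its standard
error treats the droplet as the sampling unit (cells within a droplet are
perfectly correlated), using the ratio-estimator variance
√Σ(xᵢ−p·kᵢ)² / Σkᵢ; a binomial-over-cells SE would be anticonservative by
roughly the design effect of droplet clustering.

The producer fraction b̂ is positive events over total events with a Wilson
score interval (`statsmodels`), which behaves sensibly at b̂ = 0 (one-sided
interval) unlike the Wald interval. The default positivity gate, when an
unstimulated control distribution is supplied, is its 99th percentile;
a fixed user-supplied gate avoids the 1% false-positive floor that a pure
percentile gate imposes by construction.

The 95% prediction band maps the t-based confidence interval of the mean
replicate b through the quadratic formula — valid because the formula is
monotone increasing in b — with a percentile-across-replicates variant
selectable; the band construction is a modelling choice, not forced by the
data, so both readings are available.

## Calibration

The titration curve defaults to piecewise-linear interpolation in log-log
space: it passes exactly through every standard, making forward/invert a
strict round trip inside the valid range (the property the tests pin at
<0.1% relative error, and machine precision in practice). A four-parameter
logistic fit (`y = bottom + (top−bottom)/(1+(ec50/x)^hill)`, fitted with
`scipy.optimize.curve_fit`, inverted in closed form) is available when a
parametric form is preferred; on standards with 2% multiplicative noise it
recovers the inflection within 5%. Signals outside the standards' span are
clamped to the nearest standard and flagged `below_range` / `saturated`
rather than dropped — dropping events would bias the estimated producer
fraction by discarding exactly the dim cells. Capture-antibody saturation
is represented only by the flag; no correction model is applied.

ELISA normalization is the exact arithmetic concentration × volume /
cell count × reference count (default reference 10⁵ cells), making bulk
and single-cell cultures directly comparable.

## Kinetics

Rates are finite differences over consecutive timepoints; a negative rate
is flagged as clearance (disappearance of already-secreted cytokine,
whether consumption, degradation or assay loss — the package only flags
it). The telescoping identity Σ rateᵢ·Δtᵢ = final − initial is checked to
1e-9 as an internal consistency guard. "Stopped production" is
operationalized as the earliest time the cumulative course reaches 95% of
its final amount; the threshold is configurable and, by default, the
answer is a sampled timepoint (a plateau first sampled at 8 h reports
8 h), with linear interpolation opt-in. Amounts at t = 0 are zero
(stimulation starts the clock).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
the study conditions: producer fraction 0.10; mean occupancies 2, 4, 8, 12;
densities 2.5, 5, 10, 15 ×10⁶ cells/mL; sampling at 0, 2, 4, 8, 24 h.
Numbers chosen where no published value exists, fixed once:

* Per-producer IL-10 secretion: log-normal, median 1 pg/cell, geometric
  SD 2 — an order-of-magnitude scale for single-cell cytokine content,
  configurable rather than falsely precise. TNFα median 5 pg/cell (near-
  universal secretion).
* Staining background: log-normal, median 5 MFI, geometric SD 1.5; the
  default gate of 100 MFI sits >7 background geometric SDs above the
  background median and >3 below the producer cloud, so both
  misclassification rates are ≪10⁻³ and b̂ is effectively unbiased.
* Titration response: power law signal = 1000 × amount (log-log linear, so
  the interpolating fit reproduces it exactly); 4PL parameters
  (20, 50000, 10, 1.2) for the parametric-recovery path. Standards span
  10⁻³–10² pg with 2% multiplicative noise.
* Multi-cell droplets implement the exact sharing mechanism, and the
  droplet's total secreted IL-10 is split equally over its k occupants.
  This makes per-cell received amounts shrink with occupancy, so at high
  occupancy some genuinely positive cells fall below the gate — the gated
  readout plateaus while the ground-truth fraction keeps rising, which is
  precisely the saturation phenomenon the model-vs-measurement comparison
  probes. Ground-truth flags are carried so tests can separate mechanism
  from readout.
* Density time courses: cumulative total × (1 − e^(−t/τ)) with τ =
  shutoff/3 and a hard plateau at the density-specific shutoff (24, 8, 4,
  2 h, strictly decreasing in density); 24 h totals also decrease with
  density. τ = shutoff/3 puts the course at 95% of its plateau exactly at
  shutoff, so the 95% shutoff detector recovers the generative parameter
  at the sampled timepoints. TNFα additionally decays at 1%/h after its
  peak at the two highest densities, producing the negative apparent rates
  there and only there. Donor effects are multiplicative log-normal
  (geometric SD 1.3) on totals, which per-donor normalization removes —
  matching why per-donor normalization is used at all.

What the generator does **not** emulate: fluorescence spillover and
compensation, droplet polydispersity, cytokine diffusion physics and
capture-reagent competition, partial (graded) positivity, and any
IL-10→TNFα feedback mechanism. Passing tests therefore demonstrate that
the estimators recover the parameters of this generative structure, not
that the biological assumptions hold in real data.

## Numerical choices

Sampling sizes are chosen to keep the default test run fast while leaving
4-standard-error margins: 10⁵ droplets for simulator-oracle equivalence,
5×10⁴ events for b recovery (binomial SD ≈ 0.0013), 500 replicates of 1000
events for interval coverage, 2×10⁴ droplets per occupancy condition for
the end-to-end comparison. All generators and simulators accept either an
integer seed or a `numpy.random.Generator` and are bit-reproducible under
a fixed seed; CSV writers use a fixed float format so identical frames
produce byte-identical files (checked via SHA-256 in the pipeline
manifest). Chi-square tail bins are pooled at an expected count of 1;
degenerate inputs (empty histograms, all-zero courses, all-empty droplet
sets, <2 standards, <2 replicates) raise `InvalidInputError` rather than
returning NaN.

## Known limitations

The quadratic formula's cap makes its value non-informative above the
occupancy where 100% is first reached; use the uncapped value for model
comparison there. The 4PL fit needs standards flanking the inflection and
can be ill-conditioned on plateau-only designs. Clearance flags conflate
consumption, degradation and assay loss. The shutoff detector's resolution
is the sampling grid unless interpolation is enabled.
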