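# Methods

## Model and assumptions

`pulsedyn` models one participant at a time as a discrete-time
(1 sample/minute) Wiener-type cascade: a linear time-invariant (LTI) system
driven by the stress probability u(k) ∈ [0, 1], followed by a hard sign
nonlinearity. The latent response

    y(k) = (h ∗ u)(k) + y_N(k)

produces a smoking minute exactly when y(k) ≥ 1 (the threshold value is a
convention; rescaling it rescales all coefficients inversely, which the
implementation exposes as the `threshold` parameter and the test suite
checks as an exact homogeneity property). Convolution is causal and starts
at rest at each chunk boundary; everything the system "remembers" from
before a chunk is absorbed into that chunk's natural response
y_N(k) = Σ_p C_p^{N,l} α_p p^k, whose coefficients are free per chunk.

Assumptions inherited from this structure: the system is stationary over
the recording; the stress→smoking path is open-loop (no feedback from
smoking to subsequent stress); and dynamics across missing-data gaps are
not modeled — each chunk restarts with its own natural response.

## Preprocessing

Raw event tables (Unix-epoch seconds) pass through five stages:

1. **Minute gridding** — timestamps round to the nearest minute (half-up on
   integer seconds); colliding stress samples on one minute are averaged.
2. **Short-gap interpolation** — missing stress runs of ≤ 2 minutes flanked
   by observations are filled linearly; longer runs stay missing. The
   operation is idempotent and never alters observed values.
3. **Episode delimiting** — puff detectors report an episode's start and
   puff times but not its end. A 5-minute window slides from the start one
   minute at a time; while a window holds ≥ 4 puffs the episode extends, and
   it ends at the largest puff minute inside any qualifying window. Fewer
   than 4 puffs in the first window violates the detector's contract and is
   an error.
4. **Chunking** — maximal runs of consecutive non-missing minutes become
   chunks; smoking minutes falling inside stress gaps are discarded with
   the gap (input and output must be aligned).
5. **Short-chunk removal** — chunks under 5 minutes carry too little
   dynamical information and are dropped. N_ch and the mean retained chunk
   length N_l (kept unrounded; the scaling factor accepts real exponents)
   are computed over what remains.

Overlapping episodes OR-combine into the smoking column. Only the stress
column is interpolated; smoking is never imputed.

## The atomic dictionary

Candidate poles lie on a uniform polar grid: radii r_max·i/n_radii
(default r_max = 0.98, n_radii = 10) plus the origin, angles jπ/n_angles
for j = 0..n_angles−1 (default 10). Every non-real pole is paired with its
conjugate so assembled responses are real; the origin pole, with the
convention 0⁰ = 1, is a pure impulse atom. Optional subsampling draws
conjugate-closed units in seeded order, so grids are reproducible and
serializable to JSON. The per-pole scaling α_p = (1−|p|²)/(1−|p|^{N_l+2})
normalizes the energy of slow and fast modes over a typical chunk so they
compete fairly under the ℓ1 objective; it is 1 at the origin and decreases
monotonically in |p|.

## Solving the identification program

The program minimizes Σ_p t_p subject to the margin constraints
y_l(k) ≥ 1+ε (smoking) and y_l(k) ≤ 1−ε (non-smoking), the shared bounds
|C_p| ≤ t_p and |C_p^{N,l}| ≤ t_p, and conjugate symmetry. Strict
inequalities are closed (required by any numerical solver); the margin
ε = 10⁻⁵ keeps the feasible set well posed, and the non-smoking constraint
is implemented symmetrically as y ≤ 1−ε so that thresholding a feasible
solution reproduces the training labels exactly.

Conjugate pairs are re-parameterized by real (a, b) with C_p = a + ib, so
every constraint is linear except the modulus bounds √(a²+b²) ≤ t — second-
order cones. These are handled by a cutting-plane outer approximation: each
cone starts as a regular 16-gon of supporting half-planes, the LP is solved
(scipy's HiGHS interface), and wherever a coefficient escapes its bound a
new facet is added at arg(C); the loop repeats until no violation exceeds
10⁻⁹ (relative). At termination the iterate is cone-feasible to that
tolerance and optimal for a relaxation, hence within solver tolerance of
the conic optimum. Because facet angles are scale-invariant, the exact
homogeneity of the program under threshold rescaling is preserved.

These ℓ1 programs are heavily degenerate (many optimal vertices). The
solver tries HiGHS's default simplex first with a per-solve time limit
(20 s), then interior point, then dual simplex without presolve; the optimal
*value* is method-independent, and ties among equally-optimal coefficient
vectors are solver-dependent (the model records solver metadata). LP
feasibility tolerances are set at least 100× tighter than ε so margin
feasibility implies exact label reconstruction.

The support is the set of poles with t_p > 10⁻⁶·max(1, objective) — ℓ1
solutions are sparse only to solver precision. In the objective each grid
pole counts once, so a conjugate pair contributes 2 t_p.

Degenerate inputs: all-non-smoking data yields the zero model at objective
0; infeasibility (possible when the grid is too sparse for the observed
pattern) raises an error suggesting a denser grid; a solver that stops
short of optimality yields a model flagged `inaccurate` with a warning, not
a silent success.

## Hold-out validation

Chunks are assigned whole to modeling and validation sides at a 2:1 minute
ratio (greedy assignment over a seeded shuffle; whole chunks only, so the
achieved ratio can be off by a few minutes). After identification on the
modeling side, the poles and input coefficients are frozen and, per
validation chunk, only natural coefficients on the identified support are
refit by the linear program

    min Σ_k |δ(k)|   s.t.  y(k) + δ(k) ≥ 1+ε (s=1),  y(k) + δ(k) ≤ 1−ε (s=0).

The program is always feasible. Restricting the refit to the support is
the stricter reading of "validate with the identified poles" and makes the
check more falsifiable; a full-grid refit is available via `refit_poles`
and can only lower the slack. The validity threshold on Σ|δ| is a required
user parameter — it scales with the number of validation minutes, so no
universal default is defensible; the report also exposes slack per minute
to guide the choice. On the model's own training chunks the slack is zero
by construction (the training natural coefficients are a feasible point).

## Pulse response and the cluster taxonomy

Models are compared via the causal response to a standardized stress
episode: u = 1.0 (maximal stress probability) for 10 minutes, natural
response zero, horizon 30 minutes — all configurable. The five-cluster
taxonomy of response shapes was originally a qualitative visual grouping;
`classify_pulse_response` codifies it as a deterministic, scale-invariant
rule set with exposed thresholds: a peak is *delayed* if it occurs after
minute 4, an *undershoot* is a post-peak dip below 10% of the peak height,
a second peak counts at ≥ 25% of the first, and an *initial dip* is an
excursion below −10% of the maximum within minutes 0–2. These cutoffs are
this package's construction (the qualitative literature does not quantify
"instant" vs "delayed"); they are parameters, not claims. An early single
peak without undershoot is mapped to cluster 1 as the nearest shape; a
never-positive curve maps to cluster 5 (suppression is its defining
feature). The identically-zero response is unclassifiable and raises.

## Synthetic data generator

Because the motivating sensor datasets are not publicly distributable, the
generator produces records with the same statistical structure so the whole
pipeline is testable end to end against a known answer:

* **Volume**: 720 minutes per participant by default (~12 h, matching the
  typical per-participant volume of 3-day chest-band studies).
* **Stress input**: baseline 0.08 with Gaussian noise (σ = 0.03, clipped to
  [0, 1]); stress episodes arrive as a Poisson process (1/hour) lasting
  5–15 minutes at level 0.95.
* **Gaps**: per-minute onset of short (1–2 min, interpolable) and long
  (3–15 min) missing runs, 2% each — yielding a few dozen chunks of a few
  tens of minutes, comparable to reported chunk statistics.
* **Ground truth**: a conjugate-symmetric pole-atom model (defaults: one
  real pole at 0.49 and a pair at 0.653·e^{±iπ/8}, all on the default
  recovery grid) drives the interpolated, chunked stress exactly as the
  identification machinery would, and smoking is the thresholded response.
* **Separability**: minutes with |y − 1| < ε_gen (default 10⁻⁴, 10× the
  identification margin) make the identification program nearly infeasible
  — a property of the method, not the data — so such draws are rejected and
  the noise regenerated (bounded retries, seeded deterministically).

What the generator does *not* emulate: sensor noise in the stress estimate
itself (labels are exactly consistent with a true model — real detectors
have false positives/negatives), circadian structure, activity-driven
missingness correlated with stress, or any feedback from smoking to stress.
Passing recovery tests therefore demonstrates correctness of the estimation
machinery under the model class, not robustness to model misspecification.

Generated records export to the same CSV dialect the preprocessing consumes
(each smoking run becomes a puff episode with four puffs per smoking
minute, which the episode delimiter reproduces exactly), so the round trip
through the full pipeline is exercised in tests.

## Problem sizes and numerical choices

Recovery experiments run 720-minute participants (~550–650 retained
minutes, 6–16 chunks) against a 91-pole grid (n_radii = 6, n_angles = 8);
one identification solves LPs with ~1,000–2,500 variables in seconds. The
test suite's end-to-end checks use ten seeded participants of this size;
the acceptance script uses five. Key tolerances: margin ε = 10⁻⁵; LP
feasibility 10⁻⁹–10⁻¹⁰; cutting-plane violation 10⁻⁹ relative; support
threshold 10⁻⁶·max(1, objective); realness of assembled responses asserted
below 10⁻⁹ imaginary magnitude.

## Known limitations

* Binary observations identify the model only up to the feasible set of the
  margin constraints; coefficients are not unique even with infinite data,
  and recovered pulse responses should be read as representatives (the
  recovery experiments report the cosine to the true response, typically
  > 0.99 in the noiseless regime).
* The cutting-plane LP approach recovers the conic optimum to solver
  tolerance but returns one optimal vertex among many; downstream shape
  classification can in principle differ between equally-optimal models.
* The cluster rules are a codification with chosen cutoffs; near rule
  boundaries labels are sensitive to those parameters.
* Validation refits natural coefficients on validation data by design, so
  held-out label agreement is an optimistic measure when chunks are short
  (the natural terms can absorb much of a short chunk); the slack total is
  the primary validation quantity.
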