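# Methods

## The model family

All simulations are two-dimensional Cellular Potts Models (CPM) on a
periodic square lattice. A cell is the set of lattice sites carrying its
identifier σ > 0; σ = 0 is medium. The energy is

    H = Σ_{Moore pairs, σ≠σ'} J(τ, τ')  +  Σ_cells λ_V (v(σ) − V_τ)²

with a symmetric surface-energy table J (per unlike Moore neighbor pair,
each unordered pair counted once), cell areas v, target area V_τ and
elastic constant λ_V. Dynamics proceed by elementary copy attempts: a
uniformly drawn target site considers adopting the identifier of a
uniformly drawn Moore neighbor (identical-owner pairs are discarded without
counting as rejections). The attempt is accepted with the Metropolis
probability p = 1 for ΔH ≤ 0 and exp(−ΔH/T) otherwise. One Monte Carlo
step (MCS) is width·height elementary attempts. Model extensions add terms
to ΔH; a +∞ term blocks the attempt outright.

Model variants (selectable per run):

* **base** — adhesion and area constraint only; an isolated cell performs
  Brownian motion.
* **persistence** — each cell carries a target direction t⃗, updated once
  per MCS as t⃗ ← (1−dr)·t⃗ + dr·Δx⃗/|Δx⃗| with dr = min(1/decay-time, 1)
  and Δx⃗ the centroid shift of the previous MCS (a zero shift leaves t⃗
  unchanged). A copy attempt with update direction s⃗ (unit vector from
  source toward target site) adds Σ_{σ∈S, σ≠0} −λ_P·v(σ)·(s⃗·t⃗_σ) over
  the two involved cells. The cell-area weight makes λ_P an
  inertia-scaled strength; with a single cell type of near-constant area
  it acts as a constant rescaling.
* **act** — every site carries an activity value that is set to Max_act
  when the site is conquered (reset to 0 when lost to medium) and decays
  by 1 per MCS to a floor of 0. ΔH_act = −(λ_Act/Max_act)·(GM(source) −
  GM(target)), where GM is the geometric mean of activities over the Moore
  neighborhood *including* the central site, restricted to sites sharing
  that site's cell identifier (0 for medium). Copies from active into less
  active contexts are favored, which yields the well-known local positive
  feedback and persistent protrusion. The inclusion of the central pixel
  is a convention; excluding it only rescales λ_Act.
* **ariotti** — explicit pseudopods, described below.
* **pseudopod-ext** — pseudopods plus tip adhesion, pulling, and a touch
  behavior (the proposed mechanism for density-enhanced migration).

### Pseudopod finite state machine

Each cell owns `n-pseudopods` (default 3) independent pseudopods. States:

* **INIT** — place the first actin site at the cell's rounded centroid;
  only accepted if that pixel belongs to the cell, otherwise retry next
  MCS. A growth direction is drawn from a von Mises distribution centered
  on the cell's smoothed movement direction with concentration
  `init-dir-strength`.
* **GROWING** — each MCS, with probability p_ext = 0.3, propose one Moore
  step from the tip in a direction drawn von Mises around the current
  growth direction (`cont-dir-strength`), discretized to the nearest of
  the 8 lattice steps. The continuous growth direction is updated to the
  realized step, which avoids lattice-axis locking. Growth into a foreign
  cell fires the touch behavior; growth into medium simply fails. The
  pseudopod retracts when its growth timer exceeds `max-growth-time` or
  after 20 MCS without a successful extension (stall counter; reset on
  every successful extension; the timer starts at the INIT→GROWING
  transition).
* **RETRACTING** — with probability p_retr = 0.3 per MCS remove the tip
  (`retraction-mode = backward`, default) or the origin (`forward`,
  treadmilling). An empty chain goes INACTIVE.
* **INACTIVE** — re-enter INIT with probability
  1/`time-between-extensions` per MCS (geometric dwell).
* **TOUCHING** — only under the `attach` touch behavior: neither growing
  nor retracting; fall into RETRACTING with probability `p-touch-retr`
  per MCS.

Coupling to the lattice: a copy attempt that grows cell σ next to σ's own
actin (Moore neighborhood of the target site, center included) receives
−`neighboring-actin-bonus` (once, regardless of how many actin sites are
near); an attempt that would shrink a cell next to its own actin is
blocked (ΔH = ∞). The block keeps every actin site inside its owner cell,
which is verified as an invariant.

Touch behaviors on a growth attempt into a neighboring cell (the actin
growth itself is always rejected): `nothing`; `retract` (enter
RETRACTING); `attach` (enter TOUCHING); `poof-dir` — if the pseudopod is
lateral to the cell's movement direction (cos α < 0.85, α between the
origin→tip vector and the movement direction), the entire chain is removed
instantly and the pseudopod re-enters INIT. This mimics contact inhibition
of locomotion: misaligned protrusions repolarize quickly. If either
vector is zero the angle is undefined and nothing happens.

### Proposed-model energy terms

* **Pulling**: with f⃗_σ the vector sum of the cell's origin→tip pseudopod
  vectors, a copy attempt adds Σ_{σ∈S, σ≠0} −F·(s⃗·f⃗_σ)/v(σ)
  (`pull-strength` F; the area divisor models inertia).
* **Tip adhesion**: for each involved cell σ that has a foreign cell in
  the Moore neighborhood of the site changing identity, compare the
  minimum distances from that site to σ's own pseudopod tips (r_σ) and to
  the tips of the neighboring foreign cells (r_σo) against
  `max-distance-for-tip-bonus`: no bonus if both exceed it, −`tip-bonus`
  if exactly one is within range, −2·`tip-bonus` if both are. The
  shrinking cell's term enters with opposite sign, so growth that
  displaces another cell under symmetric tip coverage nets zero — tips
  adhere at interfaces but cannot energetically poke into neighbors.

Two details are deliberate design choices because the source description
is ambiguous: distances are measured from the **site changing identity**
(the target of the copy), and when several foreign cells neighbor that
site the nearest foreign tip is used.

### Smoothed movement direction

The pseudopod models need a "current movement direction" per cell (for
INIT direction draws and the poof-dir angle). It is maintained as an
exponentially smoothed centroid displacement with the same blend rule as
the persistence target direction (`move-dir-decay-time`, default 10 MCS).

## Simulation conventions

Periodic boundaries on both axes (avoids edge artifacts in density
sweeps); centroids are maintained as unwrapped running coordinate sums, so
tracks cross the seam without jumps (exact for cells narrower than half
the lattice — heavily fragmented cells would accumulate centroid error,
which the adhesion and area terms discourage). Cells are initialized as
distinct random single pixels and grow toward the target area during early
MCS; measurements discard a 1,000-MCS equilibration phase. Cell positions
are recorded every MCS by default. A cell whose area reaches zero is
retired. An optional connectivity constraint vetoes any copy whose removal
would locally split the losing cell (single-Moore-component test on the
8-site ring around the removed pixel; a cell may still vanish entirely).

The Metropolis loop is compiled (numba); all randomness is pre-drawn per
MCS from one `numpy.random.Generator`, so a run is a pure function of
(config, seed). Pure-Python implementations of every energy term serve as
the test oracle for the compiled kernel, alongside full-Hamiltonian
recomputation. Throughput is roughly 10⁷ elementary attempts per second
per core, so a 150×150-lattice, 5,000-MCS run takes seconds to ~30 s
depending on the model.

## Track and point-pattern statistics

* **Instantaneous speed** — per-frame displacement over Δt for
  experimental-style tracks; for simulation tracks, net displacement over
  non-overlapping 50-MCS subtracks divided by the elapsed time (suppresses
  centroid jitter).
* **Directional autocorrelation (DAC)** — mean dot product of normalized
  step directions n sampling intervals apart, averaged over all cells and
  time offsets with equal pair weight (per-cell-first averaging is
  available as an option). DAC(0) ≡ 1; zero-length steps are skipped;
  lags without valid pairs are omitted.
* **Persistence fit** — unweighted nonlinear least squares of
  φ·exp(−τ/τ_p) to DAC at lags > 0, with φ ∈ [0, 1] and τ_p ∈ (0, 10×max
  lag]; initial guess φ₀ = DAC(Δt), τ₀ = first lag below φ₀/e. Fits
  pinned at a bound or failing to converge are flagged, not raised; φ
  estimates are known to be less reliable than τ_p.
* **Streaming angles** — for all unordered pairs of moving cells, the
  angle (degrees, [0, 180]) between step directions, binned by
  center-of-mass distance (default bin 5 lattice units / 10 µm-scale
  units; bins with < 20 pairs suppressed). Random migration averages 90°.
* **Drift correction** — per frame, subtract the mean displacement over
  all cells stepping in that frame and rebuild positions cumulatively;
  idempotent by construction.
* **Ripley K/L** — K(r) with Ripley's isotropic edge correction in a
  rectangular window, computed from the closed-form circle-in-rectangle
  arc formula, with the usual estimator |A|/(n(n−1))·Σ w_ij·1(d_ij ≤ r);
  L = √(K/π) and r − L(r) is reported (0 under complete spatial
  randomness, < 0 clustering, > 0 dispersion). The correction is valid for
  r below half the shorter window side; larger r raise an error. The
  implementation is cross-checked against an independent spatial-statistics
  package on a frozen 12-point pattern.
* **Confinement ratio** — net displacement / path length; biased downward
  for longer random tracks (verified as a property), which is why τ_p from
  the DAC is the primary persistence measure.
* **Correlograms** — Pearson correlations between observed density, mean
  speed and τ_p across wells, computed per replicate and averaged via the
  Fisher z transform (artanh → mean → tanh; |r| = 1 entries are passed
  through only when all replicates agree, otherwise excluded with a
  warning). Observed density is the time-averaged number of live cells
  divided by the lattice (or field) area.

## Synthetic fixtures

Fixtures are pure functions of (kind, parameters, seed):

* **brownian** — fixed-length steps with i.i.d. uniform directions;
  DAC ≈ 0 beyond lag 0.
* **prw** — fixed-speed von Mises turning walk. Consecutive directions
  satisfy E[cos Δθ] = I₁(κ)/I₀(κ) ≡ R, so DAC(nΔt) = Rⁿ and κ is chosen
  by inverting R = exp(−Δt/τ_p) (Bessel ratio solved numerically with
  exponentially scaled I₀, I₁). Ground truth: φ = 1, τ_p as requested.
* **streaming** — each step blends a shared constant drift vector with a
  private uniform step (weight `drift_fraction`).
* **point patterns** — CSR (uniform), parent–offspring clusters (uniform
  parents, Gaussian offspring, wrapped into the window), and hard-core
  (sequential rejection below a minimum distance; raises on saturation).

What the fixtures do *not* emulate: measurement noise, segmentation or
tracking errors, track fragmentation/gaps, finite-size nuclei, or
heterogeneous cell populations. Passing tests therefore demonstrate the
correctness of the estimators and the qualitative model behavior, not
robustness to real imaging artifacts.

## Calibrated parameters and what they reproduce

The shipped presets (`podcpm.presets`, mirrored by `configs/*.cfg`) are
calibration choices tuned once at desk scale — 150×150 lattice, target
area 250 sites (≈20 µm cell at ≈2 µm/pixel), T = 20, λ_V = 25, 5,000 MCS
with 1,000 MCS equilibration, cell counts 10–60 — to reproduce each
model's characteristic density response:

| model | key values | density signature |
|---|---|---|
| base | J_cm 20, J_cc 30 | Brownian single cells (MSD slope ≈ 1) |
| persistence | λ_P 0.3, decay-time 2, J_cc 16 | speed ↑ with density (cells merge/interpenetrate) |
| act | λ_Act 100, Max_act 40, J_cc 60 | speed ↓ with density |
| ariotti | actin-bonus 100, κ_init 3, κ_cont 8, max-growth-time 60 | speed ↓ with density |
| pseudopod-ext | + J_cm 50, pull-strength 400, tip-bonus 60, r_max 3, poof-dir | speed ↑ *and* τ_p ↑ with density |

The proposed-model mechanism: at J_cell,med = 50 sparse single cells are
nearly stuck; tip adhesion keeps clusters dynamic and pulling lets
clusters migrate collectively, so crowding *frees* cells — speed and
persistence rise together. Removing pulling leaves slow or rotating
clusters; removing tip adhesion leaves collectives that barely move.
Varying the touch behavior mainly shifts the J_cell,med range over which
the effect holds.

A known limitation of this scaled setup: the highest count (60 cells ≈
67% lattice coverage) is considerably denser than the full-scale
experiments it abstracts. In that crowded regime the basic persistence
model's merging mechanism entrains neighboring cells, so the fitted τ_p
rises together with speed across every parameter regime we examined —
the density–speed increase reproduces, while τ_p flatness does not
transfer to this density range (see the test suite's model-discrimination
checks, where this is asserted and documented). With the connectivity
constraint enabled, the merging channel closes and the speed–density
slope reverses sign, consistent with the mechanism.

## Numerical details and edge cases

* Geometric means use a running product with a single pow; any
  zero-activity included site collapses the mean to 0.
* Von Mises sampling with κ = 0 (or a zero mean direction) is uniform on
  the circle.
* Blocked attempts (ΔH = ∞) and connectivity vetoes are rejected before
  the Metropolis draw; per-attempt uniforms are pre-drawn, so determinism
  is unaffected by the rejection path.
* DAC fitting needs ≥ 3 positive lags; fewer return a flagged result.
* `drift_correct` on a frame where only one cell moves subtracts that
  cell's own displacement (the frame mean) — per-frame means over few
  cells are noisy, which is the standard caveat of the correction.
* Hard-core fixture generation aborts after 1,000·n rejected proposals.
* Ripley weights use min-image-free Euclidean distances (point patterns
  are analyzed in a bounded window, not on the torus); simulation
  positions are wrapped into the window before the analysis.
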