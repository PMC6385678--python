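# Methods

## The synthetic binding model

The dynamics engine is a patchy-sphere Brownian model of a rigid
receptor–ligand pair.  The receptor (radius `R_rec`) is fixed at the
origin with its binding patch along +z; the ligand (radius `R_lig`)
carries a patch axis and two surface "anchor" points, diffuses by
overdamped Langevin dynamics (translation plus rotation), and is
confined by a reflecting spherical wall at `R_out`.  The interaction
energy, with `r` the centre distance, `c_r`/`c_l` the cosines of the
patch–patch alignment angles, `g(x) = max(x, 0)` and `σ = R_rec + R_lig`,
is

    U = U_rep(r) − eps · f(r) · [ (1 − w_enc) g(c_r)^p_rec g(c_l)^p_lig
                                  + w_enc · (2 + c_r + c_l)/4 ]

* `U_rep(r) = k_rep (σ − r)² / 2` below contact — soft-core repulsion;
* `f(r)` — a C¹ radial switch equal to 1 inside contact and exactly 0 at
  the cutoff `r_cut`, so `U = 0` identically beyond `r_cut`;
* the first attraction term is the *native* well: it requires both
  patches to face each other, and at perfect alignment at contact the
  energy is exactly `−eps`;
* the second term is an orientationally broad shoulder of depth
  `~ eps·w_enc` active at any contact orientation.  It creates the
  metastable *encounter complex*: non-native collision complexes that
  persist long enough to either dissociate or rearrange into the native
  pose.

Analytic forces and torques (verified against finite differences in the
test suite) drive an Euler–Maruyama integrator:
`Δx = (D_t/kT) F dt + √(2 D_t dt) ξ`, and an orientation update by a
random rotation vector of per-axis variance `2 D_r dt` plus torque
drift.  Reflections are applied at `R_out` and at an inner core `σ/2`
(the soft repulsion alone cannot strictly exclude deep overlap at finite
`dt`).  A guard aborts with advice to reduce `dt` if a single drift step
exceeds `R_rec`.

### Units and default parameters

Reduced units throughout: `kT = 1`, lengths in Å-like units, times in
ps-like units; diffusion coefficients are therefore in Å²/ps-like units.
A mapping to physical units (e.g. 1 length unit = 1 Å, 1 time unit =
1 ps) is a relabeling and is never enforced.

| parameter | default | why |
|---|---|---|
| `R_rec`, `R_lig` | 3, 2 | contact at σ = 5, matching the 5 Å contact threshold of the bin scheme |
| `eps` | 12 kT | deep enough that the native complex is stable on run timescales (quasi-irreversible binding) |
| `p_rec`, `p_lig` | 2 | moderately narrow patches: orientational rearrangement is rate-limiting but observable |
| `w_enc` | 0.3 | shoulder of ~1–2 kT: the encounter state is clearly metastable and measurably populated |
| `D_t`, `D_r` | 2, 0.6 | diffusional search of the container in O(10²) time units |
| `dt` | 0.02 | per-step noise displacement ≈ 0.28 length units ≪ geometric features; drift guard satisfied with margin |
| `R_out` | 30 | the smallest container compatible with an unbound state at min_sep ≥ 20 plus margin |
| `r_cut` | 8 | interactions vanish before the contact bin boundary region ends |
| `anchor_tilt_deg` | 30° | anchors near, but not on, the patch axis: binding RMSD resolves azimuthal orientation |

The defaults were chosen once, by scanning for a clear three-state
topology (stable bound basin, visited metastable encounter, diffusive
unbound state) under the state thresholds below, and then frozen.

### Progress coordinate and states

* `min_sep` = centre distance − σ, clamped at 0 (the analytic sphere
  form of a minimum surface separation);
* `binding_rmsd` = RMSD of the two ligand anchor points from their
  bound-pose positions after superposing the receptor onto its
  reference.  In the toy model the receptor never moves, so the
  superposition is the identity; the generic Kabsch path
  (`coords_bins.binding_rmsd`) is cross-checked against the analytic one
  in the tests.  At large separations this coordinate acts as a
  distance; near contact it also encodes relative orientation, which is
  what separates the native complex from encounter complexes.

Default state thresholds: unbound `min_sep ≥ 20`; encounter
`4 ≤ binding_rmsd ≤ 20` and `min_sep ≤ 3`; bound `binding_rmsd ≤ 3.5`
and `min_sep ≤ 3`.  The RMSD gap between 3.5 and 4 is deliberate — a
conformation there is in no state, and history labels are untouched.
Thresholds are constructor arguments; overlapping regions are rejected.

### Bin schemes

Cells are half-open `[lo, hi)` with the final cell open-ended, so a
value on an edge belongs to the upper cell (a separation of exactly 5 is
"not in contact").  Three canonical schemes:

* preparatory (1-D RMSD): 0.1-spaced cells on [0, 3), 0.5-spaced on
  [3, 10), one overflow cell — 45 cells;
* binding stage 1 (2-D): separation split at 5 into contact/non-contact;
  inside each, RMSD cells of 0.5 on [0, 10), 1 on [10, 60), one overflow
  cell (71 per separation cell);
* binding stage 2: identical in the contact region, but the non-contact
  region collapses to a single RMSD cell.  Under a fixed global walker
  count this shifts most sampling onto rearrangement of already-formed
  encounter complexes.

## The WE engine

One iteration: propagate every walker for τ = `tau_steps · dt`,
recompute progress coordinates, assign states, update history labels,
record arrival events, optionally recycle, then resample.  Resampling
rules:

* splitting: the highest-weight walker in an undersubscribed bin splits
  first (ties to the lowest index), into as many equal pieces as the
  remaining deficit allows — a lone walker in a bin with target M
  becomes M children of weight w/M;
* merging: repeatedly combine the two lowest-weight walkers in an
  oversubscribed bin; the survivor's configuration is drawn with
  probability proportional to weight and inherits the summed weight, so
  weighted observables are preserved in expectation (verified to 3σ
  over 10⁴ resamplings);
* `fixed_total` allocation: each occupied bin receives
  `max(1, total // n_occupied)` slots; leftover slots go to occupied
  bins in descending bin weight.  A total below the number of occupied
  bins is an error, not a silent reallocation.

Recycling mode moves each bound-arriving walker to a draw from the
initial pool with its weight intact, producing the nonequilibrium
binding steady state whose arrival flux obeys the Hill relation.
Equilibrium mode (the default) never removes anything, so state
definitions can be chosen after the run.  The recycling pool can be
supplied separately from the starting ensemble (used by the
steady-profile validation fixture below).

Randomness: iteration t of a run with seed s uses a generator spawned
from `SeedSequence([s, t])`; each walker consumes its own row of the
iteration's noise, so the two children of a split decorrelate
immediately.  Runs are bitwise reproducible from the seed.

The stage-1 → stage-2 switch can be triggered manually (an iteration
number) or by the run-level trigger `stage1_complete()`: every
initial-conformation lineage has either produced a descendant that
visited the encounter state or has no live descendants.  Switching
never touches weights or dynamic states — only future binning.

## Kinetics

State entries are detected once per τ; recrossings faster than τ are
invisible.  This is the analysis resolution of the whole pipeline, and
it biases absorbing-boundary fluxes slightly low (see "Validation
fixtures").

`conditional_flux(A → B | binding)` sums, per iteration, the weights of
walkers entering B that qualify for the binding direction: history
label 'U' when A is the unbound (initial) state, or previous
instantaneous state A with label 'U' when A is an intermediate
(encounter).  Every labeled entry event is counted, including repeated
entries by the same lineage.  Labeled populations are time averages of
the summed weights per (state, label) cell.  Rates follow the equations
in the README; fluxes are kept in 1/τ internally and converted to
physical units only at reporting.  Rate windows default to trailing
spans (e.g. the last 100 iterations of a stage) and are reported with
every rate.

`effective_concentration` demands an explicit volume unit: a nm³/Å³
mix-up changes C0 by 10⁹, which is easy to miss in a reduced-unit code.
The validated reference point is 956 nm³ ↔ 1.737 mM.

## Uncertainty

* `flux_autocorr_tc`: the correlation time is the largest lag ℓ such
  that the autocorrelation is significant at every lag 1..ℓ, judged
  against a null distribution from iid resamples of the series.
  Requiring the run of significant lags to be contiguous is what makes
  the estimator stable: with ~n/10 lags tested, isolated false
  positives at long lags would otherwise set t_c almost surely.  A
  series with an insignificant lag-1 autocorrelation has t_c = 1.  No
  multiplicity correction is applied (single-lag decisions), which is
  conservative only through the contiguity requirement.
* `blocked_bootstrap_ci`: non-overlapping blocks of length t_c, trailing
  partial block dropped, percentile interval of the mean over resampled
  block means.  Percentile (not BCa) intervals: simplest method whose
  calibration we verify directly (95% coverage within ±3% on iid data).
* `independent_event_count`: the total arrival count plus an effective
  count `total² / Var_boot(total)` from block-resampled per-iteration
  counts.  For sparse uncorrelated unit events this equals the total
  (Poisson variance); duplicating events inside a correlation window
  leaves it unchanged.  For dense WE arrival series the effective count
  can exceed the raw total — weight-regularized arrivals are
  sub-Poisson — and should then be read as "the counting noise is
  smaller than independent events would give", not as extra events.
* `ratio_ci`: first-order delta method; relative half-widths add in
  quadrature.  Used for the productive-collision percentage.

## Pathway analyses

The transition path ensemble (TPE) contains, for every first entry into
the bound state by a binding-labeled walker, the frames from just after
the lineage's last unbound visit through the arrival frame, recovered by
walking the stored parent links backwards.  All intermediate frames are
included; encounter membership is flagged per frame.  A frame's TPE
weight is the sum of the arrival weights of the successful paths through
it.  Paths with different root conformations are statistically
independent; the number of distinct roots is the independent-event count
of the pathway analysis.  Recycling truncates lineages, so TPE analyses
are normally run on equilibrium-mode stores.

Event durations are `n_frames · τ` with a weighted histogram (default
bin width τ) and the modal value reported with its bin width.  Contact
probabilities are weighted frame fractions within a distance cutoff
(default 4.5 length units) for each (receptor patch point, ligand
anchor) pair — the toy stand-in for residue–residue contacts, chosen so
that a real-structure extension only changes the distance table.

The histogram entropy is `S/R = −Σ p_i ln p_i` over a weighted
histogram; exact closed forms (`ln k` for k uniform cells) are asserted
in the tests, and a 15–35 bin scan checks qualitative stability.
K-centers is the greedy farthest-point algorithm (deterministic given
the seed index, 2-approximation verified exhaustively on small
instances) with a Canberra metric by default; the default k = 50 for toy
runs is a scaled-down analogue of thousands of clusters on large
atomistic TPEs, and is a flag.  The conformation space network is a
directed graph of cluster-to-cluster transitions with node weights equal
to total cluster probability; layout is deliberately out of scope (any
force-directed renderer works on the exported GraphML).

The spherical entry-point map uses `n_bins` equal-area latitude bands
(uniform in z) subdivided in longitude into near-equal-area cells; each
cell is annotated with its exact solid angle, and isotropy of uniform
directions is verified at 3σ.  The binning scheme is recorded in the
output metadata.

## Validation fixtures and problem sizes

* Double-well Langevin (h = 3 kT): WE equilibrium bin probabilities
  (4000 iterations, first 1000 discarded, per-bin σ from
  correlation-time-blocked bootstrap) against a 10⁷-step brute-force
  histogram and the Boltzmann closed form.
* Hill relation: eps = 0 free diffusion with an absorbing sphere at
  b = 8 inside the reflecting wall, recycled from the unbound shell.
  The closed form `T(r0) = (1/D)[(R³/3)(1/b − 1/r0) − (r0² − b²)/6]`
  gives the expected flux 1/⟨T⟩.  Because flux fluctuations relax on
  the container diffusion timescale, a single run is one correlated
  sample; the check therefore uses 12 independent replicas, each started
  from the analytic steady-state radial profile
  (`shell_steady_positions`, which removes the container-scale
  transient) and treated as one block in the bootstrap.  Detection at τ
  resolution and the Euler scheme bias the flux a few percent low at
  the chosen dt = 0.004, τ = 6 steps; the replica CI comfortably
  contains the closed form.
* Rate pipeline: a 300-replica brute-force renewal oracle (states
  evaluated every τ, ≥ 200 binding events) against a 300-walker
  recycling WE run, compared through overlapping 95% CIs for k1, k2 and
  kon.
* Weight conservation: |Σw − 1| ≤ 10⁻¹² at each of 500 iterations.

These sizes are the package's validation defaults; they were chosen to
give decisive statistics for each check on a single CPU.

## What the synthetic generator does and does not show

The toy model reproduces the statistical structure the analysis assumes:
diffusive encounter, a metastable non-native intermediate, orientational
rearrangement into a deep native basin, and a two-dimensional progress
coordinate with the distance/orientation duality of a binding RMSD.  It
has no internal conformational degrees of freedom, no solvent, no
hydrodynamics, and spheres instead of molecular surfaces.  Passing tests
therefore demonstrate that the WE machinery, kinetics, uncertainty and
pathway analyses are algorithmically correct and statistically unbiased
— not that any particular molecular system behaves like the toy.
Quantities like the productive-collision percentage or modal event
duration reported by the acceptance script characterize the toy model
itself.

## Known limitations

* Sub-τ recrossings are invisible everywhere (single analysis
  resolution), so absorbing-state fluxes carry a small negative bias
  that shrinks with τ.
* The correlation-time estimator assumes monotonically decaying
  autocorrelation; oscillatory correlation structures would truncate the
  contiguous run early.
* The effective independent-event count is a variance-based effective
  sample size, not a count of distinct physical events; use TPE roots
  for the latter.
* `fixed_total` allocation can starve fine bins when many are occupied
  (each gets at least one walker, but no more until heavy bins are
  served); this mirrors the even-coverage intent of the rule and is the
  documented trade-off.
* The run store keeps full per-iteration tables; very long runs with
  `store_dyn=True` grow linearly in memory and file size.
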