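# Methods

`hbdyn` reimplements, end to end, the quantitative analysis of early
*hunchback* (*hb*) transcription driven by the Bicoid morphogen gradient in
the syncytial fly embryo: from MS2-MCP-style intensity traces through
trace features and embryo-scale pattern statistics to a stochastic
N-binding-site promoter model, its fitting and selection, and
concentration-sensing limits.  Because no raw movies are available, the
package ships a first-class synthetic-data generator whose defaults encode
the study conditions; every pipeline stage is validated against it.

## Coordinates, clocks and study conditions

Positions are percent egg length (% EL) in a boundary-aligned frame: 0 is
where the cumulative activity probability P_ON crosses 1/2 at nuclear
cycle 12, anterior negative.  The imaged window is −25..+25% EL.  Times
are seconds on the per-nucleus clock, origin at nucleus birth (first
sibling separation).  Interphase durations are 400/500/750 s for nc11/12/13
and expression shuts off simultaneously at all positions at those times;
nucleus counts double each cycle (defaults 100/200/400 in the window).
Traces are sampled at the reference frame interval of 13.05 s.

The activator gradient is exponential, `c(x) = c0·exp(−x/λ)` with
λ = 20% EL, so a 2% EL step (one internuclear distance) changes the
concentration by ≈10% — the discrimination problem the boundary poses.
λ is configurable; every steepness value records the λ convention used,
because a Hill coefficient in concentration equals λ times the logistic
slope in position.

## Synthetic embryos

`place_nuclei` draws a jittered lattice; `assign_birth_times` models the
two mitotic waves as constant-speed fronts starting at the poles and
meeting at t = 0 (wave speed default 5/3 % EL/s, i.e. a pole-to-middle
delay of ≈30 s).  `generate_parametric_traces` emits, per nucleus, a
plateau trace that is zero before a position-dependent onset (a hard floor
of 150 s after mitosis — genome decondensation, activator re-import and
reporter signal build-up — plus an exponential latency whose mean scales
inversely with local activator concentration) and zero after the common
shut-off.  Activity along the axis follows a logistic law of configurable
steepness.  Noise is multiplicative log-normal on the plateau plus
additive Gaussian detection noise, both configurable and zero-able; the
ground-truth table stores the features of the noiseless trace, so feature
extraction on noiseless data recovers it exactly (tested).
`render_stack` draws one discrete Gaussian blob per active nucleus whose
voxel sum equals the trace value, over Poisson-noised background, for the
spot-detection stage.

What the generator deliberately does not emulate: photobleaching, MCP
maturation, nuclear import dynamics, nuclei tracking errors, transcription
bursting within the ON period of a trace (the parametric traces are
plateaus; bursty traces come from the promoter model instead).  Tests
passing on synthetic data therefore validate the pipeline's arithmetic and
statistical behaviour, not its robustness to those real-data artifacts.

## Spot detection and birth times

Spots are detected per the published recipe: per-Z mean filter (half-width
1), threshold at 2× background (background = median voxel value), 3D
connected components (26-connectivity, configurable to 6), discard
components under 10 voxels, intensity = sum of *raw* voxel values of the
component.  Detection is monotone in the threshold factor (raising it can
only remove spots — the rule used to kill MCP-aggregate artifacts) and has
precision = recall = 1 on noiseless rendered fixtures.  Birth time is
estimated from the sibling centroid-distance series as the time its
smoothed derivative first falls below 10% of the peak separation speed
after that peak; the threshold crossing is interpolated and the moving
-average group delay subtracted, giving median errors below one frame on
noisy saturating curves.

## Trace features and pattern statistics

A trace is summarized by three consecutive epochs — t_init (onset of
interphase to first detection), t_active (first to last detection;
interior gaps count as active), t_end (remainder) — which partition the
interphase to within one frame (asserted per trace), plus the trapezoidal
integral ΣI and mean rate μI = ΣI/t_active.  Position summaries follow the
reference convention: t_init over expressing nuclei only; ΣI and μI
include silent nuclei as zeros.

P_SPOT(t, x) is the fraction of nuclei per 2% EL bin with a visible spot
at t (empty bins are NaN, never zero); P_ON is its cumulative per-cycle
counterpart, and P_ON(x) ≥ P_SPOT(t, x) always (property-tested).
Embryos are aligned by shifting each P_ON profile so its interpolated 0.5
crossing sits at 0% EL, which compensates the 2–3% EL inter-embryo
gradient variability before pooling.

Boundary profiles are fitted with `f(x) = f_max/(1 + exp(H (x − x0)/λ))`,
f_max estimated jointly; with per-bin nucleus counts the fit is
iteratively reweighted by the binomial variance (this matters: on
500-nucleus binary fixtures the weighted fit recovers the generating
exponent within 15% in ≥90% of seeds, the unweighted one does not).
Two steepness measures coexist on purpose:

* `fit_sigmoid` — global logistic least squares, the measure for data
  profiles and for steep model patterns (which are nearly logistic);
* `hill_of_model` — the log-slope of ln(f/(f_max − f)) versus ln c at the
  half-maximum, the Hill coefficient proper.  For the asymmetric pattern
  of independent binding sites the two differ (the posterior flank is
  steeper than the boundary): the closed form 2N(1 − 2^(−1/N)) ≈ 1.31 at
  N = 6 is the *local* measure, and that is what the package reports for
  such profiles.

Formation time at a position is Δt = t_steady − t_first, with t_first the
first time above the noise floor (2 SD of the pre-onset baseline; zero for
deterministic series) and t_steady the first time within 5% of the
plateau.  The anterior/boundary zone partition slides a 5% EL window and
KS-tests it against the most-anterior pool at α = 0.05 without multiple
-testing correction, reporting the first significant window; both window
width and the first-crossing rule are conventions recorded in the output.

## The promoter model

The promoter has N identical activator sites; the state is the number
bound.  Binding per free site is diffusion-limited,
`k_b(x) = (1/t_bind)·c(x)/c(boundary)` with t_bind = 4 s (the single-site
search time at the boundary); binding can never be tuned above this cap.
Unbinding constants are position-independent but may depend on occupancy —
lower unbinding from high-occupancy states is the model's notion of
cooperativity.  The gene is active only when all N sites are bound
(all-or-nothing); RNAP then arrives as a Poisson process with
k_ini = 1/6 s⁻¹ (the canonical loading interval reported for this
promoter by live-imaging studies).  Each initiation launches a polymerase
at 25 nt/s along a 3.3 knt transcript whose 1.3 knt 24-loop MS2 cassette
starts 0.7 knt in, giving the loop-count kernel L(t): zero until 28 s, a
ramp to 24 loops by 80 s, constant until release at 132 s.  Spot intensity
is the summed loop count of all nascent transcripts; a spot is detectable
at threshold 24 loop-equivalents (one fully loaded transcript).  All of
these are configurable; the published text fixes only the shape of L(t)
and t_bind, so the rate values are this package's own documented choices.

The occupancy chain is solved three ways, cross-validated against each
other: closed-form stationary distribution (detailed balance), exact
eigendecomposition of the master equation (the 11-state system is tiny, so
an implicit stiff integrator is unnecessary; conservation is checked to
1e−9 at every step), and exact Gillespie simulation.  The spot probability
P_SPOT(t) is computed deterministically by an initiation-counting
extension of the master equation: a spot is visible iff at least one
initiation fell within the window [t − 132 s, t − 80 s] during which a
transcript carries its full loop complement, and the probability of *no*
initiation in a window is obtained by propagating with the generator minus
a k_ini sink on the ON state (a Feynman–Kac functional).  This observable
ignores sub-threshold pile-up of partially transcribed cassettes, so the
trajectory-simulated, intensity-thresholded P_SPOT sits slightly above it
(≈0.5–0.6 at a boundary calibrated to 0.5); the exact window-event
observable agrees with the simulation to Monte-Carlo error (tested), and
the published pattern maps are reproduced with the simulated route
(200 trajectories per position by default).

## Fitting, model selection and sensing limits

The boundary is where the steady spot probability equals 1/2: calibration
bisects the overall unbinding scale (the occupancy observable is also
supported, and is the one the closed-form oracles use).  With binding
capped and the scale pinned, the only freedom is the cooperativity
profile.  `fit_kinetics` searches it to maximize the steady pattern's
steepness subject to the boundary formation time Δt ≤ 180 s (5% plateau
tolerance): by default over the full per-state unbinding vector (N − 1
log-rate shape parameters; seeded differential evolution with a
Nelder–Mead polish, deterministic given the seed), optionally over the
single last-state stabilization factor ε, whose optimum sits on the
formation-time frontier and is found by bisection.  The single-ε family
saturates around fitted H ≈ 5 for N = 9 under the time constraint, far
below what per-state cooperativity achieves — which is why the general
profile is the default.

`min_sites_for_steepness` runs this fit for N = 6..10 and reports the
smallest N whose achieved (sigmoid-fitted) steepness reaches the target.
Under the package's defaults the achievable steepness at 180 s is
≈6.1/6.9/7.7/8.4/9.1 for N = 6..10, so the scan returns N = 8 for a
target of H = 7; the nine-site model comfortably exceeds the target.  The
reference analysis, whose exact fitting machinery is not public, reports
N = 9 — the discrepancy is within the reconstruction uncertainty of the
detection threshold and initiation rate, both of which were fixed here a
priori and not adjusted afterwards.

Model selection uses per-nucleus Bernoulli likelihoods of late-interphase
activity against each fitted model's steady profile, likelihood-ratio
tests between consecutive N (χ², df = parameter difference) and
BIC = k·ln n − 2·logL.  The Berg–Purcell limit is implemented in its
single-receptor occupancy-noise form, T = 2·t_bind/(δ²(1 − p)): with
t_bind = 4 s, 10% accuracy and half occupancy, T = 1600 s ≈ 26.7 min —
a single site cannot read the gradient in one interphase.  The prefactor
convention (factor 2, (1 − p) correction) is stated here because
conventions differ across the literature; the ≥25 min conclusion is robust
to the occupancy correction.  `readout_noise` measures δmRNA/⟨mRNA⟩ of
integrated initiation counts across trajectories; the fitted cooperative
models are strictly noisier than the independent-sites model at equal
integration time (tested), the price of steepness.

## Zelda motif scan

The 24×MS2 cassette is reconstructed as 12 tandem repeats of a two-loop
unit: each repeat carries one CAGGTCG in its short linker and one TAGGTAC
plus one TAGGCAA in its long linker.  The published linker sequences are
not available verbatim, so the filler bases are synthetic, chosen so the
cassette carries exactly these 36 TAGteam-like heptamers and nothing else
(the unit is flagged as a reconstruction in the module).  The scan rule
requires the AGG core (positions 2–4 of CAGGTAG) intact and at most three
mismatches overall — the signature shared by all literature TAGteam
variants; a plain mismatch count without the core requirement would match
spurious windows inside the stem-loop itself.  CAGGTCG's mismatch sits at
the critical position 6 and is flagged as such.  `mutate_sites` disrupts
every hit by transversions (critical positions first) until the window can
no longer satisfy the rule, preserves length and stem loops, and verifies
by re-scanning.  Coordinates are 0-based half-open; the forward strand is
scanned by default (the reverse strand of the shipped cassette carries no
sites), with reverse-strand scanning one flag away.

## Numerical choices and limitations

* Master-equation solutions via dense eigendecomposition: exact and fast
  for ≤ 11 states; not intended for large state spaces.
* Calibration bisection to 1e−12 on the log scale; steepness optimization
  budgets (differential evolution maxiter 100, popsize 12, Sobol
  initialization) chosen so the full N = 6..10 scan runs in ~5 minutes on
  one CPU; enlarging the budget changes achieved steepness by ≲1%.
* Formation-time grids: 5 s steps to 900 s (the plateau criterion is
  grid-resolved to half a step).
* Degenerate inputs are first-class: absorbing chains (zero unbinding),
  flat densities, profiles that never cross 1/2, empty bins and inactive
  traces all return flagged results or warnings rather than fabricated
  numbers.
* The deterministic P_SPOT observable undercounts partial-transcript
  pile-up (see above); analyses that need the exact intensity-threshold
  observable should use `pattern_from_model(..., method="ssa")`.
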