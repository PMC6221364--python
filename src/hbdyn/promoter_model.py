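"""Stochastic N-site promoter model of Bicoid-activated transcription.

The promoter carries ``N`` identical activator binding sites.  Its state is
the number of bound activator molecules, ``i = 0..N``; binding of the
diffusing activator is concentration-limited, so the per-free-site binding
rate at anterior-posterior position ``x`` is

    k_b(x) = (1 / t_bind) * c(x) / c(x_boundary),

where ``t_bind`` is the diffusion-limited search time of one molecule for
one site at the boundary concentration (default 4 s) and ``c`` the
exponential activator gradient.  Unbinding rate constants are uniform along
the axis but may depend on the occupancy state — lower unbinding from highly
occupied states encodes binding cooperativity.  The gene is active in the
all-or-nothing sense: transcription initiation is possible only while all
``N`` sites are bound, during which RNA polymerases arrive as a Poisson
process of rate ``k_ini``.

Each initiation event launches a polymerase along the reporter gene; the
nascent transcript picks up MS2 stem loops while the cassette is being
transcribed and sheds them on release, giving the loop-count kernel
``L(t)``.  The summed loop count over all nascent transcripts is the spot
intensity; a locus shows a detectable spot when that intensity reaches the
detection threshold (by default the brightness of one fully loaded
transcript).

Both an exact Gillespie simulation and a master-equation solution (via
eigendecomposition of the occupancy-state generator) are provided, together
with a deterministic computation of the spot probability ``P_SPOT(t, x)``
that uses an initiation-counting (Feynman-Kac) extension of the master
equation: a spot is visible at time ``t`` iff at least one initiation fell
in the window ``[t - t_release, t - t_full]`` during which a transcript
carries its full complement of loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .synthetic_embryo import BicoidGradient

__all__ = [
    "PromoterKinetics",
    "MasterSolution",
    "PromoterTrajectory",
    "MS2Params",
    "ModelPattern",
    "build_generator",
    "stationary_distribution",
    "solve_master_equation",
    "simulate_ssa",
    "simulate_initiations",
    "ms2_loop_count",
    "synthesize_intensity",
    "spot_probability_steady",
    "spot_probability_timecourse",
    "pattern_from_model",
]

#: Default RNAP arrival rate while the gene is active (one initiation every
#: ~6 s, the canonical loading interval measured for the hb P2 promoter).
DEFAULT_K_INI = 1.0 / 6.0


@dataclass(frozen=True)
class MS2Params:
    """Geometry of the MS2 reporter transcript (nt and nt/s)."""

    n_loops: int = 24
    cassette_start: float = 700.0
    cassette_length: float = 1300.0
    gene_length: float = 3300.0
    elongation_rate: float = 25.0

    def __post_init__(self) -> None:
        if self.cassette_start < 0 or self.cassette_length <= 0:
            raise ValueError("invalid cassette geometry")
        if self.cassette_start + self.cassette_length > self.gene_length:
            raise ValueError("cassette extends past the gene end")
        if self.elongation_rate <= 0 or self.n_loops <= 0:
            raise ValueError("rates and loop count must be positive")

    @property
    def t_cassette_start(self) -> float:
        """Seconds after initiation when loops start appearing."""
        return self.cassette_start / self.elongation_rate

    @property
    def t_cassette_full(self) -> float:
        """Seconds after initiation when all loops are present."""
        return (self.cassette_start + self.cassette_length) / self.elongation_rate

    @property
    def t_release(self) -> float:
        """Seconds after initiation when the transcript is released."""
        return self.gene_length / self.elongation_rate


@dataclass(frozen=True)
class PromoterKinetics:
    """Rates of the N-site promoter at every AP position.

    ``k_u[i-1]`` is the per-molecule unbinding rate constant from the state
    with ``i`` bound (total rate out of state ``i`` downward is
    ``i * k_u[i-1]``); it is position-independent.  The per-free-site binding
    rate is concentration-proportional and capped at ``1/t_bind`` scaled by
    the local-to-boundary concentration ratio (diffusion limit).
    """

    n_sites: int
    k_u: np.ndarray
    t_bind: float = 4.0
    gradient: BicoidGradient = field(default_factory=BicoidGradient)
    x_boundary: float = 0.0
    k_ini: float = DEFAULT_K_INI

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_u", np.asarray(self.k_u, dtype=float))
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.k_u.shape != (self.n_sites,):
            raise ValueError("k_u must have one entry per occupancy state 1..N")
        if np.any(self.k_u < 0) or self.t_bind <= 0 or self.k_ini < 0:
            raise ValueError("rates must be non-negative and t_bind positive")

    def binding_rate(self, x) -> np.ndarray | float:
        """Per-free-site binding rate at position(s) ``x`` (1/s)."""
        c = self.gradient.concentration(x)
        return (1.0 / self.t_bind) * c / self.gradient.concentration(self.x_boundary)

    def with_scaled_unbinding(self, scale: float) -> "PromoterKinetics":
        return replace(self, k_u=self.k_u * float(scale))

    @staticmethod
    def uniform(n_sites: int, k_u: float, eps: float = 1.0, **kw) -> "PromoterKinetics":
        """Uniform unbinding with optional stabilization of the full state.

        ``eps < 1`` lowers only the unbinding constant of the fully bound
        state (the minimal cooperativity parameterization).
        """
        ku = np.full(n_sites, float(k_u))
        ku[-1] *= float(eps)
        return PromoterKinetics(n_sites=n_sites, k_u=ku, **kw)


@dataclass
class MasterSolution:
    """Occupancy-state probabilities ``P_i(t)`` on a time grid at one position."""

    times: np.ndarray
    probabilities: np.ndarray  # shape (T, N+1)
    x: float

    @property
    def p_full(self) -> np.ndarray:
        """Probability that all sites are bound (gene active)."""
        return self.probabilities[:, -1]


@dataclass
class PromoterTrajectory:
    """One Gillespie realization of the occupancy chain.

    ``times[j]`` is the time of the j-th jump into ``states[j]``; the state
    is held until the next jump or ``duration``.  ``times[0] = 0`` with the
    initial state.
    """

    times: np.ndarray
    states: np.ndarray
    duration: float
    n_sites: int

    def on_intervals(self) -> np.ndarray:
        """Maximal intervals during which all sites are bound, shape (k, 2)."""
        out = []
        t_on = None
        for t, s in zip(self.times, self.states):
            if s == self.n_sites and t_on is None:
                t_on = t
            elif s != self.n_sites and t_on is not None:
                out.append((t_on, t))
                t_on = None
        if t_on is not None:
            out.append((t_on, self.duration))
        return np.asarray(out, dtype=float).reshape(-1, 2)

    def state_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return self.states[np.clip(idx, 0, None)]


def build_generator(kin: PromoterKinetics, x: float) -> np.ndarray:
    """Transition-rate matrix over occupancy states 0..N at position ``x``.

    Row convention: ``Q[i, j]`` is the rate from state ``i`` to ``j``; rows
    sum to zero.  Binding ``i -> i+1`` at rate ``(N - i) k_b(x)``; unbinding
    ``i -> i-1`` at rate ``i * k_u[i-1]``.
    """
    kb = float(kin.binding_rate(x))
    if not np.isfinite(kb) or kb < 0:
        raise ValueError(f"position {x} outside the gradient domain")
    n = kin.n_sites
    q = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        if i < n:
            q[i, i + 1] = (n - i) * kb
        if i > 0:
            q[i, i - 1] = i * kin.k_u[i - 1]
        q[i, i] = -q[i].sum()
    return q


def stationary_distribution(kin: PromoterKinetics, x: float) -> np.ndarray:
    """Equilibrium occupancy distribution (detailed balance of the chain)."""
    kb = float(kin.binding_rate(x))
    n = kin.n_sites
    logpi = np.zeros(n + 1)
    for i in range(n):
        down = (i + 1) * kin.k_u[i]
        if down == 0:
            # absorbing upward: all mass ends at the top of the reachable set
            logpi[i + 1:] = np.inf if kb > 0 else -np.inf
            break
        logpi[i + 1] = logpi[i] + np.log((n - i) * kb) - np.log(down)
    if np.any(np.isinf(logpi)):
        pi = np.zeros(n + 1)
        pi[np.argmax(logpi)] = 1.0
        return pi
    pi = np.exp(logpi - logpi.max())
    return pi / pi.sum()


def _eig_propagator(q_colform: np.ndarray):
    vals, vecs = np.linalg.eig(q_colform)
    inv = np.linalg.inv(vecs)
    def apply(t: float, p: np.ndarray) -> np.ndarray:
        return np.real(vecs @ (np.exp(vals * t) * (inv @ p)))
    return apply


def solve_master_equation(kin: PromoterKinetics, x: float, times: np.ndarray,
                          p0: np.ndarray | None = None) -> MasterSolution:
    """Time-dependent occupancy probabilities from the empty-promoter start.

    All sites are free at ``t = 0`` unless ``p0`` is given.  Solved by
    eigendecomposition of the generator (exact for this small linear
    system); probabilities are renormalized against accumulated round-off
    and conservation is enforced to 1e-9.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or times[0] < 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be increasing and start at >= 0")
    n = kin.n_sites
    if p0 is None:
        p0 = np.zeros(n + 1)
        p0[0] = 1.0
    prop = _eig_propagator(build_generator(kin, x).T)
    probs = np.empty((times.size, n + 1))
    for j, t in enumerate(times):
        p = prop(t, p0)
        s = p.sum()
        if not np.isfinite(s) or abs(s - 1.0) > 1e-6:
            raise FloatingPointError(
                f"master-equation propagation lost probability at t={t}: sum={s}")
        probs[j] = np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()
    return MasterSolution(times=times, probabilities=probs, x=x)


def simulate_ssa(kin: PromoterKinetics, x: float, duration: float,
                 seed=None) -> PromoterTrajectory:
    """Exact stochastic simulation of the occupancy chain (Gillespie)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    kb = float(kin.binding_rate(x))
    n = kin.n_sites
    t, state = 0.0, 0
    times, states = [0.0], [0]
    while True:
        up = (n - state) * kb
        down = state * kin.k_u[state - 1] if state > 0 else 0.0
        total = up + down
        if total <= 0:
            break  # absorbing state
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        state += 1 if rng.random() < up / total else -1
        times.append(t)
        states.append(state)
    return PromoterTrajectory(np.asarray(times), np.asarray(states, dtype=int),
                              float(duration), n)


def simulate_initiations(traj: PromoterTrajectory, k_ini: float,
                         seed=None) -> np.ndarray:
    """Poisson transcription-initiation times within the ON intervals."""
    if k_ini < 0:
        raise ValueError("k_ini must be >= 0")
    rng = np.random.default_rng(seed)
    events = []
    for a, b in traj.on_intervals():
        k = rng.poisson(k_ini * (b - a))
        events.extend(rng.uniform(a, b, size=k))
    return np.sort(np.asarray(events, dtype=float))


def ms2_loop_count(t_since_init, p: MS2Params = MS2Params()) -> np.ndarray:
    """Number of MS2 loops on one nascent transcript ``t`` s after initiation.

    Zero until the polymerase reaches the cassette, a linear ramp to
    ``n_loops`` while the cassette is transcribed, constant until the gene
    end is reached, then zero on release.
    """
    t = np.asarray(t_since_init, dtype=float)
    ramp = (t - p.t_cassette_start) / (p.t_cassette_full - p.t_cassette_start)
    out = np.clip(ramp, 0.0, 1.0) * p.n_loops
    out = np.where((t < 0) | (t >= p.t_release), 0.0, out)
    return out if out.ndim else float(out)


def synthesize_intensity(events: np.ndarray, p: MS2Params,
                         times: np.ndarray) -> np.ndarray:
    """Spot intensity (loop-equivalents): summed loop counts of all nascents."""
    events = np.asarray(events, dtype=float)
    times = np.asarray(times, dtype=float)
    if events.size == 0:
        return np.zeros_like(times)
    if np.any(np.diff(events) < 0):
        raise ValueError("events must be sorted")
    return ms2_loop_count(times[:, None] - events[None, :], p).sum(axis=1)


# ---------------------------------------------------------------------------
# Deterministic spot probability
#
# A locus shows a spot at time t (threshold = one fully loaded transcript)
# iff at least one initiation occurred in [t - t_release, t - t_full].  The
# probability of *no* initiation in a window is the expectation of
# exp(-k_ini * time spent ON during the window), an observable of the
# occupancy chain computed exactly by propagating with the generator minus
# the initiation-rate sink on the ON state.
# ---------------------------------------------------------------------------

def _q_colform(kin: PromoterKinetics, x: float, sink: bool):
    q = build_generator(kin, x).T
    if sink:
        q = q.copy()
        q[-1, -1] -= kin.k_ini
    return q


def spot_probability_steady(kin: PromoterKinetics, x, ms2: MS2Params = MS2Params()) -> np.ndarray | float:
    """Steady-state probability of a visible spot at position(s) ``x``."""
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    w = ms2.t_release - ms2.t_cassette_full
    out = np.empty(xs.shape)
    for j, xi in enumerate(xs):
        pi = stationary_distribution(kin, xi)
        prop = _eig_propagator(_q_colform(kin, xi, sink=True))
        out[j] = 1.0 - prop(w, pi).sum()
    return out if np.ndim(x) else float(out[0])


def spot_probability_timecourse(kin: PromoterKinetics, x: float, times: np.ndarray,
                                ms2: MS2Params = MS2Params()) -> np.ndarray:
    """``P_SPOT(t)`` at one position from the empty-promoter start.

    Exactly zero before one cassette can have been fully transcribed
    (``t < t_cassette_full``).
    """
    times = np.asarray(times, dtype=float)
    n = kin.n_sites
    p0 = np.zeros(n + 1)
    p0[0] = 1.0
    prop_free = _eig_propagator(_q_colform(kin, x, sink=False))
    prop_sink = _eig_propagator(_q_colform(kin, x, sink=True))
    out = np.zeros(times.shape)
    for j, t in enumerate(times):
        t1 = max(0.0, t - ms2.t_release)
        t2 = max(0.0, t - ms2.t_cassette_full)
        if t2 <= t1:
            continue
        p = prop_free(t1, p0)
        out[j] = 1.0 - prop_sink(t2 - t1, p).sum()
    return np.clip(out, 0.0, 1.0)


@dataclass
class ModelPattern:
    """``P_SPOT`` on a (time x position) grid with its provenance."""

    x: np.ndarray
    times: np.ndarray
    pspot: np.ndarray  # shape (T, X)
    n_trajectories: int
    threshold: float
    method: str


def pattern_from_model(kin: PromoterKinetics, x_grid: np.ndarray, times: np.ndarray,
                       n_traj: int = 200, threshold: float = 24.0,
                       ms2: MS2Params = MS2Params(), seed=None,
                       method: str = "ssa") -> ModelPattern:
    """Model-predicted spot-probability pattern ``P_SPOT(t, x)``.

    ``method="ssa"`` runs ``n_traj`` Gillespie trajectories per position,
    synthesizes their MS2 intensities and thresholds them (the trajectory
    count of the published maps is 200).  ``method="master"`` returns the
    deterministic one-mature-transcript computation instead (fast, no
    sampling noise; ``n_traj`` and ``threshold`` are ignored beyond being
    recorded).
    """
    x_grid = np.asarray(x_grid, dtype=float)
    times = np.asarray(times, dtype=float)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    pspot = np.zeros((times.size, x_grid.size))
    if method == "master":
        for j, x in enumerate(x_grid):
            pspot[:, j] = spot_probability_timecourse(kin, x, times, ms2)
        return ModelPattern(x_grid, times, pspot, 0, threshold, "master")
    if method != "ssa":
        raise ValueError("method must be 'ssa' or 'master'")
    root = np.random.default_rng(seed)
    duration = float(times[-1])
    for j, x in enumerate(x_grid):
        count = np.zeros(times.size)
        for _ in range(n_traj):
            traj = simulate_ssa(kin, x, duration, seed=root)
            ev = simulate_initiations(traj, kin.k_ini, seed=root)
            inten = synthesize_intensity(ev, ms2, times)
            count += inten >= threshold
        pspot[:, j] = count / n_traj
    return ModelPattern(x_grid, times, pspot, n_traj, threshold, "ssa")
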