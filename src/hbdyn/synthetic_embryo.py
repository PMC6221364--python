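"""Synthetic embryo-scale datasets for the transcription-pattern pipeline.

Generates the raw material the analysis consumes — an exponential activator
gradient, nuclei with positions and mitotic-wave birth times, per-nucleus
MS2-like intensity traces with known ground truth, and optional 3D image
stacks with Gaussian spots — so that every downstream stage can be exercised
and validated without any external data.

Conventions: anterior-posterior positions in percent egg length (% EL) in a
boundary-aligned frame (0 at the nc12 expression boundary, anterior
negative); times in seconds.  The default imaged window is -25..+25% EL and
the interphase durations are 400/500/750 s for nuclear cycles 11/12/13,
with nucleus counts doubling each cycle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .trace_analysis import IntensityTrace, extract_features

__all__ = [
    "BicoidGradient",
    "EmbryoConfig",
    "TraceParams",
    "place_nuclei",
    "assign_birth_times",
    "generate_parametric_traces",
    "sample_hill_activity",
    "render_stack",
    "save_dataset",
]

#: Interphase durations (s) by nuclear cycle: expression shuts off
#: simultaneously at all positions at these times.
INTERPHASE_S = {11: 400.0, 12: 500.0, 13: 750.0}

#: Default nucleus counts in the imaged window; density doubles per cycle.
N_NUCLEI = {11: 100, 12: 200, 13: 400}

#: Earliest possible transcription onset after mitosis (s): genome
#: decondensation, activator re-import and signal build-up.
ONSET_FLOOR_S = 150.0

#: Frame interval of the reference movies (s).
FRAME_INTERVAL_S = 13.05


@dataclass(frozen=True)
class BicoidGradient:
    """Exponential anterior-posterior activator gradient.

    ``c(x) = c0 * exp(-(x - x_ref) / lambda_el)``, strictly decreasing
    toward the posterior.  The default decay length of 20% EL makes the
    concentration drop ~10% across a 2% EL step — the difference a nucleus
    on one side of the boundary must distinguish from the other side.
    """

    c0: float = 1.0
    lambda_el: float = 20.0
    x_ref: float = 0.0

    def __post_init__(self) -> None:
        if self.c0 <= 0 or self.lambda_el <= 0:
            raise ValueError("c0 and lambda_el must be positive")

    def concentration(self, x) -> np.ndarray | float:
        return self.c0 * np.exp(-(np.asarray(x, dtype=float) - self.x_ref) / self.lambda_el)

    __call__ = concentration


@dataclass(frozen=True)
class EmbryoConfig:
    """One synthetic embryo / nuclear cycle."""

    cycle: int = 12
    interphase_duration: float | None = None
    window: tuple[float, float] = (-25.0, 25.0)
    n_nuclei: int | None = None
    wave_speed: float = 5.0 / 3.0  # % EL per s; pole-to-middle delay ~30 s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle not in INTERPHASE_S and self.interphase_duration is None:
            raise ValueError(f"unknown cycle {self.cycle}: give interphase_duration")
        if self.window[1] <= self.window[0]:
            raise ValueError("empty window")
        if self.interphase_duration is not None and self.interphase_duration <= 0:
            raise ValueError("interphase_duration must be positive")

    @property
    def duration(self) -> float:
        return float(self.interphase_duration if self.interphase_duration is not None
                     else INTERPHASE_S[self.cycle])

    @property
    def count(self) -> int:
        return int(self.n_nuclei if self.n_nuclei is not None else N_NUCLEI[self.cycle])


def place_nuclei(cfg: EmbryoConfig) -> pd.DataFrame:
    """Nucleus table (nucleus_id, cycle, x_pct_el) on a jittered lattice."""
    n = cfg.count
    if n < 1:
        raise ValueError("n_nuclei must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.window
    spacing = (hi - lo) / n
    centers = lo + spacing * (np.arange(n) + 0.5)
    x = centers + rng.uniform(-spacing / 3, spacing / 3, size=n)
    x = np.clip(x, lo, hi)
    return pd.DataFrame({
        "nucleus_id": np.arange(n),
        "cycle": cfg.cycle,
        "x_pct_el": x,
    })


def assign_birth_times(nuclei: pd.DataFrame, wave_speed: float,
                       poles: tuple[float, float] = (-50.0, 50.0)) -> pd.DataFrame:
    """Birth times from two constant-speed mitotic waves meeting at t = 0.

    Each wave starts at a pole; a nucleus is born when the first wave
    reaches it, and the time axis is shifted so the two waves meet at
    ``t_meet = 0`` (all births at ``t <= 0``, earliest at the poles).
    """
    if wave_speed <= 0:
        raise ValueError("wave_speed must be positive")
    p1, p2 = poles
    if p1 == p2:
        raise ValueError("poles must be distinct")
    x = nuclei["x_pct_el"].to_numpy(dtype=float)
    d_near = np.minimum(np.abs(x - p1), np.abs(x - p2))
    d_meet = abs(p2 - p1) / 2.0
    out = nuclei.copy()
    out["t_birth_s"] = (d_near - d_meet) / wave_speed
    return out


@dataclass(frozen=True)
class TraceParams:
    """Parameters of the parametric (non-mechanistic) trace generator.

    Activity along the axis follows a logistic law of steepness
    ``hill_exponent`` around ``boundary_x``; active nuclei turn on after a
    position-dependent latency (floor plus an exponential waiting time whose
    mean scales inversely with local activator concentration) and hold a
    noisy plateau until the common interphase shut-off.
    """

    hill_exponent: float = 7.0
    boundary_x: float = 0.0
    onset_floor_s: float = ONSET_FLOOR_S
    onset_tau_s: float = 60.0
    plateau: float = 200.0
    noise_mult_sigma: float = 0.25
    noise_add_sigma: float = 5.0
    frame_interval_s: float = FRAME_INTERVAL_S
    shutoff_s: float | None = None

    def __post_init__(self) -> None:
        if self.noise_mult_sigma < 0 or self.noise_add_sigma < 0:
            raise ValueError("noise scales must be >= 0")
        if self.hill_exponent < 0:
            raise ValueError("hill_exponent must be >= 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")


def _activation_probability(x, params: TraceParams, gradient: BicoidGradient) -> np.ndarray:
    z = params.hill_exponent * (np.asarray(x, dtype=float) - params.boundary_x) / gradient.lambda_el
    return 1.0 / (1.0 + np.exp(z))


def generate_parametric_traces(nuclei: pd.DataFrame, gradient: BicoidGradient,
                               cfg: EmbryoConfig, params: TraceParams = TraceParams(),
                               ) -> tuple[list[IntensityTrace], pd.DataFrame]:
    """Per-nucleus traces plus the ground truth they were generated from.

    Traces are sampled on the per-nucleus clock (origin at nucleus birth) at
    the configured frame interval, are exactly zero before onset and after
    the common shut-off, and never turn on before the onset floor.  The
    returned ground-truth table holds the generating parameters and the
    feature values of the *noiseless* trace, so feature extraction on a
    noiseless dataset recovers it exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    shutoff = params.shutoff_s if params.shutoff_s is not None else cfg.duration
    times = np.arange(0.0, cfg.duration + 1e-9, params.frame_interval_s)
    traces: list[IntensityTrace] = []
    truth_rows = []
    p_act = _activation_probability(nuclei["x_pct_el"].to_numpy(), params, gradient)
    for row, p in zip(nuclei.itertuples(index=False), p_act):
        active = rng.random() < p
        signal = np.zeros_like(times)
        t_on = np.nan
        plateau_n = np.nan
        if active:
            c_rel = (gradient.concentration(params.boundary_x)
                     / gradient.concentration(row.x_pct_el))
            t_on = params.onset_floor_s + rng.exponential(params.onset_tau_s * c_rel)
            plateau_n = params.plateau * np.exp(
                rng.normal(0.0, params.noise_mult_sigma)
                - 0.5 * params.noise_mult_sigma ** 2)
            on = (times >= t_on) & (times <= shutoff)
            signal[on] = plateau_n
            if params.noise_add_sigma > 0:
                signal[on] = np.clip(
                    signal[on] + rng.normal(0.0, params.noise_add_sigma, on.sum()),
                    0.0, None)
            if t_on > shutoff:
                active = False  # latency outran the interphase
        tr = IntensityTrace(row.nucleus_id, times, signal, cfg.duration)
        traces.append(tr)
        clean = IntensityTrace(row.nucleus_id, times,
                               np.where((times >= (t_on if active else np.inf))
                                        & (times <= shutoff),
                                        plateau_n if active else 0.0, 0.0),
                               cfg.duration)
        f = extract_features(clean)
        truth_rows.append({
            "nucleus_id": row.nucleus_id, "x_pct_el": row.x_pct_el,
            "active": bool(f.active), "p_active": float(p),
            "t_onset_drawn_s": t_on, "plateau": plateau_n,
            "t_init_s": f.t_init, "t_active_s": f.t_active, "t_end_s": f.t_end,
            "sum_I": f.sum_I, "mu_I": f.mu_I,
        })
    return traces, pd.DataFrame(truth_rows)


def sample_hill_activity(n: int, hill_exponent: float, x0: float,
                         lambda_el: float = 20.0, seed=None,
                         window: tuple[float, float] = (-25.0, 25.0)) -> pd.DataFrame:
    """Binary activity sampled from a logistic law of position.

    Each nucleus at position ``x`` is active with probability
    ``1 / (1 + exp(H (x - x0) / lambda_el))`` — the fixture used to test
    steepness recovery by the sigmoid fitter.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if hill_exponent < 0:
        raise ValueError("hill_exponent must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(window[0], window[1], size=n)
    p = 1.0 / (1.0 + np.exp(hill_exponent * (x - x0) / lambda_el))
    return pd.DataFrame({"x_pct_el": x, "active": rng.random(n) < p, "p_active": p})


def render_stack(nuclei: pd.DataFrame, traces: list[IntensityTrace], t: float,
                 shape: tuple[int, int, int] = (12, 48, 192),
                 psf_sigma: tuple[float, float, float] = (1.2, 1.5, 1.5),
                 background: float = 10.0, noise: str | None = "poisson",
                 seed=None, window: tuple[float, float] = (-25.0, 25.0),
                 ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a 3D image stack of the spots active at time ``t``.

    One Gaussian blob per active nucleus, with integrated (summed-voxel)
    intensity equal to the trace value at ``t``, over a constant background
    that is Poisson-noised when ``noise="poisson"``.  Returns the stack and
    a ground-truth blob table (voxel-space centers and intensities).
    Positions map the AP window onto the last voxel axis; the other two
    coordinates are drawn reproducibly from ``seed``.
    """
    if min(shape) < 1 or min(psf_sigma) <= 0:
        raise ValueError("invalid stack geometry")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    stack = np.full(shape, float(background))
    rows = []
    for row, tr in zip(nuclei.itertuples(index=False), traces):
        if not (tr.times[0] <= t <= tr.times[-1]):
            raise ValueError(f"t={t} outside trace support for nucleus {row.nucleus_id}")
        amp = float(np.interp(t, tr.times, tr.intensities))
        cz = nz / 2.0 + rng.normal(0, nz / 8.0)
        cy = rng.uniform(0.15 * ny, 0.85 * ny)
        cx = (row.x_pct_el - window[0]) / (window[1] - window[0]) * nx
        cz = float(np.clip(cz, 2, nz - 3))
        cx = float(np.clip(cx, 2, nx - 3))
        if amp > 0:
            _add_blob(stack, (cz, cy, cx), psf_sigma, amp)
        rows.append({"nucleus_id": row.nucleus_id, "z": cz, "y": cy, "x": cx,
                     "intensity": amp})
    if noise == "poisson":
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
    elif noise is not None:
        raise ValueError("noise must be 'poisson' or None")
    return stack, pd.DataFrame(rows)


def _add_blob(stack: np.ndarray, center, sigma, total: float) -> None:
    """Add a discrete Gaussian blob whose voxel sum equals ``total``."""
    half = [int(np.ceil(4 * s)) for s in sigma]
    slices, axes = [], []
    for dim, (c, s, h) in enumerate(zip(center, sigma, half)):
        lo = max(0, int(np.floor(c)) - h)
        hi = min(stack.shape[dim], int(np.floor(c)) + h + 1)
        idx = np.arange(lo, hi)
        axes.append(np.exp(-0.5 * ((idx - c) / s) ** 2))
        slices.append(slice(lo, hi))
    kernel = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    ksum = kernel.sum()
    if ksum > 0:
        stack[tuple(slices)] += total * kernel / ksum


def save_dataset(path, nuclei: pd.DataFrame, traces: list[IntensityTrace],
                 truth: pd.DataFrame | None = None,
                 cfg: EmbryoConfig | None = None) -> None:
    """Write a dataset as plain-text files (nuclei.csv, traces.csv, ...)."""
    from pathlib import Path
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    nuclei.to_csv(p / "nuclei.csv", index=False)
    long = pd.concat([
        pd.DataFrame({"nucleus_id": tr.nucleus_id, "time_s": tr.times,
                      "intensity": tr.intensities})
        for tr in traces], ignore_index=True)
    long.to_csv(p / "traces.csv", index=False)
    if truth is not None:
        truth.to_csv(p / "ground_truth.csv", index=False)
    if cfg is not None:
        (p / "config.json").write_text(json.dumps(asdict(cfg), indent=2))
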