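"""Seeded generators for every input the analysis pipeline consumes.

Three kinds of data are emulated at the table level (no pixels):

* paired AP2/CLC fluorescence tracks of single endocytic events, with the
  AP2 channel saturating at a plateau and the CLC channel continuing to a
  maximum at scission, under one of three growth scenarios
  (``constant_area``, ``two_phase``, ``ap2_plateau``);
* steady-state EM morphometry snapshots (per-structure morphology class
  and projected area, grouped by membrane), produced by sampling events at
  uniformly random ages;
* CLEM calibration tables where summed fluorescence is proportional to
  coat surface area, i.e. to the projected area times a curvature
  correction factor embedded per morphology class and channel;
* osmotic-shock track sets in which a configurable fraction of events
  stalls at the pre-transition plateau during the stall window.

Every generator is driven by a single integer seed and emits a
ground-truth table alongside the data, enabling exact recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import _constant_area_projection
from .growth import (
    DEFAULT_THETA_MAX,
    CurvedGrowthParams,
    FlatGrowthParams,
    TransitionRule,
    TwoPhaseModel,
    assign_morphology_timeline,
)
from .tracks import MIN_FRAMES, IntensityTrack

__all__ = [
    "SimulationConfig",
    "ShockConfig",
    "generate_tracks",
    "generate_em_snapshot",
    "generate_clem_dataset",
    "generate_shock_tracks",
    "DEFAULT_TRUE_FACTORS",
]

GROWTH_MODELS = ("constant_area", "two_phase", "ap2_plateau")

#: Curvature correction factors embedded in the default CLEM scenario:
#: clathrin signal scales with the full coat surface (dome 1.4, pit 2.8)
#: while AP2 is diluted on curved coats (dome 1.2, pit 1.7).
DEFAULT_TRUE_FACTORS = {"clathrin": (1.4, 2.8), "ap2": (1.2, 1.7)}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the track generator.

    Lifetimes and per-event amplitudes are lognormal (right-skewed, as CME
    lifetimes are); ``time_offset_median`` (s) is the lag between the AP2
    plateau and the CLC maximum, and ``intensity_offset`` the configured
    excess of the normalized CLC maximum over the normalized AP2 maximum
    (set to ``None`` to let the two-phase surface geometry dictate the CLC
    overshoot instead).  Noise is additive Gaussian with standard
    deviation ``noise_sigma`` times the channel amplitude, with optional
    Poisson resampling on top.
    """

    n_tracks: int = 200
    frame_interval: float = 3.0
    model: str = "ap2_plateau"
    lifetime_median: float = 60.0
    lifetime_sigma: float = 0.25
    time_offset_median: float = 10.0
    time_offset_sigma: float = 0.20
    intensity_offset: float | None = 0.15
    s_final_median_nm2: float = 3.0e4
    s_final_sigma: float = 0.25
    ap2_amplitude: float = 100.0
    calibration_scale: float = 1.0
    rule: TransitionRule = field(default_factory=TransitionRule)
    theta_max: float = DEFAULT_THETA_MAX
    epsilon: float = 0.05
    noise_sigma: float = 0.05
    poisson: bool = False
    n_cells: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in GROWTH_MODELS:
            raise ValueError(f"unknown growth model {self.model!r}")
        for name in (
            "frame_interval",
            "lifetime_median",
            "time_offset_median",
            "s_final_median_nm2",
            "ap2_amplitude",
            "calibration_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError("epsilon must be in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass(frozen=True)
class ShockConfig:
    """Osmotic-shock timeline (all times in s on the experiment clock).

    The shock is applied at ``shock_onset``; after ``latency`` the coats
    stall for ``stall_duration``; recovery is exponential with mean
    ``reversion``.  A track whose flat-to-curved transition would fall in
    the stall window stalls with probability ``stalled_fraction``: both
    channels freeze at the plateau until the stall window ends, then the
    curved phase resumes.
    """

    shock_onset: float = 300.0
    latency: float = 60.0
    stall_duration: float = 540.0
    reversion: float = 120.0
    stalled_fraction: float = 0.7
    observation_end: float | None = None

    def __post_init__(self) -> None:
        for name in ("shock_onset", "latency", "stall_duration", "reversion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 <= self.stalled_fraction <= 1.0):
            raise ValueError("stalled_fraction must be in [0, 1]")

    @property
    def stall_end(self) -> float:
        return self.shock_onset + self.latency + self.stall_duration

    @property
    def t_end(self) -> float:
        if self.observation_end is not None:
            return self.observation_end
        return self.stall_end + self.reversion + 300.0


class _EventTruth:
    """Noise-free time courses of one simulated event (t0 = 0).

    Provides the AP2 and CLC intensity curves (a.u.), the geometric
    projected area (nm²) and the morphology timeline.
    """

    def __init__(self, config: SimulationConfig, rng: np.random.Generator) -> None:
        c = config
        eps, rule = c.epsilon, c.rule
        self.config = c
        self.x_eps = -np.log(1.0 - np.sqrt(1.0 - eps))
        self.x_f = -np.log(1.0 - np.sqrt(rule.f_star))

        dt_off = rng.lognormal(np.log(c.time_offset_median), c.time_offset_sigma)
        lifetime = rng.lognormal(np.log(c.lifetime_median), c.lifetime_sigma)
        lifetime = max(lifetime, dt_off + 6.0 * c.frame_interval)
        self.s_final_nm2 = rng.lognormal(np.log(c.s_final_median_nm2), c.s_final_sigma)
        self.a_ap2 = c.ap2_amplitude * rng.lognormal(0.0, c.s_final_sigma)
        self.clc_amax = c.calibration_scale * self.s_final_nm2

        cos0 = 1.0 - rule.f_star * (1.0 - np.cos(c.theta_max))
        self.theta0 = float(np.arccos(np.clip(cos0, -1.0, 1.0)))

        if c.model == "ap2_plateau":
            self.tau = (lifetime - dt_off) / self.x_eps
            self.t_plateau = self.tau * self.x_eps
            self.t_transition = self.t_plateau
            self.t_scission = lifetime
        elif c.model == "two_phase":
            self.tau = (lifetime - dt_off) / self.x_f
            self.t_transition = self.tau * self.x_f
            self.t_plateau = self.tau * self.x_eps  # never reached in flat phase
            self.t_scission = lifetime
        else:  # constant_area
            self.tau = (lifetime - dt_off) / self.x_eps
            self.t_plateau = self.tau * self.x_eps
            self.t_transition = self.t_plateau
            self.t_scission = lifetime
        self.lifetime = lifetime

        self.flat = FlatGrowthParams.from_plateau(self.clc_amax, self.tau, 0.0)
        self.ap2_flat = FlatGrowthParams.from_plateau(self.a_ap2, self.tau, 0.0)

        self._model = None
        if c.model == "two_phase":
            curved_span = self.t_scission - self.t_transition
            omega = (c.theta_max - self.theta0) / curved_span
            self._model = TwoPhaseModel(
                FlatGrowthParams.from_plateau(self.s_final_nm2, self.tau, 0.0),
                CurvedGrowthParams(omega=omega, tip_radius=1.0, theta_max=c.theta_max),
                rule,
                self.s_final_nm2,
            )

        # configured CLC maximum for the offset-matched scenario
        ap2_norm_max = self._ap2_curve(self.t_scission) / ((1.0 - eps) * self.a_ap2)
        self.ap2_norm_max = float(ap2_norm_max)
        if c.model == "ap2_plateau":
            clc_at_plateau = (1.0 - eps) * self.clc_amax
            off = c.intensity_offset if c.intensity_offset is not None else 1.0 / rule.f_star - ap2_norm_max
            self.clc_max = float((ap2_norm_max + off) * clc_at_plateau)
            self.intensity_offset = float(off)
        elif c.model == "two_phase":
            s_tr = rule.f_star * self.s_final_nm2
            clc_at_plateau = c.calibration_scale * float(
                self._model.surface(min(self.t_plateau, self.t_scission))
            )
            self.clc_max = c.calibration_scale * self.s_final_nm2
            self.intensity_offset = float(self.clc_max / max(clc_at_plateau, 1e-300) - ap2_norm_max)
        else:
            self.clc_max = float(self._clc_curve(self.t_scission))
            self.intensity_offset = float(
                self.clc_max / ((1.0 - eps) * self.clc_amax) - ap2_norm_max
            )
        self.time_offset = self.t_scission - self.t_plateau

    # --- channel curves -------------------------------------------------
    def _eq1(self, params: FlatGrowthParams, t: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(t, dtype=float) / params.tau, 0.0, None)
        return params.a_max * (1.0 - np.exp(-x)) ** 2

    def _ap2_curve(self, t) -> np.ndarray:
        return self._eq1(self.ap2_flat, t)

    def _theta(self, t: np.ndarray) -> np.ndarray:
        """Contact angle during the curved phase (0 before transition)."""
        c = self.config
        span = max(self.t_scission - self.t_transition, 1e-300)
        u = np.clip((np.asarray(t, dtype=float) - self.t_transition) / span, 0.0, 1.0)
        if c.model == "constant_area":
            return u * c.theta_max
        return self.theta0 + u * (c.theta_max - self.theta0)

    def _clc_curve(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        c = self.config
        if c.model == "constant_area":
            return self._eq1(self.flat, t)
        if c.model == "two_phase":
            return c.calibration_scale * np.asarray(self._model.surface(t))
        # ap2_plateau: flat-law growth, then an affine-rescaled spherical
        # rise to the configured maximum at scission
        flat_part = self._eq1(self.flat, t)
        c_tr = (1.0 - c.epsilon) * self.clc_amax
        theta = self._theta(t)
        g_num = (1.0 - np.cos(theta)) - (1.0 - np.cos(self.theta0))
        g_den = (1.0 - np.cos(c.theta_max)) - (1.0 - np.cos(self.theta0))
        g = np.clip(g_num / g_den, 0.0, 1.0)
        curved_part = c_tr + (self.clc_max - c_tr) * g
        return np.where(t < self.t_transition, flat_part, curved_part)

    def _projected_nm2(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        c = self.config
        surface_nm2 = self._clc_curve(t) / c.calibration_scale
        theta = self._theta(t)
        if c.model == "constant_area":
            curved = _constant_area_projection(self.s_final_nm2, theta)
        else:
            # bending on a (locally) fixed sphere: R from surface and angle
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = surface_nm2 / (2.0 * np.pi * np.maximum(1.0 - np.cos(theta), 1e-300))
            curved = np.where(
                theta <= np.pi / 2,
                np.pi * r2 * np.sin(theta) ** 2,
                np.pi * r2,
            )
        return np.where(t < self.t_transition, surface_nm2, curved)

    def timeline(self, rule: TransitionRule):
        return assign_morphology_timeline(0.0, self.t_transition, self.t_scission, rule)


def _apply_noise(
    y: np.ndarray, amplitude: float, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    out = np.asarray(y, dtype=float)
    if config.poisson:
        out = rng.poisson(np.clip(out, 0.0, None)).astype(float)
    if config.noise_sigma > 0:
        out = out + rng.normal(0.0, config.noise_sigma * amplitude, size=out.shape)
    return np.clip(out, 0.0, None)


def generate_tracks(
    config: SimulationConfig, seed: int | None = None
) -> tuple[list[IntensityTrack], pd.DataFrame]:
    """Generate paired AP2/CLC tracks plus a ground-truth table.

    The time grid is anchored at scission so the CLC maximum falls exactly
    on a frame; the first frame precedes nucleation by at most one frame
    interval.  Fully deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dt = config.frame_interval
    tracks: list[IntensityTrack] = []
    truth_rows = []
    for i in range(config.n_tracks):
        ev = _EventTruth(config, rng)
        n_frames = int(np.floor(ev.t_scission / dt)) + 2
        t_first = ev.t_scission - (n_frames - 1) * dt
        times = t_first + dt * np.arange(n_frames)
        shift = -t_first  # report times starting at 0
        ap2 = _apply_noise(ev._ap2_curve(times), ev.a_ap2, config, rng)
        clc = _apply_noise(ev._clc_curve(times), ev.clc_max, config, rng)
        cell = f"cell{rng.integers(config.n_cells)}"
        track_id = f"trk{i:05d}"
        tracks.append(
            IntensityTrack(
                track_id=track_id,
                times=times + shift,
                ap2=ap2,
                clc=clc,
                condition="iso",
                cell_id=cell,
            )
        )
        truth_rows.append(
            {
                "track_id": track_id,
                "cell_id": cell,
                "model": config.model,
                "t0": shift,
                "tau": ev.tau,
                "a_max_ap2": ev.a_ap2,
                "clc_amax": ev.clc_amax,
                "s_final_nm2": ev.s_final_nm2,
                "t_plateau": ev.t_plateau + shift,
                "t_transition": ev.t_transition + shift,
                "t_scission": ev.t_scission + shift,
                "time_offset": ev.time_offset,
                "intensity_offset": ev.intensity_offset,
                "lifetime": ev.t_scission,
                "f_star": config.rule.f_star,
                "dome_fraction": config.rule.dome_fraction,
                "theta_max": config.theta_max,
            }
        )
    return tracks, pd.DataFrame(truth_rows)


def generate_em_snapshot(
    config: SimulationConfig,
    n_structures: int,
    seed: int,
    n_membranes: int = 3,
) -> pd.DataFrame:
    """Steady-state EM morphometry table.

    Events nucleate at a constant rate, so a snapshot catches each event
    at a uniformly random age within its lifetime; morphology comes from
    the event timeline and projected area (nm²) from the growth curve and
    spherical-cap geometry.  No detection limit is applied here.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_structures):
        ev = _EventTruth(config, rng)
        age = rng.uniform(0.0, ev.t_scission)
        tl = ev.timeline(config.rule)
        rows.append(
            {
                "structure_id": f"em{i:05d}",
                "membrane_id": f"mb{rng.integers(n_membranes)}",
                "morphology": tl.morphology_at(age),
                "projected_area_nm2": float(ev._projected_nm2(age)),
                "age_s": age,
                "lifetime_s": ev.t_scission,
            }
        )
    return pd.DataFrame(rows)


def generate_clem_dataset(
    n_per_class: int = 100,
    true_factors: dict | None = None,
    seed: int = 0,
    channel_scales: dict | None = None,
    noise_sigma: float = 0.05,
    area_median_nm2: float = 8.0e3,
    area_sigma: float = 0.4,
    n_multiple: int = 0,
    n_membranes: int = 3,
) -> pd.DataFrame:
    """CLEM calibration table with embedded correction factors.

    For every channel, summed fluorescence is proportional to the coat
    surface area: ``scale * factor(class) * projected_area``, with flat
    factor 1 and the dome/pit factors from ``true_factors`` (default: the
    clathrin/AP2 scenario in :data:`DEFAULT_TRUE_FACTORS`).  Multiplicative
    Gaussian noise of relative width ``noise_sigma`` is applied.
    "multiple" records (unresolved merged objects) carry inflated
    intensity and must not influence any calibration.
    """
    rng = np.random.default_rng(seed)
    factors = DEFAULT_TRUE_FACTORS if true_factors is None else true_factors
    scales = {"clathrin": 1.0, "ap2": 0.5} if channel_scales is None else channel_scales
    rows = []
    counter = 0
    for channel, (f_dome, f_pit) in factors.items():
        scale = scales.get(channel, 1.0)
        for cls, factor in (("flat", 1.0), ("dome", f_dome), ("pit", f_pit)):
            areas = rng.lognormal(np.log(area_median_nm2), area_sigma, size=n_per_class)
            noise = 1.0 + rng.normal(0.0, noise_sigma, size=n_per_class)
            intensity = np.clip(scale * factor * areas * noise, 0.0, None)
            for p, f in zip(areas, intensity):
                rows.append(
                    {
                        "structure_id": f"clem{counter:05d}",
                        "morphology": cls,
                        "projected_area_nm2": float(p),
                        "fluorescence_sum": float(f),
                        "channel": channel,
                        "membrane_id": f"mb{rng.integers(n_membranes)}",
                    }
                )
                counter += 1
        for _ in range(n_multiple):
            p = rng.lognormal(np.log(area_median_nm2), area_sigma)
            f = scale * p * rng.uniform(1.5, 4.0)
            rows.append(
                {
                    "structure_id": f"clem{counter:05d}",
                    "morphology": "multiple",
                    "projected_area_nm2": float(p),
                    "fluorescence_sum": float(f),
                    "channel": channel,
                    "membrane_id": f"mb{rng.integers(n_membranes)}",
                }
            )
            counter += 1
    return pd.DataFrame(rows)


def generate_shock_tracks(
    config: SimulationConfig,
    shock: ShockConfig,
    seed: int | None = None,
) -> tuple[list[IntensityTrack], pd.DataFrame]:
    """Tracks spanning an osmotic-shock experiment, plus ground truth.

    Events nucleate uniformly over the observation window on a common
    imaging clock.  An event whose flat-to-curved transition falls inside
    the stall window stalls with probability ``shock.stalled_fraction``:
    both channels freeze at their transition values until the stall window
    ends (plus an exponential reversion tail), after which the curved
    phase resumes; scission shifts accordingly.  Tracks are truncated at
    the observation end, so an event still stalled at that point never
    shows a CLC-over-AP2 crossing — it is recorded as a flat, stalled coat.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dt = config.frame_interval
    stall_start = shock.shock_onset + shock.latency
    stall_end = shock.stall_end
    t_obs_end = shock.t_end
    tracks: list[IntensityTrack] = []
    rows = []
    i = 0
    attempts = 0
    while len(tracks) < config.n_tracks and attempts < 20 * config.n_tracks:
        attempts += 1
        ev = _EventTruth(config, rng)
        t0_abs = rng.uniform(0.0, max(t_obs_end - MIN_FRAMES * dt, dt))
        t_tr_abs = t0_abs + ev.t_transition
        stalled = bool(
            stall_start <= t_tr_abs < stall_end and rng.random() < shock.stalled_fraction
        )
        hold = 0.0
        if stalled:
            hold = (stall_end - t_tr_abs) + rng.exponential(shock.reversion)
        t_sc_abs = t0_abs + ev.t_scission + hold

        k_first = int(np.ceil(t0_abs / dt))
        k_last = int(np.floor(min(t_sc_abs, t_obs_end) / dt))
        if k_last - k_first + 1 < MIN_FRAMES:
            continue
        times = dt * np.arange(k_first, k_last + 1)
        # remap the imaging clock onto the event clock, freezing the hold
        rel = times - t0_abs
        rel_eff = np.where(
            rel < ev.t_transition,
            rel,
            np.where(rel < ev.t_transition + hold, ev.t_transition, rel - hold),
        )
        ap2 = _apply_noise(ev._ap2_curve(rel_eff), ev.a_ap2, config, rng)
        clc = _apply_noise(ev._clc_curve(rel_eff), ev.clc_max, config, rng)
        track_id = f"shk{i:05d}"
        cell = "cell0"
        tracks.append(
            IntensityTrack(
                track_id=track_id,
                times=times,
                ap2=ap2,
                clc=clc,
                condition="shock",
                shock_onset=shock.shock_onset,
                cell_id=cell,
            )
        )
        rows.append(
            {
                "track_id": track_id,
                "t0_abs": t0_abs,
                "tau": ev.tau,
                "t_transition_abs": t_tr_abs + (hold if stalled else 0.0),
                "t_scission_abs": t_sc_abs,
                "stalled": stalled,
                "hold": hold,
                "truncated": bool(t_sc_abs > t_obs_end),
                "lifetime_recorded": float(times[-1] - times[0]),
            }
        )
        i += 1
    if len(tracks) < config.n_tracks:
        raise RuntimeError("could not generate the requested number of shock tracks")
    return tracks, pd.DataFrame(rows)
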