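"""Per-event analysis of AP2/clathrin fluorescence intensity tracks.

Each clathrin-mediated endocytosis event is observed as a pair of intensity
time series (AP2 adaptor and clathrin light chain, CLC) sampled at a
uniform frame interval (default 3 s).  This module fits the growth laws to
individual tracks, detects the AP2 plateau, computes the time and intensity
offsets between the two channels, applies the 5 % CLC-over-AP2 transition
rule, and bins per-event statistics around an osmotic-shock onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .growth import (
    DEFAULT_THETA_MAX,
    CurvedGrowthParams,
    FlatGrowthParams,
    TransitionRule,
    TwoPhaseModel,
    constant_area_curve,
    plateau_time,
)

__all__ = [
    "IntensityTrack",
    "TrackFit",
    "OffsetResult",
    "fit_flat_model",
    "fit_two_phase_model",
    "normalize_to_plateau",
    "compute_offsets",
    "transition_time_threshold",
    "bin_by_shock_onset",
]

MIN_FRAMES = 6


@dataclass
class IntensityTrack:
    """One CME event: time-stamped AP2 and (optionally) CLC intensities.

    Times must be strictly increasing with uniform spacing; intensities are
    assumed background-corrected and nonnegative.
    """

    track_id: str
    times: np.ndarray
    ap2: np.ndarray
    clc: np.ndarray | None = None
    condition: str = "iso"
    shock_onset: float | None = None
    cell_id: str = "cell0"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ap2 = np.asarray(self.ap2, dtype=float)
        if self.clc is not None:
            self.clc = np.asarray(self.clc, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError(f"track {self.track_id}: need >= 2 frames")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError(f"track {self.track_id}: times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"track {self.track_id}: non-uniform frame interval")
        for name, y in (("ap2", self.ap2), ("clc", self.clc)):
            if y is None:
                continue
            if len(y) != len(self.times):
                raise ValueError(f"track {self.track_id}: {name} length mismatch")
            if np.any(y < -1e-9):
                raise ValueError(f"track {self.track_id}: negative {name} intensity")
        if self.condition not in ("iso", "shock"):
            raise ValueError(f"track {self.track_id}: unknown condition {self.condition!r}")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def lifetime(self) -> float:
        return float(self.times[-1] - self.times[0])

    def channel(self, name: str) -> np.ndarray:
        if name == "ap2":
            return self.ap2
        if name == "clc":
            if self.clc is None:
                raise ValueError(f"track {self.track_id}: no CLC channel")
            return self.clc
        raise ValueError(f"unknown channel {name!r}")


@dataclass
class TrackFit:
    """Result of fitting a growth law to one track.

    ``flat`` always holds the flat-phase parameters; ``curved``, ``rule``
    and ``s_final`` are set by the two-phase fit.  ``a_max_rel_err`` is the
    relative standard error of the fitted asymptote, used to flag tracks
    whose plateau lies beyond the observed frames.
    """

    track_id: str
    channel: str
    flat: FlatGrowthParams
    residual_rms: float
    converged: bool
    a_max_rel_err: float = np.nan
    curved: CurvedGrowthParams | None = None
    rule: TransitionRule | None = None
    s_final: float | None = None
    f_star_hat: float | None = None
    t_start: float = 0.0
    t_end: float = 0.0

    @property
    def model(self) -> TwoPhaseModel | None:
        if self.curved is None:
            return None
        return TwoPhaseModel(self.flat, self.curved, self.rule, self.s_final)

    def predict(self, t) -> np.ndarray | float:
        if self.curved is None:
            return constant_area_curve(self.flat, t)
        return self.model.surface(t)

    @property
    def t_transition(self) -> float | None:
        m = self.model
        return None if m is None else m.t_transition


@dataclass(frozen=True)
class OffsetResult:
    """Time/intensity offsets of CLC relative to the AP2 plateau."""

    time_offset: float
    intensity_offset: float
    clc_content_at_plateau: float
    t_plateau: float


def _flat_curve(t: np.ndarray, a_max: float, tau: float, t0: float) -> np.ndarray:
    x = np.clip((t - t0) / tau, 0.0, None)
    return a_max * (1.0 - np.exp(-x)) ** 2


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    a0 = float(np.percentile(y, 95))
    if a0 <= 0:
        a0 = float(np.max(y))
    above = np.nonzero(y > 0.1 * a0)[0]
    t0 = float(t[above[0]]) if len(above) else float(t[0])
    tau0 = max((t[-1] - t[0]) / 4.0, (t[1] - t[0]))
    return a0, tau0, t0


def _rel_stderr(res, n_params: int, index: int, value: float) -> float:
    """Relative standard error of one parameter from a least-squares result."""
    n = len(res.fun)
    dof = max(n - n_params, 1)
    s2 = float(res.fun @ res.fun) / dof
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.inv(jtj) * s2
        se = float(np.sqrt(max(cov[index, index], 0.0)))
    except np.linalg.LinAlgError:
        return np.inf
    if value == 0:
        return np.inf
    return se / abs(value)


def fit_flat_model(
    track: IntensityTrack,
    channel: str = "ap2",
    max_rel_err: float = 0.5,
    min_coverage: float = 0.75,
) -> TrackFit:
    """Least-squares fit of the constant-area (saturating) law to one channel.

    The curve ``A_max (1 - exp(-(t-t0)/tau))^2`` is fitted in the
    observable parametrisation (A_max, tau, t0).  The fit is flagged
    non-converged when the optimiser fails or when the asymptote is not
    constrained by the data — relative standard error of A_max above
    ``max_rel_err``, or a fitted curve that reaches less than
    ``min_coverage`` of its asymptote by the last frame (the plateau lies
    beyond the end of the track, as for a still-rising ramp).
    """
    t = track.times
    y = track.channel(channel)
    if len(t) < MIN_FRAMES:
        raise ValueError(f"track {track.track_id}: need >= {MIN_FRAMES} frames")
    if np.all(y <= 0):
        raise ValueError(f"track {track.track_id}: all-zero {channel} channel")

    a0, tau0, t00 = _initial_guess(t, y)
    span = t[-1] - t[0]
    lo = [a0 * 1e-3, track.frame_interval * 0.05, t[0] - span]
    hi = [a0 * 1e3, span * 20.0, t[-1]]
    x0 = np.clip([a0, tau0, t00], lo, hi)

    def resid(p):
        return _flat_curve(t, *p) - y

    res = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf")
    a_max, tau, t0 = res.x
    rel = _rel_stderr(res, 3, 0, a_max)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    coverage = _flat_curve(np.array([t[-1]]), a_max, tau, t0)[0] / a_max
    converged = (
        bool(res.success)
        and np.isfinite(rel)
        and rel <= max_rel_err
        and coverage >= min_coverage
    )
    return TrackFit(
        track_id=track.track_id,
        channel=channel,
        flat=FlatGrowthParams.from_plateau(a_max, tau, t0),
        residual_rms=rms,
        converged=converged,
        a_max_rel_err=rel,
        t_start=float(t[0]),
        t_end=float(t[-1]),
    )


def fit_two_phase_model(
    track: IntensityTrack,
    rule: TransitionRule,
    theta_max: float = DEFAULT_THETA_MAX,
    fit_f_star: bool = False,
    fix_transition_at: float | None = None,
    max_rel_err: float = 0.5,
) -> TrackFit:
    """Least-squares fit of the flat-to-curved law to the CLC channel.

    Free parameters are the final surface ``s_final``, the flat-phase
    relaxation time ``tau``, the nucleation time ``t0`` and the bending
    rate ``omega``; the flat phase grows toward ``s_final`` and bending
    starts at ``rule.f_star * s_final``.  With ``fit_f_star`` the
    transition fraction itself is estimated; with ``fix_transition_at`` the
    transition time is pinned (e.g. to the AP2 plateau) by tying ``t0`` to
    ``tau``.  The fit range ends at the (smoothed) CLC maximum so that the
    post-scission drop does not bias the growth parameters.
    """
    t_all = track.times
    y_all = track.channel("clc")
    if len(t_all) < MIN_FRAMES:
        raise ValueError(f"track {track.track_id}: need >= {MIN_FRAMES} frames")
    if np.all(y_all <= 0):
        raise ValueError(f"track {track.track_id}: all-zero clc channel")

    k_max = int(np.argmax(moving_average(y_all, 3)))
    k_max = max(k_max, MIN_FRAMES - 1)
    t = t_all[: k_max + 1]
    y = y_all[: k_max + 1]

    s0 = float(np.max(y))
    a0, tau0, t00 = _initial_guess(t, y)
    span = max(t[-1] - t[0], track.frame_interval)
    cos_t0 = 1.0 - rule.f_star * (1.0 - np.cos(theta_max))
    theta0_default = float(np.arccos(np.clip(cos_t0, -1.0, 1.0)))
    omega0 = (theta_max - theta0_default) / max(span * 0.3, track.frame_interval)

    # free parameters: s_final, tau, omega, plus t0 unless the transition
    # time is pinned (then t0 is tied to tau), plus f_star when estimated
    names = ["s_final", "tau", "omega"]
    if fix_transition_at is None:
        names.append("t0")
    if fit_f_star:
        names.append("f_star")

    def unpack(p) -> dict:
        d = dict(zip(names, p))
        fs = d.get("f_star", rule.f_star)
        if fix_transition_at is not None:
            d["t0"] = fix_transition_at - d["tau"] * (-np.log(1.0 - np.sqrt(fs)))
        d["f_star"] = fs
        return d

    def build(p) -> TwoPhaseModel:
        d = unpack(p)
        r = TransitionRule(f_star=d["f_star"], dome_fraction=rule.dome_fraction)
        flat = FlatGrowthParams.from_plateau(d["s_final"], d["tau"], d["t0"])
        curved = CurvedGrowthParams(omega=d["omega"], tip_radius=1.0, theta_max=theta_max)
        return TwoPhaseModel(flat, curved, r, d["s_final"])

    def resid(p):
        try:
            m = build(p)
        except ValueError:
            return np.full_like(y, 1e6)
        return np.asarray(m.surface(t)) - y

    bounds = {
        "s_final": (s0 * 1e-3, s0 * 1e3),
        "tau": (track.frame_interval * 0.05, span * 20.0),
        "omega": (omega0 * 1e-3, omega0 * 1e3),
        "t0": (t[0] - span, t[-1]),
        "f_star": (0.05, 0.99),
    }
    start = {"s_final": s0, "tau": tau0, "omega": omega0, "t0": t00, "f_star": rule.f_star}
    lo = [bounds[n][0] for n in names]
    hi = [bounds[n][1] for n in names]
    x0 = np.clip([start[n] for n in names], lo, hi)

    res = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf")
    d = unpack(res.x)
    s_final, tau, t0, omega, fs = d["s_final"], d["tau"], d["t0"], d["omega"], d["f_star"]
    rel = _rel_stderr(res, len(res.x), 0, s_final)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    converged = bool(res.success) and np.isfinite(rel) and rel <= max_rel_err
    fitted_rule = TransitionRule(f_star=fs, dome_fraction=rule.dome_fraction)
    model = TwoPhaseModel(
        FlatGrowthParams.from_plateau(s_final, tau, t0),
        CurvedGrowthParams(omega=omega, tip_radius=1.0, theta_max=theta_max),
        fitted_rule,
        s_final,
    )
    return TrackFit(
        track_id=track.track_id,
        channel="clc",
        flat=model.flat,
        residual_rms=rms,
        converged=converged,
        a_max_rel_err=rel,
        curved=model.curved,
        rule=fitted_rule,
        s_final=float(s_final),
        f_star_hat=fs if fit_f_star else None,
        t_start=float(t_all[0]),
        t_end=float(t_all[-1]),
    )


def moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    if window <= 1:
        return np.asarray(y, dtype=float)
    return (
        pd.Series(np.asarray(y, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def _interp(t: np.ndarray, y: np.ndarray, t_query: float) -> float:
    if not (t[0] <= t_query <= t[-1]):
        raise ValueError(f"t={t_query} outside track span [{t[0]}, {t[-1]}]")
    return float(np.interp(t_query, t, y))


def normalize_to_plateau(
    track: IntensityTrack,
    t_plateau: float,
    ap2_norm_value: float | None = None,
) -> IntensityTrack:
    """Divide each channel by its own value at the AP2 plateau time.

    AP2 is divided by ``ap2_norm_value`` when given (normally the fitted
    curve's plateau value, which is noise-free), otherwise by the
    interpolated raw value; CLC by its interpolated raw value.  The
    returned AP2 channel is ~1 at ``t_plateau`` and the operation is
    invariant under rescaling of the raw intensities.
    """
    t = track.times
    a_ref = ap2_norm_value if ap2_norm_value is not None else _interp(t, track.ap2, t_plateau)
    if a_ref <= 0:
        raise ValueError(f"track {track.track_id}: nonpositive AP2 normaliser")
    clc = None
    if track.clc is not None:
        c_ref = _interp(t, track.clc, t_plateau)
        if c_ref <= 0:
            raise ValueError(f"track {track.track_id}: nonpositive CLC normaliser")
        clc = track.clc / c_ref
    return IntensityTrack(
        track_id=track.track_id,
        times=t.copy(),
        ap2=track.ap2 / a_ref,
        clc=clc,
        condition=track.condition,
        shock_onset=track.shock_onset,
        cell_id=track.cell_id,
    )


def _plateau_normalizer(track: IntensityTrack, fit: TrackFit, epsilon: float) -> float:
    """CLC value at the AP2 plateau time, estimated from the fitted curve.

    During flat growth both channels are proportional to the coat area, so
    the CLC series is matched by least squares to the normalized fitted
    AP2 curve over the pre-plateau frames; the resulting scale is the CLC
    plateau value.  This pools many frames instead of relying on a single
    noisy sample, and is exact on noise-free data.  Falls back to
    interpolation when fewer than 3 pre-plateau frames exist.
    """
    t = track.times
    t_plateau = float(np.clip(plateau_time(fit.flat, epsilon), t[0], t[-1]))
    g = np.asarray(constant_area_curve(fit.flat, t)) / ((1.0 - epsilon) * fit.flat.a_max)
    pre = (t <= t_plateau) & (g > 0)
    if pre.sum() < 3:
        return _interp(t, track.clc, t_plateau)
    gg = g[pre]
    return float(np.dot(track.clc[pre], gg) / np.dot(gg, gg))


def compute_offsets(
    track: IntensityTrack,
    fit: TrackFit,
    epsilon: float = 0.05,
    smooth_window: int = 3,
) -> OffsetResult:
    """Time and intensity offsets of CLC relative to the AP2 plateau.

    * time offset: time of the CLC maximum (located on a smoothed copy of
      the series to suppress single-frame spikes; the value is read from
      the raw series at that frame) minus the AP2 plateau time from the
      fitted curve.
    * intensity offset: excess of the normalized CLC maximum over the
      normalized AP2 maximum, both channels normalized to their value at
      the plateau time (AP2 via the fitted curve, CLC via interpolation of
      the raw series).
    * clc content at plateau: CLC at the plateau time as a fraction of the
      CLC maximum.
    """
    if track.clc is None:
        raise ValueError(f"track {track.track_id}: CLC channel required")
    t = track.times
    t_plateau = plateau_time(fit.flat, epsilon)
    t_plateau = float(np.clip(t_plateau, t[0], t[-1]))
    ap2_plateau_value = (1.0 - epsilon) * fit.flat.a_max
    c_ref = _plateau_normalizer(track, fit, epsilon)
    if c_ref <= 0:
        raise ValueError(f"track {track.track_id}: nonpositive CLC normaliser")
    ap2_norm = track.ap2 / ap2_plateau_value
    clc_norm = track.clc / c_ref

    k_clc = int(np.argmax(moving_average(clc_norm, smooth_window)))
    k_ap2 = int(np.argmax(moving_average(ap2_norm, smooth_window)))
    time_offset = float(t[k_clc] - t_plateau)
    intensity_offset = float(clc_norm[k_clc] - ap2_norm[k_ap2])

    clc_at_plateau = c_ref
    clc_max = float(track.clc[k_clc])
    content = clc_at_plateau / clc_max if clc_max > 0 else np.nan
    return OffsetResult(
        time_offset=time_offset,
        intensity_offset=intensity_offset,
        clc_content_at_plateau=float(np.clip(content, 0.0, 1.0)),
        t_plateau=t_plateau,
    )


def transition_time_threshold(
    track: IntensityTrack,
    fit: TrackFit,
    delta: float = 0.05,
    epsilon: float = 0.05,
    mode: str = "additive",
    t_max: float | None = None,
    smooth_window: int = 3,
    min_run: int = 2,
    min_ap2_frac: float = 0.5,
) -> float | None:
    """First time at which CLC exceeds AP2 by ``delta`` on plateau-normalized
    channels.

    AP2 is represented by its fitted curve (normalized to the plateau
    value); CLC by the normalized raw series, lightly smoothed
    (``smooth_window`` frames).  The crossing time is the first frame from
    which the excess holds for every remaining frame of the evaluation
    window (a bent coat does not revert), with at least ``min_run`` frames
    in that suffix; this makes single-frame noise spikes on a long stalled
    plateau irrelevant.  Candidate frames are further restricted to the
    grown part of the track (fitted AP2 at ``min_ap2_frac`` of its plateau
    or more), where the normalized comparison is meaningful.  Returns
    ``None`` when the threshold is never crossed, which downstream
    analysis interprets as a coat that is still flat — the relevant case
    for stalled events under osmotic shock, where the AP2 plateau itself
    no longer marks bending.  With ``t_max`` the evaluation window ends at
    that time instead of the last frame.
    """
    if track.clc is None:
        raise ValueError(f"track {track.track_id}: CLC channel required")
    if mode not in ("additive", "multiplicative"):
        raise ValueError(f"unknown mode {mode!r}")
    t = track.times
    ap2_norm = np.asarray(constant_area_curve(fit.flat, t)) / ((1.0 - epsilon) * fit.flat.a_max)
    c_ref = _plateau_normalizer(track, fit, epsilon)
    if c_ref <= 0:
        raise ValueError(f"track {track.track_id}: nonpositive CLC normaliser")
    clc_norm = moving_average(track.clc / c_ref, smooth_window)
    if mode == "additive":
        crossed = clc_norm >= ap2_norm + delta
    else:
        crossed = clc_norm >= ap2_norm * (1.0 + delta)
    run = max(int(min_run), 1)
    last = len(t) - 1
    if t_max is not None:
        inside = np.nonzero(t <= t_max)[0]
        if len(inside) == 0:
            return None
        last = int(inside[-1])
    # on a near-zero baseline the normalized ratio is dominated by noise
    candidates = crossed & (ap2_norm >= min_ap2_frac)
    candidates[last + 1 :] = False
    # suffix criterion: crossed from frame k through the window end
    ok = np.nonzero(candidates)[0]
    for k in ok:
        if last - k + 1 >= run and crossed[k : last + 1].all():
            return float(t[k])
    return None


def bin_by_shock_onset(
    tracks: Sequence[IntensityTrack],
    fits: Sequence[TrackFit],
    bin_width: float = 180.0,
    epsilon: float = 0.05,
    smooth_window: int = 3,
) -> pd.DataFrame:
    """Per-bin summaries of lifetime, AP2 plateau duration and time offset.

    Tracks are assigned to half-open bins ``[k*w, (k+1)*w)`` by their start
    time relative to the shock onset; tracks starting before the onset are
    pooled into a single baseline group (bin -1, label ``pre``).  The AP2
    plateau duration is the time the track persists past the fitted
    plateau.  Bins with no tracks are simply absent from the output.
    """
    rows = []
    for track, fit in zip(tracks, fits):
        if track.shock_onset is None:
            raise ValueError(f"track {track.track_id}: shock_onset required")
        rel_start = track.times[0] - track.shock_onset
        bin_index = -1 if rel_start < 0 else int(np.floor(rel_start / bin_width))
        t_plateau = float(np.clip(plateau_time(fit.flat, epsilon), track.times[0], track.times[-1]))
        off = compute_offsets(track, fit, epsilon=epsilon, smooth_window=smooth_window)
        rows.append(
            {
                "track_id": track.track_id,
                "bin": bin_index,
                "lifetime": track.lifetime,
                "plateau_duration": float(track.times[-1] - t_plateau),
                "time_offset": off.time_offset,
            }
        )
    per_track = pd.DataFrame(rows)
    grouped = per_track.groupby("bin").agg(
        n=("track_id", "size"),
        lifetime_median=("lifetime", "median"),
        lifetime_mean=("lifetime", "mean"),
        plateau_median=("plateau_duration", "median"),
        plateau_mean=("plateau_duration", "mean"),
        time_offset_median=("time_offset", "median"),
        time_offset_mean=("time_offset", "mean"),
    )
    grouped = grouped.reset_index()
    grouped.insert(1, "label", np.where(grouped["bin"] < 0, "pre", "post"))
    return grouped
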