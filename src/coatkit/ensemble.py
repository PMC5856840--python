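"""Snapshot-ensemble prediction of coat morphology and size distributions.

An EM micrograph of an unroofed membrane is a single-time snapshot of many
asynchronous endocytic events.  Under steady-state nucleation, sampling a
uniformly random time point from every recorded fluorescence track (pooled
over frames, so longer-lived events contribute proportionally) emulates
such a snapshot.  Each sampled time point is labelled flat/dome/pit from
the event's morphology timeline and assigned the projected area implied by
the fitted growth curve and the spherical-cap geometry; the resulting
ensemble is filtered by the TEM detection limit and compared to measured
morphometry with Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .growth import MorphologyTimeline, TransitionRule, assign_morphology_timeline, plateau_time
from .tracks import IntensityTrack, TrackFit, transition_time_threshold

__all__ = [
    "SnapshotEnsemble",
    "DetectionLimit",
    "CalibrationScale",
    "EventPrediction",
    "intensity_to_area",
    "predict_event",
    "sample_snapshots",
    "apply_detection_limit",
    "morphology_fractions",
    "MorphologyFractions",
    "compare_distributions",
    "predict_stalled_morphology",
]

MORPHOLOGIES = ("flat", "dome", "pit")


@dataclass(frozen=True)
class DetectionLimit:
    """Smallest projected area (nm²) confidently identifiable in TEM."""

    min_projected_area: float = 1000.0

    def __post_init__(self) -> None:
        if self.min_projected_area < 0:
            raise ValueError("detection limit must be nonnegative")


@dataclass(frozen=True)
class CalibrationScale:
    """Linear fluorescence calibration: intensity (a.u.) per nm² of coat."""

    intensity_per_area: float = 1.0

    def __post_init__(self) -> None:
        if self.intensity_per_area <= 0:
            raise ValueError("intensity_per_area must be positive")


def intensity_to_area(intensity, scale: CalibrationScale):
    """Convert summed fluorescence to coat surface area (nm²)."""
    return np.asarray(intensity, dtype=float) / scale.intensity_per_area


@dataclass
class SnapshotEnsemble:
    """Table of (morphology, projected area) records at a time snapshot."""

    records: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"morphology", "projected_area_nm2"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"ensemble missing columns: {sorted(missing)}")
        bad = ~self.records["morphology"].isin(MORPHOLOGIES)
        if bad.any():
            raise ValueError(
                f"unknown morphology values: {self.records.loc[bad, 'morphology'].unique()}"
            )
        if (self.records["projected_area_nm2"] <= 0).any():
            raise ValueError("projected areas must be positive")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class EventPrediction:
    """One event's morphology timeline and projected-area time course."""

    track_id: str
    timeline: MorphologyTimeline
    projected_area: Callable[[np.ndarray], np.ndarray]
    surface: Callable[[np.ndarray], np.ndarray]

    def morphology(self, t: np.ndarray) -> np.ndarray:
        tl = self.timeline
        return np.where(
            t < tl.t_transition, "flat", np.where(t < tl.t_dome_end, "dome", "pit")
        )


def _constant_area_projection(s_fixed: float, theta: np.ndarray) -> np.ndarray:
    """Projected area of a cap bending at constant surface area ``s_fixed``.

    With S = 2 pi R^2 (1 - cos theta) held fixed the tip radius shrinks as
    the angle grows, giving S (1 + cos theta)/2 up to the hemisphere and
    S / (2 (1 - cos theta)) beyond it (continuous, equal to S at theta=0).
    """
    theta = np.asarray(theta, dtype=float)
    below = s_fixed * (1.0 + np.cos(theta)) / 2.0
    above = np.where(theta > 0, s_fixed / (2.0 * (1.0 - np.cos(theta)) + 1e-300), s_fixed)
    return np.where(theta <= np.pi / 2, below, above)


def predict_event(
    fit: TrackFit,
    rule: TransitionRule,
    epsilon: float = 0.05,
    theta_max: float | None = None,
) -> EventPrediction:
    """Morphology timeline and projected-area curve implied by a track fit.

    For a flat (constant-area) fit the coat grows flat until the fitted
    plateau, then bends at constant surface area with the contact angle
    increasing linearly over the remaining lifetime.  For a two-phase fit
    the fitted model supplies the transition time and the fixed-tip-radius
    bending geometry directly.  Areas are in the fit's intensity units;
    apply a :class:`CalibrationScale` to obtain nm².
    """
    # the event exists from its (fitted) nucleation, not the first frame
    t_start = float(np.clip(fit.flat.t0, fit.t_start, fit.t_end))
    t_end = fit.t_end
    if fit.curved is None:
        from .growth import constant_area_curve, DEFAULT_THETA_MAX

        th_max = DEFAULT_THETA_MAX if theta_max is None else theta_max
        t_tr = float(np.clip(plateau_time(fit.flat, epsilon), t_start, t_end))
        s_fixed = fit.flat.a_max
        curved_span = max(t_end - t_tr, 1e-300)

        def proj(t, _t_tr=t_tr, _s=s_fixed, _span=curved_span, _thm=th_max):
            t = np.asarray(t, dtype=float)
            flat_part = np.asarray(constant_area_curve(fit.flat, t))
            theta = np.clip((t - _t_tr) / _span, 0.0, 1.0) * _thm
            return np.where(t < _t_tr, flat_part, _constant_area_projection(_s, theta))

        def surf(t, _t_tr=t_tr, _s=s_fixed):
            t = np.asarray(t, dtype=float)
            flat_part = np.asarray(constant_area_curve(fit.flat, t))
            return np.where(t < _t_tr, flat_part, _s)

    else:
        model = fit.model
        t_tr = float(np.clip(model.t_transition, t_start, t_end))
        r = model.tip_radius

        def proj(t, _m=model, _t_tr=t_tr, _r=r):
            t = np.asarray(t, dtype=float)
            theta = np.asarray(_m.theta(t))
            cap = np.where(
                theta <= np.pi / 2,
                np.pi * _r * _r * np.sin(theta) ** 2,
                np.pi * _r * _r,
            )
            return np.where(t < _t_tr, np.asarray(_m.surface(t)), cap)

        def surf(t, _m=model):
            return np.asarray(_m.surface(t))

    timeline = assign_morphology_timeline(t_start, t_tr, t_end, rule)
    return EventPrediction(
        track_id=fit.track_id, timeline=timeline, projected_area=proj, surface=surf
    )


def sample_snapshots(
    predictions: Sequence[EventPrediction],
    n_samples: int,
    seed: int,
    scale: CalibrationScale | None = None,
    restrict: str = "all",
    weighting: str = "frames",
    groups: dict | None = None,
) -> SnapshotEnsemble:
    """Draw a steady-state snapshot ensemble from per-event predictions.

    Each sample is a (track, uniform random time within the track's
    lifetime) pair; tracks are weighted by lifetime (``weighting='frames'``,
    the steady-state convention) or equally (``'per_track'``).  With
    ``restrict='curved'`` sampling is confined to each event's curved
    phase.  ``groups`` maps track ids to a grouping key (cell or membrane)
    carried into the records.
    """
    if len(predictions) == 0:
        raise ValueError("need at least one event prediction")
    if restrict not in ("all", "curved"):
        raise ValueError(f"unknown restrict {restrict!r}")
    if weighting not in ("frames", "per_track"):
        raise ValueError(f"unknown weighting {weighting!r}")
    rng = np.random.default_rng(seed)

    if restrict == "all":
        lo = np.array([p.timeline.t_nucleation for p in predictions])
        hi = np.array([p.timeline.t_scission for p in predictions])
    else:
        lo = np.array([p.timeline.t_transition for p in predictions])
        hi = np.array([p.timeline.t_scission for p in predictions])
    spans = hi - lo
    usable = spans > 0
    if not usable.any():
        raise ValueError("no events with a nonzero sampling window")
    weights = np.where(usable, spans if weighting == "frames" else 1.0, 0.0)
    p = weights / weights.sum()

    idx = rng.choice(len(predictions), size=n_samples, p=p)
    u = rng.random(n_samples)
    times = lo[idx] + u * spans[idx]

    morph = np.empty(n_samples, dtype=object)
    area = np.empty(n_samples, dtype=float)
    for i in np.unique(idx):
        sel = idx == i
        pred = predictions[i]
        morph[sel] = pred.morphology(times[sel])
        area[sel] = pred.projected_area(times[sel])
    if scale is not None:
        area = intensity_to_area(area, scale)

    records = pd.DataFrame(
        {
            "morphology": morph,
            "projected_area_nm2": area,
            "source_track": [predictions[i].track_id for i in idx],
            "time": times,
        }
    )
    if groups is not None:
        records["group"] = records["source_track"].map(groups)
    meta = {"method": f"{weighting}/{restrict}", "seed": seed, "n_samples": n_samples}
    return SnapshotEnsemble(records=records, meta=meta)


def apply_detection_limit(ensemble: SnapshotEnsemble, limit: DetectionLimit) -> SnapshotEnsemble:
    """Remove records whose projected area falls below the TEM limit.

    The number removed is recorded in the result's metadata so that the
    restriction applied to predictions matches the one implicit in EM.
    """
    keep = ensemble.records["projected_area_nm2"] >= limit.min_projected_area
    meta = dict(ensemble.meta)
    meta["detection_limit_nm2"] = limit.min_projected_area
    meta["n_removed_below_limit"] = int((~keep).sum())
    return SnapshotEnsemble(records=ensemble.records.loc[keep].reset_index(drop=True), meta=meta)


@dataclass(frozen=True)
class MorphologyFractions:
    """Flat/dome/pit percentages, optionally with per-group mean ± SD."""

    fractions: dict
    group_mean: dict | None = None
    group_sd: dict | None = None
    n: int = 0
    n_groups: int = 0


def morphology_fractions(
    ensemble: SnapshotEnsemble, group_key: str | None = None
) -> MorphologyFractions:
    """Percentage of flat, dome and pit records (sums to 100).

    With ``group_key`` (a column such as the membrane or cell id) the
    per-group percentages are also summarised as mean ± SD, matching how
    EM morphology ratios are reported across membranes.
    """
    df = ensemble.records
    if len(df) == 0:
        raise ValueError("empty ensemble")
    counts = df["morphology"].value_counts()
    overall = {m: 100.0 * counts.get(m, 0) / len(df) for m in MORPHOLOGIES}
    group_mean = group_sd = None
    n_groups = 0
    if group_key is not None:
        if group_key not in df.columns:
            raise ValueError(f"no column {group_key!r} in ensemble records")
        per_group = (
            df.groupby(group_key)["morphology"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=MORPHOLOGIES, fill_value=0.0)
            * 100.0
        )
        n_groups = len(per_group)
        group_mean = per_group.mean().to_dict()
        group_sd = per_group.std(ddof=1).to_dict()
    return MorphologyFractions(
        fractions=overall,
        group_mean=group_mean,
        group_sd=group_sd,
        n=len(df),
        n_groups=n_groups,
    )


def _summary(x: np.ndarray) -> dict:
    return {
        "n": int(len(x)),
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "p10": float(np.percentile(x, 10)),
        "p90": float(np.percentile(x, 90)),
    }


def compare_distributions(predicted, measured) -> dict:
    """Welch's unequal-variance t-test between two area distributions.

    Returns the two-sided t statistic and p-value plus box/whisker
    summaries (mean, median, 10th/90th percentiles) of each side.
    Degenerate input (both sides constant and equal) yields t=0, p=1 by
    convention.
    """
    a = np.asarray(predicted, dtype=float)
    b = np.asarray(measured, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per side")
    if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
        t_stat, p_value = 0.0, 1.0
    else:
        t_stat, p_value = stats.ttest_ind(a, b, equal_var=False)
    return {
        "t": float(t_stat),
        "p_value": float(p_value),
        "predicted": _summary(a),
        "measured": _summary(b),
    }


def predict_stalled_morphology(
    tracks: Sequence[IntensityTrack],
    fits: Sequence[TrackFit],
    rule: TransitionRule,
    delta: float = 0.05,
    epsilon: float = 0.05,
    t_max: float | None = None,
    seed: int = 0,
) -> tuple[MorphologyFractions, pd.DataFrame]:
    """Predicted flat/dome/pit fractions for osmotic-shock tracks.

    Because coat growth stalls under shock, the flat-to-curved transition
    is detected by the 5 % CLC-over-AP2 threshold rather than the AP2
    plateau.  A track whose CLC never exceeds the AP2 curve by ``delta``
    (within its recorded frames, or before ``t_max``) is counted flat;
    crossed tracks are labelled dome or pit by drawing a uniform time in
    their curved span and splitting it by the rule's dome fraction.
    Returns the fractions and a per-track label table.
    """
    if len(tracks) == 0:
        raise ValueError("no tracks")
    rng = np.random.default_rng(seed)
    rows = []
    for track, fit in zip(tracks, fits):
        t_c = transition_time_threshold(track, fit, delta=delta, epsilon=epsilon, t_max=t_max)
        t_end = track.times[-1] if t_max is None else min(track.times[-1], t_max)
        if t_c is None or t_end <= t_c:
            label = "flat"
        else:
            u = rng.random()
            label = "dome" if u < rule.dome_fraction else "pit"
        rows.append({"track_id": track.track_id, "t_cross": t_c, "morphology": label})
    labels = pd.DataFrame(rows)
    counts = labels["morphology"].value_counts()
    fractions = {m: 100.0 * counts.get(m, 0) / len(labels) for m in MORPHOLOGIES}
    return MorphologyFractions(fractions=fractions, n=len(labels)), labels
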