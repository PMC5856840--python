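"""Readers/writers for the track, EM and CLEM table schemas, plus the
pipeline configuration and end-to-end orchestration.

All tables are delimited text: comma for ``.csv``, tab for ``.tsv``/``.txt``.
Canonical schemas (documented in the README):

* tracks:  track_id, t_s, ap2, clc, condition, shock_onset_s[, cell_id]
* EM:      structure_id, membrane_id, morphology, projected_area_nm2
* CLEM:    structure_id, morphology, projected_area_nm2, fluorescence_sum,
           channel, membrane_id

A ``column_map`` (dict of file-column -> canonical name, loadable from the
YAML config) adapts externally deposited tables without code changes.
Row-level violations are reported with 1-based file line numbers (header
is line 1).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clem import flat_regression, infer_correction_factors, ratio_by_morphology
from .ensemble import (
    CalibrationScale,
    DetectionLimit,
    apply_detection_limit,
    compare_distributions,
    morphology_fractions,
    predict_event,
    sample_snapshots,
)
from .growth import TransitionRule
from .synthetic import SimulationConfig, generate_clem_dataset, generate_em_snapshot, generate_tracks
from .tracks import IntensityTrack, compute_offsets, fit_flat_model, fit_two_phase_model

__all__ = [
    "DataError",
    "PipelineConfig",
    "read_tracks",
    "write_tracks",
    "read_em_table",
    "write_em_table",
    "read_clem_table",
    "write_clem_table",
    "run_pipeline",
]

logger = logging.getLogger("coatkit")

TRACK_COLUMNS = ["track_id", "t_s", "ap2", "clc", "condition", "shock_onset_s"]
EM_COLUMNS = ["structure_id", "membrane_id", "morphology", "projected_area_nm2"]
CLEM_COLUMNS = [
    "structure_id",
    "morphology",
    "projected_area_nm2",
    "fluorescence_sum",
    "channel",
    "membrane_id",
]
EM_CLASSES = {"flat", "dome", "pit"}
CLEM_CLASSES = EM_CLASSES | {"multiple"}


class DataError(Exception):
    """Structured input-data validation failure."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path, required: list[str], column_map: dict | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: file not found")
    df = pd.read_csv(path, sep=_sep_for(path))
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    return df


def _first_bad_line(mask: pd.Series) -> int:
    """1-based file line of the first offending row (header = line 1)."""
    return int(mask.to_numpy().nonzero()[0][0]) + 2


def read_tracks(path, column_map: dict | None = None) -> list[IntensityTrack]:
    """Read and validate a track table into IntensityTrack objects."""
    path = Path(path)
    df = _read_table(path, ["track_id", "t_s", "ap2"], column_map)
    for col in ("ap2", "clc"):
        if col in df.columns:
            bad = df[col].notna() & (df[col] < 0)
            if bad.any():
                raise DataError(
                    f"{path}: negative {col} intensity on line {_first_bad_line(bad)}"
                )
    tracks = []
    for track_id, group in df.groupby("track_id", sort=False):
        group = group.sort_values("t_s")
        clc = group["clc"].to_numpy(dtype=float) if "clc" in group.columns else None
        if clc is not None and np.all(np.isnan(clc)):
            clc = None
        condition = str(group["condition"].iloc[0]) if "condition" in group.columns else "iso"
        onset = None
        if "shock_onset_s" in group.columns and pd.notna(group["shock_onset_s"].iloc[0]):
            onset = float(group["shock_onset_s"].iloc[0])
        cell = str(group["cell_id"].iloc[0]) if "cell_id" in group.columns else "cell0"
        try:
            tracks.append(
                IntensityTrack(
                    track_id=str(track_id),
                    times=group["t_s"].to_numpy(dtype=float),
                    ap2=group["ap2"].to_numpy(dtype=float),
                    clc=clc,
                    condition=condition,
                    shock_onset=onset,
                    cell_id=cell,
                )
            )
        except ValueError as exc:
            raise DataError(f"{path}: {exc}") from exc
    if not tracks:
        raise DataError(f"{path}: no tracks found")
    return tracks


def write_tracks(tracks, path) -> None:
    path = Path(path)
    rows = []
    for tr in tracks:
        for k, t in enumerate(tr.times):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "t_s": t,
                    "ap2": tr.ap2[k],
                    "clc": tr.clc[k] if tr.clc is not None else np.nan,
                    "condition": tr.condition,
                    "shock_onset_s": tr.shock_onset if tr.shock_onset is not None else np.nan,
                    "cell_id": tr.cell_id,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def read_em_table(path, column_map: dict | None = None) -> pd.DataFrame:
    path = Path(path)
    df = _read_table(path, ["morphology", "projected_area_nm2"], column_map)
    bad = ~df["morphology"].isin(EM_CLASSES)
    if bad.any():
        raise DataError(
            f"{path}: unknown morphology {df.loc[bad, 'morphology'].iloc[0]!r} "
            f"on line {_first_bad_line(bad)}"
        )
    bad = df["projected_area_nm2"] <= 0
    if bad.any():
        raise DataError(f"{path}: nonpositive area on line {_first_bad_line(bad)}")
    if "membrane_id" not in df.columns:
        df = df.assign(membrane_id="mb0")
    return df


def write_em_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_clem_table(path, column_map: dict | None = None) -> pd.DataFrame:
    path = Path(path)
    df = _read_table(
        path, ["morphology", "projected_area_nm2", "fluorescence_sum", "channel"], column_map
    )
    bad = ~df["morphology"].isin(CLEM_CLASSES)
    if bad.any():
        raise DataError(
            f"{path}: unknown morphology {df.loc[bad, 'morphology'].iloc[0]!r} "
            f"on line {_first_bad_line(bad)}"
        )
    bad = df["projected_area_nm2"] <= 0
    if bad.any():
        raise DataError(f"{path}: nonpositive area on line {_first_bad_line(bad)}")
    bad = df["fluorescence_sum"] < 0
    if bad.any():
        raise DataError(f"{path}: negative fluorescence on line {_first_bad_line(bad)}")
    if "membrane_id" not in df.columns:
        df = df.assign(membrane_id="mb0")
    return df


def write_clem_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (units: nm, nm², s, a.u.).

    With ``simulate`` true, inputs are generated by the synthetic module
    from ``sim``; otherwise ``tracks_path`` (and optionally ``em_path``,
    ``clem_path``) are read.  All randomness derives from ``seed``.
    """

    simulate: bool = True
    tracks_path: str | None = None
    em_path: str | None = None
    clem_path: str | None = None
    column_map: dict = field(default_factory=dict)
    model: str = "ap2_plateau"
    f_star: float = 0.70
    dome_fraction: float = 0.40
    epsilon: float = 0.05
    delta: float = 0.05
    detection_limit_nm2: float = 1000.0
    theta_max_deg: float = 160.0
    calibration_scale: float = 1.0
    n_samples: int = 10000
    seed: int = 0
    group_key: str = "cell_id"
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    @property
    def rule(self) -> TransitionRule:
        return TransitionRule(f_star=self.f_star, dome_fraction=self.dome_fraction)

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            model=self.model,
            rule=self.rule,
            theta_max=np.deg2rad(self.theta_max_deg),
            epsilon=self.epsilon,
            calibration_scale=self.calibration_scale,
            seed=self.seed,
            **self.sim,
        )


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except DataError:
                raise
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run the full analysis: tracks -> fits -> offsets -> predicted
    ensemble -> detection limit -> morphology fractions (+ optional EM
    comparison and CLEM calibration).  Deterministic given ``config.seed``.

    Returns the JSON-ready summary; with ``outdir`` also writes the
    ensemble table, the summary and a log of every default used.
    """
    logger.info("pipeline start: seed=%d model=%s", config.seed, config.model)
    summary: dict = {"seed": config.seed, "model": config.model}
    rule = config.rule
    theta_max = np.deg2rad(config.theta_max_deg)

    @_stage("load")
    def load():
        if config.simulate:
            tracks, truth = generate_tracks(config.sim_config())
            return tracks, truth
        if config.tracks_path is None:
            raise DataError("tracks_path required when simulate is false")
        return read_tracks(config.tracks_path, config.column_map or None), None

    tracks, truth = load()
    summary["n_tracks"] = len(tracks)

    @_stage("fit")
    def fit():
        fits, excluded = [], 0
        for tr in tracks:
            try:
                ap2_fit = fit_flat_model(tr, "ap2")
                if config.model == "constant_area":
                    f = fit_flat_model(tr, "clc")
                elif config.model == "two_phase":
                    f = fit_two_phase_model(tr, rule, theta_max=theta_max)
                else:
                    from .growth import plateau_time

                    t_p = plateau_time(ap2_fit.flat, config.epsilon)
                    f = fit_two_phase_model(tr, rule, theta_max=theta_max, fix_transition_at=t_p)
            except ValueError:
                excluded += 1
                continue
            if not (f.converged and ap2_fit.converged):
                excluded += 1
                continue
            fits.append((tr, ap2_fit, f))
        if not fits:
            raise DataError("no convergent track fits")
        return fits, excluded

    fits, n_excluded = fit()
    summary["n_excluded"] = n_excluded
    summary["n_fitted"] = len(fits)

    @_stage("offsets")
    def offsets():
        rows = []
        for tr, ap2_fit, _ in fits:
            if tr.clc is None:
                continue
            off = compute_offsets(tr, ap2_fit, epsilon=config.epsilon)
            rows.append(
                {
                    "time_offset": off.time_offset,
                    "intensity_offset": off.intensity_offset,
                    "clc_content_at_plateau": off.clc_content_at_plateau,
                }
            )
        return pd.DataFrame(rows)

    off_df = offsets()
    if len(off_df):
        summary["offsets"] = {
            "time_offset_median_s": float(off_df["time_offset"].median()),
            "intensity_offset_median": float(off_df["intensity_offset"].median()),
            "clc_content_at_plateau_median": float(off_df["clc_content_at_plateau"].median()),
        }

    @_stage("ensemble")
    def ensemble():
        preds = [predict_event(f, rule, epsilon=config.epsilon) for _, _, f in fits]
        groups = {tr.track_id: tr.cell_id for tr, _, _ in fits}
        ens = sample_snapshots(
            preds,
            n_samples=config.n_samples,
            seed=config.seed,
            scale=CalibrationScale(config.calibration_scale),
            groups=groups,
        )
        ens = apply_detection_limit(ens, DetectionLimit(config.detection_limit_nm2))
        return ens

    ens = ensemble()
    frac = morphology_fractions(ens, group_key="group")
    summary["ensemble"] = {
        "fractions_pct": frac.fractions,
        "group_mean_pct": frac.group_mean,
        "group_sd_pct": frac.group_sd,
        "n_samples_kept": frac.n,
        "n_removed_below_limit": ens.meta.get("n_removed_below_limit"),
        "detection_limit_nm2": config.detection_limit_nm2,
    }

    if config.em_path or config.simulate:
        @_stage("em_compare")
        def em_compare():
            if config.em_path:
                em = read_em_table(config.em_path, config.column_map or None)
            else:
                em = generate_em_snapshot(config.sim_config(), 1000, seed=config.seed + 1)
                em = em[em["projected_area_nm2"] >= config.detection_limit_nm2]
            return compare_distributions(
                ens.records["projected_area_nm2"], em["projected_area_nm2"]
            )

        summary["em_comparison"] = em_compare()

    if config.clem_path or config.simulate:
        @_stage("clem")
        def clem_stage():
            if config.clem_path:
                clem = read_clem_table(config.clem_path, config.column_map or None)
            else:
                clem = generate_clem_dataset(seed=config.seed + 2)
            out = {}
            channels = sorted(clem["channel"].unique())
            for ch in channels:
                sub = clem[clem["channel"] == ch]
                flat_fit = flat_regression(sub)
                facs = infer_correction_factors(sub, flat_fit)
                out[ch] = {
                    "slope": flat_fit.slope,
                    "intercept": flat_fit.intercept,
                    "r": flat_fit.r,
                    "dome_factor": facs.dome,
                    "pit_factor": facs.pit,
                }
            if {"clathrin", "ap2"} <= set(channels):
                ratios = ratio_by_morphology(
                    clem[clem["channel"] == "clathrin"], clem[clem["channel"] == "ap2"]
                )
                out["ap2_clathrin_ratio"] = ratios
            return out

        summary["clem"] = clem_stage()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ens.records.to_csv(outdir / "ensemble.csv", index=False)
        if truth is not None:
            truth.to_csv(outdir / "ground_truth.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        with open(outdir / "pipeline.log", "w") as fh:
            fh.write("coatkit pipeline\n")
            for k, v in asdict(config).items():
                fh.write(f"{k}: {v}\n")
    logger.info("pipeline done")
    return summary
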