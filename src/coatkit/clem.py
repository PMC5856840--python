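"""CLEM quantification: fluorescence–area calibration and registration.

Correlative light and electron microscopy pairs each coated structure's
summed fluorescence (clathrin or AP2 channel) with its projected area and
morphology class from TEM.  For flat coats projected and surface area
coincide, so the flat-coat linear regression calibrates intensity per nm²
of coat.  Curved structures fall above that line because their surface
exceeds their TEM footprint; the per-class correction factor is the
multiplier on projected area that best maps a class back onto the flat
regression.  Comparing the factors between the AP2 and clathrin channels
measures how the AP2/clathrin stoichiometry changes with curvature.

Registration utilities (landmark affine estimation, subpixel Gaussian spot
centres) support mapping fluorescence coordinates onto the EM montage.

Input tables use columns: structure_id, morphology (flat|dome|pit|multiple),
projected_area_nm2, fluorescence_sum, channel (clathrin|ap2), membrane_id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RegressionResult",
    "CorrectionFactors",
    "flat_regression",
    "infer_correction_factors",
    "ratio_by_morphology",
    "estimate_affine_from_landmarks",
    "apply_affine",
    "gaussian_center",
]

CLEM_CLASSES = ("flat", "dome", "pit", "multiple")


@dataclass(frozen=True)
class RegressionResult:
    """Linear fit of fluorescence_sum against projected_area_nm2."""

    slope: float
    intercept: float
    r: float
    n: int

    def predict(self, projected_area):
        return self.slope * np.asarray(projected_area, dtype=float) + self.intercept


@dataclass(frozen=True)
class CorrectionFactors:
    """Curvature correction factors: multiply a class's projected areas by
    the factor to land on the flat-coat regression."""

    dome: float
    pit: float


def _select(records: pd.DataFrame, morphology: str, channel: str | None) -> pd.DataFrame:
    df = records
    if channel is not None:
        if "channel" not in df.columns:
            raise ValueError("records have no 'channel' column")
        df = df[df["channel"] == channel]
    return df[df["morphology"] == morphology]


def flat_regression(
    records: pd.DataFrame,
    channel: str | None = None,
    zero_intercept: bool = False,
) -> RegressionResult:
    """Least-squares line of fluorescence vs projected area over flat coats.

    "multiple" records (several structures merged into one fluorescent
    object) are excluded by construction since only single flat structures
    calibrate the intensity scale.  At least 3 flat records are required.
    """
    flat = _select(records, "flat", channel)
    if len(flat) < 3:
        raise ValueError(f"need >= 3 flat records, got {len(flat)}")
    x = flat["projected_area_nm2"].to_numpy(dtype=float)
    y = flat["fluorescence_sum"].to_numpy(dtype=float)
    if zero_intercept:
        slope = float(np.dot(x, y) / np.dot(x, x))
        resid = y - slope * x
        ss_tot = float(np.dot(y, y))
        r = float(np.sqrt(max(1.0 - np.dot(resid, resid) / ss_tot, 0.0))) if ss_tot else 0.0
        return RegressionResult(slope=slope, intercept=0.0, r=r, n=len(x))
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept), r=float(fit.rvalue), n=len(x)
    )


def _class_factor(df: pd.DataFrame, flat_fit: RegressionResult) -> float:
    """argmin over k of sum (I_i - flat_fit(k * P_i))^2, closed form."""
    p = df["projected_area_nm2"].to_numpy(dtype=float)
    y = df["fluorescence_sum"].to_numpy(dtype=float)
    m, b = flat_fit.slope, flat_fit.intercept
    denom = m * np.dot(p, p)
    if denom == 0 or not np.isfinite(denom):
        raise ValueError("degenerate class regression (zero flat slope or areas)")
    return float(np.dot(p, y - b) / denom)


def infer_correction_factors(
    records: pd.DataFrame,
    flat_fit: RegressionResult,
    channel: str | None = None,
) -> CorrectionFactors:
    """Per-class multiplier mapping dome/pit records onto the flat line.

    For each class the factor k minimises the squared residuals of
    ``fluorescence_sum`` against ``flat_fit(k * projected_area)``; with a
    zero intercept this reduces to the ratio of class to flat slope.
    Spherical-cap geometry bounds the factors at 2 (hemispherical dome)
    and 4 (complete sphere), so a pit factor below the dome factor is
    geometrically inconsistent and triggers a warning.
    """
    factors = {}
    for cls in ("dome", "pit"):
        df = _select(records, cls, channel)
        if len(df) < 3:
            raise ValueError(f"need >= 3 {cls} records, got {len(df)}")
        factors[cls] = _class_factor(df, flat_fit)
    if factors["pit"] < factors["dome"]:
        warnings.warn(
            "pit correction factor below dome factor: inconsistent with "
            "increasing curvature",
            stacklevel=2,
        )
    return CorrectionFactors(dome=factors["dome"], pit=factors["pit"])


def ratio_by_morphology(
    clathrin_records: pd.DataFrame,
    ap2_records: pd.DataFrame,
    zero_intercept: bool = False,
) -> dict:
    """Relative AP2/clathrin density per morphology class, flat = 1.

    The per-class correction factor in each channel measures how much that
    channel's signal grows with curvature; the ratio of AP2 to clathrin
    factors therefore tracks the AP2/clathrin stoichiometry relative to
    flat coats.  A monotone decrease (flat > dome > pit) indicates AP2
    dilution as curvature increases; the ``monotone_decreasing`` flag
    reports whether the data show it.  Invariant to global intensity
    rescaling of either channel.
    """
    out = {"flat": 1.0}
    facs = {}
    for name, rec in (("clathrin", clathrin_records), ("ap2", ap2_records)):
        flat_fit = flat_regression(rec, zero_intercept=zero_intercept)
        facs[name] = infer_correction_factors(rec, flat_fit)
    for cls in ("dome", "pit"):
        clc_f = getattr(facs["clathrin"], cls)
        if clc_f == 0:
            raise ValueError(f"zero clathrin correction factor for {cls}")
        out[cls] = getattr(facs["ap2"], cls) / clc_f
    out["monotone_decreasing"] = bool(out["flat"] > out["dome"] > out["pit"])
    return out


def estimate_affine_from_landmarks(
    src: np.ndarray, dst: np.ndarray
) -> tuple[np.ndarray, float]:
    """Least-squares 2D affine transform mapping src landmarks onto dst.

    Used to register a fluorescence image to the EM montage from (at
    least) three manually identified structures.  Returns a 3x3 matrix in
    homogeneous form and the RMS residual (exactly 0 for three
    non-collinear pairs, where the affine interpolates).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must both be (n, 2) arrays")
    n = src.shape[0]
    if n < 3:
        raise ValueError("need at least 3 landmark pairs")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(src).max())) < 2:
        raise ValueError("landmarks are collinear; affine is underdetermined")
    design = np.column_stack([src, np.ones(n)])
    coef, _, _, _ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = np.eye(3)
    matrix[:2, :2] = coef[:2].T
    matrix[:2, 2] = coef[2]
    resid = apply_affine(matrix, src) - dst
    rms = float(np.sqrt(np.mean(resid**2)))
    return matrix, rms


def apply_affine(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 3x3 homogeneous affine to (n, 2) points."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    hom = np.column_stack([pts, np.ones(len(pts))])
    out = hom @ matrix.T
    out = out[:, :2]
    return out[0] if single else out


def gaussian_center(patch: np.ndarray) -> tuple[float, float]:
    """Subpixel centre (x, y) of a fluorescent spot by 2D Gaussian fit.

    Fits an isotropic Gaussian with offset,
    ``b + a exp(-((x-x0)^2 + (y-y0)^2) / (2 sigma^2))``, initialised from
    the intensity centroid.  Column index is x and row index is y.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or min(patch.shape) < 3:
        raise ValueError("patch must be a 2D array of at least 3x3 pixels")
    span = float(patch.max() - patch.min())
    if span <= 0:
        raise ValueError("flat patch: no spot to fit")
    ny, nx = patch.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    w = patch - patch.min()
    x0 = float((w * xx).sum() / w.sum())
    y0 = float((w * yy).sum() / w.sum())
    sigma0 = max(np.sqrt((w * ((xx - x0) ** 2 + (yy - y0) ** 2)).sum() / w.sum() / 2.0), 0.5)

    def resid(p):
        a, b, cx, cy, sigma = p
        model = b + a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2))
        return (model - patch).ravel()

    p0 = [span, float(patch.min()), x0, y0, sigma0]
    lo = [span * 1e-3, -np.inf, -1.0, -1.0, 0.1]
    hi = [span * 1e3, np.inf, nx, ny, max(nx, ny)]
    res = optimize.least_squares(resid, np.clip(p0, lo, hi), bounds=(lo, hi))
    _, _, cx, cy, _ = res.x
    if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
        raise ValueError("fitted centre outside patch bounds")
    return float(cx), float(cy)
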