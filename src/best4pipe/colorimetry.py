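"""Colorimetric and ratiometric pH quantification.

Luminal pH is read off an indicator dye's color: ROI colors are
background-shifted so every image shares the experiment's mean background,
converted from sRGB to hue-chroma-luminance (here the polar form of CIE
L*u*v* under D65 — "HCL" is ambiguous across color libraries, so the dialect
is fixed explicitly), hue is rotated 180 deg to move the circular wrap point
out of the indicators' color range, and the per-animal hue is summarized
over time with t-based 95% confidence intervals. Quartic hue~chroma and
hue~luminance fits verify that hue alone describes the indicator color.
Intracellular pH uses the background-subtracted 405/488 nm pHluorin
excitation ratio; CTCF is the standard integrated-density background
correction for fluorescence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import curve_fit
from scipy.stats import t as t_dist

logger = logging.getLogger("best4pipe")

# linear sRGB -> XYZ, ITU-R BT.709 primaries as tabulated in the original
# sRGB proposal; paired with the tabulated D65 white point (2 deg observer).
# "HCL" dialects differ mainly in the lineage of these constants; these are
# the ones the common color toolchains ship.
_RGB_TO_XYZ = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)
_WHITE = np.array([0.95047, 1.0, 1.08883])
_EPS = (6.0 / 29.0) ** 3
_KAPPA = (29.0 / 3.0) ** 3
ACHROMATIC_C = 1e-6


@dataclass
class RatioConfig:
    """ROI geometry for ratiometric pHluorin quantification."""

    roi_edge_px: int = 12
    z_extent_um: float = 5.0
    num_channel: int = 405
    den_channel: int = 488

    def __post_init__(self) -> None:
        if self.roi_edge_px <= 0:
            raise ValueError("roi_edge_px must be positive")


# ---------------------------------------------------------------------------
# ROI extraction and background shift
# ---------------------------------------------------------------------------

def extract_roi_color(image: np.ndarray, roi, bg_roi) -> tuple[np.ndarray, np.ndarray]:
    """Channel-wise mean color over two rectangles of an RGB raster.

    Rectangles are (row, col, height, width); both must lie within bounds.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be an H x W x 3 RGB raster")

    def mean_rect(rect) -> np.ndarray:
        r, c, h, w = rect
        if r < 0 or c < 0 or h <= 0 or w <= 0 or r + h > image.shape[0] or c + w > image.shape[1]:
            raise ValueError(f"ROI {rect} outside image of shape {image.shape[:2]}")
        return image[r : r + h, c : c + w].mean(axis=(0, 1))

    return mean_rect(roi), mean_rect(bg_roi)


def background_shift(series: pd.DataFrame, group_col: str = "condition") -> pd.DataFrame:
    """Shift each record so all backgrounds equal the experiment's mean background.

    Per group, target = mean of all background RGB; each record's ROI and
    background colors are shifted additively by (target - record background),
    leaving roi - bg differences untouched and setting every shifted
    background exactly to the target.
    """
    required = {"R", "G", "B", "bgR", "bgG", "bgB"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"color series missing columns: {sorted(missing)}")
    out = series.copy()
    groups = out.groupby(group_col) if group_col in out.columns else [(None, out)]
    for key, grp in groups:
        if len(grp) == 1:
            logger.info("background_shift: single-record experiment %r", key)
        target = grp[["bgR", "bgG", "bgB"]].mean(axis=0).to_numpy()
        delta = target[None, :] - grp[["bgR", "bgG", "bgB"]].to_numpy()
        out.loc[grp.index, ["R", "G", "B"]] = grp[["R", "G", "B"]].to_numpy() + delta
        out.loc[grp.index, ["bgR", "bgG", "bgB"]] = target[None, :] + np.zeros_like(delta)
    return out


# ---------------------------------------------------------------------------
# sRGB -> HCL (polar CIE L*u*v*)
# ---------------------------------------------------------------------------

def _srgb_decode(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def rgb_to_hcl(rgb) -> tuple[float, float, float]:
    """Convert one sRGB triple (0..255) to (L*, C, H degrees).

    Gamma-decode -> linear RGB -> XYZ (D65) -> CIE L*u*v* -> polar:
    C = sqrt(u*^2 + v*^2), H = atan2(v*, u*) mod 360. Near-achromatic colors
    (C < 1e-6) get H = 0 by convention. Out-of-gamut inputs (possible after
    background shifting) are clamped to [0, 255] with a logged count.
    """
    L, C, H, clamped = _rgb_to_hcl_array(np.asarray(rgb, dtype=float)[None, :])
    if clamped:
        logger.info("rgb_to_hcl: %d channel value(s) clamped to [0,255]", clamped)
    return float(L[0]), float(C[0]), float(H[0])


def _rgb_to_hcl_array(rgb: np.ndarray):
    rgb = np.asarray(rgb, dtype=float)
    clamped = int(np.sum((rgb < 0) | (rgb > 255)))
    rgb = np.clip(rgb, 0.0, 255.0)
    lin = _srgb_decode(rgb / 255.0)
    xyz = lin @ _RGB_TO_XYZ.T
    X, Y, Z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    Xn, Yn, Zn = _WHITE

    yr = Y / Yn
    L = np.where(yr > _EPS, 116.0 * np.cbrt(yr) - 16.0, _KAPPA * yr)
    denom = X + 15.0 * Y + 3.0 * Z
    denom_n = Xn + 15.0 * Yn + 3.0 * Zn
    up_n, vp_n = 4.0 * Xn / denom_n, 9.0 * Yn / denom_n
    with np.errstate(invalid="ignore", divide="ignore"):
        up = np.where(denom > 0, 4.0 * X / np.where(denom > 0, denom, 1.0), up_n)
        vp = np.where(denom > 0, 9.0 * Y / np.where(denom > 0, denom, 1.0), vp_n)
    u = 13.0 * L * (up - up_n)
    v = 13.0 * L * (vp - vp_n)
    C = np.hypot(u, v)
    H = np.degrees(np.arctan2(v, u)) % 360.0
    H = np.where(C < ACHROMATIC_C, 0.0, H)
    return L, C, H, clamped


def hue_shift(h: float) -> float:
    """Rotate hue by 180 degrees: (h + 180) mod 360. Self-inverse."""
    return float((np.asarray(h, dtype=float) + 180.0) % 360.0)


def series_to_hue(series: pd.DataFrame, shift_background: bool = True) -> pd.DataFrame:
    """ColorSeries frame -> per-record HCL with shifted hue.

    Applies :func:`background_shift` (per condition) and converts the ROI
    color of every record; adds luminance, chroma, hue, hue_shifted, and an
    achromatic flag.
    """
    if shift_background:
        series = background_shift(series)
    rgb = series[["R", "G", "B"]].to_numpy(dtype=float)
    L, C, H, clamped = _rgb_to_hcl_array(rgb)
    if clamped:
        logger.info("series_to_hue: %d channel value(s) clamped", clamped)
    out = series.copy()
    out["luminance"] = L
    out["chroma"] = C
    out["hue"] = H
    out["hue_shifted"] = (H + 180.0) % 360.0
    out["achromatic"] = C < ACHROMATIC_C
    return out


# ---------------------------------------------------------------------------
# hue statistics
# ---------------------------------------------------------------------------

def fit_hue_polynomials(records: pd.DataFrame, degree: int = 4) -> dict:
    """Quartic OLS fits of shifted hue against chroma and against luminance.

    Returns coefficient vectors (highest power first) and R^2 for each fit.
    A strong fit justifies summarizing each animal's color by hue alone.
    Constant hue gives R^2 = 1 with a zero-variance note.
    """
    if len(records) < degree + 2:
        raise ValueError(f"need >= {degree + 2} records for a degree-{degree} fit")
    hue = records["hue_shifted"].to_numpy(dtype=float)
    out: dict = {}
    for pred in ("chroma", "luminance"):
        x = records[pred].to_numpy(dtype=float)
        coef = np.polyfit(x, hue, deg=degree)
        resid = hue - np.polyval(coef, x)
        ss_tot = float(np.sum((hue - hue.mean()) ** 2))
        if ss_tot == 0:
            r2, note = 1.0, "zero-variance response"
        else:
            r2, note = 1.0 - float(np.sum(resid**2)) / ss_tot, ""
        out[f"hue~{pred}"] = {"coef": coef, "r2": r2, "note": note}
    return out


def hue_timeseries(records: pd.DataFrame, times=None) -> pd.DataFrame:
    """Across-animal mean shifted hue per timepooint with t-based 95% CI.

    Timepoints with a single animal are kept as points (CI columns NaN);
    requested timepoints with no records are omitted with a warning.
    """
    if times is None:
        times = sorted(records["time"].unique())
    rows = []
    for tp in times:
        vals = records.loc[records["time"] == tp, "hue_shifted"].to_numpy(dtype=float)
        if vals.size == 0:
            logger.warning("hue_timeseries: no records at time %s", tp)
            continue
        mean = float(vals.mean())
        if vals.size >= 2:
            sem = vals.std(ddof=1) / np.sqrt(vals.size)
            half = float(t_dist.ppf(0.975, vals.size - 1) * sem)
            lo, hi = mean - half, mean + half
        else:
            lo = hi = float("nan")
        rows.append({"time": tp, "n": int(vals.size), "mean_hue": mean, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def calibrate_hue_to_ph(standards: pd.DataFrame):
    """Monotone interpolation from measured hue to pH using known standards.

    ``standards`` needs columns ``ph`` and ``hue_shifted`` (from imaging
    solutions of known pH). Returns a callable clamping to the calibrated
    hue range. Intended for synthetic recovery checks; the indicator's real
    hue-pH relationship should be calibrated per experiment.
    """
    std = standards.sort_values("hue_shifted")
    hue = std["hue_shifted"].to_numpy(dtype=float)
    ph = std["ph"].to_numpy(dtype=float)
    if len(hue) < 3 or np.any(np.diff(hue) <= 0):
        raise ValueError("standards must have >= 3 strictly monotone hue values")
    interp = PchipInterpolator(hue, ph)

    def hue_to_ph(h):
        return interp(np.clip(np.asarray(h, dtype=float), hue[0], hue[-1]))

    return hue_to_ph


def fit_relaxation(times, values) -> dict:
    """Fit v(t) = v_inf + (v_0 - v_inf) exp(-t / tau) by least squares."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)

    def model(t, v_inf, v0, tau):
        return v_inf + (v0 - v_inf) * np.exp(-t / tau)

    span = max(times.max() - times.min(), 1.0)
    p0 = (values[-1], values[0], span / 3.0)
    popt, _ = curve_fit(model, times, values, p0=p0, maxfev=20000)
    return {"v_inf": float(popt[0]), "v_0": float(popt[1]), "tau": float(abs(popt[2]))}


# ---------------------------------------------------------------------------
# fluorescence quantification
# ---------------------------------------------------------------------------

def phluorin_ratio(f405: float, f488: float, bg405: float, bg488: float) -> float:
    """Background-subtracted 405/488 excitation ratio; NaN when the
    denominator is non-positive (cell excluded with a warning)."""
    den = f488 - bg488
    if den <= 0:
        logger.warning("phluorin_ratio: non-positive 488 signal after background subtraction")
        return float("nan")
    return float((f405 - bg405) / den)


def ctcf(integrated_density: float, area: float, mean_bg: float) -> float:
    """Corrected total cell fluorescence: IntDen - area * mean background."""
    if area <= 0:
        raise ValueError("area must be positive")
    return float(integrated_density - area * mean_bg)
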