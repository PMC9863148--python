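"""Normalization, background-based detection calls and FDR adjustment.

Detection follows the membrane-array convention: the noise floor is defined
by the *background spots* — positions whose density lies within a small
fraction (default 5%) of the dynamic range above the per-membrane minimum —
and an analyte counts as expressed when its duplicate densities sit
significantly above that background population (one-sided Welch t,
p < 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import PchipInterpolator
from statsmodels.stats.multitest import multipletests

from .quantify import DensityTable, ExpressionMatrix

__all__ = [
    "DetectionParams",
    "robust_spline_normalize",
    "log2_transform",
    "background_spot_set",
    "detection_pvalue",
    "detect_analytes",
    "bh_adjust",
]


@dataclass(frozen=True)
class DetectionParams:
    """Background definition and detection significance level.

    ``background_fraction`` is the fraction of the dynamic range above the
    minimum density that delimits background spots (threshold =
    min + fraction * (max - min)); ``alpha_detect`` the one-sided
    significance level for the expressed call.
    """

    background_fraction: float = 0.05
    alpha_detect: float = 0.05

    def __post_init__(self):
        if not 0 < self.background_fraction < 1:
            raise ValueError("background_fraction must be in (0, 1)")
        if not 0 < self.alpha_detect < 1:
            raise ValueError("alpha_detect must be in (0, 1)")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _monotone_map(x_knots: np.ndarray, y_knots: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Strictly increasing spline through (x, y) knots, unit-slope beyond them.

    The unit-slope (log-scale) extension outside the knot range preserves
    fold changes of features brighter or dimmer than every anchor point.
    """
    order = np.argsort(x_knots, kind="stable")
    xs, ys = x_knots[order], y_knots[order]
    uniq, inverse = np.unique(xs, return_inverse=True)
    if len(uniq) == 1:
        return col + (ys.mean() - uniq[0])
    y_uniq = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(y_uniq, inverse, ys)
    np.add.at(counts, inverse, 1.0)
    y_uniq /= counts
    # enforce strict increase so the fitted map preserves ranks exactly
    eps = 1e-12 * max(1.0, float(np.abs(y_uniq).max())) / len(uniq)
    y_uniq = np.maximum.accumulate(y_uniq)
    y_uniq += eps * np.arange(len(uniq))
    spline = PchipInterpolator(uniq, y_uniq, extrapolate=False)
    out = np.empty_like(col, dtype=float)
    lo, hi = uniq[0], uniq[-1]
    below, above = col < lo, col > hi
    inside = ~(below | above)
    out[inside] = spline(col[inside])
    out[below] = y_uniq[0] + (col[below] - lo)
    out[above] = y_uniq[-1] + (col[above] - hi)
    # pchip may have zero slope at boundary knots; repair strictness so that
    # strictly increasing inputs stay strictly increasing (ties stay ties)
    o = np.argsort(col, kind="stable")
    sc, so = col[o], out[o]
    for i in range(1, len(so)):
        if sc[i] > sc[i - 1] and so[i] <= so[i - 1]:
            so[i] = so[i - 1] + max(4 * np.spacing(abs(so[i - 1])), 1e-12)
        elif sc[i] == sc[i - 1]:
            so[i] = so[i - 1]
    out[o] = so
    return out


def _bin_knots(x: np.ndarray, y: np.ndarray, n_knots: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Condense anchor pairs into few spline knots by quantile binning.

    The low knot count keeps the fitted curve smooth: individual anchors
    are not matched exactly, so replicate-to-replicate variation survives
    normalization instead of being absorbed into the curve.  Every bin
    holds at least three anchors (down to a two-knot line) for the same
    reason — a single-anchor bin would pin that anchor exactly.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    k = max(2, min(n_knots, len(xs) // 3))
    k = min(k, len(xs))
    edges = np.linspace(0, len(xs), k + 1).astype(int)
    xk = np.array([xs[a:b].mean() for a, b in zip(edges[:-1], edges[1:]) if b > a])
    yk = np.array([ys[a:b].mean() for a, b in zip(edges[:-1], edges[1:]) if b > a])
    return xk, yk


def _rank_invariant_mask(logv: np.ndarray, min_points: int = 8,
                         rank_tolerance: float = 0.1,
                         rank_trim: float = 0.1) -> np.ndarray:
    """Features whose rank is stable across all samples, away from the tails.

    A feature qualifies when the spread of its within-sample ranks is at
    most ``rank_tolerance`` of the feature count; if fewer than
    ``min_points`` qualify the most rank-stable features are taken instead.
    Differentially expressed features shift rank between samples and are
    thereby excluded from the normalization curve.  The extreme
    ``rank_trim`` fraction of ranks is excluded as well: a differential
    feature that is already the dimmest or brightest keeps its rank no
    matter how large its fold change, so rank stability carries no
    information there and anchoring it would normalize the effect away.
    """
    n, m = logv.shape
    ranks = np.argsort(np.argsort(logv, axis=0, kind="stable"), axis=0)
    spread = ranks.max(axis=1) - ranks.min(axis=1)
    mean_rank = ranks.mean(axis=1)
    interior = (mean_rank >= rank_trim * (n - 1)) & (mean_rank <= (1 - rank_trim) * (n - 1))
    mask = (spread <= max(1.0, rank_tolerance * n)) & interior
    if mask.sum() < min(min_points, n):
        k = min(min_points, n)
        mask = np.zeros(n, dtype=bool)
        order = np.lexsort((~interior, spread))
        mask[order[:k]] = True
    return mask


def robust_spline_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Robust monotone-spline normalization onto the mean quantile curve.

    Per sample, a strictly increasing cubic spline maps the sample's log2
    values onto the across-sample mean curve, anchored only on
    *rank-invariant* features (those whose rank hardly moves between
    samples); differential features therefore do not warp the curve and
    keep their fold changes.  Beyond the anchor range the map continues
    with unit slope.  Output is back-transformed to the linear scale; rank
    order within each sample is preserved exactly.  Zeros are offset by
    half the smallest positive value before the log transform.  With fewer
    than two samples normalization is skipped with a warning.
    """
    if matrix.scale == "log2":
        raise ValueError("normalize the linear-scale matrix, then log-transform")
    if matrix.n_samples < 2:
        warnings.warn("fewer than 2 samples: normalization skipped")
        return ExpressionMatrix(
            values=matrix.values.copy(),
            sample_info=matrix.sample_info.copy(),
            scale="normalized",
            qc=matrix.qc,
        )
    vals = matrix.values.to_numpy(float)
    if np.isnan(vals).any():
        raise ValueError("matrix contains missing values; resolve before normalizing")
    positive = vals[vals > 0]
    if positive.size == 0:
        raise ValueError("matrix has no positive values")
    offset = 0.5 * positive.min()
    logv = np.log2(np.where(vals > 0, vals, offset))
    invariant = _rank_invariant_mask(logv)
    target = logv[invariant].mean(axis=1)  # per-feature mean over samples
    out = np.empty_like(logv)
    for j in range(logv.shape[1]):
        xk, yk = _bin_knots(logv[invariant, j], target)
        out[:, j] = _monotone_map(xk, yk, logv[:, j])
    norm = pd.DataFrame(2.0 ** out, index=matrix.values.index,
                        columns=matrix.values.columns)
    return ExpressionMatrix(values=norm, sample_info=matrix.sample_info.copy(),
                            scale="normalized", qc=matrix.qc)


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Log2 with half-minimum-positive offset for zeros."""
    vals = matrix.values.to_numpy(float)
    positive = vals[vals > 0]
    if positive.size == 0:
        raise ValueError("matrix has no positive values")
    offset = 0.5 * positive.min()
    logv = np.log2(np.where(vals > 0, vals, offset))
    return ExpressionMatrix(
        values=pd.DataFrame(logv, index=matrix.values.index, columns=matrix.values.columns),
        sample_info=matrix.sample_info.copy(), scale="log2", qc=matrix.qc,
    )


# ---------------------------------------------------------------------------
# background and detection
# ---------------------------------------------------------------------------

def background_spot_set(
    sample_values, background_fraction: float = 0.05,
    min_background_fraction: float = 0.1,
) -> tuple[list, float, bool]:
    """Identify background positions: density <= min + fraction * (max - min).

    ``sample_values`` is a pandas Series (index = positions) or 1-D array.
    Returns ``(background_keys, threshold, degenerate)``; when all values are
    equal every position is background and ``degenerate`` is True.  The set
    always contains the minimum, hence is non-empty.

    When fewer than ``min_background_fraction`` of the spots fall under the
    threshold, the membrane has no meaningful signal range above its noise
    floor — the threshold is then cutting into the noise distribution
    itself, and taking only its lower tail would bias the background mean
    and SD downward.  In that case every spot is treated as background
    (the smooth extension of the all-values-equal degenerate rule).
    """
    series = pd.Series(sample_values, dtype=float)
    if len(series) < 2:
        raise ValueError("need >= 2 density values to define background")
    lo, hi = float(series.min()), float(series.max())
    threshold = lo + background_fraction * (hi - lo)
    degenerate = hi == lo
    keys = list(series.index[series <= threshold])
    if len(keys) < min_background_fraction * len(series):
        keys = list(series.index)
        threshold = hi
    return keys, threshold, degenerate


def detection_pvalue(spot_replicates, background, method: str = "background") -> float:
    """One-sided p for 'analyte density exceeds the background population'.

    Default (``method="background"``): under the null an analyte spot is
    just another background spot, so the background population's SD is the
    noise scale; the statistic is

        t = (mean_analyte - mean_bg) / (sd_bg * sqrt(1/n_a + 1/n_bg))

    referred to a t distribution with n_bg - 1 df.  With only two duplicate
    spots per analyte this stays calibrated, whereas a Welch test (also
    available, ``method="welch"``) relies on a 1-df analyte variance and is
    both liberal under the null and underpowered.  A single analyte
    replicate reduces to the classic z-score against background mean/SD.
    Zero background variance degenerates to an exact rule: p = 0 if the
    analyte mean exceeds the background value, else 1.
    """
    x = np.asarray(spot_replicates, dtype=float)
    bg = np.asarray(background, dtype=float)
    x = x[~np.isnan(x)]
    bg = bg[~np.isnan(bg)]
    if len(bg) < 2:
        raise ValueError("need >= 2 background densities")
    if len(x) == 0:
        raise ValueError("no analyte replicate densities")
    bg_sd = bg.std(ddof=1)
    if bg_sd == 0:
        return 0.0 if x.mean() > bg[0] else 1.0
    if method == "welch" and len(x) >= 2 and x.std(ddof=1) > 0:
        res = sps.ttest_ind(x, bg, equal_var=False, alternative="greater")
        return float(res.pvalue)
    se = bg_sd * np.sqrt(1.0 / len(x) + 1.0 / len(bg))
    t = (x.mean() - bg.mean()) / se
    return float(sps.t.sf(t, df=len(bg) - 1))


def detect_analytes(
    table: DensityTable, params: DetectionParams = DetectionParams()
) -> pd.DataFrame:
    """Per-analyte detection call for one membrane.

    Background spots are taken from the membrane's own per-position
    densities via :func:`background_spot_set`; each analyte's duplicates are
    tested against that background population.  Reference spots are
    fiducial markers, not measurements, and are excluded before the
    dynamic range (hence the threshold) is computed.  Densities are
    compared per unit aperture area (mean pixel intensity), which cancels
    the fixed-pattern variation of pixel-quantized aperture sizes.
    Returns a DataFrame indexed by analyte with ``detect_p`` and boolean
    ``detected``.
    """
    frame = table.frame[~table.frame.missing & (table.frame.area > 0)
                        & (table.frame.role != "reference")]
    per_area = frame.density.to_numpy(float) / frame.area.to_numpy(float)
    series = pd.Series(per_area, index=frame.index)
    keys, threshold, degenerate = background_spot_set(series, params.background_fraction)
    bg = series.loc[keys].to_numpy(float)
    rows = {}
    area_by_analyte = {
        a: g.area.to_numpy(float)
        for a, g in frame[frame.role == "analyte"].groupby("analyte", sort=False)
    }
    for analyte, reps in table.analyte_replicates().items():
        areas = area_by_analyte.get(analyte)
        reps_pa = reps / areas if areas is not None and len(areas) == len(reps) else reps
        p = detection_pvalue(reps_pa, bg) if not degenerate else 1.0
        rows[analyte] = (p, p < params.alpha_detect)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["detect_p", "detected"])
    out.attrs["background_threshold"] = threshold
    out.attrs["n_background"] = len(keys)
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
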