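"""Empirical-Bayes moderated-t differential expression.

The model is the two-group limma-style linear model: per analyte g, observed
log2 densities split into a case and a control group give a mean difference
and a pooled residual variance s_g^2 on d_g degrees of freedom.  The
variances are assumed exchangeable, s_g^2 ~ s0^2 * invChi2(d0)/d0; the prior
(d0, s0^2) is estimated from the marginal distribution of log s_g^2 by
closed-form method of moments (trigamma inversion).  The posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces s_g^2 in the t-statistic, which then has d0 + d_g degrees of
freedom — the key gain in designs with very few replicates, here the
duplicate spots of a pooled-urine membrane.

Usage follows the Model / Results convention::

    model = DifferentialExpression.from_matrix(log2mat, case="ckd", control="control")
    res = model.fit()
    res.calls(detection_p, DECriteria())
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps

from .quantify import ExpressionMatrix
from .stats import bh_adjust

__all__ = [
    "DECriteria",
    "DifferentialExpression",
    "DEResults",
    "estimate_variance_prior",
    "trigamma_inverse",
    "call_differential",
]


@dataclass(frozen=True)
class DECriteria:
    """Composite differential-expression gates.

    An analyte is called up-regulated when it is detected in at least one
    condition, its case/control ratio exceeds ``ratio_up``, its moderated-t
    p-value is below ``alpha_p`` and its BH FDR below ``alpha_fdr``;
    down-regulation uses ``ratio_down`` symmetrically.
    """

    ratio_down: float = 0.667
    ratio_up: float = 1.5
    alpha_p: float = 0.05
    alpha_fdr: float = 0.25
    require_detect_in_one_condition: bool = True

    def __post_init__(self):
        if not self.ratio_down < 1 < self.ratio_up:
            raise ValueError("need ratio_down < 1 < ratio_up")


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi^2 variance prior.

    Matches the mean and variance of ``log(s2)`` against the theoretical
    moments of log F-distributed sample variances; returns ``(d0, s02)``.
    ``d0 = inf`` signals homogeneous variances (no excess spread beyond
    chi^2 sampling noise), in which case ``s02`` is the df-weighted pooled
    variance.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (df > 0)
    s2_ok, df_ok = s2[ok], df[ok]
    if len(s2_ok) < 2:
        pooled = float(np.average(s2_ok, weights=df_ok)) if len(s2_ok) else np.nan
        return np.inf, pooled
    floor = 1e-12 * max(1.0, float(np.median(s2_ok[s2_ok > 0])) if np.any(s2_ok > 0) else 1.0)
    z = np.log(np.maximum(s2_ok, floor))
    e = z - special.digamma(df_ok / 2.0) + np.log(df_ok / 2.0)
    emean = e.mean()
    n = len(e)
    evar = ((e - emean) ** 2).sum() / (n - 1)
    excess = evar - float(np.mean(special.polygamma(1, df_ok / 2.0)))
    if excess <= 0:
        return np.inf, float(np.average(s2_ok, weights=df_ok))
    d0 = 2.0 * trigamma_inverse(excess)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


class DifferentialExpression:
    """Two-group moderated-t model on a log2 expression matrix.

    Parameters
    ----------
    endog
        DataFrame of log2 densities, analytes as rows, observation columns.
    groups
        Sequence aligned with the columns, each entry ``case`` or
        ``control`` (other labels are rejected).
    """

    def __init__(self, endog: pd.DataFrame, groups, case: str = "ckd",
                 control: str = "control"):
        self.endog = pd.DataFrame(endog)
        groups = list(groups)
        if len(groups) != self.endog.shape[1]:
            raise ValueError("groups must align with matrix columns")
        unknown = set(groups) - {case, control}
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        self.case, self.control = case, control
        self.groups = np.array(groups)
        self.case_mask = self.groups == case
        self.control_mask = self.groups == control
        if self.case_mask.sum() == 0 or self.control_mask.sum() == 0:
            raise ValueError("each group needs at least one observation column")

    @classmethod
    def from_matrix(cls, matrix: ExpressionMatrix, case: str = "ckd",
                    control: str = "control", group_field: str = "group"):
        """Build from an annotated :class:`ExpressionMatrix` (scale log2)."""
        if matrix.scale != "log2":
            raise ValueError("moderated t expects a log2-scale matrix")
        groups = matrix.sample_info[group_field].tolist()
        return cls(matrix.values, groups, case=case, control=control)

    def fit(self, prior_df: float | None = None,
            prior_var: float | None = None) -> "DEResults":
        """Estimate the variance prior and compute moderated statistics.

        ``prior_df`` / ``prior_var`` override the estimated (d0, s0^2);
        ``prior_df=0`` reproduces the ordinary pooled-variance t exactly,
        ``prior_df=np.inf`` fully shrinks every variance to ``prior_var``.
        """
        vals = self.endog.to_numpy(float)
        n_analytes = vals.shape[0]
        mean_case = np.full(n_analytes, np.nan)
        mean_ctl = np.full(n_analytes, np.nan)
        s2 = np.full(n_analytes, np.nan)
        df_resid = np.zeros(n_analytes)
        n1_arr = np.zeros(n_analytes)
        n2_arr = np.zeros(n_analytes)
        for g in range(n_analytes):
            row = vals[g]
            x = row[self.case_mask]
            y = row[self.control_mask]
            x = x[~np.isnan(x)]
            y = y[~np.isnan(y)]
            n1, n2 = len(x), len(y)
            n1_arr[g], n2_arr[g] = n1, n2
            if n1 == 0 or n2 == 0:
                continue
            mean_case[g] = x.mean()
            mean_ctl[g] = y.mean()
            d = n1 + n2 - 2
            df_resid[g] = d
            if d > 0:
                s2[g] = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / d

        est_d0, est_s02 = estimate_variance_prior(s2[df_resid > 0], df_resid[df_resid > 0])
        d0 = est_d0 if prior_df is None else float(prior_df)
        s02 = est_s02 if prior_var is None else float(prior_var)

        with np.errstate(invalid="ignore", divide="ignore"):
            if np.isinf(d0):
                s2_post = np.full(n_analytes, s02)
                df_total = np.full(n_analytes, np.inf)
            elif d0 == 0:
                s2_post = s2.copy()
                df_total = df_resid.astype(float)
            else:
                s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
                df_total = d0 + df_resid
            log2fc = mean_case - mean_ctl
            se = np.sqrt(s2_post * (1.0 / n1_arr + 1.0 / n2_arr))
            t = log2fc / se
            p = np.where(
                np.isfinite(t) & (df_total > 0),
                2.0 * sps.t.sf(np.abs(t), np.where(df_total > 0, df_total, 1.0)),
                np.nan,
            )

        table = pd.DataFrame(
            {
                "mean_case_log2": mean_case,
                "mean_control_log2": mean_ctl,
                "log2_ratio": log2fc,
                "s2": s2,
                "df_resid": df_resid,
                "s2_post": s2_post,
                "df_total": df_total,
                "t": t,
                "p": p,
            },
            index=self.endog.index,
        )
        ok = np.isfinite(p)
        fdr = np.full(n_analytes, np.nan)
        if ok.any():
            fdr[ok] = bh_adjust(p[ok])
        table["fdr"] = fdr
        # linear-scale ratio of group means of the (normalized) densities
        lin = 2.0 ** vals
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lin_case = np.nanmean(lin[:, self.case_mask], axis=1)
            lin_ctl = np.nanmean(lin[:, self.control_mask], axis=1)
            table["ratio"] = lin_case / lin_ctl
        return DEResults(self, table, d0=d0, s02=s02,
                         d0_estimated=est_d0, s02_estimated=est_s02)


class DEResults:
    """Fitted moderated-t results: one row of statistics per analyte.

    Attributes
    ----------
    table
        DataFrame with per-analyte group means, log2 ratio, linear ratio,
        residual and posterior variances, moderated t, p and BH FDR.
    d0, s02
        Prior degrees of freedom and prior variance actually used.
    """

    def __init__(self, model, table: pd.DataFrame, d0: float, s02: float,
                 d0_estimated: float, s02_estimated: float):
        self.model = model
        self.table = table
        self.d0 = d0
        self.s02 = s02
        self.d0_estimated = d0_estimated
        self.s02_estimated = s02_estimated

    @property
    def pvalues(self) -> pd.Series:
        return self.table["p"]

    @property
    def fdr(self) -> pd.Series:
        return self.table["fdr"]

    def calls(self, detection_p: pd.DataFrame | None,
              criteria: DECriteria = DECriteria()) -> pd.DataFrame:
        """Apply the composite criteria; returns the full per-analyte table.

        ``detection_p`` holds one column of detection p-values per condition
        (any column names), indexed by analyte; an analyte passes the
        detection gate when any condition's p is below 0.05.  Analytes with
        missing statistics are flagged ``unevaluable`` and called ``ns``.
        """
        return call_differential(self, detection_p, criteria)

    def summary(self, top: int = 15) -> str:
        t = self.table
        called = t["call"].value_counts().to_dict() if "call" in t else {}
        lines = [
            "Moderated-t differential expression",
            "=" * 51,
            f"analytes: {len(t)}   case: {self.model.case_mask.sum()} obs   "
            f"control: {self.model.control_mask.sum()} obs",
            f"prior df (d0): {self.d0:.4g}   prior variance (s0^2): {self.s02:.4g}",
        ]
        if called:
            lines.append(
                "calls: " + ", ".join(f"{k}={v}" for k, v in sorted(called.items()))
            )
        lines.append("-" * 51)
        cols = ["ratio", "log2_ratio", "t", "p", "fdr"]
        if "call" in t:
            cols.append("call")
        show = t.sort_values("p").head(top)[cols]
        lines.append(show.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def call_differential(results: DEResults, detection_p: pd.DataFrame | None,
                      criteria: DECriteria = DECriteria()) -> pd.DataFrame:
    """Composite up/down/ns calls from moderated-t results + detection gate."""
    t = results.table
    n = len(t)
    ratio = t["ratio"].to_numpy(float)
    p = t["p"].to_numpy(float)
    fdr = t["fdr"].to_numpy(float)

    if detection_p is not None:
        det = detection_p.reindex(t.index)
        detected_any = (det < 0.05).any(axis=1).to_numpy()
        det_known = det.notna().any(axis=1).to_numpy()
    else:
        detected_any = np.ones(n, dtype=bool)
        det_known = np.ones(n, dtype=bool)

    have_stats = np.isfinite(ratio) & np.isfinite(p) & np.isfinite(fdr) & det_known
    gate = p < criteria.alpha_p
    gate &= fdr < criteria.alpha_fdr
    if criteria.require_detect_in_one_condition:
        gate &= detected_any
    up = have_stats & gate & (ratio > criteria.ratio_up)
    down = have_stats & gate & (ratio < criteria.ratio_down)

    call = np.where(up, "up", np.where(down, "down", "ns"))
    out = t.copy()
    out["call"] = call
    out["unevaluable"] = ~have_stats
    if detection_p is not None:
        for col in detection_p.columns:
            out[f"detect_p_{col}"] = detection_p[col].reindex(t.index)
    results.table = out
    return out
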