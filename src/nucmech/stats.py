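"""Population-level statistics of the single-cell tables.

Covers the binned summaries (geometric mean / IQR for positive quantities,
arithmetic mean ± SD for Poisson's ratio), the rational height law
h = a + b/(c + CSA) and its bounds, power laws [X] ∝ CSA^γ, the iterative
multiplicative global fit Y = Y0·Π(X/⟨X⟩)^α_X with backward elimination of
non-significant terms, the shared-exponent ANCOVA across treatment groups,
the linear chromatin-condensation/volume slope, axial circular statistics
of nucleus-versus-fibre orientation differences, and the binned
anisotropy/aspect-ratio slope.

All multiplicative fits run as ordinary least squares in log space; p-values
are standard linear-model t-tests with no multiple-testing correction.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .core import DomainError, FitError, axial_resultant, axial_sd_deg

log = logging.getLogger("nucmech")

P_RETAIN = 0.05
CONDITION_LIMIT = 1e6


@dataclasses.dataclass(frozen=True)
class RationalHeightFit:
    a: float
    b: float
    c: float
    h_isolated: float            # a + b/c, the CSA = 0 bound
    h_min: float                 # a, the CSA → ∞ bound
    compression_ratio_pct: float  # 100·h_min/h_isolated
    h_isolated_se: float = float("nan")
    h_min_se: float = float("nan")


@dataclasses.dataclass(frozen=True)
class PowerLawFit:
    gamma: float
    prefactor: float
    gamma_se: float
    p_value: float


@dataclasses.dataclass(frozen=True)
class GlobalFitResult:
    response_name: str
    y0: float
    alpha: dict
    se: dict
    p_values: dict
    eliminated: tuple
    n_used: int
    n_excluded_sign: int = 0


@dataclasses.dataclass(frozen=True)
class AncovaResult:
    shared_alpha: float
    shared_alpha_se: float
    intercepts: dict
    shared_resid_var: float
    pergroup_resid_var: float


@dataclasses.dataclass(frozen=True)
class CircularStats:
    mean_deg: float
    sd_deg: float
    resultant_length: float


@dataclasses.dataclass(frozen=True)
class LinearSlopeFit:
    slope: float
    intercept: float
    slope_se: float
    p_value: float


# --------------------------------------------------------------------------
# Binned summaries
# --------------------------------------------------------------------------

def binned_summary(table: pd.DataFrame, covariate: str,
                   value_cols: list[str] | None = None,
                   min_cells_per_bin: int = 50,
                   arithmetic_cols: tuple[str, ...] = ("nu",)
                   ) -> pd.DataFrame:
    """Equal-count bins along a covariate with per-bin summaries.

    Positive quantities get geometric mean plus Q1–Q3; columns named in
    ``arithmetic_cols`` (Poisson's ratio, which is negative) get arithmetic
    mean ± SD.
    """
    n = len(table)
    if n < 2 * min_cells_per_bin:
        raise DomainError("too few cells for two bins")
    if value_cols is None:
        value_cols = [c for c in table.columns
                      if c not in (covariate, "cell_id", "group")
                      and pd.api.types.is_numeric_dtype(table[c])]
    n_bins = n // min_cells_per_bin
    order = table.sort_values(covariate).reset_index(drop=True)
    rows = []
    for idx in np.array_split(np.arange(n), n_bins):
        chunk = order.iloc[idx]
        row = {covariate: float(np.exp(np.log(chunk[covariate]).mean()))
               if (chunk[covariate] > 0).all() else float(chunk[covariate].mean()),
               "n": len(chunk)}
        for col in value_cols:
            vals = chunk[col].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            if col in arithmetic_cols or (vals <= 0).any():
                row[f"{col}_mean"] = float(vals.mean())
                row[f"{col}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            else:
                row[f"{col}_gmean"] = float(np.exp(np.log(vals).mean()))
                row[f"{col}_q1"] = float(np.percentile(vals, 25))
                row[f"{col}_q3"] = float(np.percentile(vals, 75))
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Rational height law
# --------------------------------------------------------------------------

def fit_rational_height(table: pd.DataFrame, csa_col: str = "csa",
                        height_col: str = "height") -> RationalHeightFit:
    """Nonlinear least squares of h = a + b/(c + CSA), multi-start in c."""
    csa = table[csa_col].to_numpy(dtype=float)
    h = table[height_col].to_numpy(dtype=float)
    if len(csa) < 10:
        raise DomainError("need at least 10 cells")
    if csa.max() / csa.min() < 3.0:
        raise DomainError("CSA must span at least a 3x range")

    def model(x, a, b, c):
        return a + b / (c + x)

    best = None
    for c0 in (1e2, 1e3, 1e4):
        b0 = (h.max() - h.min()) * (c0 + np.median(csa))
        try:
            popt, pcov = optimize.curve_fit(
                model, csa, h, p0=(h.min(), b0, c0),
                bounds=([0.0, 0.0, 1e-6], [np.inf] * 3), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(((model(csa, *popt) - h) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        raise FitError("rational height fit failed from all starts")
    a, b, c = (float(v) for v in best[1])
    h_iso = a + b / c
    # delta-method SE of the CSA = 0 bound a + b/c
    grad = np.array([1.0, 1.0 / c, -b / c ** 2])
    h_iso_var = float(grad @ best[2] @ grad)
    return RationalHeightFit(a=a, b=b, c=c, h_isolated=h_iso, h_min=a,
                             compression_ratio_pct=100.0 * a / h_iso,
                             h_isolated_se=math.sqrt(max(h_iso_var, 0.0)),
                             h_min_se=math.sqrt(max(float(best[2][0, 0]), 0.0)))


# --------------------------------------------------------------------------
# Power laws and linear slopes
# --------------------------------------------------------------------------

def fit_power_law(table: pd.DataFrame, x: str, y: str) -> PowerLawFit:
    """OLS of ln y on ln x; gamma is the slope (null: slope = 0)."""
    xv = table[x].to_numpy(dtype=float)
    yv = table[y].to_numpy(dtype=float)
    bad = np.nonzero((xv <= 0) | (yv <= 0) | ~np.isfinite(xv) | ~np.isfinite(yv))[0]
    if bad.size:
        raise DomainError(f"non-positive values in rows {bad[:10].tolist()}")
    design = sm.add_constant(np.log(xv))
    res = sm.OLS(np.log(yv), design).fit()
    return PowerLawFit(gamma=float(res.params[1]),
                       prefactor=float(math.exp(res.params[0])),
                       gamma_se=float(res.bse[1]),
                       p_value=float(res.pvalues[1]))


def cc_volume_slope(table: pd.DataFrame, cc_col: str = "cc",
                    volume_col: str = "volume") -> LinearSlopeFit:
    """OLS slope of chromatin condensation on nuclear volume."""
    v = table[volume_col].to_numpy(dtype=float)
    cc = table[cc_col].to_numpy(dtype=float)
    if len(v) < 10:
        raise DomainError("need at least 10 cells")
    if np.ptp(v) == 0:
        raise DomainError("degenerate volume variance")
    res = sm.OLS(cc, sm.add_constant(v)).fit()
    return LinearSlopeFit(slope=float(res.params[1]),
                          intercept=float(res.params[0]),
                          slope_se=float(res.bse[1]),
                          p_value=float(res.pvalues[1]))


# --------------------------------------------------------------------------
# Iterative multiplicative global fit
# --------------------------------------------------------------------------

def _signed_log_response(y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Log-transform a response that may be all-negative (Poisson's ratio).

    Majority sign wins; minority-sign rows are excluded with a count."""
    neg = y < 0
    if neg.all():
        return np.log(-y), -1.0, 0
    if (~neg & (y > 0)).all():
        return np.log(y), 1.0, 0
    sign = -1.0 if neg.mean() > 0.5 else 1.0
    keep = neg if sign < 0 else (y > 0)
    return np.log(sign * y[keep]), sign, int((~keep).sum())


def global_fit(table: pd.DataFrame, response: str,
               predictors: tuple[str, ...] = ("actin", "myosin", "tubulin",
                                              "vimentin"),
               p_retain: float = P_RETAIN) -> GlobalFitResult:
    """Fit Y = Y0·Π(X/⟨X⟩)^α_X in log space with backward elimination.

    Predictors are median-centred (divided by their population median) so
    the intercept back-transforms directly to the prefactor.  One term —
    the one with the largest p ≥ ``p_retain`` — is removed per iteration
    until every retained exponent is significant; eliminating everything is
    a valid outcome, in which case Y0 is the geometric mean of the response.
    """
    predictors = tuple(predictors)
    if len(table) < 10 * max(len(predictors), 1):
        raise DomainError("need at least 10 rows per predictor")
    yraw = table[response].to_numpy(dtype=float)
    neg = yraw < 0
    sign = -1.0 if neg.mean() > 0.5 else 1.0
    keep = neg if sign < 0 else yraw > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        log.info("global_fit(%s): excluded %d rows with sign opposite the "
                 "majority", response, n_excluded)
    ylog = np.log(sign * yraw[keep])

    cols = {}
    for p in predictors:
        x = table[p].to_numpy(dtype=float)[keep]
        if (x <= 0).any():
            raise DomainError(f"non-positive values in predictor {p!r}")
        cols[p] = np.log(x / np.median(x))
    design_full = np.column_stack([cols[p] for p in predictors])
    if len(predictors) > 1 and np.linalg.cond(design_full) > CONDITION_LIMIT:
        worst = max(combinations(range(len(predictors)), 2),
                    key=lambda ij: abs(np.corrcoef(design_full[:, ij[0]],
                                                   design_full[:, ij[1]])[0, 1]))
        raise DomainError("collinear predictors: "
                          f"{predictors[worst[0]]!r} and {predictors[worst[1]]!r}")

    retained = list(predictors)
    eliminated: list[str] = []
    while True:
        design = sm.add_constant(
            np.column_stack([cols[p] for p in retained])
            if retained else np.empty((ylog.size, 0)))
        res = sm.OLS(ylog, design).fit()
        if not retained:
            break
        pvals = dict(zip(retained, res.pvalues[1:]))
        # a numerically-zero coefficient in an exact fit is noise, not signal
        for i, p in enumerate(retained):
            if abs(res.params[1 + i]) < 1e-10:
                pvals[p] = 1.0
        worst_p = max(pvals, key=pvals.get)
        if pvals[worst_p] < p_retain:
            break
        retained.remove(worst_p)
        eliminated.append(worst_p)

    alpha = {p: float(res.params[1 + i]) for i, p in enumerate(retained)}
    se = {p: float(res.bse[1 + i]) for i, p in enumerate(retained)}
    pv = {p: float(res.pvalues[1 + i]) for i, p in enumerate(retained)}
    return GlobalFitResult(response_name=response,
                           y0=float(sign * math.exp(res.params[0])),
                           alpha=alpha, se=se, p_values=pv,
                           eliminated=tuple(eliminated), n_used=int(ylog.size),
                           n_excluded_sign=n_excluded)


# --------------------------------------------------------------------------
# Shared-exponent ANCOVA
# --------------------------------------------------------------------------

def ancova_shared_exponent(table: pd.DataFrame, response: str,
                           group_col: str = "group",
                           covariate: str = "csa") -> AncovaResult:
    """Log-linear model with one exponent shared across groups and a
    per-group prefactor, Y = Y0(g)·(X/⟨X⟩)^α.

    The per-group residual variance from separate slopes is reported
    alongside the shared-slope residual variance as a pooling diagnostic.
    """
    groups = list(table[group_col].unique())
    if len(groups) < 2:
        log.warning("single group: falling back to a plain power-law fit")
        pl = fit_power_law(table, covariate, response)
        return AncovaResult(shared_alpha=pl.gamma, shared_alpha_se=pl.gamma_se,
                            intercepts={groups[0]: pl.prefactor},
                            shared_resid_var=float("nan"),
                            pergroup_resid_var=float("nan"))
    for g in groups:
        if (table[group_col] == g).sum() < 10:
            raise DomainError(f"group {g!r} has fewer than 10 cells")

    y, sign, _ = _signed_log_response(table[response].to_numpy(dtype=float))
    mask = (table[response] * sign > 0).to_numpy()
    sub = table[mask]
    x = sub[covariate].to_numpy(dtype=float)
    if (x <= 0).any():
        raise DomainError("non-positive covariate")
    lx = np.log(x / np.median(x))
    dummies = pd.get_dummies(sub[group_col]).to_numpy(dtype=float)
    design = np.column_stack([dummies, lx])  # no global intercept
    res = sm.OLS(y, design).fit()
    labels = list(pd.get_dummies(sub[group_col]).columns)
    intercepts = {g: float(sign * math.exp(res.params[i]))
                  for i, g in enumerate(labels)}

    pergroup_rss, pergroup_df = 0.0, 0
    for g in labels:
        sel = (sub[group_col] == g).to_numpy()
        r = sm.OLS(y[sel], sm.add_constant(lx[sel])).fit()
        pergroup_rss += float(r.ssr)
        pergroup_df += int(r.df_resid)
    return AncovaResult(shared_alpha=float(res.params[-1]),
                        shared_alpha_se=float(res.bse[-1]),
                        intercepts=intercepts,
                        shared_resid_var=float(res.ssr / res.df_resid),
                        pergroup_resid_var=pergroup_rss / max(pergroup_df, 1))


# --------------------------------------------------------------------------
# Orientation statistics
# --------------------------------------------------------------------------

def axial_circular_stats(angles_deg) -> CircularStats:
    """Axial circular mean and SD of orientation differences (doubled-angle
    arithmetic; SD = sqrt(−2 ln R)/2 mapped back to degrees).  The mean is
    reported in (−90, 90]."""
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise DomainError("empty angle list")
    r, mean = axial_resultant(angles)
    if mean > 90.0:
        mean -= 180.0
    return CircularStats(mean_deg=mean, sd_deg=axial_sd_deg(r),
                         resultant_length=r)


def anisotropy_aspect_slope(table: pd.DataFrame,
                            anisotropy_col: str = "anisotropy",
                            aspect_col: str = "aspect_ratio_xy",
                            min_cells_per_bin: int = 15) -> LinearSlopeFit:
    """Slope of nuclear in-plane aspect ratio on fibre anisotropy, fitted on
    equal-count bin means."""
    sub = table[[anisotropy_col, aspect_col]].dropna()
    if len(sub) < 10:
        raise DomainError("need at least 10 cells")
    n_bins = max(len(sub) // min_cells_per_bin, 2)
    order = sub.sort_values(anisotropy_col).reset_index(drop=True)
    xm, ym = [], []
    for idx in np.array_split(np.arange(len(order)), n_bins):
        chunk = order.iloc[idx]
        xm.append(float(chunk[anisotropy_col].mean()))
        ym.append(float(chunk[aspect_col].mean()))
    res = sm.OLS(np.asarray(ym), sm.add_constant(np.asarray(xm))).fit()
    return LinearSlopeFit(slope=float(res.params[1]),
                          intercept=float(res.params[0]),
                          slope_se=float(res.bse[1]),
                          p_value=float(res.pvalues[1]))
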