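"""Between-device agreement statistics.

Bland-Altman analysis of per-session HR means (bias = mean of test - reference
differences; limits of agreement = bias +/- 1.96 SD of the differences),
per-participant and cohort-level, plus least-squares fits of four candidate
relationships between the devices — linear, logarithmic, negative
exponential and four-parameter sigmoid — ranked by the Gaussian
least-squares Akaike information criterion AIC = n ln(RSS/n) + 2k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "BlandAltmanResult",
    "ModelFit",
    "bland_altman",
    "per_participant_agreement",
    "overall_bias",
    "aic",
    "linear_fit",
    "fit_family",
    "fit_all_families",
    "select_model",
    "predict",
    "MODEL_FAMILIES",
    "LOA_Z",
]

#: Normal quantile used for the limits of agreement (central 95%).
LOA_Z = 1.96

MODEL_FAMILIES = ("linear", "logarithmic", "negative_exponential", "sigmoid")

#: Number of curve parameters per family (error variance excluded: constant
#: offsets in k cancel in within-dataset AIC comparisons, the only use here).
FAMILY_K = {
    "linear": 2,
    "logarithmic": 2,
    "negative_exponential": 3,
    "sigmoid": 4,
}

# Physiological bpm bounds preventing degenerate sigmoid flips.
SIGMOID_BOUNDS = ([0.0, 80.0, -1000.0, 1e-3], [120.0, 260.0, 2000.0, 2000.0])


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland-Altman bias and limits of agreement (test - reference, bpm)."""

    condition: str
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float


@dataclass
class ModelFit:
    family: str
    params: np.ndarray
    param_names: tuple[str, ...]
    rss: float
    n: int
    k: int
    aic: float
    r_squared: float | None = None
    success: bool = True
    message: str = ""
    x_range: tuple[float, float] = (np.nan, np.nan)


def bland_altman(
    test: np.ndarray, reference: np.ndarray, condition: str = ""
) -> BlandAltmanResult:
    """Bland-Altman statistics for paired per-session means.

    Differences are test - reference; the SD uses the n-1 denominator and
    the limits of agreement are mean +/- 1.96 SD.
    """
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if test.shape != reference.shape:
        raise ValueError("test and reference must be paired (equal length)")
    ok = np.isfinite(test) & np.isfinite(reference)
    d = test[ok] - reference[ok]
    if d.size < 2:
        raise ValueError(f"Bland-Altman needs >= 2 pairs, got {d.size}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        condition=condition,
        n=int(d.size),
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - LOA_Z * sd,
        loa_high=mean + LOA_Z * sd,
    )


_CONDITION_COLUMNS = {
    "baseline": ("baseline_test", "baseline_ref"),
    "high_intensity": ("peak20_test", "peak20_ref"),
}


def per_participant_agreement(
    summaries: pd.DataFrame, condition: str
) -> pd.DataFrame:
    """One Bland-Altman row per participant for one condition.

    Participants with fewer than 2 usable sessions in the condition are
    reported with their n and NaN statistics rather than dropped.
    """
    tcol, rcol = _condition_columns(condition)
    rows = []
    for pid, grp in summaries.groupby("participant_id", sort=True):
        ok = grp[[tcol, rcol]].notna().all(axis=1)
        n = int(ok.sum())
        if n >= 2:
            ba = bland_altman(
                grp.loc[ok, tcol].to_numpy(),
                grp.loc[ok, rcol].to_numpy(),
                condition,
            )
            rows.append(
                {
                    "participant_id": pid,
                    "n": ba.n,
                    "mean_diff": ba.mean_diff,
                    "sd_diff": ba.sd_diff,
                    "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high,
                }
            )
        else:
            rows.append(
                {
                    "participant_id": pid,
                    "n": n,
                    "mean_diff": np.nan,
                    "sd_diff": np.nan,
                    "loa_low": np.nan,
                    "loa_high": np.nan,
                }
            )
    return pd.DataFrame(rows)


def _condition_columns(condition: str) -> tuple[str, str]:
    try:
        return _CONDITION_COLUMNS[condition]
    except KeyError:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of "
            f"{sorted(_CONDITION_COLUMNS)}"
        ) from None


def cohort_bland_altman(summaries: pd.DataFrame, condition: str) -> BlandAltmanResult:
    """Cohort-level Bland-Altman for one condition of the summary table."""
    tcol, rcol = _condition_columns(condition)
    return bland_altman(
        summaries[tcol].to_numpy(), summaries[rcol].to_numpy(), condition
    )


def overall_bias(baseline: BlandAltmanResult | float, high: BlandAltmanResult | float) -> float:
    """Mean device bias: average of the baseline and high-intensity mean
    differences."""
    b = baseline.mean_diff if isinstance(baseline, BlandAltmanResult) else float(baseline)
    h = high.mean_diff if isinstance(high, BlandAltmanResult) else float(high)
    return (b + h) / 2.0


# ---------------------------------------------------------------------------
# Model families
# ---------------------------------------------------------------------------

def aic(rss: float, n: int, k: int) -> float:
    """Gaussian least-squares AIC: n ln(max(RSS, eps)/n) + 2k."""
    if n <= 0 or k < 1:
        raise ValueError("aic requires n > 0 and k >= 1")
    return n * np.log(max(rss, 1e-12) / n) + 2 * k


def _sigmoid(x, a, b, c, d):
    return a + (b - a) / (1.0 + np.exp(-(x - c) / d))


def _neg_exponential(x, alpha, beta, gamma):
    return alpha - beta * np.exp(-gamma * x)


def linear_fit(x: np.ndarray, y: np.ndarray) -> ModelFit:
    """Ordinary least squares y = alpha + beta x with R^2 = 1 - RSS/TSS.

    Convention throughout: the reference device on the abscissa, the test
    device on the ordinate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("linear fit needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("reference values have zero variance")
    beta, alpha = np.polyfit(x, y, 1)
    resid = y - (alpha + beta * x)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return ModelFit(
        family="linear",
        params=np.array([alpha, beta]),
        param_names=("intercept", "slope"),
        rss=rss,
        n=x.size,
        k=FAMILY_K["linear"],
        aic=aic(rss, x.size, FAMILY_K["linear"]),
        r_squared=r2,
        x_range=(float(x.min()), float(x.max())),
    )


def _fit_logarithmic(x: np.ndarray, y: np.ndarray) -> ModelFit:
    if np.any(x <= 0):
        raise ValueError("logarithmic family requires all reference values > 0")
    lx = np.log(x)
    beta, alpha = np.polyfit(lx, y, 1)
    resid = y - (alpha + beta * lx)
    rss = float(resid @ resid)
    return ModelFit(
        family="logarithmic",
        params=np.array([alpha, beta]),
        param_names=("alpha", "beta"),
        rss=rss,
        n=x.size,
        k=FAMILY_K["logarithmic"],
        aic=aic(rss, x.size, FAMILY_K["logarithmic"]),
        x_range=(float(x.min()), float(x.max())),
    )


def _multistart_curve_fit(
    f, x, y, starts, bounds, names, family
) -> ModelFit:
    """Deterministic multi-start nonlinear least squares; keeps the best
    converged start by RSS."""
    best = None
    last_err = "no start converged"
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    f, x, y, p0=p0, bounds=bounds, maxfev=20000
                )
            resid = y - f(x, *popt)
            rss = float(resid @ resid)
            if best is None or rss < best[1]:
                best = (popt, rss)
        except (RuntimeError, ValueError) as exc:
            last_err = str(exc)
    k = FAMILY_K[family]
    if best is None:
        return ModelFit(
            family=family,
            params=np.full(len(names), np.nan),
            param_names=names,
            rss=np.inf,
            n=x.size,
            k=k,
            aic=np.inf,
            success=False,
            message=last_err,
            x_range=(float(x.min()), float(x.max())),
        )
    popt, rss = best
    return ModelFit(
        family=family,
        params=np.asarray(popt),
        param_names=names,
        rss=rss,
        n=x.size,
        k=k,
        aic=aic(rss, x.size, k),
        x_range=(float(x.min()), float(x.max())),
    )


def _sigmoid_starts(x: np.ndarray, y: np.ndarray) -> list[list[float]]:
    lo, hi = SIGMOID_BOUNDS
    rng_x = max(np.ptp(x), 1e-6)
    a0 = float(np.clip(y.min(), lo[0], hi[0]))
    b0 = float(np.clip(y.max(), lo[1], hi[1]))
    starts = [
        [a0, b0, float(np.percentile(x, q)), dv]
        for q in (25, 50, 75)
        for dv in (rng_x / 10.0, rng_x / 4.0)
    ]
    # Linear-mimic start so a near-linear relationship is reachable.
    slope, intercept = np.polyfit(x, y, 1)
    d0 = rng_x / 2.0
    c0 = float(np.median(x))
    half = 2.0 * d0 * slope
    a_lin = float(np.clip(intercept + slope * c0 - half, lo[0], hi[0]))
    b_lin = float(np.clip(intercept + slope * c0 + half, lo[1], hi[1]))
    starts.append([a_lin, b_lin, c0, d0])
    return starts


def fit_family(x: np.ndarray, y: np.ndarray, family: str) -> ModelFit:
    """Least-squares fit of one candidate family, test = f(reference).

    Families: linear ``alpha + beta x`` (k=2), logarithmic
    ``alpha + beta ln x`` (k=2), negative exponential
    ``alpha - beta exp(-gamma x)`` (k=3, gamma > 0) and sigmoid
    ``a + (b - a)/(1 + exp(-(x - c)/d))`` (k=4, d > 0). Nonlinear
    families use deterministic multi-start initialization; a family whose
    starts all fail to converge is returned with ``success=False`` and
    infinite AIC so model selection skips it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    k = FAMILY_K.get(family)
    if k is None:
        raise ValueError(f"unknown model family {family!r}")
    if x.size <= k:
        raise ValueError(f"{family} fit needs more than {k} points")

    if family == "linear":
        return linear_fit(x, y)
    if family == "logarithmic":
        return _fit_logarithmic(x, y)
    if family == "negative_exponential":
        rng_x = max(np.ptp(x), 1e-6)
        alpha0 = float(y.max())
        starts = [
            [alpha0, max(alpha0 - y.min(), 1.0) * np.exp(g * x.min()), g]
            for g in (0.5 / rng_x, 2.0 / rng_x, 8.0 / rng_x)
        ]
        bounds = ([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf])
        return _multistart_curve_fit(
            _neg_exponential, x, y, starts, bounds,
            ("alpha", "beta", "gamma"), family,
        )
    return _multistart_curve_fit(
        _sigmoid, x, y, _sigmoid_starts(x, y), SIGMOID_BOUNDS,
        ("a", "b", "c", "d"), family,
    )


def fit_all_families(x: np.ndarray, y: np.ndarray) -> dict[str, ModelFit]:
    """Fit every candidate family; families whose preconditions fail are
    reported as unsuccessful fits rather than raising."""
    fits: dict[str, ModelFit] = {}
    for family in MODEL_FAMILIES:
        try:
            fits[family] = fit_family(x, y, family)
        except ValueError as exc:
            x_arr = np.asarray(x, dtype=float)
            fits[family] = ModelFit(
                family=family,
                params=np.array([]),
                param_names=(),
                rss=np.inf,
                n=int(np.isfinite(x_arr).sum()),
                k=FAMILY_K[family],
                aic=np.inf,
                success=False,
                message=str(exc),
            )
    return fits


def select_model(fits: dict[str, ModelFit] | list[ModelFit]) -> str:
    """Family with minimal AIC among successful fits; ties go to smaller k."""
    pool = list(fits.values()) if isinstance(fits, dict) else list(fits)
    ok = [f for f in pool if f.success and np.isfinite(f.aic)]
    if not ok:
        raise ValueError("no successful model fit to select from")
    best = min(ok, key=lambda f: (f.aic, f.k))
    return best.family


def predict(fit: ModelFit, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a fitted family at ``x``.

    Returns ``(yhat, extrapolated)`` where ``extrapolated`` flags points
    outside the reference range seen during fitting — the fitted
    relationship should not be trusted there.
    """
    if not fit.success:
        raise ValueError(f"cannot predict from failed {fit.family} fit")
    x = np.asarray(x, dtype=float)
    p = fit.params
    if fit.family == "linear":
        yhat = p[0] + p[1] * x
    elif fit.family == "logarithmic":
        yhat = p[0] + p[1] * np.log(x)
    elif fit.family == "negative_exponential":
        yhat = _neg_exponential(x, *p)
    elif fit.family == "sigmoid":
        yhat = _sigmoid(x, *p)
    else:
        raise ValueError(f"unknown model family {fit.family!r}")
    lo, hi = fit.x_range
    extrapolated = (x < lo) | (x > hi)
    return yhat, extrapolated
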