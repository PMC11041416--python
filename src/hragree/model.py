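"""Statsmodels-style front end: a DeviceAgreement model over a cohort of
session summaries, whose fit() returns a results object bundling the
Bland-Altman estimates, model-family comparison, classification
diagnostics and ROC/AUC, with a text summary() and plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import agreement as agr
from . import diagnostics as diag
from .features import summarize_cohort
from .series import PairedMinuteSession

__all__ = ["DeviceAgreement", "DeviceAgreementResults"]

SUMMARY_COLUMNS = [
    "session_id",
    "participant_id",
    "age",
    "baseline_test",
    "baseline_ref",
    "peak20_test",
    "peak20_ref",
    "hr_th_max",
]


class DeviceAgreement:
    """Device-agreement model over per-session paired HR summaries.

    Parameters
    ----------
    summaries : pandas.DataFrame
        One row per session with columns ``session_id, participant_id,
        age, baseline_test, baseline_ref, peak20_test, peak20_ref``
        (``hr_th_max`` is derived if absent). Baselines may be NaN for
        sessions whose rest period was incomplete; such sessions still
        contribute to the high-intensity analyses.

    Examples
    --------
    >>> model = DeviceAgreement.from_sessions(paired_sessions)  # doctest: +SKIP
    >>> res = model.fit(thresholds=(0.70, 0.85))                # doctest: +SKIP
    >>> print(res.summary())                                    # doctest: +SKIP
    """

    def __init__(self, summaries: pd.DataFrame):
        df = summaries.copy()
        missing = [
            c for c in SUMMARY_COLUMNS if c not in df.columns and c != "hr_th_max"
        ]
        if missing:
            raise ValueError(f"summary table is missing columns {missing}")
        if "hr_th_max" not in df.columns:
            df["hr_th_max"] = 220.0 - df["age"].astype(float)
        if len(df) == 0:
            raise ValueError("summary table is empty")
        self.summaries = df.reset_index(drop=True)

    @classmethod
    def from_sessions(
        cls,
        sessions: Sequence[PairedMinuteSession],
        exclusions: list | None = None,
    ) -> "DeviceAgreement":
        """Build the model from aligned per-minute sessions (computes the
        baseline / peak-20 summaries first). Sessions lacking a gap-free
        20-minute window are dropped and recorded in ``exclusions``."""
        if not sessions:
            raise ValueError("no paired sessions supplied")
        return cls(summarize_cohort(list(sessions), exclusions))

    @classmethod
    def from_summary_csv(cls, path: str | Path) -> "DeviceAgreement":
        return cls(pd.read_csv(path))

    def fit(
        self,
        thresholds: Sequence[float] = (0.70, 0.85),
        p_grid: Sequence[float] | None = None,
    ) -> "DeviceAgreementResults":
        """Run the full agreement analysis.

        Bland-Altman per condition and per participant, OLS R^2 per
        condition, the four-family fit ranked by AIC on the pooled
        (baseline + high-intensity) session means, confusion metrics at
        each threshold fraction, and the threshold-swept ROC with AUC.
        """
        df = self.summaries
        ba_high = agr.cohort_bland_altman(df, "high_intensity")
        have_base = df[["baseline_test", "baseline_ref"]].notna().all(axis=1)
        ba_base = (
            agr.cohort_bland_altman(df[have_base], "baseline")
            if have_base.sum() >= 2
            else None
        )
        per_part = {
            cond: agr.per_participant_agreement(df, cond)
            for cond in ("baseline", "high_intensity")
        }
        bias = (
            agr.overall_bias(ba_base, ba_high) if ba_base is not None else None
        )

        lin = {}
        for cond, (tcol, rcol) in (
            ("baseline", ("baseline_test", "baseline_ref")),
            ("high_intensity", ("peak20_test", "peak20_ref")),
        ):
            sub = df[[rcol, tcol]].dropna()
            if len(sub) >= 3 and np.ptp(sub[rcol].to_numpy()) > 0:
                lin[cond] = agr.linear_fit(
                    sub[rcol].to_numpy(), sub[tcol].to_numpy()
                )

        # Pool baseline and high-intensity session means into one dataset.
        x = np.concatenate(
            [df.loc[have_base, "baseline_ref"].to_numpy(), df["peak20_ref"].to_numpy()]
        )
        y = np.concatenate(
            [df.loc[have_base, "baseline_test"].to_numpy(), df["peak20_test"].to_numpy()]
        )
        fits = agr.fit_all_families(x, y)
        selected = agr.select_model(fits)

        confusion = {}
        for p in thresholds:
            counts, metrics = diag.confusion_at_threshold(df, float(p))
            confusion[float(p)] = (counts, metrics)
        roc = diag.roc_sweep(df, p_grid)

        return DeviceAgreementResults(
            model=self,
            n_sessions=len(df),
            n_baseline=int(have_base.sum()),
            ba_baseline=ba_base,
            ba_high=ba_high,
            per_participant=per_part,
            overall_bias=bias,
            linear_fits=lin,
            model_fits=fits,
            selected_family=selected,
            confusion=confusion,
            roc=roc,
        )


@dataclass
class DeviceAgreementResults:
    """Fitted agreement results; see :meth:`summary` for a text report."""

    model: DeviceAgreement
    n_sessions: int
    n_baseline: int
    ba_baseline: agr.BlandAltmanResult | None
    ba_high: agr.BlandAltmanResult
    per_participant: dict[str, pd.DataFrame]
    overall_bias: float | None
    linear_fits: dict[str, agr.ModelFit]
    model_fits: dict[str, agr.ModelFit]
    selected_family: str
    confusion: dict[float, tuple[diag.ConfusionCounts, diag.ConfusionMetrics]]
    roc: diag.RocCurve

    # -- tabular views -----------------------------------------------------

    def model_comparison(self) -> pd.DataFrame:
        rows = []
        for fam, fit in self.model_fits.items():
            rows.append(
                {
                    "family": fam,
                    "k": fit.k,
                    "n": fit.n,
                    "rss": fit.rss,
                    "aic": fit.aic,
                    "success": fit.success,
                    "selected": fam == self.selected_family,
                }
            )
        return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)

    def bland_altman_table(self) -> pd.DataFrame:
        rows = []
        for ba in (self.ba_baseline, self.ba_high):
            if ba is None:
                continue
            rows.append(
                {
                    "condition": ba.condition,
                    "n": ba.n,
                    "mean_diff": ba.mean_diff,
                    "sd_diff": ba.sd_diff,
                    "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high,
                }
            )
        return pd.DataFrame(rows)

    def confusion_table(self) -> pd.DataFrame:
        rows = []
        for p, (c, m) in sorted(self.confusion.items()):
            rows.append(
                {
                    "threshold": p,
                    "tp": c.tp,
                    "fp": c.fp,
                    "tn": c.tn,
                    "fn": c.fn,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "ppv": m.ppv,
                    "npv": m.npv,
                }
            )
        return pd.DataFrame(rows)

    # -- report ------------------------------------------------------------

    def summary(self) -> str:
        """Human-readable report of every fitted quantity."""
        L: list[str] = []
        L.append("Device agreement analysis (test vs reference HR)")
        L.append("=" * 56)
        L.append(f"Sessions analysed: {self.n_sessions} "
                 f"(with complete baseline: {self.n_baseline})")
        L.append("")
        L.append("Bland-Altman (test - reference, bpm)")
        for ba in (self.ba_baseline, self.ba_high):
            if ba is None:
                L.append("  baseline        : unavailable (<2 complete baselines)")
                continue
            L.append(
                f"  {ba.condition:<16}: bias {ba.mean_diff:+.2f}  "
                f"SD {ba.sd_diff:.2f}  LoA [{ba.loa_low:.2f}, {ba.loa_high:.2f}]"
                f"  (n={ba.n})"
            )
        if self.overall_bias is not None:
            L.append(f"  overall mean bias: {self.overall_bias:+.2f} bpm")
        L.append("")
        for cond, fit in self.linear_fits.items():
            L.append(
                f"Linear fit ({cond}): slope {fit.params[1]:.3f}, "
                f"intercept {fit.params[0]:.1f}, R^2 = {fit.r_squared:.3f}"
            )
        L.append("")
        L.append("Model comparison on pooled session means (AIC, lower is better)")
        for _, row in self.model_comparison().iterrows():
            tag = "  <- selected" if row["selected"] else ""
            status = "" if row["success"] else "  [failed]"
            aic_s = f"{row['aic']:.1f}" if np.isfinite(row["aic"]) else "inf"
            L.append(
                f"  {row['family']:<20} k={row['k']}  AIC={aic_s}{status}{tag}"
            )
        L.append("")
        L.append("High-intensity classification (reference = gold standard)")
        for p, (c, m) in sorted(self.confusion.items()):
            L.append(
                f"  p={p:.2f}: TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn}  "
                f"sens={_pct(m.sensitivity)} spec={_pct(m.specificity)} "
                f"ppv={_pct(m.ppv)} npv={_pct(m.npv)}"
            )
        L.append(f"  ROC AUC (joint threshold sweep): {self.roc.auc:.3f}")
        return "\n".join(L)

    # -- plotting ----------------------------------------------------------

    def plot_bland_altman(self, ax=None):
        """Bland-Altman scatter (mean vs difference) per condition."""
        import matplotlib.pyplot as plt

        df = self.model.summaries
        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        panels = [
            ("baseline", "baseline_test", "baseline_ref", self.ba_baseline),
            ("high intensity", "peak20_test", "peak20_ref", self.ba_high),
        ]
        for a, (title, tcol, rcol, ba) in zip(np.ravel(ax), panels):
            sub = df[[tcol, rcol]].dropna()
            mean = (sub[tcol] + sub[rcol]) / 2
            diff = sub[tcol] - sub[rcol]
            a.scatter(mean, diff, s=8, alpha=0.5)
            if ba is not None:
                a.axhline(ba.mean_diff, color="k")
                a.axhline(ba.loa_low, color="k", linestyle="--")
                a.axhline(ba.loa_high, color="k", linestyle="--")
            a.set_title(title)
            a.set_xlabel("mean HR (bpm)")
        np.ravel(ax)[0].set_ylabel("test - reference (bpm)")
        return ax

    def plot_model_fits(self, ax=None):
        """Pooled session means with each fitted family overlaid."""
        import matplotlib.pyplot as plt

        df = self.model.summaries
        x = np.concatenate([df["baseline_ref"].dropna(), df["peak20_ref"]])
        y = np.concatenate([df["baseline_test"].dropna(), df["peak20_test"]])
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(x, y, s=8, alpha=0.4, label="sessions")
        grid = np.linspace(np.nanmin(x), np.nanmax(x), 200)
        for fam, fit in self.model_fits.items():
            if not fit.success:
                continue
            yhat, _ = agr.predict(fit, grid)
            style = "-" if fam == self.selected_family else "--"
            ax.plot(grid, yhat, style, label=f"{fam} (AIC {fit.aic:.0f})")
        ax.set_xlabel("reference HR (bpm)")
        ax.set_ylabel("test HR (bpm)")
        ax.legend(fontsize=8)
        return ax

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc.fpr, self.roc.tpr, marker=".")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"AUC = {self.roc.auc:.3f}")
        return ax


def _pct(x: float) -> str:
    return "undef" if np.isnan(x) else f"{100 * x:.1f}%"
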