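"""Report assembly, display rounding and the annotated ROC plot.

Estimates are stored at full precision and rounded only here, at the
presentation boundary: three decimals, half-up (so 0.80556 renders as
0.806), with missing values rendered as the text "NA".
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import pandas as pd

from dxeval.metrics import AnalysisConfig, Estimate
from dxeval.roc import AUCResult, CutoffResult, ROCCurve, SensitivityBand

__all__ = [
    "METRIC_ORDER",
    "MetricsReport",
    "round_for_display",
    "auc_label",
    "render_roc_plot",
]

#: fixed order of the indicator table
METRIC_ORDER = (
    "Sensitivity",
    "Specificity",
    "Accuracy",
    "PPV",
    "NPV",
    "LR+",
    "LR-",
    "Youden index",
    "AUC",
)


def round_for_display(x: Optional[float], decimals: int = 3) -> str:
    """Half-up decimal rounding to fixed width; missing renders as "NA"."""
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    if x is None or (isinstance(x, float) and x != x):
        return "NA"
    quantum = decimal.Decimal(1).scaleb(-decimals)
    d = decimal.Decimal(repr(float(x))).quantize(
        quantum, rounding=decimal.ROUND_HALF_UP
    )
    return str(d)


@dataclass
class MetricsReport:
    """Ordered table of named estimates plus the configuration that produced them."""

    entries: dict[str, Estimate]
    config: Optional[AnalysisConfig] = None
    cutoff: Optional[CutoffResult] = None

    @classmethod
    def from_estimates(
        cls,
        estimates: Sequence[Estimate],
        config: Optional[AnalysisConfig] = None,
        cutoff: Optional[CutoffResult] = None,
    ) -> "MetricsReport":
        entries = {e.label: e for e in estimates}
        unknown = set(entries) - set(METRIC_ORDER)
        if unknown:
            raise ValueError(f"unknown metric labels: {sorted(unknown)}")
        ordered = {k: entries[k] for k in METRIC_ORDER if k in entries}
        return cls(entries=ordered, config=config, cutoff=cutoff)

    def __iter__(self) -> Iterator[Estimate]:
        return iter(self.entries.values())

    def __getitem__(self, label: str) -> Estimate:
        return self.entries[label]

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def with_auc(self, auc_result: AUCResult) -> "MetricsReport":
        """Return a copy with the AUC estimate appended."""
        est = Estimate("AUC", auc_result.auc, auc_result.lower, auc_result.upper)
        return MetricsReport.from_estimates(
            list(self) + [est], config=self.config, cutoff=self.cutoff
        )

    def to_dataframe(self, rounded: bool = True) -> pd.DataFrame:
        """Tabulate as metric/estimate/ci_lower/ci_upper.

        With ``rounded`` the cells are display strings (3 decimals, "NA");
        otherwise raw floats with missing as NaN.
        """
        decimals = self.config.report_decimals if self.config is not None else 3
        rows = []
        for est in self:
            if rounded:
                rows.append(
                    [
                        est.label,
                        round_for_display(est.value, decimals),
                        round_for_display(est.lower, decimals),
                        round_for_display(est.upper, decimals),
                    ]
                )
            else:
                rows.append([est.label, est.value, est.lower, est.upper])
        return pd.DataFrame(
            rows, columns=["metric", "estimate", "ci_lower", "ci_upper"]
        )


def auc_label(auc_result: AUCResult, decimals: int = 3) -> str:
    """Annotation text, e.g. ``AUC = 0.731 (95% CI: 0.630–0.833)``."""
    a = round_for_display(auc_result.auc, decimals)
    lo = round_for_display(auc_result.lower, decimals)
    hi = round_for_display(auc_result.upper, decimals)
    return f"AUC = {a} (95% CI: {lo}–{hi})"


def render_roc_plot(
    curve: ROCCurve,
    auc_result: AUCResult,
    path: Union[str, Path],
    band: Optional[SensitivityBand] = None,
    cutoff: Optional[CutoffResult] = None,
    dpi: int = 300,
    decimals: int = 3,
) -> None:
    """Render the ROC curve to an image file (PNG or SVG by extension).

    Specificity runs along the x-axis in reversed direction (equivalent to
    plotting 1 - specificity), with the bootstrap band shaded when given,
    the optimal cutoff annotated with its threshold/Se/Sp, and the AUC and
    its interval printed in the lower-right corner.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6.0, 6.0))
    try:
        if band is not None:
            ax.fill_between(
                band.sp_grid,
                band.se_lower,
                band.se_upper,
                color="#9ecae1",
                alpha=0.5,
                linewidth=0,
                label="95% bootstrap band",
            )
        # chance line: Se = 1 - Sp
        ax.plot([1, 0], [0, 1], linestyle="--", color="0.6", linewidth=1)

        order = curve.sp.argsort()[::-1]
        ax.plot(curve.sp[order], curve.se[order], color="#08519c", linewidth=1.8)

        if cutoff is not None:
            ax.plot([cutoff.sp], [cutoff.se], "o", color="#d62728", markersize=7)
            ax.annotate(
                f"{round_for_display(cutoff.threshold, decimals)} "
                f"(Sp = {round_for_display(cutoff.sp, decimals)}, "
                f"Se = {round_for_display(cutoff.se, decimals)})",
                xy=(cutoff.sp, cutoff.se),
                xytext=(8, -12),
                textcoords="offset points",
                fontsize=9,
            )
        ax.text(
            0.03,
            0.05,
            auc_label(auc_result, decimals),
            transform=ax.transAxes,
            ha="left",
            fontsize=10,
        )
        ax.set_xlim(1.02, -0.02)  # specificity reversed
        ax.set_ylim(-0.02, 1.02)
        ax.set_xlabel("Specificity")
        ax.set_ylabel("Sensitivity")
        ax.set_title("ROC curve")
        fig.tight_layout()
        fig.savefig(Path(path), dpi=dpi)
    finally:
        plt.close(fig)
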