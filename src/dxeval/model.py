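"""Model/results interface for single diagnostic-test evaluation.

:class:`DiagnosticTest` holds the validated data and analysis settings;
:meth:`DiagnosticTest.fit` runs the full evaluation and returns a
:class:`DiagnosticTestResults` carrying the confusion matrix, the
indicator table with 95% intervals, the ROC curve with its AUC/DeLong
interval, the optimal cutoff and the bootstrap sensitivity band, plus
``summary()`` and export/plot helpers.

For a quantitative test the pipeline is: ROC curve over all candidate
thresholds -> optimal cutoff (closest to the top-left corner) ->
dichotomize -> confusion matrix -> indicators.  For a qualitative (0/1)
test the observed classifications are used directly; the AUC then equals
(Se + Sp)/2 via the same Mann-Whitney machinery, and cutoff search and
band are skipped.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from dxeval import io as dio
from dxeval import roc as droc
from dxeval.metrics import AnalysisConfig, ConfusionMatrix, build_confusion_matrix, evaluate_all
from dxeval.reporting import MetricsReport, render_roc_plot

__all__ = ["DiagnosticTest", "DiagnosticTestResults"]


def _table_from_values(test, ref) -> dio.RawTable:
    rows = []
    for t, r in zip(np.asarray(test, dtype=object), np.asarray(ref, dtype=object)):
        rows.append([t, r])
    return dio.RawTable(column_names=["test", "reference"], rows=rows)


class DiagnosticTest:
    """A single index test evaluated against a binary reference standard.

    Parameters
    ----------
    test
        Test measurements: 0/1 for a qualitative test, numeric for a
        quantitative one.  Missing entries (None/NaN) are dropped pairwise
        with the reference.
    reference
        Binary disease status (1 = diseased, 0 = non-diseased).
    test_kind
        "quantitative" or "qualitative".
    prevalence
        Population (pre-test) disease probability used for PPV/NPV; must
        lie strictly in (0, 1).
    direction
        "auto" (compare group medians), "higher" or "lower": whether large
        or small quantitative scores indicate disease.
    """

    def __init__(
        self,
        test: Sequence,
        reference: Sequence,
        test_kind: str = dio.QUANTITATIVE,
        prevalence: float = 0.1,
        direction: str = "auto",
    ) -> None:
        if direction not in ("auto", "higher", "lower"):
            raise ValueError("direction must be 'auto', 'higher' or 'lower'")
        self.config = AnalysisConfig(prevalence=prevalence)
        self.data = dio.validate_and_clean(
            _table_from_values(test, reference), "test", "reference", test_kind
        )
        self._direction_request = direction

    # ------------------------------------------------------------------ #
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        test_col: str,
        ref_col: str,
        test_kind: str = dio.QUANTITATIVE,
        prevalence: float = 0.1,
        direction: str = "auto",
    ) -> "DiagnosticTest":
        """Build from a DataFrame, applying the same validation as file input."""
        if test_col not in df.columns:
            raise KeyError(f"no column named {test_col!r}")
        if ref_col not in df.columns:
            raise KeyError(f"no column named {ref_col!r}")
        return cls(
            df[test_col].tolist(),
            df[ref_col].tolist(),
            test_kind=test_kind,
            prevalence=prevalence,
            direction=direction,
        )

    @classmethod
    def from_xlsx(
        cls,
        path: Union[str, Path],
        test_col: str,
        ref_col: str,
        test_kind: str = dio.QUANTITATIVE,
        prevalence: float = 0.1,
        sheet: Union[int, str] = 0,
        direction: str = "auto",
    ) -> "DiagnosticTest":
        """Build from an .xlsx workbook (first sheet by default)."""
        if direction not in ("auto", "higher", "lower"):
            raise ValueError("direction must be 'auto', 'higher' or 'lower'")
        table = dio.read_table(path, sheet=sheet)
        data = dio.validate_and_clean(table, test_col, ref_col, test_kind)
        model = cls.__new__(cls)
        model.config = AnalysisConfig(prevalence=prevalence)
        model.data = data
        model._direction_request = direction
        return model

    # ------------------------------------------------------------------ #
    @property
    def test_kind(self) -> str:
        return self.data.test_kind

    def _resolve_direction(self) -> str:
        if self._direction_request == "higher":
            return droc.HIGHER_IS_POSITIVE
        if self._direction_request == "lower":
            return droc.LOWER_IS_POSITIVE
        return droc.detect_direction(self.data.test_values, self.data.ref_values)

    def fit(
        self,
        n_boot: int = 5000,
        band: bool = True,
        seed: Optional[int] = None,
    ) -> "DiagnosticTestResults":
        """Run the evaluation.

        ``n_boot`` bootstrap replicates build the ROC sensitivity band
        (quantitative tests only; set ``band=False`` to skip it).  With a
        seed the band is reproducible; without one fresh randomness is
        used, so the band may vary slightly across runs.
        """
        scores = self.data.test_values
        ref = self.data.ref_values
        cfg = self.config

        if self.test_kind == dio.QUANTITATIVE:
            direction = self._resolve_direction()
            curve = droc.roc_curve(scores, ref, direction)
            auc_result = droc.delong_ci(scores, ref, z=cfg.z, direction=direction)
            cutoff = droc.optimal_cutoff(curve)
            if cutoff is None:
                raise ValueError(
                    "the test variable is constant; no classification threshold exists"
                )
            binary = droc.dichotomize(scores, cutoff.threshold, direction)
            band_result = (
                droc.bootstrap_band(
                    scores, ref, n_boot=n_boot, seed=seed, direction=direction
                )
                if band
                else None
            )
        else:
            direction = droc.HIGHER_IS_POSITIVE
            binary = scores.astype(int)
            curve = droc.roc_curve(scores, ref, direction)
            auc_result = droc.delong_ci(scores, ref, z=cfg.z, direction=direction)
            cutoff = None
            band_result = None

        cm = build_confusion_matrix(binary, ref)
        report = evaluate_all(cm, cfg).with_auc(auc_result)
        report.cutoff = cutoff
        return DiagnosticTestResults(
            model=self,
            confusion_matrix=cm,
            metrics=report,
            roc=curve,
            auc_result=auc_result,
            cutoff=cutoff,
            band=band_result,
            direction=direction,
        )


class DiagnosticTestResults:
    """Fitted evaluation results with summary, plotting and export helpers."""

    def __init__(
        self,
        model: DiagnosticTest,
        confusion_matrix: ConfusionMatrix,
        metrics: MetricsReport,
        roc: droc.ROCCurve,
        auc_result: droc.AUCResult,
        cutoff: Optional[droc.CutoffResult],
        band: Optional[droc.SensitivityBand],
        direction: str,
    ) -> None:
        self.model = model
        self.confusion_matrix = confusion_matrix
        self.metrics = metrics
        self.roc = roc
        self.auc_result = auc_result
        self.cutoff = cutoff
        self.band = band
        self.direction = direction

    # ------------------------------------------------------------------ #
    def summary_frame(self, rounded: bool = True) -> pd.DataFrame:
        """The indicator table as a DataFrame (display-rounded by default)."""
        return self.metrics.to_dataframe(rounded=rounded)

    def summary(self) -> str:
        """Plain-text summary: sample, counts, cutoff and the indicator table."""
        from dxeval.reporting import round_for_display

        cm = self.confusion_matrix
        lines = [
            "Diagnostic test evaluation",
            "==========================",
            f"Observations: {cm.total} "
            f"(diseased: {cm.n_diseased}, non-diseased: {cm.n_nondiseased}; "
            f"dropped: {self.model.data.n_dropped})",
            f"Test type: {self.model.test_kind}",
            f"Prevalence (population): {self.model.config.prevalence}",
            f"Direction: {self.direction}",
        ]
        if self.cutoff is not None:
            lines.append(
                f"Optimal cutoff: {round_for_display(self.cutoff.threshold)} "
                f"(Se = {round_for_display(self.cutoff.se)}, "
                f"Sp = {round_for_display(self.cutoff.sp)}, "
                f"distance = {round_for_display(self.cutoff.distance)})"
            )
        lines += [
            "",
            f"Confusion matrix: TP={cm.tp}  FP={cm.fp}  FN={cm.fn}  TN={cm.tn}",
            "",
            self.summary_frame().to_string(index=False),
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------------ #
    def save_confusion_matrix(self, path: Union[str, Path]) -> None:
        dio.write_confusion_matrix(self.confusion_matrix, path)

    def save_metrics(self, path: Union[str, Path]) -> None:
        dio.write_metrics(self.metrics, path)

    def save_roc_points(self, path: Union[str, Path]) -> None:
        dio.write_roc_points(self.roc, path)

    def plot_roc(self, path: Union[str, Path], dpi: int = 300) -> None:
        """Save the annotated ROC plot (band and cutoff marker when present)."""
        render_roc_plot(
            self.roc,
            self.auc_result,
            path,
            band=self.band,
            cutoff=self.cutoff,
            dpi=dpi,
        )
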