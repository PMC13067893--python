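"""Synthetic diagnostic-test datasets for demonstration and testing.

The generator emulates a typical single-test evaluation study: a binary
disease indicator, one positive-valued right-skewed quantitative marker
(chi-square scores whose degrees of freedom differ by disease status) and
one imperfect binary test (Bernoulli draws conditional on disease status
with configurable sensitivity/specificity).  The default degrees of
freedom (3 for diseased vs 1.5 for non-diseased) put the marker's
discriminative ability in the moderate regime, AUC around 0.73.

Note that ``p_disease`` controls the sampling of the study cohort and is
deliberately distinct from the population prevalence passed to the
analysis: a case-enriched study sample is the norm in test evaluation,
while predictive values should reflect the (often much lower) population
prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "generate", "write_example_workbook"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    n: cohort size (>= 2).
    p_disease: probability a subject is diseased (sampling, not analysis
        prevalence); default 0.64 mimics a case-enriched evaluation cohort.
    quant_df_diseased / quant_df_nondiseased: chi-square degrees of freedom
        of the quantitative marker in the two groups.
    binary_se / binary_sp: true sensitivity/specificity of the binary test.
    seed: reproducibility seed; ``None`` draws fresh randomness.
    """

    n: int = 113
    p_disease: float = 0.64
    quant_df_diseased: float = 3.0
    quant_df_nondiseased: float = 1.5
    binary_se: float = 0.9
    binary_sp: float = 0.7
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        for name in ("p_disease", "binary_se", "binary_sp"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly between 0 and 1, got {v!r}")
        for name in ("quant_df_diseased", "quant_df_nondiseased"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def generate(config: SyntheticConfig) -> pd.DataFrame:
    """Draw a synthetic cohort with columns Disease, Test1, Test2.

    Disease ~ Bernoulli(p_disease); Test1 | Disease=d ~ chi-square with the
    group's degrees of freedom (all values strictly positive); Test2 |
    Disease=1 ~ Bernoulli(binary_se) and Test2 | Disease=0 ~
    Bernoulli(1 - binary_sp).
    """
    rng = np.random.default_rng(config.seed)
    disease = rng.binomial(1, config.p_disease, size=config.n)
    scores_d = rng.chisquare(config.quant_df_diseased, size=config.n)
    scores_nd = rng.chisquare(config.quant_df_nondiseased, size=config.n)
    test1 = np.where(disease == 1, scores_d, scores_nd)
    pos_d = rng.binomial(1, config.binary_se, size=config.n)
    pos_nd = rng.binomial(1, 1.0 - config.binary_sp, size=config.n)
    test2 = np.where(disease == 1, pos_d, pos_nd)
    return pd.DataFrame(
        {"Disease": disease.astype(int), "Test1": test1, "Test2": test2.astype(int)}
    )


def write_example_workbook(config: SyntheticConfig, path: Union[str, Path]) -> pd.DataFrame:
    """Generate a cohort and persist it as an .xlsx workbook; returns the frame."""
    df = generate(config)
    df.to_excel(Path(path), index=False, engine="openpyxl")
    return df
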