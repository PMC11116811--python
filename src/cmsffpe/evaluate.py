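"""Validation metrics: accuracy, contingency, per-class rates, exact binomial concordance.

Predicted calls are compared against benchmark "core" CMS labels; benchmark
samples without a core call (NOLBL) are excluded, and the denominator
actually used is always part of the result. Concordance significance uses
the one-sided exact binomial tail against a null agreement probability of
0.25 (uniform chance over the four subtypes) unless another null is given.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .classify import CmsCall
from .io import CMS_CLASSES, NO_LABEL

__all__ = [
    "ConcordanceResult",
    "accuracy",
    "contingency",
    "per_class_metrics",
    "concordance_binomial_test",
    "evaluation_report",
]


@dataclass(frozen=True)
class ConcordanceResult:
    n_total: int
    n_concordant: int
    p0: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_concordant <= self.n_total:
            raise ValueError("need 0 <= n_concordant <= n_total")


def _paired(calls, benchmark: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Align calls with benchmark labels on sample id, dropping NOLBL benchmarks."""
    if isinstance(calls, pd.Series):
        pred = calls.astype(str)
    elif len(calls) and isinstance(calls[0], CmsCall):
        pred = pd.Series({c.sample_id: c.label for c in calls})
    else:
        pred = pd.Series(dict(calls)).astype(str)
    bench = pd.Series(dict(benchmark)) if not isinstance(benchmark, pd.Series) else benchmark
    bench = bench[bench != NO_LABEL]
    common = pred.index.intersection(bench.index)
    if len(common) == 0:
        raise ValueError("no sample has both a call and a benchmark core label")
    return pd.DataFrame({"pred": pred.loc[common], "bench": bench.loc[common]})


def accuracy(calls, benchmark) -> float:
    """Fraction of jointly labeled samples whose call equals the benchmark."""
    df = _paired(calls, benchmark)
    return float((df["pred"] == df["bench"]).mean())


def contingency(calls, benchmark) -> pd.DataFrame:
    """4x4 table of counts; rows = predicted CMS, columns = benchmark CMS.

    The diagonal sum over the grand total equals ``accuracy`` on the same input.
    """
    df = _paired(calls, benchmark)
    table = pd.crosstab(df["pred"], df["bench"]).reindex(
        index=CMS_CLASSES, columns=CMS_CLASSES, fill_value=0
    )
    table.index.name = "predicted"
    table.columns.name = "benchmark"
    return table.astype(int)


def per_class_metrics(calls, benchmark) -> pd.DataFrame:
    """One-vs-rest sensitivity and specificity per CMS.

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP); NaN where the
    denominator is zero (e.g. no benchmark sample of that class).
    """
    table = contingency(calls, benchmark)
    total = table.to_numpy().sum()
    rows = {}
    for cls in CMS_CLASSES:
        tp = table.loc[cls, cls]
        fn = table[cls].sum() - tp
        fp = table.loc[cls].sum() - tp
        tn = total - tp - fn - fp
        rows[cls] = {
            "sensitivity": tp / (tp + fn) if tp + fn > 0 else np.nan,
            "specificity": tn / (tn + fp) if tn + fp > 0 else np.nan,
        }
    out = pd.DataFrame(rows).T
    out.index.name = "cms"
    return out


def concordance_binomial_test(
    n_concordant: int, n_total: int, p0: float = 0.25
) -> ConcordanceResult:
    """One-sided exact binomial test of observed concordance against chance.

    P = sum_{k >= n_concordant} C(n_total, k) p0^k (1-p0)^(n_total-k): the
    probability of at least this much agreement if calls matched the
    benchmark with probability ``p0`` (default 1/4, chance among four
    subtypes).
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_concordant <= n_total:
        raise ValueError("need 0 <= n_concordant <= n_total")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"null probability p0 = {p0} outside (0, 1)")
    p_value = float(binom.sf(n_concordant - 1, n_total, p0))
    return ConcordanceResult(n_total, n_concordant, p0, min(p_value, 1.0))


def evaluation_report(calls, benchmark, p0: float = 0.25) -> dict:
    """Bundle all validation metrics for one cohort comparison."""
    df = _paired(calls, benchmark)
    n_total = len(df)
    n_conc = int((df["pred"] == df["bench"]).sum())
    return {
        "n_evaluated": n_total,
        "accuracy": n_conc / n_total,
        "contingency": contingency(calls, benchmark),
        "per_class": per_class_metrics(calls, benchmark),
        "concordance": concordance_binomial_test(n_conc, n_total, p0),
    }
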