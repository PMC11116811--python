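"""Feature-gene selection and binary gene-pair encoding.

Two ideas make CMS classification survive both platform changes and FFPE
degradation. First, only candidate signature genes that remain well covered
in degraded material (median TIN above a threshold, 20 by default) are kept
as features. Second, expression is reduced to within-sample *order*
information: after per-gene z-normalization across the cohort, each ordered
gene pair (a, b) with a < b contributes the binary feature 1[z_a > z_b] per
sample — a top-scoring-pair-style encoding that is invariant to any per-gene
positive affine transform of the input and therefore robust to protocol and
platform effects.

Cohort mode: z-scores are taken per gene ACROSS the samples of the cohort at
hand, so each cohort (training set, each test set) is normalized internally.
A single sample cannot be encoded; this mirrors the fact that the method is
not a single-sample predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureGeneSet",
    "AlignmentReport",
    "log_transform",
    "zscore_by_gene",
    "select_feature_genes",
    "encode_gene_pairs",
    "align_features",
    "pair_ids",
]


@dataclass(frozen=True)
class FeatureGeneSet:
    """Lexicographically ordered feature genes plus how they were selected."""

    genes: tuple[str, ...]
    threshold: float
    n_candidates: int

    def __post_init__(self) -> None:
        if list(self.genes) != sorted(set(self.genes)):
            raise ValueError("feature genes must be sorted and unique")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass(frozen=True)
class AlignmentReport:
    missing: tuple[str, ...]
    missing_frac: float


def log_transform(x: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1); variance stabilization for TPM-scale input.

    Skip this for data already on a log scale (e.g. microarray intensities).
    """
    if (x.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    return np.log2(x + 1.0)


def zscore_by_gene(x: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene across samples (mean 0, sd 1; n-1 denominator).

    Constant genes cannot be standardized and map to all-zero rows (with a
    warning); downstream their pair features reduce to the tie rule.
    """
    if x.shape[1] < 2:
        raise ValueError(
            "z-normalization needs a cohort of >= 2 samples; single-sample "
            "classification is unsupported — classify samples together in cohort mode"
        )
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant gene(s) set to z=0 (e.g. %s)",
            int(constant.sum()),
            x.index[constant][:3].tolist(),
        )
    z = x.sub(mean, axis=0).div(sd.where(~constant, 1.0), axis=0)
    z[constant] = 0.0
    return z


def select_feature_genes(
    candidates: Sequence[str],
    gene_tin: pd.DataFrame,
    threshold: float = 20.0,
) -> FeatureGeneSet:
    """Keep candidate genes whose median TIN across samples is strictly > threshold.

    Candidates absent from the TIN table are dropped with a warning. The
    result is sorted; an empty result is an error (nothing to classify with).
    """
    if len(candidates) == 0:
        raise ValueError("candidate gene list is empty")
    candidates = list(dict.fromkeys(candidates))  # de-dup, keep order for report
    present = [g for g in candidates if g in gene_tin.index]
    absent = [g for g in candidates if g not in gene_tin.index]
    if absent:
        logger.warning(
            "%d candidate gene(s) absent from TIN table (e.g. %s)",
            len(absent),
            absent[:3],
        )
    if not present:
        raise ValueError("no candidate gene is covered by the TIN table")
    medians = gene_tin.loc[present].median(axis=1, skipna=True)
    kept = sorted(medians.index[medians > threshold])
    if not kept:
        raise ValueError(
            f"no candidate gene has median TIN > {threshold}; no classifiable features"
        )
    return FeatureGeneSet(tuple(kept), float(threshold), len(candidates))


def pair_ids(genes: Sequence[str]) -> list[str]:
    """Ordered pair labels "(a,b)" with a < b, in lexicographic pair order."""
    ordered = list(genes)
    if ordered != sorted(ordered):
        raise ValueError("gene list must be sorted")
    return [f"({a},{b})" for a, b in combinations(ordered, 2)]


def encode_gene_pairs(z: pd.DataFrame, genes: FeatureGeneSet | Sequence[str]) -> pd.DataFrame:
    """Sample-by-pair binary matrix: 1 if z[a] > z[b] for pair (a, b), a < b.

    Ties (including padded constant genes, z = 0) encode 0. The column order
    is the lexicographic pair order and is part of the model contract.
    """
    ordered = sorted(genes)
    missing = [g for g in ordered if g not in z.index]
    if missing:
        raise KeyError(
            f"feature genes missing from matrix: {missing[:5]} — run align_features first"
        )
    m = len(ordered)
    if m < 2:
        raise ValueError("need >= 2 feature genes to form pairs")
    zv = z.loc[ordered].to_numpy()  # m x n_samples
    ia, ib = np.triu_indices(m, k=1)
    feats = (zv[ia] > zv[ib]).T.astype(np.uint8)  # n_samples x m(m-1)/2
    return pd.DataFrame(feats, index=z.columns.copy(), columns=pair_ids(ordered))


def align_features(
    x: pd.DataFrame,
    genes: FeatureGeneSet | Sequence[str],
    max_missing_frac: float = 0.2,
) -> tuple[pd.DataFrame, AlignmentReport]:
    """Restrict an expression matrix to the feature genes, padding absent ones.

    Cross-platform inputs may lack some feature genes; those are injected as
    constant zero rows (z = 0 downstream, so their pair features fall to the
    tie/comparison-with-zero rule) and reported. More than
    ``max_missing_frac`` missing is an error.
    """
    ordered = sorted(genes)
    if x.empty:
        raise ValueError("empty expression matrix")
    missing = tuple(g for g in ordered if g not in x.index)
    frac = len(missing) / len(ordered)
    if frac > max_missing_frac:
        raise ValueError(
            f"{len(missing)}/{len(ordered)} feature genes missing "
            f"({frac:.0%} > {max_missing_frac:.0%}): {list(missing)}"
        )
    if missing:
        logger.warning("padding %d missing feature gene(s): %s", len(missing), list(missing)[:5])
    out = x.reindex(ordered, fill_value=0.0)
    return out, AlignmentReport(missing, frac)
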