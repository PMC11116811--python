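"""Glue: expression matrix -> pair-feature matrix, the path every cohort takes.

Each cohort is normalized internally (cohort-mode z-scores), so training and
test sets from different platforms or protocols can be encoded independently
and still land in the same feature space.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .features import (
    FeatureGeneSet,
    align_features,
    encode_gene_pairs,
    log_transform,
    zscore_by_gene,
)

__all__ = ["encode_cohort"]


def encode_cohort(
    expr: pd.DataFrame,
    genes: FeatureGeneSet | Sequence[str],
    log: bool = True,
    max_missing_frac: float = 0.2,
) -> pd.DataFrame:
    """Encode one cohort's expression as the sample-by-pair binary matrix.

    ``log`` applies log2(x+1) first (use for TPM-scale input; turn off for
    data already on a log scale). Missing feature genes are zero-padded up
    to ``max_missing_frac``.
    """
    aligned, _ = align_features(expr, genes, max_missing_frac=max_missing_frac)
    if log:
        aligned = log_transform(aligned)
    z = zscore_by_gene(aligned)
    return encode_gene_pairs(z, sorted(genes))
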