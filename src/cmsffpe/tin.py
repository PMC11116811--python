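"""Transcript integrity number (TIN) computation and aggregation.

The TIN quantifies how uniformly reads cover a transcript and serves as a
per-transcript proxy for RNA integrity: formalin fixation fragments RNA, so
degraded transcripts show spiky, 3'-biased coverage and low TIN, while intact
transcripts are covered evenly and score near 100.

Given read depths ``c_1..c_k`` at ``k`` positions sampled along the spliced
mRNA, with coverage probabilities ``p_i = c_i / sum(c)``, the score is

    H   = -sum_{p_i > 0} p_i * ln(p_i)        (Shannon entropy, nats)
    TIN = 100 * exp(H) / k

so perfectly uniform coverage gives TIN = 100 and a single covered position
gives TIN = 100/k. ``exp(H)`` is the "effective number" of covered positions;
TIN is that number as a percentage of all sampled positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoverageProfile",
    "TinScore",
    "transcript_tin",
    "sample_positions",
    "sample_median_tin",
    "gene_tin",
]


@dataclass(frozen=True)
class CoverageProfile:
    """Read depth at ``k`` sampled positions along one spliced transcript, 5'->3'."""

    transcript_id: str
    depths: np.ndarray
    positions_sampled: int = field(init=False)

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        if depths.ndim != 1 or depths.size == 0:
            raise ValueError(
                f"{self.transcript_id}: depth vector must be non-empty and 1-D"
            )
        if np.any(depths < 0) or not np.all(np.isfinite(depths)):
            raise ValueError(
                f"{self.transcript_id}: depths must be finite and non-negative"
            )
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "positions_sampled", depths.size)

    @property
    def mean_depth(self) -> float:
        return float(self.depths.mean())


@dataclass(frozen=True)
class TinScore:
    transcript_id: str
    sample_id: str
    tin: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.tin <= 100.0:
            raise ValueError(f"TIN {self.tin} outside [0, 100]")


def transcript_tin(cov: CoverageProfile, sample_id: str = "") -> TinScore:
    """Score one transcript's coverage uniformity on the 0-100 TIN scale.

    Returns 0 for a transcript with no coverage at all. Invariant to
    rescaling all depths by a positive constant (only the coverage
    *distribution* matters, not sequencing depth).
    """
    depths = cov.depths
    k = cov.positions_sampled
    total = depths.sum()
    if total == 0:
        return TinScore(cov.transcript_id, sample_id, 0.0)
    p = depths / total
    nz = p[p > 0]
    # 0 * ln 0 := 0 by restricting to positive probabilities
    entropy = float(-(nz * np.log(nz)).sum())
    tin = 100.0 * np.exp(entropy) / k
    # guard against float overshoot at exact uniformity
    return TinScore(cov.transcript_id, sample_id, float(min(tin, 100.0)))


def sample_positions(exon_lengths: Sequence[int], step: int = 10) -> np.ndarray:
    """1-based positions every ``step`` nt along the spliced mRNA, endpoints included.

    ``exon_lengths`` are the exon block lengths of the transcript model; only
    their total matters. The first and last mRNA positions are always sampled,
    so ``k >= 1`` (``k = 1`` only for a length-1 transcript).
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    length = int(sum(int(x) for x in exon_lengths))
    if length < 1:
        raise ValueError("total mRNA length must be >= 1")
    pos = np.arange(1, length + 1, step)
    if pos[-1] != length:
        pos = np.append(pos, length)
    return pos


def sample_median_tin(
    tins: pd.DataFrame,
    sample_id: str,
    min_cov: float = 10.0,
    mean_depth: pd.DataFrame | None = None,
) -> float:
    """Median TIN over a sample's sufficiently covered transcripts (medTIN).

    ``tins`` is a transcript-by-sample table (NaN = transcript below the
    coverage floor for that sample). When ``mean_depth`` (same shape) is
    given, transcripts with mean depth < ``min_cov`` are excluded first;
    without it the table is assumed to be pre-filtered. Returns NaN when no
    transcript qualifies.
    """
    if sample_id not in tins.columns:
        raise KeyError(f"sample {sample_id!r} not in TIN table")
    col = tins[sample_id]
    if mean_depth is not None:
        if sample_id not in mean_depth.columns:
            raise KeyError(f"sample {sample_id!r} not in mean-depth table")
        depth = mean_depth[sample_id].reindex(col.index)
        col = col[depth >= min_cov]
    col = col.dropna()
    if col.empty:
        return float("nan")
    return float(col.median())


def gene_tin(
    tins: pd.DataFrame,
    gene_map: Mapping[str, Iterable[str]],
    aggregate: Literal["max_coverage", "mean"] = "max_coverage",
    mean_depth: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Collapse a transcript-by-sample TIN table to gene level.

    ``gene_map`` maps each gene id to its transcript ids; a transcript may
    belong to at most one gene. ``max_coverage`` (default) takes, per sample,
    the TIN of the gene's most-covered transcript and requires ``mean_depth``;
    ``mean`` averages the gene's non-missing transcript TINs.
    """
    seen: dict[str, str] = {}
    for gene, txs in gene_map.items():
        for tx in txs:
            if tx in seen and seen[tx] != gene:
                raise ValueError(
                    f"transcript {tx!r} mapped to both {seen[tx]!r} and {gene!r}"
                )
            seen[tx] = gene
    if aggregate not in ("max_coverage", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    if aggregate == "max_coverage" and mean_depth is None:
        raise ValueError("max_coverage aggregation requires a mean_depth table")

    rows = {}
    for gene, txs in gene_map.items():
        tx_ids = [t for t in txs if t in tins.index]
        if not tx_ids:
            continue
        sub = tins.loc[tx_ids]
        if aggregate == "mean":
            rows[gene] = sub.mean(axis=0, skipna=True)
        else:
            depth = mean_depth.reindex(index=tx_ids, columns=tins.columns)
            # per sample: TIN of the transcript with the deepest mean coverage
            idx = depth.fillna(-np.inf).to_numpy().argmax(axis=0)
            vals = sub.to_numpy()[idx, np.arange(sub.shape[1])]
            rows[gene] = pd.Series(vals, index=tins.columns)
    out = pd.DataFrame(rows).T
    out.index.name = "gene_id"
    return out.reindex(columns=tins.columns)
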