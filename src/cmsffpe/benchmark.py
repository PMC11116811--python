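"""Desk-scale validation experiments on synthetic cohorts.

The central claim of the pipeline is that filtering candidate genes by
preservation (median TIN > 20) protects classification of degraded FFPE
material. ``degradation_benchmark`` measures this end to end: simulate a
paired FF/FFPE cohort, split it, train on fresh-frozen features with the
TIN-filtered gene set and with the full candidate set, and score both models
on held-out fresh-frozen and degraded-FFPE samples against the planted truth.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .classify import Hyperparams, predict, train
from .evaluate import accuracy
from .features import FeatureGeneSet, select_feature_genes
from .pipeline import encode_cohort
from .simulate import SimConfig, simulate_cohort

__all__ = ["degradation_benchmark", "run_split_experiment"]


def run_split_experiment(
    cfg: SimConfig,
    n_train: int = 200,
    tin_threshold: float = 20.0,
) -> dict[str, float]:
    """One seed's experiment: returns test accuracies for both gene sets.

    Simulates ``n_train`` + remaining test samples in one cohort, selects
    feature genes from the synthetic TIN table, trains both models on the
    fresh-frozen training split, and evaluates on the held-out split twice:
    on fresh-frozen and on degraded FFPE expression. Keys:
    ``filtered_ff``, ``filtered_ffpe``, ``all_ff``, ``all_ffpe``,
    ``n_filtered_genes``, ``oob_filtered``.
    """
    if not 0 < n_train < cfg.n_samples:
        raise ValueError("need 0 < n_train < n_samples to hold out a test split")
    cohort = simulate_cohort(cfg)
    samples = cohort.ff_expr.columns
    train_s, test_s = samples[:n_train], samples[n_train:]

    candidates = cohort.candidate_genes
    filtered = select_feature_genes(candidates, cohort.tin, tin_threshold)
    unfiltered = FeatureGeneSet(tuple(sorted(candidates)), float("-inf"), len(candidates))

    out: dict[str, float] = {"n_filtered_genes": float(len(filtered))}
    for name, genes in (("filtered", filtered), ("all", unfiltered)):
        x_train = encode_cohort(cohort.ff_expr[train_s], genes)
        model = train(x_train, cohort.true_labels[train_s], genes,
                      Hyperparams(seed=cfg.seed))
        if name == "filtered":
            out["oob_filtered"] = model.training_manifest["oob_accuracy"]
        for split, expr in (("ff", cohort.ff_expr), ("ffpe", cohort.ffpe_expr)):
            calls = predict(model, encode_cohort(expr[test_s], genes))
            out[f"{name}_{split}"] = accuracy(calls, cohort.true_labels[test_s])
    return out


def degradation_benchmark(
    seeds: list[int],
    cfg: SimConfig | None = None,
    n_train: int = 200,
    n_test: int = 200,
    tin_threshold: float = 20.0,
) -> pd.DataFrame:
    """Run the split experiment across seeds; one row per seed.

    Uses the generator defaults (including severe immune degradation) unless
    ``cfg`` overrides them; ``cfg.n_samples`` and ``cfg.seed`` are set from
    ``n_train + n_test`` and each seed in turn.
    """
    base = cfg if cfg is not None else SimConfig()
    rows = []
    for seed in seeds:
        run_cfg = replace(base, n_samples=n_train + n_test, seed=int(seed))
        rows.append({"seed": seed, **run_split_experiment(run_cfg, n_train, tin_threshold)})
    return pd.DataFrame(rows).set_index("seed")
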