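"""Random-forest CMS prediction on binary gene-pair features.

A plain random forest (500 trees, mtry = floor(sqrt(P)), unlimited depth —
the classical defaults) is trained on the pair-feature matrix against
benchmark CMS labels. Class probabilities are the fraction of trees voting
each subtype; the call is the argmax, with ties broken toward the
lower-numbered CMS. Every sample receives a call — there is no reject tier.

Models persist as a zip archive holding a JSON manifest (feature genes, pair
order, classes, hyperparameters, seed, format version, forest checksum) plus
the serialized forest; the loader verifies internal consistency so a
tampered or mismatched archive fails loudly rather than misclassifying.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
import math
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureGeneSet, pair_ids
from .io import CMS_CLASSES, NO_LABEL

__all__ = ["Hyperparams", "TrainedModel", "CmsCall", "train", "predict", "save_model", "load_model"]

FORMAT_VERSION = "1.0"


class ModelIntegrityError(RuntimeError):
    """Model archive is corrupt, tampered with, or from an incompatible version."""


@dataclass(frozen=True)
class Hyperparams:
    n_trees: int = 500
    mtry: int | None = None  # None -> floor(sqrt(#features))
    min_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_leaf < 1:
            raise ValueError("n_trees and min_leaf must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")

    def resolved_mtry(self, n_features: int) -> int:
        if self.mtry is not None:
            if self.mtry > n_features:
                raise ValueError(f"mtry {self.mtry} > #features {n_features}")
            return self.mtry
        return max(1, math.floor(math.sqrt(n_features)))


@dataclass(frozen=True)
class TrainedModel:
    forest: RandomForestClassifier
    feature_genes: FeatureGeneSet
    pair_order: tuple[str, ...]
    hyperparams: Hyperparams
    classes: tuple[str, ...] = CMS_CLASSES
    training_manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = len(self.feature_genes)
        if len(self.pair_order) != m * (m - 1) // 2:
            raise ValueError("pair_order length must be m(m-1)/2 for m feature genes")
        if tuple(self.pair_order) != tuple(pair_ids(sorted(self.feature_genes))):
            raise ValueError("pair_order does not match the feature-gene set")


@dataclass(frozen=True)
class CmsCall:
    sample_id: str
    label: str
    probs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        if self.label != CMS_CLASSES[int(np.argmax(p))]:
            raise ValueError("label must be the (tie-broken) argmax of probs")


def train(
    features: pd.DataFrame,
    labels: pd.Series,
    feature_genes: FeatureGeneSet,
    hp: Hyperparams = Hyperparams(),
) -> TrainedModel:
    """Fit the forest on a sample-by-pair matrix against CMS labels.

    Samples labeled NOLBL (or absent from ``labels``) are dropped with a
    warning; at least two subtypes must remain. Out-of-bag accuracy is
    recorded in the training manifest. Deterministic given ``hp.seed``.
    """
    import logging

    logger = logging.getLogger(__name__)

    expected = tuple(pair_ids(sorted(feature_genes)))
    _check_columns(features, expected)

    labels = labels.reindex(features.index)
    usable = labels.notna() & (labels != NO_LABEL)
    bad = labels.dropna()[~labels.dropna().isin([*CMS_CLASSES, NO_LABEL])]
    if len(bad):
        raise ValueError(f"labels outside CMS1..CMS4/{NO_LABEL}: {sorted(set(bad))[:5]}")
    if (n_dropped := int((~usable).sum())):
        logger.warning("dropping %d unlabeled sample(s) from training", n_dropped)
    x = features.loc[usable]
    y = labels.loc[usable]
    if x.shape[0] == 0:
        raise ValueError("no labeled training samples")
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError(f"training labels contain a single class ({counts.index[0]})")

    forest = RandomForestClassifier(
        n_estimators=hp.n_trees,
        max_features=hp.resolved_mtry(features.shape[1]),
        min_samples_leaf=hp.min_leaf,
        oob_score=True,
        random_state=hp.seed,
        n_jobs=1,
    )
    forest.fit(x.to_numpy(), y.to_numpy())
    manifest = {
        "n_train": int(x.shape[0]),
        "class_counts": {c: int(counts.get(c, 0)) for c in CMS_CLASSES},
        "oob_accuracy": float(forest.oob_score_),
        "n_features": int(features.shape[1]),
    }
    return TrainedModel(forest, feature_genes, expected, hp, CMS_CLASSES, manifest)


def predict(model: TrainedModel, features: pd.DataFrame) -> list[CmsCall]:
    """Call a subtype (with its 4-class probability vector) for every sample.

    Probabilities are tree-vote fractions over CMS1..CMS4 (zero for a
    subtype absent from training); ties go to the lower-numbered CMS.
    """
    _check_columns(features, model.pair_order)
    raw = model.forest.predict_proba(features.to_numpy())
    probs = np.zeros((features.shape[0], len(CMS_CLASSES)))
    for j, cls in enumerate(model.forest.classes_):
        probs[:, CMS_CLASSES.index(cls)] = raw[:, j]
    calls = []
    for sid, p in zip(features.index, probs):
        label = CMS_CLASSES[int(np.argmax(p))]  # argmax takes the first = lowest CMS on ties
        calls.append(CmsCall(str(sid), label, tuple(float(v) for v in p)))
    return calls


def calls_to_frame(calls: Sequence[CmsCall]) -> pd.DataFrame:
    """Tabulate calls as sample_id, label, p_CMS1..p_CMS4 (the predictions TSV layout)."""
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "label": [c.label for c in calls],
            **{
                f"p_{cls}": [c.probs[i] for c in calls]
                for i, cls in enumerate(CMS_CLASSES)
            },
        }
    ).set_index("sample_id")


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist as a zip of manifest.json + forest.joblib; round-trips bit-exactly."""
    buf = _stdio.BytesIO()
    joblib.dump(model.forest, buf)
    forest_bytes = buf.getvalue()
    manifest = {
        "format_version": FORMAT_VERSION,
        "feature_genes": list(model.feature_genes),
        "selection_threshold": model.feature_genes.threshold,
        "n_candidates": model.feature_genes.n_candidates,
        "pair_order": list(model.pair_order),
        "classes": list(model.classes),
        "hyperparams": {
            "n_trees": model.hyperparams.n_trees,
            "mtry": model.hyperparams.mtry,
            "min_leaf": model.hyperparams.min_leaf,
            "seed": model.hyperparams.seed,
        },
        "training_manifest": model.training_manifest,
        "forest_sha256": hashlib.sha256(forest_bytes).hexdigest(),
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
        zf.writestr("forest.joblib", forest_bytes)


def load_model(path: str | Path) -> TrainedModel:
    """Load and verify a model archive; any inconsistency raises ModelIntegrityError."""
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            forest_bytes = zf.read("forest.joblib")
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise ModelIntegrityError(f"unreadable model archive {path}: {exc}") from exc

    version = str(manifest.get("format_version", ""))
    if version.split(".")[0] != FORMAT_VERSION.split(".")[0]:
        raise ModelIntegrityError(
            f"model format {version!r} incompatible with {FORMAT_VERSION}"
        )
    if hashlib.sha256(forest_bytes).hexdigest() != manifest.get("forest_sha256"):
        raise ModelIntegrityError("forest checksum mismatch: archive corrupt or tampered")

    genes = FeatureGeneSet(
        tuple(manifest["feature_genes"]),
        float(manifest.get("selection_threshold", float("nan"))),
        int(manifest.get("n_candidates", len(manifest["feature_genes"]))),
    )
    expected_pairs = pair_ids(sorted(genes))
    if list(manifest["pair_order"]) != expected_pairs:
        raise ModelIntegrityError("pair order inconsistent with manifest gene list")
    forest = joblib.load(_stdio.BytesIO(forest_bytes))
    if getattr(forest, "n_features_in_", None) != len(expected_pairs):
        raise ModelIntegrityError(
            f"forest expects {getattr(forest, 'n_features_in_', '?')} features, "
            f"manifest defines {len(expected_pairs)} pairs"
        )
    hp = Hyperparams(**manifest["hyperparams"])
    return TrainedModel(
        forest, genes, tuple(manifest["pair_order"]), hp,
        tuple(manifest["classes"]), dict(manifest.get("training_manifest", {})),
    )


def _check_columns(features: pd.DataFrame, expected: Sequence[str]) -> None:
    got = list(features.columns)
    if got != list(expected):
        for i, (g, e) in enumerate(zip(got, expected)):
            if g != e:
                raise ValueError(
                    f"feature columns do not match model pair order: "
                    f"column {i} is {g!r}, expected {e!r}"
                )
        raise ValueError(
            f"feature columns do not match model pair order: "
            f"{len(got)} columns given, {len(expected)} expected"
        )
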