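"""Stacked ensemble of the three feature-specific base networks.

Each base network is trained on one feature-forming module (ffmod 0, 1, 2)
and contributes one predicted probability per residue; the three
probabilities form the meta-feature vector. The meta-decision rule is by
default a logistic regression fitted on the validation split's
meta-features; decision tree, random forest and nearest-neighbor rules,
plain averaging, majority voting, and a least-squares linear rule
(``linear_mse``) are also supported. The final call thresholds the
ensemble probability at 0.5 (voting: majority of base calls, no
probability emitted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier

from .features import featurize_dataset
from .io import ProteinRecord
from .model import SiteNet

__all__ = [
    "RULES",
    "StackedEnsemble",
    "collect_meta_features",
    "fit_meta_learner",
    "ensemble_predict",
    "train_stacked_ensemble",
]

RULES = (
    "logistic_regression",
    "decision_tree",
    "random_forest",
    "nearest_neighbor",
    "voting",
    "averaging",
    "linear_mse",
)

K_BASE_MODELS = 3


@dataclass
class StackedEnsemble:
    """Three trained base networks (ffmod order 0, 1, 2) plus a meta rule."""

    base_models: list[SiteNet]
    rule: str = "logistic_regression"
    meta: object | None = None
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if len(self.base_models) != K_BASE_MODELS:
            raise ValueError(f"exactly {K_BASE_MODELS} base models required")
        ffmods = [m.config.ffmod for m in self.base_models]
        if ffmods != [0, 1, 2]:
            raise ValueError(f"base models must be in ffmod order 0,1,2, got {ffmods}")
        if self.rule not in RULES:
            raise ValueError(f"unsupported rule {self.rule!r}; choose from {RULES}")


def collect_meta_features(
    ensemble: StackedEnsemble, records: list[ProteinRecord]
) -> np.ndarray:
    """Per-residue base probabilities, columns in fixed ffmod order 0, 1, 2."""
    cols = []
    for net in ensemble.base_models:
        if not net.trained:
            raise ValueError(f"base model for ffmod {net.config.ffmod} is untrained")
        tr, ctx, mask, _, _ = featurize_dataset(records, net.config.window, net.config.ffmod)
        cols.append(net.predict(ctx, mask, tr))
    return np.column_stack(cols)


def fit_meta_learner(meta_features, labels, rule: str, seed: int = 0):
    """Fit the named meta rule on held-out meta-features.

    ``voting`` and ``averaging`` need no fit and return None.
    """
    if rule not in RULES:
        raise ValueError(f"unsupported rule {rule!r}; choose from {RULES}")
    if rule in ("voting", "averaging"):
        return None
    X = np.asarray(meta_features, dtype=float)
    y = np.asarray(labels)
    if rule == "linear_mse":
        # least-squares linear rule on [1 | X]
        A = np.column_stack([np.ones(len(X)), X])
        coef, *_ = np.linalg.lstsq(A, y.astype(float), rcond=None)
        return coef
    if len(np.unique(y)) < 2:
        raise ValueError("single-class labels cannot fit a trainable meta rule")
    if rule == "logistic_regression":
        clf = LogisticRegression(max_iter=5000, tol=1e-10)
    elif rule == "decision_tree":
        clf = DecisionTreeClassifier(random_state=seed)
    elif rule == "random_forest":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    else:  # nearest_neighbor
        clf = KNeighborsClassifier()
    clf.fit(X, y)
    return clf


def ensemble_predict(
    ensemble: StackedEnsemble, records: list[ProteinRecord]
) -> tuple[np.ndarray | None, np.ndarray]:
    """Ensemble probabilities and thresholded calls per residue.

    Voting emits no probability (scores is None); its call is the majority
    of the thresholded base calls, ties broken toward the positive class.
    """
    meta_X = collect_meta_features(ensemble, records)
    return _predict_from_meta(ensemble, meta_X)


def _predict_from_meta(
    ensemble: StackedEnsemble, meta_X: np.ndarray
) -> tuple[np.ndarray | None, np.ndarray]:
    rule, thr = ensemble.rule, ensemble.threshold
    if rule == "averaging":
        scores = meta_X.mean(axis=1)
        return scores, (scores >= thr).astype(int)
    if rule == "voting":
        votes = (meta_X >= thr).sum(axis=1)
        calls = (votes >= (meta_X.shape[1] + 1) // 2).astype(int)
        return None, calls
    if ensemble.meta is None:
        raise ValueError(f"rule {rule!r} requires a fitted meta learner")
    if rule == "linear_mse":
        scores = np.clip(
            np.column_stack([np.ones(len(meta_X)), meta_X]) @ ensemble.meta, 0.0, 1.0
        )
    else:
        scores = ensemble.meta.predict_proba(meta_X)[:, list(ensemble.meta.classes_).index(1)]
    return scores, (scores >= thr).astype(int)


def train_stacked_ensemble(
    base_models: list[SiteNet],
    val_records: list[ProteinRecord],
    rule: str = "logistic_regression",
    threshold: float = 0.5,
    seed: int = 0,
) -> StackedEnsemble:
    """Assemble the ensemble and fit its meta rule on the validation split."""
    ensemble = StackedEnsemble(base_models=base_models, rule=rule, threshold=threshold)
    if rule not in ("voting", "averaging"):
        meta_X = collect_meta_features(ensemble, val_records)
        y = np.concatenate([rec.labels for rec in val_records])
        ensemble.meta = fit_meta_learner(meta_X, y, rule, seed=seed)
    return ensemble


def save_ensemble(ensemble: StackedEnsemble, outdir: str | Path) -> None:
    """Serialize as a directory: three checkpoints + meta parameters + manifest."""
    import json
    import pickle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for net in ensemble.base_models:
        net.save(outdir / f"base_ffmod{net.config.ffmod}.npz")
    with (outdir / "meta.pkl").open("wb") as fh:
        pickle.dump(ensemble.meta, fh)
    manifest = {"rule": ensemble.rule, "threshold": ensemble.threshold}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_ensemble(outdir: str | Path) -> StackedEnsemble:
    import json
    import pickle

    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    bases = [SiteNet.load(outdir / f"base_ffmod{f}.npz") for f in (0, 1, 2)]
    with (outdir / "meta.pkl").open("rb") as fh:
        meta = pickle.load(fh)
    return StackedEnsemble(
        base_models=bases, rule=manifest["rule"], meta=meta,
        threshold=manifest["threshold"],
    )
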