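"""Activity-probability reward: ECFP6 random forest behind a pure reward interface.

The search maximizes the predicted probability that a molecule is active
against a target.  A random forest classifier is trained on 2048-bit ECFP6
fingerprints of active/inactive labelled molecules; its positive-class
probability (the raw averaged tree vote) is the reward, always in [0, 1].

Hyperparameter presets carry the per-target values tuned at full scale
("drd2", "akt1", "cxcr4"); the "toy" preset is a small forest for the
synthetic activity task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import train_test_split

from .chem import ECFP6, canonical_smiles, fingerprint, is_valid_smiles


@dataclass(frozen=True)
class RFHyperparams:
    bootstrap: bool = True
    max_depth: int | None = None
    max_features: float | str = "sqrt"
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    n_estimators: int = 100


PRESETS: dict[str, RFHyperparams] = {
    "toy": RFHyperparams(),
    "drd2": RFHyperparams(
        bootstrap=False, max_depth=429, max_features=0.0749,
        min_samples_split=2, min_samples_leaf=2, n_estimators=151,
    ),
    "akt1": RFHyperparams(
        bootstrap=False, max_depth=410, max_features=0.0690,
        min_samples_split=2, min_samples_leaf=5, n_estimators=158,
    ),
    "cxcr4": RFHyperparams(
        bootstrap=False, max_depth=498, max_features=0.225,
        min_samples_split=5, min_samples_leaf=1, n_estimators=223,
    ),
}


class QSARReward:
    """Pure callable SMILES -> activity probability in [0, 1].

    Results are cached by canonical SMILES, so repeated evaluation of the
    same molecule during a search is free and provably identical.
    """

    def __init__(self, model: RandomForestClassifier):
        self._model = model
        self._cache: dict[str, float] = {}

    def __call__(self, smiles: str) -> float:
        if not is_valid_smiles(smiles):
            raise ValueError(f"invalid SMILES: {smiles!r}")
        can = canonical_smiles(smiles)
        hit = self._cache.get(can)
        if hit is None:
            x = fingerprint(can, ECFP6)[None, :]
            proba = self._model.predict_proba(x)[0]
            idx = list(self._model.classes_).index(1)
            hit = float(proba[idx])
            assert 0.0 <= hit <= 1.0
            self._cache[can] = hit
        return hit


@dataclass
class QSARReport:
    accuracy: float
    auc: float
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "auc": self.auc,
                "n_train": self.n_train, "n_test": self.n_test}


def train_qsar(
    data: pd.DataFrame,
    hp: RFHyperparams | str = "toy",
    seed: int = 0,
    test_fraction: float = 0.1,
) -> tuple[QSARReward, QSARReport]:
    """Fit the activity forest on a ``smiles,label`` table.

    The held-out split is stratified by class.  Raises if a canonical
    molecule would land in both train and test (leakage), or if either class
    is empty.
    """
    if isinstance(hp, str):
        hp = PRESETS[hp]
    smiles = [canonical_smiles(s) for s in data["smiles"]]
    labels = np.asarray(data["label"], dtype=int)
    if len(set(labels)) < 2:
        raise ValueError("need both active and inactive molecules")
    # deduplicate by canonical SMILES before splitting so no molecule leaks
    seen: dict[str, int] = {}
    for s, y in zip(smiles, labels):
        if s in seen and seen[s] != y:
            raise ValueError(f"molecule {s} carries conflicting labels")
        seen[s] = y
    uniq_smiles = list(seen)
    uniq_labels = np.array([seen[s] for s in uniq_smiles])
    X = np.stack([fingerprint(s, ECFP6) for s in uniq_smiles])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, uniq_labels, test_size=test_fraction, stratify=uniq_labels, random_state=seed
    )
    model = RandomForestClassifier(
        bootstrap=hp.bootstrap,
        max_depth=hp.max_depth,
        max_features=hp.max_features,
        min_samples_split=hp.min_samples_split,
        min_samples_leaf=hp.min_samples_leaf,
        n_estimators=hp.n_estimators,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X_tr, y_tr)
    idx = list(model.classes_).index(1)
    probs = model.predict_proba(X_te)[:, idx]
    report = QSARReport(
        accuracy=float(accuracy_score(y_te, (probs > 0.5).astype(int))),
        auc=float(roc_auc_score(y_te, probs)),
        n_train=len(y_tr),
        n_test=len(y_te),
    )
    return QSARReward(model), report


def auc_by_concordance(labels: np.ndarray, scores: np.ndarray) -> float:
    """Brute-force pairwise-concordance AUC (independent check of the ROC AUC)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg)))
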