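"""Two-stage activity classification from per-window movement features.

Stage 1 predicts the four mutually exclusive main activities (grazing,
walking, standing, lying) from standardized, PCA-projected accelerometer
plus individual-GPS window features.  Stage 2 predicts a binary
rumination flag on standing/lying windows only, from the same projected
features plus a posture indicator — the observed posture at training
time, the stage-1 prediction at inference time (no train-time leakage of
predictions).  All data splits are blocked by clock hour to respect the
strong autocorrelation of movement data.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import MAIN_CLASSES
from .metrics import mean_balanced_accuracy

logger = logging.getLogger("envtrace")


def hour_blocked_split(hour_keys: np.ndarray, test_fraction: float = 0.2,
                       seed: int = 0):
    """Assign whole hours to train/test; returns boolean masks (train, test)."""
    keys = np.asarray(hour_keys)
    uniq = np.unique(keys)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct hours to split")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(uniq)
    n_test = max(1, int(round(test_fraction * uniq.size)))
    test_hours = set(shuffled[:n_test].tolist())
    test = np.array([k in test_hours for k in keys])
    return ~test, test


def cv_folds_by_hour(hour_keys: np.ndarray, k: int = 5, seed: int = 0):
    """Hour-disjoint cross-validation folds of near-equal hour counts.

    Returns a list of k boolean masks (validation-fold membership).
    """
    keys = np.asarray(hour_keys)
    uniq = np.unique(keys)
    if uniq.size < k:
        raise ValueError(f"need at least {k} distinct hours for {k} folds")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(uniq)
    folds = []
    for part in np.array_split(shuffled, k):
        members = set(part.tolist())
        folds.append(np.array([key in members for key in keys]))
    return folds


@dataclass
class ClassifierConfig:
    """Backend and reduced-dimension settings for the two-stage model."""

    backend: str = "svm"          # "svm" (RBF, one-against-one) or "rf"
    n_components: int = 20
    window_s: float = 3.0
    cost: float = 1.0             # SVM
    gamma: str | float = "scale"  # SVM
    class_weight: object = None   # SVM
    n_trees: int = 500            # RF
    mtry: object = "sqrt"         # RF max_features
    min_node_size: int = 1        # RF min_samples_leaf
    sample_frac: float = 1.0      # RF bootstrap sample size
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def make_backend(self, seed_offset: int = 0):
        if self.backend == "svm":
            return SVC(kernel="rbf", C=self.cost, gamma=self.gamma,
                       class_weight=self.class_weight,
                       random_state=self.seed + seed_offset)
        if self.backend == "rf":
            return RandomForestClassifier(
                n_estimators=self.n_trees, max_features=self.mtry,
                min_samples_leaf=self.min_node_size,
                max_samples=None if self.sample_frac >= 1.0 else self.sample_frac,
                random_state=self.seed + seed_offset, n_jobs=1)
        raise ValueError(f"unknown backend {self.backend!r}")


class ActivityModel:
    """Fitted two-stage activity classifier.

    Standardization and principal axes are estimated from the training
    rows only and reused verbatim at prediction time.
    """

    def __init__(self, config: ClassifierConfig):
        self.config = config
        self.scaler: StandardScaler | None = None
        self.pca: PCA | None = None
        self.stage1 = None
        self.stage2 = None

    # posture indicator: 1 = lying, 0 = standing
    @staticmethod
    def _posture(labels: np.ndarray) -> np.ndarray:
        return (np.asarray(labels) == "lying").astype(float)

    def fit(self, features: np.ndarray, main_labels: np.ndarray,
            ruminating: np.ndarray):
        features = np.asarray(features, float)
        main_labels = np.asarray(main_labels)
        ruminating = np.asarray(ruminating, bool)
        present = set(np.unique(main_labels))
        missing = set(MAIN_CLASSES) - present
        if missing:
            raise ValueError(f"classes absent from training data: {sorted(missing)}")

        self.scaler = StandardScaler().fit(features)
        z = self.scaler.transform(features)
        n_comp = min(self.config.n_components, z.shape[1], z.shape[0])
        self.pca = PCA(n_components=n_comp, random_state=self.config.seed).fit(z)
        pcs = self.pca.transform(z)

        self.stage1 = self.config.make_backend().fit(pcs, main_labels)

        posture_rows = np.isin(main_labels, ("standing", "lying"))
        if posture_rows.any() and len(np.unique(ruminating[posture_rows])) == 2:
            x2 = np.column_stack([pcs[posture_rows],
                                  self._posture(main_labels[posture_rows])])
            self.stage2 = self.config.make_backend(seed_offset=1).fit(
                x2, ruminating[posture_rows])
        else:
            logger.warning("stage-2 rumination model not trained "
                           "(missing posture rows or single rumination class)")
        return self

    def _project(self, features: np.ndarray) -> np.ndarray:
        return self.pca.transform(self.scaler.transform(np.asarray(features, float)))

    def predict(self, features: np.ndarray) -> pd.DataFrame:
        """Main class for every window; rumination via stage 2 on windows
        predicted standing/lying (others are not-ruminating)."""
        pcs = self._project(features)
        main = self.stage1.predict(pcs)
        rum = np.zeros(len(main), dtype=bool)
        mask = np.isin(main, ("standing", "lying"))
        if self.stage2 is not None and mask.any():
            x2 = np.column_stack([pcs[mask], self._posture(main[mask])])
            rum[mask] = np.asarray(self.stage2.predict(x2), bool)
        return pd.DataFrame({"main_class": main, "ruminating": rum})


def fit_activity_model(features, main_labels, ruminating,
                       config: ClassifierConfig) -> ActivityModel:
    return ActivityModel(config).fit(features, main_labels, ruminating)


def _config_complexity(cfg: ClassifierConfig):
    return (cfg.n_components,
            cfg.cost if cfg.backend == "svm" else cfg.n_trees)


def grid_search_activity(features, main_labels, ruminating, hour_keys,
                         grid: list[ClassifierConfig], k: int = 5,
                         seed: int = 0):
    """Evaluate each config by its mean over k hour-blocked folds of the
    cross-validated mean balanced accuracy (stage 1); ties go to the
    lowest-complexity config.

    Returns (best_config, report) where the report has one row per config.
    """
    if not grid:
        raise ValueError("empty grid")
    features = np.asarray(features, float)
    main_labels = np.asarray(main_labels)
    ruminating = np.asarray(ruminating, bool)
    folds = cv_folds_by_hour(hour_keys, k=k, seed=seed)
    rows = []
    for cfg in grid:
        scores = []
        for val_mask in folds:
            tr = ~val_mask
            if set(np.unique(main_labels[val_mask])) - set(
                    np.unique(main_labels[tr])):
                continue
            model = ActivityModel(cfg).fit(features[tr], main_labels[tr],
                                           ruminating[tr])
            pred = model.predict(features[val_mask])
            scores.append(mean_balanced_accuracy(
                main_labels[val_mask], pred["main_class"].to_numpy(),
                classes=list(MAIN_CLASSES)))
        rows.append({"config": cfg, "cv_mean_balanced_accuracy":
                     float(np.mean(scores)) if scores else np.nan,
                     "n_folds_scored": len(scores)})
    report = pd.DataFrame(rows)
    best_score = report["cv_mean_balanced_accuracy"].max()
    tied = report[np.isclose(report["cv_mean_balanced_accuracy"], best_score)]
    if len(tied) > 1:
        logger.info("grid tie among %d configs; choosing lowest complexity",
                    len(tied))
    best = min(tied["config"], key=_config_complexity)
    return best, report


def make_grid(base: ClassifierConfig, **axes) -> list[ClassifierConfig]:
    """Cartesian-product grid of configs over keyword value lists."""
    keys = list(axes)
    out = []
    for combo in itertools.product(*(axes[k] for k in keys)):
        cfg = ClassifierConfig(**{**base.__dict__, **dict(zip(keys, combo))})
        out.append(cfg)
    return out
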