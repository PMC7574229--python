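"""Environmental-influence quantification.

A regression backend (epsilon-insensitive kernel regression or a
randomized-tree ensemble) predicts an environmental target from the
per-family movement principal components; the coefficient of
determination on a session-held-out test set is the influence measure
(0 = no influence, negative values allowed).  Fitting influence models
per sensor family and combined allows the explained variation to be
partitioned into family-independent and shared components.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR

from .activity import cv_folds_by_hour, hour_blocked_split  # noqa: F401
from .hourly import (SensorFamilyProjection, fit_family_projection,
                     standardize_day_night)
from .metrics import partition_variation, r_squared

logger = logging.getLogger("envtrace")

TARGETS = ("biomass", "time_since_milking", "wind")


def session_split(records: pd.DataFrame, test_session) -> tuple:
    """Split hourly records by pasture-plot session; warns when the
    held-out target ranges exceed the training ranges (extrapolation)."""
    sessions = set(records["session_id"].unique())
    if test_session not in sessions:
        raise ValueError(f"unknown session {test_session!r}; have {sorted(sessions)}")
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions to split")
    test = records["session_id"] == test_session
    train_df, test_df = records[~test].copy(), records[test].copy()
    for target in TARGETS:
        if target in records.columns:
            lo, hi = train_df[target].min(), train_df[target].max()
            if (test_df[target].min() < lo) or (test_df[target].max() > hi):
                logger.warning("test-set %s range [%.3g, %.3g] not contained "
                               "in train range [%.3g, %.3g]", target,
                               test_df[target].min(), test_df[target].max(),
                               lo, hi)
    return train_df, test_df


@dataclass
class RegressorConfig:
    """Backend and feature-family settings for one influence model."""

    backend: str = "svr"                  # "svr" or "rfr"
    families: tuple = ("gps", "acc")
    n_components: dict = field(default_factory=lambda: {"gps": 20, "acc": 20})
    cost: float = 1.0                     # SVR
    gamma: str | float = "scale"          # SVR
    epsilon: float = 0.1                  # SVR
    n_trees: int = 1000                   # RFR
    seed: int = 0

    def make_backend(self):
        if self.backend == "svr":
            return SVR(kernel="rbf", C=self.cost, gamma=self.gamma,
                       epsilon=self.epsilon)
        if self.backend == "rfr":
            return RandomForestRegressor(n_estimators=self.n_trees,
                                         random_state=self.seed, n_jobs=1)
        raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class InfluenceResult:
    """Test-set influence of one environmental target."""

    target: str
    config: RegressorConfig
    r2_test: float
    observed: np.ndarray
    predicted: np.ndarray
    train_sessions: tuple
    test_session: object

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"observed": self.observed,
                             "predicted": self.predicted})


def _project(train_df, test_df, config: RegressorConfig,
             projections: dict | None = None):
    if projections is None:
        projections = {
            fam: fit_family_projection(train_df, fam,
                                       config.n_components.get(fam, 20))
            for fam in config.families
        }
    xtr = np.hstack([projections[f].transform(train_df) for f in config.families])
    xte = np.hstack([projections[f].transform(test_df) for f in config.families])
    return xtr, xte, projections


def fit_and_score(train_df: pd.DataFrame, test_df: pd.DataFrame, target: str,
                  config: RegressorConfig,
                  projections: dict[str, SensorFamilyProjection] | None = None
                  ) -> InfluenceResult:
    """Fit one influence model on training hours, score Eq.-style R^2 on the
    held-out session.  Family projections are fitted on the training rows
    only (or passed in, pre-fitted on training rows)."""
    y_tr = train_df[target].to_numpy(float)
    y_te = test_df[target].to_numpy(float)
    if np.std(y_tr) == 0 or np.std(y_te) == 0:
        raise ValueError(f"degenerate target {target!r} (zero variance)")
    xtr, xte, _ = _project(train_df, test_df, config, projections)
    # the target is standardized with training moments so cost/epsilon act
    # on a comparable scale for every environmental variable
    y_mean, y_sd = y_tr.mean(), y_tr.std()
    model = config.make_backend().fit(xtr, (y_tr - y_mean) / y_sd)
    pred = model.predict(xte) * y_sd + y_mean
    return InfluenceResult(
        target=target, config=config, r2_test=r_squared(y_te, pred),
        observed=y_te, predicted=pred,
        train_sessions=tuple(sorted(train_df["session_id"].unique())),
        test_session=test_df["session_id"].iloc[0],
    )


def _complexity(cfg: RegressorConfig):
    return (sum(cfg.n_components.get(f, 0) for f in cfg.families),
            cfg.cost if cfg.backend == "svr" else cfg.n_trees)


def grid_search_regressor(train_df: pd.DataFrame, test_df: pd.DataFrame,
                          target: str, grid: list[RegressorConfig],
                          mode: str = "nested", seed: int = 0, k: int = 5):
    """Select hyperparameters over a config grid.

    mode "paper" selects on the held-out test R^2 (reproduction of the
    original selection rule; optimistically biased and flagged as such in
    the report).  mode "nested" (default) selects on k-fold hour-blocked
    cross-validation inside the training sessions — averaging over folds
    keeps a flexible config from winning a single small validation split
    by chance — then reports the chosen config's test R^2.  Ties go to
    the lowest-complexity config.
    """
    if not grid:
        raise ValueError("empty grid")
    if mode not in ("paper", "nested"):
        raise ValueError("mode must be 'paper' or 'nested'")

    if mode == "nested":
        folds = cv_folds_by_hour(train_df["hour_key"].to_numpy(), k=k,
                                 seed=seed)

    rows = []
    for cfg in grid:
        if mode == "paper":
            score, se = fit_and_score(train_df, test_df, target,
                                      cfg).r2_test, 0.0
        else:
            fold_scores = []
            for val_mask in folds:
                res = fit_and_score(train_df[~val_mask], train_df[val_mask],
                                    target, cfg)
                fold_scores.append(res.r2_test)
            score = float(np.mean(fold_scores))
            se = float(np.std(fold_scores, ddof=1) / np.sqrt(len(fold_scores)))
        rows.append({"config": cfg, "selection_r2": score,
                     "selection_se": se, "mode": mode})
    report = pd.DataFrame(rows)
    report["selection_biased"] = mode == "paper"
    best_score = report["selection_r2"].max()
    if mode == "nested" and best_score <= 0:
        # no config beats the mean predictor in cross-validation: there is
        # no evidence of signal, so the most parsimonious config stands in
        # for the null model
        best = min(report["config"], key=_complexity)
    else:
        tied = report[np.isclose(report["selection_r2"], best_score)]
        best = min(tied["config"], key=_complexity)
    final = fit_and_score(train_df, test_df, target, best)
    return best, final, report


def influence_with_partition(train_df: pd.DataFrame, test_df: pd.DataFrame,
                             target: str, config: RegressorConfig) -> dict:
    """Influence for combined, GPS-only and ACC-only feature sets plus the
    two-set variation partition (identity holds exactly)."""
    projections = {
        fam: fit_family_projection(train_df, fam,
                                   config.n_components.get(fam, 20))
        for fam in ("gps", "acc")
    }
    results = {}
    for fams in (("acc",), ("gps",), ("gps", "acc")):
        cfg = RegressorConfig(**{**config.__dict__, "families": fams})
        res = fit_and_score(train_df, test_df, target, cfg,
                            {f: projections[f] for f in fams})
        results[fams] = res
    part = partition_variation(results[("acc",)].r2_test,
                               results[("gps",)].r2_test,
                               results[("gps", "acc")].r2_test)
    part["target"] = target
    return {"results": results, "partition": part}


def make_regressor_grid(base: RegressorConfig, **axes) -> list[RegressorConfig]:
    """Cartesian-product grid of regressor configs."""
    keys = list(axes)
    out = []
    for combo in itertools.product(*(axes[k] for k in keys)):
        out.append(RegressorConfig(**{**base.__dict__, **dict(zip(keys, combo))}))
    return out


def default_svr_grid(seed: int = 0) -> list[RegressorConfig]:
    """The reduced kernel-regression grid used for routine runs: cost and
    tube width span flat to flexible fits (on the standardized target
    scale), with two component counts per family."""
    # the lowest cost level is effectively the mean predictor: the null
    # baseline of the influence measure must be reachable by selection
    return make_regressor_grid(
        RegressorConfig(seed=seed),
        cost=[0.03, 0.3, 3.0, 30.0],
        epsilon=[0.1, 0.5],
        n_components=[{"gps": 5, "acc": 5}, {"gps": 15, "acc": 15}])


def quantify(records: pd.DataFrame, target: str, test_session=2,
             grid: list[RegressorConfig] | None = None, mode: str = "nested",
             seed: int = 0, families: bool = True) -> dict:
    """Standardize, split by session, select hyperparameters (per feature
    family, as each dataset gets its own optimum) and return the influence
    estimate with its sensor-family partition."""
    train, test, _ = prepare_design(records, test_session)
    if grid is None:
        grid = default_svr_grid(seed)
    family_sets = ([("acc",), ("gps",), ("gps", "acc")] if families
                   else [("gps", "acc")])
    results, configs = {}, {}
    for fams in family_sets:
        fam_grid = [RegressorConfig(**{**cfg.__dict__, "families": fams})
                    for cfg in grid]
        best, final, _ = grid_search_regressor(train, test, target, fam_grid,
                                               mode=mode, seed=seed)
        results[fams] = final
        configs[fams] = best
    out = {"results": results, "configs": configs,
           "r2_test": results[("gps", "acc")].r2_test}
    if families:
        part = partition_variation(results[("acc",)].r2_test,
                                   results[("gps",)].r2_test,
                                   results[("gps", "acc")].r2_test)
        part["target"] = target
        out["partition"] = part
    return out


def prepare_design(records: pd.DataFrame, test_session):
    """Standardize hourly records (training parameters only) and return the
    (train, test) frames ready for influence fitting."""
    train_mask = (records["session_id"] != test_session).to_numpy()
    z, params = standardize_day_night(records, train_mask)
    return (*session_split(z, test_session), params)
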