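"""Random-forest feature elimination and the RF / LM / LMM comparison harness.

Random forests follow the ecology convention: ``mtry`` candidate predictors
per split (default ``max(1, floor((K - 1) / 3))`` for K predictors) and a
minimum terminal-node size of 5.  Performance is scored by 5-fold
cross-validated R^2, computed per fold as ``1 - SSE/SST`` on the held-out
fold and averaged (a pooled-prediction variant is available).

Recursive feature elimination starts from the full predictor set and, at each
step, drops the predictor whose removal costs the least cross-validated R^2;
the resulting nested path supports a parsimonious final-set rule (smallest
set within a tolerance of the path maximum).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression

from . import variance_partition as vp
from .dataset import (
    TRAITS,
    Dataset,
    aggregate_sites,
    center_within_species,
    log_transform,
)


class DegenerateFoldError(ValueError):
    """A CV fold had zero target variance; use fewer folds or more data."""


def default_mtry(k: int) -> int:
    """Number of split candidates for k predictors: max(1, floor((k-1)/3))."""
    return max(1, (k - 1) // 3)


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters."""

    mtry: int
    min_node_size: int = 5
    n_trees: int = 500
    seed: int = 0

    def build(self) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=self.mtry,
            min_samples_leaf=self.min_node_size,
            random_state=self.seed,
            n_jobs=1,
        )


@dataclass(frozen=True)
class CVScheme:
    """K-fold assignment by uniform random permutation (fold sizes differ by <= 1)."""

    n_folds: int = 5
    seed: int = 0

    def assign(self, n: int) -> np.ndarray:
        if n < self.n_folds:
            raise ValueError(f"need >= {self.n_folds} records for {self.n_folds}-fold CV, got {n}")
        rng = np.random.default_rng(self.seed)
        folds = np.arange(n) % self.n_folds
        return folds[rng.permutation(n)]


def _as_matrix(predictors) -> tuple[np.ndarray, list[str]]:
    if isinstance(predictors, pd.DataFrame):
        X = predictors.to_numpy(float)
        names = list(predictors.columns)
    else:
        X = np.asarray(predictors, float)
        names = [f"x{i}" for i in range(X.shape[1])]
    if not np.isfinite(X).all():
        bad = names[int(np.argwhere(~np.isfinite(X))[0][1])]
        raise ValueError(f"non-finite values in predictor {bad!r}")
    return X, names


def _cv_scores(X, y, model_factory, scheme: CVScheme, metric: str) -> np.ndarray:
    y = np.asarray(y, float)
    folds = scheme.assign(len(y))
    scores = np.empty(scheme.n_folds)
    for f in range(scheme.n_folds):
        test = folds == f
        model = model_factory()
        model.fit(X[~test], y[~test])
        pred = model.predict(X[test])
        sst = float(np.sum((y[test] - y[test].mean()) ** 2))
        sse = float(np.sum((y[test] - pred) ** 2))
        if metric == "rmse":
            scores[f] = np.sqrt(sse / test.sum())
        else:
            if sst == 0.0:
                raise DegenerateFoldError(
                    "held-out fold has zero target variance; use larger folds or more data"
                )
            scores[f] = 1.0 - sse / sst
    return scores


def cv_r2(predictors, target, model_factory, scheme: CVScheme = CVScheme(),
          pooled: bool = False) -> float:
    """Cross-validated R^2 of ``model_factory()`` on (predictors, target).

    Per-fold R^2 (1 - SSE/SST on the held-out fold) averaged over folds; with
    ``pooled=True``, a single R^2 over the pooled out-of-fold predictions.
    """
    X, _ = _as_matrix(predictors)
    y = np.asarray(target, float)
    if not pooled:
        return float(_cv_scores(X, y, model_factory, scheme, "r2").mean())
    folds = scheme.assign(len(y))
    pred = np.empty_like(y)
    for f in range(scheme.n_folds):
        test = folds == f
        model = model_factory()
        model.fit(X[~test], y[~test])
        pred[test] = model.predict(X[test])
    return float(1.0 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2))


def cv_rmse(predictors, target, model_factory, scheme: CVScheme = CVScheme()) -> float:
    """Mean held-out RMSE over the CV folds."""
    X, _ = _as_matrix(predictors)
    return float(_cv_scores(X, np.asarray(target, float), model_factory, scheme, "rmse").mean())


def tune_rf(predictors, target, grid, scheme: CVScheme = CVScheme(),
            n_trees: int = 500, seed: int = 0) -> RFConfig:
    """Pick the (mtry, min_node_size) grid point minimizing mean CV RMSE.

    Ties break toward smaller mtry, then larger min_node_size (the more
    regularized forest).
    """
    best: tuple | None = None
    for mtry, mns in grid:
        cfg = RFConfig(mtry=int(mtry), min_node_size=int(mns), n_trees=n_trees, seed=seed)
        rmse = cv_rmse(predictors, target, cfg.build, scheme)
        key = (rmse, cfg.mtry, -cfg.min_node_size)
        if best is None or key < best[0]:
            best = (key, cfg)
    return best[1]


@dataclass
class RFEStep:
    """One elimination: the set size and score before removing ``eliminated``."""

    k: int
    mtry: int
    cv_r2_before: float
    eliminated: str


@dataclass
class RFEPath:
    """Nested predictor sets from full model down to a single predictor."""

    steps: list[RFEStep]
    scores_by_size: dict[int, float]
    sets_by_size: dict[int, tuple[str, ...]]

    @property
    def elimination_order(self) -> list[str]:
        """Predictors from first-removed to last-surviving."""
        order = [s.eliminated for s in self.steps]
        order.extend(self.sets_by_size[1])
        return order

    def surviving_set(self, k: int) -> tuple[str, ...]:
        return self.sets_by_size[k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"k": s.k, "mtry": s.mtry, "cv_r2": s.cv_r2_before, "eliminated": s.eliminated}
                for s in self.steps
            ]
        )


def rfe(predictors: pd.DataFrame, target, scheme: CVScheme = CVScheme(),
        min_node_size: int = 5, n_trees: int = 500, seed: int = 0) -> RFEPath:
    """Recursive feature elimination with random forests.

    At each step, the forest for the current K' predictors uses
    ``mtry = max(1, floor((K'-1)/3))``; the candidate whose removal leaves
    the highest CV R^2 (the smallest decrease) is eliminated.  Scores are
    recorded for every nested set size down to 1.
    """
    X, names = _as_matrix(predictors)
    if len(names) < 2:
        raise ValueError("recursive feature elimination needs at least 2 predictors")
    predictors = pd.DataFrame(X, columns=names)
    y = np.asarray(target, float)

    current = list(names)
    steps: list[RFEStep] = []
    scores: dict[int, float] = {}
    sets: dict[int, tuple[str, ...]] = {}

    def score(cols: list[str]) -> float:
        cfg = RFConfig(mtry=default_mtry(len(cols)), min_node_size=min_node_size,
                       n_trees=n_trees, seed=seed)
        return cv_r2(predictors[cols], y, cfg.build, scheme)

    while True:
        k = len(current)
        sets[k] = tuple(current)
        scores[k] = score(current)
        if k == 1:
            break
        best_candidate, best_score = None, -np.inf
        for cand in current:
            remaining = [c for c in current if c != cand]
            s = score(remaining)
            if s > best_score:
                best_candidate, best_score = cand, s
        steps.append(
            RFEStep(k=k, mtry=default_mtry(k), cv_r2_before=scores[k], eliminated=best_candidate)
        )
        current.remove(best_candidate)
    return RFEPath(steps=steps, scores_by_size=scores, sets_by_size=sets)


def select_final_set(path: RFEPath, tol: float = 0.01) -> tuple[str, ...]:
    """Smallest nested set whose CV R^2 is within ``tol`` of the path maximum."""
    best = max(path.scores_by_size.values())
    for k in sorted(path.scores_by_size):
        if path.scores_by_size[k] >= best - tol:
            return path.sets_by_size[k]
    raise AssertionError("unreachable: the argmax set always qualifies")


def one_hot_identity(ds: Dataset, levels=("species", "genus", "family")) -> pd.DataFrame:
    """Indicator matrix for taxonomic identity (one column per observed level)."""
    cols = [c for c in levels if c in ds.df.columns]
    return pd.get_dummies(ds.df[cols], prefix=cols, dtype=float)


def decode_one_hot(encoded: pd.DataFrame, level: str = "species") -> pd.Series:
    """Recover the taxon labels of one level from the indicator matrix."""
    block = encoded.filter(regex=f"^{level}_")
    labels = block.idxmax(axis=1).str.removeprefix(f"{level}_")
    return labels.rename(level)


@dataclass
class GridCell:
    trait: str
    data_version: str  # "full" | "site" | "within"
    model: str  # "RF" | "LM" | "LMM" | "RF_identity_only"
    metric: str  # "cv_r2" | "r2_marginal" | "icc"
    value: float | None
    flagged: str | None = None


@dataclass
class ModelComparisonGrid:
    """Scores for every (trait, data version, model) combination."""

    cells: list[GridCell] = field(default_factory=list)
    env_contribution: dict[str, float] = field(default_factory=dict)

    def value(self, trait: str, data_version: str, model: str, metric: str = "cv_r2"):
        for c in self.cells:
            if (c.trait, c.data_version, c.model, c.metric) == (trait, data_version, model, metric):
                return c.value
        raise KeyError((trait, data_version, model, metric))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses_asdict(c) for c in self.cells])

    @property
    def n_flagged(self) -> int:
        return sum(1 for c in self.cells if c.flagged)


def dataclasses_asdict(cell: GridCell) -> dict:
    return {
        "trait": cell.trait,
        "data_version": cell.data_version,
        "model": cell.model,
        "metric": cell.metric,
        "value": cell.value,
        "flagged": cell.flagged,
    }


def compare_models(
    ds: Dataset,
    selected: dict[str, list[str]],
    traits=TRAITS,
    scheme: CVScheme = CVScheme(),
    n_trees: int = 300,
    min_node_size: int = 5,
    seed: int = 0,
    log_traits: bool = True,
    lmm_transform: str | None = "yeo-johnson",
) -> ModelComparisonGrid:
    """Fit RF / LM / LMM across the three data versions and fill the grid.

    Data versions: ``full`` (one row per record), ``site`` (community means
    per site) and ``within`` (species-centered records).  RF is fitted to all
    three; LM to site and within (where species effects are absent by
    construction); the LMM (species random intercepts) to the full data.  The
    environment-only contribution per trait is the difference between the
    full RF with environment + identity predictors and an RF with identity
    predictors alone.  Concentrations are log-transformed first by default
    (they are lognormal-like; the generative structure is additive on logs).

    Cells that cannot be fitted (e.g., zero within-species variance in a
    niche-only world) are flagged and left as None; the run continues.
    """
    work = log_transform(ds, traits=[t for t in traits]) if log_traits else ds
    grid = ModelComparisonGrid()

    site = aggregate_sites(work)
    within = center_within_species(work, traits=traits)
    identity = one_hot_identity(work)

    def rf_factory(k: int):
        return RFConfig(mtry=default_mtry(k), min_node_size=min_node_size,
                        n_trees=n_trees, seed=seed).build

    def try_cell(trait, version, model, fn):
        try:
            grid.cells.append(GridCell(trait, version, model, "cv_r2", fn()))
        except (DegenerateFoldError, ValueError) as exc:
            grid.cells.append(GridCell(trait, version, model, "cv_r2", None, flagged=str(exc)))

    for trait in traits:
        env = list(selected[trait])

        # --- site-aggregated version: RF and LM on community means
        Xs, ys = site[env], site[trait]
        if np.ptp(ys.to_numpy()) < 1e-12:
            for model in ("RF", "LM"):
                grid.cells.append(
                    GridCell(trait, "site", model, "cv_r2", None, flagged="zero site-level variance")
                )
        else:
            try_cell(trait, "site", "RF", lambda: cv_r2(Xs, ys, rf_factory(len(env)), scheme))
            try_cell(trait, "site", "LM", lambda: cv_r2(Xs, ys, LinearRegression, scheme))

        # --- within-species version
        Xw, yw = within.df[env], within.df[trait]
        if float(np.var(yw.to_numpy())) < 1e-14:
            for model in ("RF", "LM"):
                grid.cells.append(
                    GridCell(trait, "within", model, "cv_r2", None,
                             flagged="zero within-species variance")
                )
        else:
            try_cell(trait, "within", "RF", lambda: cv_r2(Xw, yw, rf_factory(len(env)), scheme))
            try_cell(trait, "within", "LM", lambda: cv_r2(Xw, yw, LinearRegression, scheme))

        # --- full version: RF with env + identity, RF identity-only, LMM
        Xf = pd.concat([work.df[env].reset_index(drop=True), identity.reset_index(drop=True)], axis=1)
        yf = work.df[trait]
        try_cell(trait, "full", "RF", lambda: cv_r2(Xf, yf, rf_factory(Xf.shape[1]), scheme))
        try_cell(trait, "full", "RF_identity_only",
                 lambda: cv_r2(identity, yf, rf_factory(identity.shape[1]), scheme))
        rf_full = grid.value(trait, "full", "RF")
        rf_id = grid.value(trait, "full", "RF_identity_only")
        if rf_full is not None and rf_id is not None:
            grid.env_contribution[trait] = rf_full - rf_id

        try:
            part, _ = vp.fit_lmm(work, env, trait, transform=lmm_transform)
            grid.cells.append(GridCell(trait, "full", "LMM", "r2_marginal", part.r2_marginal))
            grid.cells.append(GridCell(trait, "full", "LMM", "icc", part.icc))
        except (vp.LMMError, ValueError) as exc:
            grid.cells.append(GridCell(trait, "full", "LMM", "r2_marginal", None, flagged=str(exc)))
            grid.cells.append(GridCell(trait, "full", "LMM", "icc", None, flagged=str(exc)))

    return grid
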