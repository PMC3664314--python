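"""Linear support-vector regression with per-database normalization, and
the within-/cross-domain evaluation grid.

The regressor is a linear epsilon-SVR f(x) = w'x + b whose primary
optimization goal is flatness (low ||w||), solved by SMO with a very small
complexity constant C = 1e-5 — in this regime the solution direction is
essentially a robust correlation direction, which is what makes transfer
across domains with differently scaled features workable.  Each database is
mean/variance normalized with its *own* statistics (unsupervised, so the
test database never borrows training statistics).  Performance is the
Pearson correlation of predictions with the test gold standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .relevance import DomainDataset

DEFAULT_C = 1e-5
DEFAULT_EPSILON = 0.1
DEFAULT_TOL = 1e-3


@dataclass
class NormStats:
    mean: np.ndarray
    sd: np.ndarray


def znormalize(features: np.ndarray, stats: NormStats | None = None
               ) -> tuple[np.ndarray, NormStats]:
    """Per-feature mean/variance normalization; zero-SD features map to 0."""
    X = np.asarray(features, dtype=float)
    if stats is None:
        if X.shape[0] < 2:
            raise ValueError("need >= 2 instances to fit normalization stats")
        stats = NormStats(X.mean(axis=0), X.std(axis=0))
    sd = np.where(stats.sd > 0, stats.sd, 1.0)
    Z = (X - stats.mean) / sd
    Z[:, stats.sd == 0] = 0.0
    return Z, stats


@dataclass
class RegressionModel:
    w: np.ndarray
    b: float
    C: float
    epsilon: float
    norm_stats: NormStats | None = None
    feature_names: list[str] | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        if X.shape[1] != self.w.size:
            raise ValueError("feature dimensionality does not match model")
        return X @ self.w + self.b

    def dump(self) -> dict:
        w = self.w
        nz = np.flatnonzero(np.abs(w) > 0)
        names = (self.feature_names if self.feature_names is not None
                 else [f"f{i}" for i in range(w.size)])
        return {
            "b": float(self.b),
            "C": self.C,
            "epsilon": self.epsilon,
            "w": {names[i]: float(w[i]) for i in nz},
            "norm_mean": None if self.norm_stats is None
            else self.norm_stats.mean.tolist(),
            "norm_sd": None if self.norm_stats is None
            else self.norm_stats.sd.tolist(),
        }


def fit_svr(features: np.ndarray, targets: np.ndarray, C: float = DEFAULT_C,
            epsilon: float = DEFAULT_EPSILON, tol: float = DEFAULT_TOL,
            norm_stats: NormStats | None = None,
            feature_names=None) -> RegressionModel:
    """Linear epsilon-SVR via SMO; deterministic for fixed input."""
    y = np.asarray(targets, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite regression target")
    svr = SVR(kernel="linear", C=C, epsilon=epsilon, tol=tol)
    svr.fit(np.asarray(features, dtype=float), y)
    w = np.zeros(features.shape[1])
    w[:] = svr.coef_.ravel()
    return RegressionModel(w, float(svr.intercept_[0]), C, epsilon,
                           norm_stats, feature_names)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; 0 (flagged by a warning) when either side is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("constant input to correlation; r set to 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def evaluate(model: RegressionModel, features: np.ndarray,
             gold: np.ndarray) -> float:
    return pearson(model.predict(features), gold)


def within_domain_cv(dataset: DomainDataset, dimension: str,
                     feature_cols: np.ndarray | None = None,
                     C: float = DEFAULT_C, epsilon: float = DEFAULT_EPSILON,
                     seed: int = 0) -> float:
    """Twofold cross-validation within one domain: random halves, train on
    each and predict the other, Pearson r on the pooled predictions."""
    X = dataset.features if feature_cols is None \
        else dataset.features[:, feature_cols]
    y = dataset.gold(dimension)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 instances for twofold CV")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    halves = (perm[: n // 2], perm[n // 2:])
    Z, _ = znormalize(X)     # per-database normalization, unsupervised
    preds = np.empty(n)
    for tr, te in ((0, 1), (1, 0)):
        model = fit_svr(Z[halves[tr]], y[halves[tr]], C=C, epsilon=epsilon)
        p = model.predict(Z[halves[te]])
        # center each fold's predictions: at small C the within-fold spread
        # is tiny, so a fold-offset mismatch would otherwise dominate the
        # pooled correlation
        preds[halves[te]] = p - p.mean()
    return pearson(preds, y)


@dataclass
class EvalGrid:
    """Train-domain x test-domain correlation matrix (the transfer table).

    Row, column and grand means are always recomputed from the entries.
    """

    dimension: str
    feature_set: str                 # full | task_specific | generic
    domains: list[str]
    r: np.ndarray                    # train x test

    def row_means(self) -> np.ndarray:
        return self.r.mean(axis=1)

    def col_means(self) -> np.ndarray:
        return self.r.mean(axis=0)

    def grand_mean(self) -> float:
        return float(self.r.mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.r, index=self.domains, columns=self.domains)
        df["mean"] = self.row_means()
        df.loc["mean"] = np.append(self.col_means(), self.grand_mean())
        df.index.name = "train_on"
        df.columns.name = "test_on"
        return df


def grid_from_cells(cells, dimension: str = "", feature_set: str = "",
                    domains=None) -> EvalGrid:
    """Build an EvalGrid from an explicit square table of correlations."""
    r = np.asarray(cells, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("grid cells must form a square matrix")
    if domains is None:
        domains = [f"d{i}" for i in range(r.shape[0])]
    return EvalGrid(dimension, feature_set, list(domains), r)


def cross_domain_grid(datasets: list[DomainDataset], dimension: str,
                      feature_sets: dict, C: float = DEFAULT_C,
                      epsilon: float = DEFAULT_EPSILON, seed: int = 0
                      ) -> dict[str, EvalGrid]:
    """Within-/cross-domain SVR grids per feature-set condition.

    ``feature_sets`` maps a condition label to either ``None`` (full set),
    a 1-D index array (one generic subset), or a dict keyed by frozenset
    domain pairs / single-domain names with per-pair subsets (the
    task-specific condition; the diagonal uses the domain's own entry, or
    the full set when absent).
    """
    names = [ds.name for ds in datasets]
    by_name = {ds.name: ds for ds in datasets}
    norm = {ds.name: znormalize(ds.features)[0] for ds in datasets}
    grids = {}
    for label, sel in feature_sets.items():
        r = np.zeros((len(names), len(names)))
        for i, tr in enumerate(names):
            for j, te in enumerate(names):
                if isinstance(sel, dict):
                    key = tr if tr == te else frozenset((tr, te))
                    cols = sel.get(key)
                elif sel is None:
                    cols = None
                else:
                    cols = np.asarray(sel)
                if i == j:
                    r[i, j] = within_domain_cv(by_name[tr], dimension,
                                               cols, C=C, epsilon=epsilon,
                                               seed=seed)
                else:
                    Xtr = norm[tr] if cols is None else norm[tr][:, cols]
                    Xte = norm[te] if cols is None else norm[te][:, cols]
                    model = fit_svr(Xtr, by_name[tr].gold(dimension),
                                    C=C, epsilon=epsilon)
                    r[i, j] = evaluate(model, Xte, by_name[te].gold(dimension))
        grids[label] = EvalGrid(dimension, label, names, r)
    return grids
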