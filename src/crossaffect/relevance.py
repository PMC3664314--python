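"""Feature relevance: single-domain correlations, significance, and the
cross-domain correlation coefficient (CDCC).

A "domain" is the arousal (or valence) annotation of one data set.  For a
feature f with per-domain Pearson correlations r_f(i), the pairwise CDCC is

    cdcc2(r_i, r_j) = (|r_i + r_j| - |r_i - r_j|) / 2
                    = sign(r_i * r_j) * min(|r_i|, |r_j|),

i.e. the sign-consistent minimum absolute correlation: large only when the
feature correlates with the same sign and comparable strength in both
domains.  The J-domain generalization averages the pairwise values:

    cdccJ(r_1..r_J) = (1 / (J(J-1))) * sum_{i<j} (|r_i+r_j| - |r_i-r_j|).

Significance of single-domain correlations uses the two-sided t-test
t = r * sqrt((n-2)/(1-r^2)) with df = n-2, Bonferroni-adjusted for the
number of features tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .functionals import FeatureIndex

STAR_LEVELS = (0.05, 0.01, 0.001)


@dataclass
class DomainDataset:
    """Feature matrix plus gold ratings for one domain."""

    name: str
    features: np.ndarray            # instances x dims
    arousal: np.ndarray
    valence: np.ndarray
    instance_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        n = self.features.shape[0]
        for dim in ("arousal", "valence"):
            v = np.asarray(getattr(self, dim), dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{dim} length does not match feature rows")
            setattr(self, dim, v)
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"domain {self.name!r}: non-finite features")

    def gold(self, dimension: str) -> np.ndarray:
        if dimension not in ("arousal", "valence"):
            raise ValueError(f"unknown dimension {dimension!r}")
        return getattr(self, dimension)


def feature_correlation(features: np.ndarray, target: np.ndarray
                        ) -> np.ndarray:
    """Column-wise Pearson correlation with the target; zero-variance
    features get r = 0."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 instances")
    ys = y - y.mean()
    sy = np.sqrt((ys ** 2).sum())
    if sy == 0:
        raise ValueError("target has zero variance")
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    ok = sx > 0
    r = np.zeros(X.shape[1])
    r[ok] = (Xc[:, ok] * ys[:, None]).sum(axis=0) / (sx[ok] * sy)
    return np.clip(r, -1.0, 1.0)


def domain_correlation(dataset: DomainDataset, dimension: str) -> np.ndarray:
    return feature_correlation(dataset.features, dataset.gold(dimension))


def significance(r, n: int, m_tests: int = 1):
    """Bonferroni-adjusted two-sided p for Pearson r at sample size n."""
    r = np.asarray(r, dtype=float)
    if n < 3:
        raise ValueError("need n >= 3")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.minimum(p * m_tests, 1.0)


def star_level(p, levels=STAR_LEVELS) -> np.ndarray:
    """Number of significance stars (0-3) for adjusted p-values."""
    p = np.asarray(p, dtype=float)
    return sum((p < lv).astype(int) for lv in levels)


def _check_r(*rs):
    for r in rs:
        if np.any(np.abs(np.asarray(r, dtype=float)) > 1.0 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")


def cdcc2(r_i, r_j):
    """Pairwise cross-domain correlation coefficient."""
    _check_r(r_i, r_j)
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    out = (np.abs(r_i + r_j) - np.abs(r_i - r_j)) / 2.0
    return float(out) if out.ndim == 0 else out


def cdccJ(r_list):
    """J-domain CDCC; equals the mean of the pairwise cdcc2 values and
    reduces to cdcc2 at J = 2."""
    R = np.atleast_2d(np.asarray(r_list, dtype=float))
    if R.shape[0] == 1 and R.shape[1] >= 2 and np.asarray(r_list).ndim == 1:
        R = R.T                       # interpret 1-D input as J values
    J = R.shape[0]
    if J < 2:
        raise ValueError("need at least 2 domains")
    _check_r(R)
    acc = np.zeros(R.shape[1])
    for i in range(J):
        for j in range(i + 1, J):
            acc += np.abs(R[i] + R[j]) - np.abs(R[i] - R[j])
    out = acc / (J * (J - 1))
    return float(out[0]) if np.asarray(r_list).ndim == 1 else out


@dataclass
class RelevanceTable:
    """Per-feature relevance across domains for one affect dimension."""

    dimension: str
    domains: list[str]
    r: pd.DataFrame                 # features x domains
    p_adjusted: pd.DataFrame
    cdcc_pairs: pd.DataFrame        # features x "i|j" columns
    cdcc_all: pd.Series
    index: FeatureIndex | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(index=self.r.index)
        for d in self.domains:
            out[f"r_{d}"] = self.r[d]
            out[f"stars_{d}"] = star_level(self.p_adjusted[d].to_numpy())
        for c in self.cdcc_pairs.columns:
            out[f"cdcc2_{c}"] = self.cdcc_pairs[c]
        out["cdccJ"] = self.cdcc_all
        return out


def build_relevance_table(datasets: list[DomainDataset], dimension: str,
                          index: FeatureIndex | None = None,
                          m_tests: int | None = None) -> RelevanceTable:
    names = (index.names if index is not None
             else [f"f{i}" for i in range(datasets[0].features.shape[1])])
    if m_tests is None:
        m_tests = len(names)
    r = {}
    p = {}
    for ds in datasets:
        rv = domain_correlation(ds, dimension)
        r[ds.name] = rv
        p[ds.name] = significance(rv, ds.features.shape[0], m_tests)
    rdf = pd.DataFrame(r, index=names)
    pdf = pd.DataFrame(p, index=names)
    pair_cols = {}
    dnames = [ds.name for ds in datasets]
    for i in range(len(dnames)):
        for j in range(i + 1, len(dnames)):
            pair_cols[f"{dnames[i]}|{dnames[j]}"] = cdcc2(
                rdf[dnames[i]].to_numpy(), rdf[dnames[j]].to_numpy())
    pairs = pd.DataFrame(pair_cols, index=names)
    cj = pd.Series(cdccJ(rdf.to_numpy().T), index=names)
    return RelevanceTable(dimension, dnames, rdf, pdf, pairs, cj, index)


def select_top_k(scores, names=None, k: int = 200) -> list:
    """Indices (or names) of the k largest scores, descending; ties broken
    by manifest order for reproducibility."""
    scores = np.asarray(scores, dtype=float)
    if k > scores.size:
        raise ValueError("k exceeds feature count")
    order = np.argsort(-scores, kind="stable")[:k]
    if names is None:
        return order.tolist()
    names = list(names)
    return [names[i] for i in order]


def split_half_selection(dataset: DomainDataset, dimension: str,
                         k: int = 200, seed: int = 0,
                         names=None) -> list:
    """Single-domain analog of cross-domain selection: the corpus is split
    into random disjoint halves and the CDCC^2 of the per-half feature
    correlations is ranked."""
    n = dataset.features.shape[0]
    if n < 4:
        raise ValueError("need at least 4 instances")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    a, b = perm[: n // 2], perm[n // 2:]
    y = dataset.gold(dimension)
    r_a = feature_correlation(dataset.features[a], y[a])
    r_b = feature_correlation(dataset.features[b], y[b])
    return select_top_k(cdcc2(r_a, r_b), names=names, k=k)


def group_shares(selected_names, index: FeatureIndex) -> dict:
    """Counts per LLD group and functional family for a feature subset,
    with full-manifest baselines and enrichment flags (a group is enriched
    when its share of the subset exceeds its share of the full set)."""
    tab = index.table
    sub = tab[tab["name"].isin(set(selected_names))]
    out = {}
    for key in ("lld_group", "family"):
        base = tab[key].value_counts()
        got = sub[key].value_counts().reindex(base.index, fill_value=0)
        share = got / max(len(sub), 1)
        base_share = base / len(tab)
        out[key] = {
            g: {
                "count": int(got[g]),
                "share": float(share[g]),
                "baseline_count": int(base[g]),
                "baseline_share": float(base_share[g]),
                "enriched": bool(share[g] > base_share[g]),
            }
            for g in base.index
        }
    return out


def plot_group_shares(shares: dict, path) -> None:
    """Optional bar-chart rendering of a group-share report."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, key in zip(axes, ("lld_group", "family")):
        groups = list(shares[key])
        sel = [shares[key][g]["share"] for g in groups]
        base = [shares[key][g]["baseline_share"] for g in groups]
        x = np.arange(len(groups))
        ax.bar(x - 0.2, sel, width=0.4, label="selected")
        ax.bar(x + 0.2, base, width=0.4, label="full set")
        ax.set_xticks(x, groups, rotation=45, ha="right")
        ax.set_title(key)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
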