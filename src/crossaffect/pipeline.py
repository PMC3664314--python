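"""End-to-end experiment orchestration.

Ties the stages together: audio -> LLD contours -> suprasegmental feature
vectors -> EWE gold standard -> CDCC relevance/selection -> SVR transfer
grids.  Every artifact carries the configuration hash of the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .functionals import FeatureIndex, build_feature_index, extract_features
from .gold import ewe, map_scale
from .lld import LLDConfig, LLDExtractor
from .regression import DEFAULT_C, DEFAULT_EPSILON, cross_domain_grid
from .relevance import (
    DomainDataset,
    build_relevance_table,
    cdcc2,
    select_top_k,
)
from .synth import SynthConfig, SynthCorpus, gen_corpus

log = logging.getLogger("crossaffect")


def corpus_features(corpus: SynthCorpus, index: FeatureIndex,
                    extractor: LLDExtractor) -> np.ndarray:
    rows = []
    t0 = time.time()
    for clip in corpus.clips:
        lld = extractor.extract(clip)
        rows.append(extract_features(lld, index).values)
    log.info("domain %s: %d clips featurized in %.1f s", corpus.domain,
             len(corpus.clips), time.time() - t0)
    return np.asarray(rows)


def corpus_to_dataset(corpus: SynthCorpus, index: FeatureIndex,
                      extractor: LLDExtractor | None = None,
                      features: np.ndarray | None = None) -> DomainDataset:
    """Featurize a synthetic corpus and fuse its ratings into gold values.

    The corpus latent truth is deliberately not used here: the pipeline only
    ever sees the simulated raters, exactly as it would with real corpora.
    """
    if features is None:
        features = corpus_features(corpus, index,
                                   extractor or LLDExtractor())
    golds = {dim: ewe(map_scale(m)).ewe
             for dim, m in corpus.ratings.items()}
    return DomainDataset(corpus.domain, features,
                         golds["arousal"], golds["valence"],
                         [c.clip_id for c in corpus.clips])


@dataclass
class ExperimentReport:
    dimension: str
    relevance: object
    selections: dict
    grids: dict
    config_hash: str = ""

    def summary(self) -> dict:
        return {
            "dimension": self.dimension,
            "config_hash": self.config_hash,
            "grids": {
                label: {
                    "domains": g.domains,
                    "r": np.round(g.r, 3).tolist(),
                    "row_means": np.round(g.row_means(), 3).tolist(),
                    "col_means": np.round(g.col_means(), 3).tolist(),
                    "grand_mean": round(g.grand_mean(), 3),
                }
                for label, g in self.grids.items()
            },
        }


def run_analysis(datasets: list[DomainDataset], dimension: str,
                 index: FeatureIndex | None = None, k: int = 200,
                 C: float = DEFAULT_C, epsilon: float = DEFAULT_EPSILON,
                 seed: int = 0, config_hash: str = "",
                 conditions=("full", "task_specific", "generic")
                 ) -> ExperimentReport:
    """Relevance ranking, top-k selection and the SVR transfer grids for
    one affect dimension."""
    if index is None and datasets[0].features.shape[1] == 6373:
        index = build_feature_index()
    names = index.names if index is not None else None
    table = build_relevance_table(datasets, dimension, index)

    selections: dict = {}
    feature_sets: dict = {}
    if "full" in conditions:
        feature_sets["full"] = None
    if "task_specific" in conditions:
        per_pair: dict = {}
        dn = [ds.name for ds in datasets]
        for i in range(len(dn)):
            for j in range(i + 1, len(dn)):
                score = cdcc2(table.r[dn[i]].to_numpy(),
                              table.r[dn[j]].to_numpy())
                per_pair[frozenset((dn[i], dn[j]))] = np.asarray(
                    select_top_k(score, k=k))
        feature_sets["task_specific"] = per_pair
        selections["task_specific"] = {
            "|".join(sorted(key)): (list(np.asarray(names)[v]) if names
                                    else v.tolist())
            for key, v in per_pair.items()}
    if "generic" in conditions:
        generic = np.asarray(select_top_k(table.cdcc_all.to_numpy(), k=k))
        feature_sets["generic"] = generic
        selections["generic"] = (list(np.asarray(names)[generic]) if names
                                 else generic.tolist())

    grids = cross_domain_grid(datasets, dimension, feature_sets, C=C,
                              epsilon=epsilon, seed=seed)
    return ExperimentReport(dimension, table, selections, grids, config_hash)


def run_pipeline(config: SynthConfig, dimensions=("arousal", "valence"),
                 k: int = 200, C: float = DEFAULT_C, seed: int | None = None
                 ) -> dict[str, ExperimentReport]:
    """Full synthetic experiment: generate, featurize, fuse, rank, regress."""
    if seed is not None:
        config.seed = seed
    index = build_feature_index()
    extractor = LLDExtractor(LLDConfig())
    corpora = gen_corpus(config)
    feats = {c.domain: corpus_features(c, index, extractor) for c in corpora}
    datasets = [corpus_to_dataset(c, index, features=feats[c.domain])
                for c in corpora]
    return {dim: run_analysis(datasets, dim, index=index, k=k, C=C,
                              seed=config.seed, config_hash=config.hash())
            for dim in dimensions}


def write_report(reports: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump({dim: rep.summary() for dim, rep in reports.items()},
                  fh, indent=1)
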