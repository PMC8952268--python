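"""Step 1: random-forest HRT classification and Gini-importance bioindicator selection.

A random-forest classifier separates the HRT 8-day and HRT 2-day regimes from
ASV relative abundances.  Features are ranked by mean decrease in Gini
impurity, recursively eliminated from the least important upward, and the
bioindicator set is the 15 top-ranked ASVs of the elimination round with the
lowest out-of-bag error, pre-filtered by the "Gini share > 1% of total" rule.
Cross-reactor generalization is measured by training on one reactor and
testing on the other; the API takes disjoint train/test sample sets so a test
sample can never leak into training.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .tables import TableError

logger = logging.getLogger(__name__)


@dataclass
class RFClassifierSpec:
    """Forest hyperparameters: 2000 trees and mtry=40 unless overridden."""

    n_trees: int = 2000
    m_try: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise TableError("n_trees must be >= 1")
        if self.m_try < 1:
            raise TableError("m_try must be >= 1")


@dataclass
class ImportanceRanking:
    """Mean-decrease-in-Gini scores with deterministic ranking.

    Ties are broken by descending score then ascending ASV id; ``share`` is
    each score divided by the total so shares sum to one.
    """

    scores: pd.Series  # asv_id -> importance

    def __post_init__(self) -> None:
        if (self.scores < 0).any():
            raise TableError("importance scores must be non-negative")

    @property
    def shares(self) -> pd.Series:
        total = self.scores.sum()
        if total == 0:
            return pd.Series(np.full(len(self.scores), 1.0 / len(self.scores)),
                             index=self.scores.index)
        return self.scores / total

    def ranked_ids(self) -> list[str]:
        order = sorted(self.scores.index, key=lambda a: (-self.scores[a], a))
        return order

    def least_important(self) -> list[str]:
        """All features tied at the smallest importance (eliminated together)."""
        lo = self.scores.min()
        return sorted(self.scores.index[self.scores == lo])


@dataclass
class BioindicatorSet:
    """An ordered set of at most 15 ASVs with selection provenance."""

    asv_ids: list[str]
    train_reactor: str
    target: str
    importances: dict[str, float] = field(default_factory=dict)
    error_rate: float | None = None

    def __post_init__(self) -> None:
        if len(self.asv_ids) != len(set(self.asv_ids)):
            raise TableError("duplicate ids in bioindicator set")

    def __len__(self) -> int:
        return len(self.asv_ids)

    def to_frame(self, taxonomy=None) -> pd.DataFrame:
        rows = []
        for rank, asv in enumerate(self.asv_ids, 1):
            rows.append({
                "asv_id": asv,
                "rank": rank,
                "importance": self.importances.get(asv, np.nan),
                "genus": taxonomy.genus(asv) if taxonomy is not None else "",
            })
        return pd.DataFrame(rows)


def _fit_forest(X: pd.DataFrame, y: np.ndarray, spec: RFClassifierSpec) -> RandomForestClassifier:
    model = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=min(spec.m_try, X.shape[1]),
        oob_score=True,
        random_state=spec.seed % (2**31),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny forests may miss OOB coverage
        model.fit(X.to_numpy(), y)
    return model


def train_hrt_classifier(
    features: pd.DataFrame,
    labels,
    spec: RFClassifierSpec,
) -> tuple[RandomForestClassifier, float, ImportanceRanking]:
    """Fit the HRT8/HRT2 forest; return model, OOB error and Gini ranking."""
    y = np.asarray(list(labels))
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise TableError("need samples from both HRT classes")
    if counts.min() < 2:
        raise TableError("need at least two samples per class")
    model = _fit_forest(features, y, spec)
    oob_error = 1.0 - float(model.oob_score_)
    ranking = ImportanceRanking(pd.Series(model.feature_importances_, index=features.columns))
    return model, oob_error, ranking


def heldout_accuracy(model, features_test: pd.DataFrame, labels_test) -> float:
    """Classification accuracy on a held-out reactor."""
    y = np.asarray(list(labels_test))
    pred = model.predict(features_test.to_numpy())
    return float((pred == y).mean())


@dataclass
class EliminationRound:
    feature_ids: list[str]
    oob_error: float
    ranking: ImportanceRanking


def recursive_gini_elimination(
    features: pd.DataFrame,
    labels,
    spec: RFClassifierSpec,
    min_features: int = 2,
) -> list[EliminationRound]:
    """Backward elimination trace: refit, drop the least-important feature(s).

    One feature is dropped per round (all dropped together when tied at the
    minimum importance) until ``min_features`` remain.  Each round's forest
    is seeded as ``spec.seed + round`` so rounds are reproducible but not
    correlated by seed reuse.
    """
    current = list(features.columns)
    trace: list[EliminationRound] = []
    round_no = 0
    while True:
        round_spec = RFClassifierSpec(spec.n_trees, spec.m_try, spec.seed + round_no)
        _, oob, ranking = train_hrt_classifier(features[current], labels, round_spec)
        trace.append(EliminationRound(list(current), oob, ranking))
        if len(current) <= min_features:
            break
        drop = ranking.least_important()
        if len(drop) >= len(current):  # fully tied round: fall back to id order
            drop = [sorted(current)[-1]]
        if len(drop) > 1:
            logger.info("round %d: eliminating %d tied features", round_no, len(drop))
        current = [f for f in current if f not in drop]
        if len(current) < min_features:
            current = trace[-1].feature_ids[:]  # tie overshoot: keep last valid
            break
        round_no += 1
    return trace


def candidate_pool(ranking: ImportanceRanking, threshold_share: float = 0.01) -> list[str]:
    """Features whose Gini share exceeds *threshold_share* of the total."""
    shares = ranking.shares
    return [a for a in ranking.ranked_ids() if shares[a] > threshold_share]


def select_bioindicators(
    trace: list[EliminationRound],
    threshold_share: float = 0.01,
    k: int = 15,
    train_reactor: str = "",
    target: str = "HRT",
) -> BioindicatorSet:
    """Top-*k* ASVs of the lowest-OOB-error elimination round.

    The all-feature ranking (round 0) provides the "share > 1% of total Gini"
    candidate pool; the final set is the *k* top-ranked candidates of the
    round with minimum OOB error (earliest such round on ties).  If fewer
    than *k* candidates exist, all are returned with a warning.
    """
    if not trace:
        raise TableError("empty elimination trace")
    pool = set(candidate_pool(trace[0].ranking, threshold_share))
    # among rounds tied at the lowest error, prefer the most parsimonious one
    # that still offers k features: ASVs surviving deep into the elimination
    # keep proving their importance in every refit
    min_err = min(r.oob_error for r in trace)
    tied = [r for r in trace if r.oob_error == min_err and len(r.feature_ids) >= k]
    best = min(tied or [min(trace, key=lambda r: r.oob_error)],
               key=lambda r: len(r.feature_ids))
    ranked = [a for a in best.ranking.ranked_ids() if a in pool]
    if len(ranked) < k:
        # features eliminated before the best round can still be candidates
        extras = [a for a in trace[0].ranking.ranked_ids()
                  if a in pool and a not in ranked]
        ranked = ranked + extras
    if len(ranked) < k:
        logger.warning("only %d candidates pass the %g share threshold", len(ranked), threshold_share)
    chosen = ranked[:k]
    shares = trace[0].ranking.shares
    return BioindicatorSet(
        asv_ids=chosen,
        train_reactor=train_reactor,
        target=target,
        importances={a: float(shares[a]) for a in chosen},
        error_rate=float(best.oob_error),
    )


def shared_set(a: BioindicatorSet, b: BioindicatorSet) -> BioindicatorSet:
    """Intersection of two bioindicator sets, ordered by mean importance share."""
    if a.target != b.target:
        raise TableError(f"cannot intersect sets for targets {a.target!r} and {b.target!r}")
    common = [x for x in a.asv_ids if x in set(b.asv_ids)]
    if not common:
        logger.warning("bioindicator sets share no ASVs")
    mean_imp = {
        x: 0.5 * (a.importances.get(x, 0.0) + b.importances.get(x, 0.0)) for x in common
    }
    ordered = sorted(common, key=lambda x: (-mean_imp[x], x))
    return BioindicatorSet(
        asv_ids=ordered,
        train_reactor=f"{a.train_reactor}&{b.train_reactor}",
        target=a.target,
        importances={x: mean_imp[x] for x in ordered},
    )
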