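"""Feature ranking by mRMR and prefix choice by incremental feature selection.

Relevance and redundancy are mutual information values (nats) between
3-bin discretised features (bin edges at mean +/- one standard deviation,
the canonical mRMR discretisation). Ranking is the greedy difference
scheme: the first feature maximises relevance I(f, y) alone; each later
step maximises I(f, y) minus the mean I(f, g) over already-selected g.
Ties break on the frozen column order, so the ranking is deterministic.

Incremental feature selection (IFS) then evaluates nested prefixes of the
ranking with jackknife (leave-one-out) accuracy and keeps the best prefix
(smallest k on ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from .classify import SvmConfig, jackknife
from .io_formats import FeatureTable


def discretize(x: np.ndarray) -> np.ndarray:
    """3-bin discretisation at mean +/- one standard deviation."""
    x = np.asarray(x, dtype=float)
    mu, sd = x.mean(), x.std()
    return np.digitize(x, [mu - sd, mu + sd])


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI (nats) between a discretised feature and discrete labels."""
    return float(mutual_info_score(discretize(x), np.asarray(y)))


def _pairwise_mi(disc: np.ndarray) -> np.ndarray:
    """All-pairs plug-in MI (nats) between 3-bin discretised feature columns.

    Joint counts for every column pair come from nine indicator-matrix
    products, which keeps the 591 x 591 matrix tractable; entries match
    :func:`sklearn.metrics.mutual_info_score` to floating-point error.
    """
    n, d = disc.shape
    indicators = [(disc == b).astype(float) for b in range(3)]
    marg = np.stack([ind.mean(axis=0) for ind in indicators])  # (3, d)
    mi = np.zeros((d, d))
    for a in range(3):
        for b in range(3):
            p_ab = indicators[a].T @ indicators[b] / n  # (d, d)
            denom = np.outer(marg[a], marg[b])
            with np.errstate(divide="ignore", invalid="ignore"):
                term = p_ab * np.log(p_ab / denom)
            mi += np.where(p_ab > 0, term, 0.0)
    return mi


@dataclass
class RankedFeatureList:
    """Greedy mRMR ordering with per-feature relevance and objective values."""

    names: list[str]
    relevance: np.ndarray  # I(f, y) in ranked order
    objective: np.ndarray  # greedy objective value at the step each was picked

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.names) + 1),
                "feature": self.names,
                "relevance": self.relevance,
                "objective": self.objective,
            }
        ).set_index("rank")


def mrmr_rank(table: FeatureTable) -> RankedFeatureList:
    """Rank all features by greedy maximum-relevance minimum-redundancy."""
    if table.labels is None:
        raise ValueError("mRMR ranking needs class labels")
    y = table.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("labels are constant; relevance is undefined")
    X = table.values.to_numpy(dtype=float)
    names = table.feature_names
    n_feat = X.shape[1]
    if n_feat < 2:
        raise ValueError("need at least 2 features to rank")

    disc = np.column_stack([discretize(X[:, j]) for j in range(n_feat)])
    relevance = np.array(
        [mutual_info_score(disc[:, j], y) for j in range(n_feat)]
    )

    pair_mi = _pairwise_mi(disc)
    selected: list[int] = []
    objective_at_pick: list[float] = []
    remaining = list(range(n_feat))
    redundancy_sum = np.zeros(n_feat)
    while remaining:
        if not selected:
            scores = relevance[remaining]
        else:
            scores = relevance[remaining] - redundancy_sum[remaining] / len(selected)
        # argmax with ties broken by frozen column order (first occurrence)
        best_pos = int(np.argmax(scores))
        j_star = remaining.pop(best_pos)
        selected.append(j_star)
        objective_at_pick.append(float(scores[best_pos]))
        redundancy_sum += pair_mi[:, j_star]

    return RankedFeatureList(
        names=[names[j] for j in selected],
        relevance=relevance[selected],
        objective=np.asarray(objective_at_pick),
    )


@dataclass
class IFSCurve:
    """Jackknife accuracy over nested ranking prefixes."""

    k: np.ndarray          # evaluated prefix sizes, ascending
    accuracy: np.ndarray   # jackknife accuracy at each prefix
    optimal_k: int         # smallest prefix realizing the maximum

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "accuracy": self.accuracy}).set_index("k")


def ifs_select(
    table: FeatureTable,
    ranking: RankedFeatureList,
    config: SvmConfig,
    step: int = 1,
) -> IFSCurve:
    """Evaluate ranking prefixes S_k by jackknife accuracy; keep the best.

    ``step`` evaluates every step-th prefix size (the full set is always
    included) for desk-scale runs; step=1 is the exhaustive sweep.
    """
    if set(ranking.names) != set(table.feature_names):
        raise ValueError("ranking does not match the table's feature columns")
    n_feat = len(ranking.names)
    ks = sorted(set(range(step, n_feat + 1, step)) | {1, n_feat})
    accs = []
    for k in ks:
        sub = FeatureTable(table.values[ranking.names[:k]], table.labels)
        accs.append(jackknife(sub, config).acc)
    accs_arr = np.asarray(accs)
    optimal_k = int(np.asarray(ks)[int(np.argmax(accs_arr))])
    return IFSCurve(np.asarray(ks), accs_arr, optimal_k)
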