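"""Stepwise-regression pruning of learned network edges.

Each node of a fitted linear Gaussian network is a linear regression on its
parents, so the connection weights are regression coefficients and can be
t-tested.  Pruning is backward elimination: per node, refit the OLS of the
node on its current parents, and while any coefficient has a two-sided
p-value above alpha, drop the parent with the largest p and refit.  p-values
use m - |parents| - 1 residual degrees of freedom; no multiple-testing
correction is applied by default (an optional Bonferroni flag exists).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bn_core import (
    BnModel,
    DagStructure,
    bic_score,
    fit_node_ml,
    GaussianBnParameters,
)
from .roi_io import RoiTimeSeriesMatrix

__all__ = ["WeightSignificance", "prune_by_stepwise_regression", "node_coefficient_stats"]


@dataclass
class WeightSignificance:
    """Per-edge weight statistics from the final elimination step.

    ``table`` columns: child, parent, weight, se, t, p, retained.  Removed
    edges carry the statistics of the step at which they were eliminated;
    retained edges carry final-fit statistics.
    """

    table: pd.DataFrame
    alpha: float

    def retained_edges(self) -> list[tuple[str, str]]:
        kept = self.table[self.table["retained"]]
        return sorted(zip(kept["parent"], kept["child"]))


def node_coefficient_stats(
    ts: RoiTimeSeriesMatrix, node: str, parents: list[str]
) -> pd.DataFrame:
    """OLS of ``node`` on ``parents`` with intercept: weight, se, t, p per parent."""
    idx = {lab: j for j, lab in enumerate(ts.node_labels)}
    y = ts.values[:, idx[node]]
    m = y.shape[0]
    X = np.column_stack([np.ones(m)] + [ts.values[:, idx[p]] for p in parents])
    k = X.shape[1]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = m - k
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return pd.DataFrame(
        {
            "parent": parents,
            "weight": beta[1:],
            "se": se[1:],
            "t": t[1:],
            "p": p[1:],
        }
    )


def prune_by_stepwise_regression(
    model: BnModel,
    ts: RoiTimeSeriesMatrix,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> tuple[BnModel, WeightSignificance]:
    """Backward-eliminate parents with insignificant weights; refit the rest.

    Returns the pruned, refitted model and the per-edge significance table.
    With ``bonferroni=True`` the threshold for a node is alpha divided by its
    initial parent count.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    rows = []
    pruned_parents: dict[str, frozenset[str]] = {}
    for node in model.structure.nodes:
        parents = sorted(model.structure.parents[node])
        threshold = alpha / len(parents) if (bonferroni and parents) else alpha
        node_rows = []
        stats_df = None
        while parents:
            stats_df = node_coefficient_stats(ts, node, parents)
            worst = stats_df["p"].idxmax()
            if stats_df.loc[worst, "p"] <= threshold:
                break
            node_rows.append(stats_df.loc[[worst]].assign(retained=False))
            parents = [p for p in parents if p != stats_df.loc[worst, "parent"]]
            stats_df = None
        if parents:
            if stats_df is None:
                stats_df = node_coefficient_stats(ts, node, parents)
            node_rows.append(stats_df.assign(retained=True))
        for df in node_rows:
            df["child"] = node
        rows.extend(node_rows)
        pruned_parents[node] = frozenset(parents)

    structure = DagStructure(model.structure.nodes, pruned_parents)
    params = GaussianBnParameters(
        {n: fit_node_ml(ts, n, structure.parents[n]) for n in structure.nodes}
    )
    pruned = BnModel(structure=structure, params=params, score=bic_score(structure, ts))
    if rows:
        table = pd.concat(rows, ignore_index=True)[
            ["child", "parent", "weight", "se", "t", "p", "retained"]
        ]
    else:
        table = pd.DataFrame(
            columns=["child", "parent", "weight", "se", "t", "p", "retained"]
        )
    return pruned, WeightSignificance(table=table, alpha=alpha)
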