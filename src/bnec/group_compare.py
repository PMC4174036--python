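"""Permutation test for condition differences in network edge weights.

The observed statistic is, per edge, the difference (condition A minus
condition B) of the post-pruning connection weights of the two groups' full
pipelines (structure learning followed by stepwise pruning); edges absent
from a group's network contribute weight 0.  The reference distribution is
built by randomly swapping each subject's pair of condition labels (paired
design: the same subjects are measured under both conditions) and
recomputing the statistic; one-sided empirical p-values in both directions
use the (count + 1)/(B + 1) correction.

Two permutation modes exist: ``"full"`` re-learns and re-prunes both
structures for every rearranged group, as in the original procedure;
``"fixed"`` (speed mode) keeps the two observed structures and re-estimates
only the weights, which reduces every permutation to solving small normal
equations assembled from cached per-subject cross-product matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bn_core import BnModel, LearnConfig, learn_structure
from .roi_io import RoiTimeSeriesMatrix, concatenate_subjects
from .significance import prune_by_stepwise_regression

log = logging.getLogger(__name__)

__all__ = ["GroupComparisonResult", "permutation_group_test"]


@dataclass
class GroupComparisonResult:
    """Per-edge weights, observed differences and permutation p-values.

    ``table`` columns: parent, child, weight_A, weight_B, observed_diff
    (A - B), p_A_greater, p_B_greater.  ``p_A_greater`` is the probability,
    under label exchange, of a difference at least as large as observed.
    """

    table: pd.DataFrame
    n_permutations: int
    seed: int
    model_A: BnModel = field(repr=False, default=None)
    model_B: BnModel = field(repr=False, default=None)

    def edges(self) -> list[tuple[str, str]]:
        return sorted(zip(self.table["parent"], self.table["child"]))


def _pipeline_weights(
    subjects: list[RoiTimeSeriesMatrix],
    learn_config: LearnConfig,
    alpha: float,
) -> tuple[dict[tuple[str, str], float], BnModel]:
    ts = concatenate_subjects(subjects)
    model = learn_structure(ts, learn_config)
    pruned, _ = prune_by_stepwise_regression(model, ts, alpha=alpha)
    return pruned.edge_weights(), pruned


class _FixedStructureEstimator:
    """Weight re-estimation under a fixed structure from per-subject Grams.

    For each subject s, cache C_s = Z_s' Z_s with Z_s = [1 | X_s].  A
    permuted group's normal equations are the sum of its members' C_s, so
    per-permutation weights cost O(n k^2) independent of the series length.
    To mirror the full pipeline's statistic, each permutation also reruns
    the backward-elimination pruning on the fixed parent sets (t-tests are
    likewise functions of the Gram matrix); eliminated edges contribute
    weight 0, as they would after a full re-learn.
    """

    def __init__(self, subjects: list[RoiTimeSeriesMatrix], labels: list[str]):
        self.labels = labels
        self.m_per_subject = subjects[0].n_samples
        self.grams = []
        for ts in subjects:
            Z = np.column_stack([np.ones(ts.n_samples), ts.values])
            self.grams.append(Z.T @ Z)

    def weights(
        self, member_grams: list[np.ndarray], structure, alpha: float
    ) -> dict[tuple[str, str], float]:
        from scipy import stats

        C = sum(member_grams)
        m = len(member_grams) * self.m_per_subject
        idx = {lab: j for j, lab in enumerate(self.labels)}
        out = {}
        for child in structure.nodes:
            parents = sorted(structure.parents[child])
            j = idx[child] + 1
            while parents:
                cols = [0] + [idx[p] + 1 for p in parents]
                A = C[np.ix_(cols, cols)]
                b = C[cols, j]
                Ainv = np.linalg.inv(A)
                beta = Ainv @ b
                dof = m - len(cols)
                s2 = max(float(C[j, j] - beta @ b), 1e-300) / dof
                se = np.sqrt(s2 * np.diag(Ainv)[1:])
                pvals = 2 * stats.t.sf(np.abs(beta[1:]) / se, dof)
                worst = int(np.argmax(pvals))
                if pvals[worst] <= alpha:
                    break
                parents.pop(worst)
            if parents:
                for p, w in zip(parents, beta[1:]):
                    out[(p, child)] = float(w)
        return out


def permutation_group_test(
    subjects_A: list[RoiTimeSeriesMatrix],
    subjects_B: list[RoiTimeSeriesMatrix],
    n_perms: int = 1000,
    seed: int = 0,
    learn_config: LearnConfig | None = None,
    alpha: float = 0.05,
    mode: str = "fixed",
    paired: bool = True,
) -> GroupComparisonResult:
    """Paired subject-label permutation test on per-edge weight differences.

    Subjects are paired by index across the two lists; each permutation
    independently swaps each pair's condition labels with probability 1/2
    (``paired=False`` instead relabels the pooled 2N subjects uniformly at
    random into two groups of N).  ``mode`` selects full re-learning per
    permutation or the fixed-structure speed mode.  Deterministic given
    ``seed``.
    """
    if len(subjects_A) != len(subjects_B):
        raise ValueError(
            f"paired design needs equal subject counts; got "
            f"{len(subjects_A)} vs {len(subjects_B)}"
        )
    if n_perms < 100:
        log.warning("n_perms=%d < 100: p-values will be coarse", n_perms)
    if mode not in ("full", "fixed"):
        raise ValueError("mode must be 'full' or 'fixed'")
    learn_config = learn_config or LearnConfig()
    n_sub = len(subjects_A)
    labels = subjects_A[0].node_labels

    weights_A, model_A = _pipeline_weights(subjects_A, learn_config, alpha)
    weights_B, model_B = _pipeline_weights(subjects_B, learn_config, alpha)
    edges = sorted(set(weights_A) | set(weights_B))
    observed = np.array(
        [weights_A.get(e, 0.0) - weights_B.get(e, 0.0) for e in edges]
    )

    rng = np.random.default_rng(seed)
    count_ge = np.zeros(len(edges))
    count_le = np.zeros(len(edges))

    if mode == "fixed":
        est_A = _FixedStructureEstimator(subjects_A, labels)
        est_B = _FixedStructureEstimator(subjects_B, labels)
        all_grams = est_A.grams + est_B.grams  # indices: 0..N-1 = A, N..2N-1 = B

    for _ in range(n_perms):
        if paired:
            swap = rng.random(n_sub) < 0.5
            idx_A = [i + n_sub if swap[i] else i for i in range(n_sub)]
            idx_B = [i if swap[i] else i + n_sub for i in range(n_sub)]
        else:
            perm = rng.permutation(2 * n_sub)
            idx_A, idx_B = list(perm[:n_sub]), list(perm[n_sub:])
        if mode == "fixed":
            wa = est_A.weights([all_grams[i] for i in idx_A], model_A.structure, alpha)
            wb = est_B.weights([all_grams[i] for i in idx_B], model_B.structure, alpha)
        else:
            pooled = subjects_A + subjects_B
            wa, _ = _pipeline_weights([pooled[i] for i in idx_A], learn_config, alpha)
            wb, _ = _pipeline_weights([pooled[i] for i in idx_B], learn_config, alpha)
        diff = np.array([wa.get(e, 0.0) - wb.get(e, 0.0) for e in edges])
        count_ge += diff >= observed
        count_le += diff <= observed

    p_a = (count_ge + 1) / (n_perms + 1)
    p_b = (count_le + 1) / (n_perms + 1)
    table = pd.DataFrame(
        {
            "parent": [u for u, _ in edges],
            "child": [v for _, v in edges],
            "weight_A": [weights_A.get(e, 0.0) for e in edges],
            "weight_B": [weights_B.get(e, 0.0) for e in edges],
            "observed_diff": observed,
            "p_A_greater": p_a,
            "p_B_greater": p_b,
        }
    )
    return GroupComparisonResult(
        table=table,
        n_permutations=n_perms,
        seed=seed,
        model_A=model_A,
        model_B=model_B,
    )
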