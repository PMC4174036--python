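"""Calibration experiments: the package's self-validation battery.

Each function runs a seeded Monte-Carlo experiment against the synthetic
generator's ground truth and returns summary statistics: agreement of the
hill-climbing search with the exhaustive-enumeration oracle, weight-recovery
error under the true structure, CPDAG recovery of the full pipeline,
type-I behaviour of the stepwise pruning and of the permutation test, and
the power of the permutation test against a known single-edge difference.
All experiments are deterministic given their ``seed``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .bn_core import (
    BnModel,
    DagStructure,
    GaussianBnParameters,
    GaussianNodeParams,
    LearnConfig,
    bic_score,
    cpdag,
    exhaustive_search,
    fit_node_ml,
    joint_log_likelihood,
    learn_structure,
    node_log_likelihood,
)
from .group_compare import permutation_group_test
from .preprocess import preprocess_pipeline, standardize
from .roi_io import concatenate_subjects
from .significance import prune_by_stepwise_regression
from .synthetic import (
    ArtifactSpec,
    default_scenario,
    make_group_scenario,
    sample_random_dag,
    sample_random_parameters,
    simulate_gaussian_bn,
)

__all__ = [
    "oracle_equivalence",
    "parameter_recovery",
    "structure_recovery",
    "pruning_calibration",
    "permutation_null_calibration",
    "permutation_power",
    "factorization_error",
]


def oracle_equivalence(
    n_datasets: int = 50, m: int = 1000, seed: int = 0
) -> dict[str, int]:
    """Hill-climbing vs exhaustive search on small random networks.

    Half the datasets use 3 nodes, half 4.  Returns counts of BIC agreement
    (within 1e-6) and of CPDAG agreement among the BIC-equal runs.
    """
    bic_equal = 0
    cpdag_match = 0
    for i in range(n_datasets):
        n = 3 if i < n_datasets // 2 else 4
        structure = sample_random_dag(n, 0.5, seed=seed * 1000 + 100 + i)
        params = sample_random_parameters(structure, seed=seed * 1000 + 200 + i)
        ts = standardize(
            simulate_gaussian_bn(structure, params, m, seed=seed * 1000 + 300 + i)
        )
        hill = learn_structure(ts, LearnConfig(seed=seed + i))
        oracle = exhaustive_search(ts)
        if abs(hill.score.total - oracle.score.total) < 1e-6:
            bic_equal += 1
            if cpdag(hill.structure) == cpdag(oracle.structure):
                cpdag_match += 1
    return {"n": n_datasets, "bic_equal": bic_equal, "cpdag_match": cpdag_match}


def parameter_recovery(n_seeds: int = 50, seed: int = 0) -> float:
    """Mean absolute weight error with the true structure fixed.

    Default scenario (8 nodes, 14 subjects x 127 volumes = 1778 samples);
    fits run on the raw concatenated series so weights are on the
    generative scale.
    """
    maes = []
    for i in range(n_seeds):
        sc = default_scenario(seed=seed * 1000 + i)
        subjects, _ = make_group_scenario(sc)
        ts = concatenate_subjects(subjects)
        errs = []
        for node in sc.structure.nodes:
            parents = sc.structure.parents[node]
            if not parents:
                continue
            fit = fit_node_ml(ts, node, parents)
            errs.extend(
                abs(fit.weights[p] - sc.base_params[node].weights[p])
                for p in parents
            )
        if errs:
            maes.append(float(np.mean(errs)))
    return float(np.mean(maes))


def structure_recovery(
    n_seeds: int = 100, seed: int = 0, restarts: int = 10
) -> dict[str, int]:
    """Full pipeline on artifact-injected data: CPDAG-exact recovery count.

    Subjects carry 132 volumes plus injected linear trends and a shared
    low-frequency confound; the pipeline discards 5 volumes, detrends,
    regresses the (identically conditioned) confound, standardizes, learns
    and prunes, and the learned CPDAG is compared with the truth.
    """
    ok = 0
    for i in range(n_seeds):
        sc = default_scenario(
            seed=seed * 1000 + i,
            volumes_per_subject=132,
            artifact_spec=ArtifactSpec(),
        )
        subjects, _, nuisances, _ = make_group_scenario(sc, return_nuisance=True)
        cleaned = []
        for ts, nuis in zip(subjects, nuisances):
            regs = dataclasses.replace(nuis, values=nuis.values[5:])
            cleaned.append(
                preprocess_pipeline(ts, discard=5, band=None, regressors=regs)
            )
        ts = concatenate_subjects(cleaned)
        model = learn_structure(ts, LearnConfig(restarts=restarts, seed=seed + i))
        pruned, _ = prune_by_stepwise_regression(model, ts, alpha=0.05)
        ok += cpdag(pruned.structure) == cpdag(sc.structure)
    return {"n": n_seeds, "recovered": ok}


def pruning_calibration(n_runs: int = 400, m: int = 2000, seed: int = 0) -> float:
    """Retention rate of a truly-zero parent under backward elimination.

    The child depends on one real parent (b = 0.8); a second, independent
    parent is claimed by the model.  Returns the fraction of runs in which
    the spurious parent survives at alpha = 0.05.
    """
    truth = DagStructure.from_edges(("X1", "X2", "X3"), [("X1", "X3")])
    params = GaussianBnParameters(
        {
            "X1": GaussianNodeParams(0.0, {}, 1.0),
            "X2": GaussianNodeParams(0.0, {}, 1.0),
            "X3": GaussianNodeParams(0.0, {"X1": 0.8}, 0.36),
        }
    )
    claimed = DagStructure.from_edges(
        ("X1", "X2", "X3"), [("X1", "X3"), ("X2", "X3")]
    )
    retained = 0
    for i in range(n_runs):
        ts = simulate_gaussian_bn(truth, params, m, seed=seed * 10000 + i)
        node_params = GaussianBnParameters(
            {n: fit_node_ml(ts, n, claimed.parents[n]) for n in claimed.nodes}
        )
        model = BnModel(claimed, node_params, bic_score(claimed, ts))
        pruned, _ = prune_by_stepwise_regression(model, ts, alpha=0.05)
        retained += "X2" in pruned.structure.parents["X3"]
    return retained / n_runs


def _standardized_groups(sc):
    A, B = make_group_scenario(sc)
    return [standardize(t) for t in A], [standardize(t) for t in B]


def permutation_null_calibration(
    n_runs: int = 400,
    n_perms: int = 200,
    seed: int = 0,
    mode: str = "fixed",
    learn_config: LearnConfig | None = None,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Per-edge one-sided rejection rate on null two-condition scenarios.

    Both conditions share the same generative network; every reported edge
    contributes two one-sided tests.  Returns the pooled rejection rate.
    """
    rejected = 0
    total = 0
    for i in range(n_runs):
        sc = default_scenario(seed=seed * 1000 + 5000 + i)
        A, B = _standardized_groups(sc)
        lc = learn_config or LearnConfig(restarts=10, seed=i)
        res = permutation_group_test(
            A, B, n_perms=n_perms, seed=seed * 1000 + i, learn_config=lc, mode=mode
        )
        rejected += int((res.table["p_A_greater"] <= alpha).sum())
        rejected += int((res.table["p_B_greater"] <= alpha).sum())
        total += 2 * len(res.table)
    return {"rejected": rejected, "total": total, "rate": rejected / max(total, 1)}


def permutation_power(
    n_runs: int = 100,
    n_perms: int = 200,
    delta: float = 0.5,
    seed: int = 0,
    mode: str = "fixed",
) -> dict[str, int]:
    """Detection rate of a known single-edge weight difference.

    Each run applies ``delta`` to the first edge of the scenario's network in
    condition B and counts a success when that edge's smaller one-sided
    permutation p-value is <= 0.05.
    """
    hits = 0
    n_done = 0
    i = 0
    while n_done < n_runs:
        base = default_scenario(seed=seed * 1000 + 9000 + i)
        edges = base.structure.edges()
        i += 1
        if not edges:
            continue  # edgeless draw: no edge to perturb
        u, v = edges[0]
        sc = default_scenario(
            seed=seed * 1000 + 9000 + (i - 1), delta_edge=(u, v), delta=delta
        )
        A, B = _standardized_groups(sc)
        res = permutation_group_test(
            A, B, n_perms=n_perms, seed=seed * 1000 + i,
            learn_config=LearnConfig(restarts=10, seed=i), mode=mode,
        )
        row = res.table[(res.table["parent"] == u) & (res.table["child"] == v)]
        if len(row) == 1 and min(
            float(row["p_A_greater"].iloc[0]), float(row["p_B_greater"].iloc[0])
        ) <= 0.05:
            hits += 1
        n_done += 1
    return {"n": n_runs, "detected": hits}


def factorization_error(n_models: int = 20, m: int = 200, seed: int = 0) -> float:
    """Max |joint MVN log-density - sum of conditional log-likelihoods|.

    The joint density is evaluated through the implied covariance
    (I - W)^-1 Sigma (I - W)^-T; exact agreement with the per-node
    factorization is an identity of the linear Gaussian network.
    """
    worst = 0.0
    for i in range(n_models):
        structure = sample_random_dag(5, 0.5, seed=seed * 100 + i)
        params = sample_random_parameters(structure, seed=seed * 100 + 50 + i)
        ts = simulate_gaussian_bn(structure, params, m, seed=seed * 100 + 90 + i)
        parent_means = {n: params[n].mean for n in structure.nodes}
        total = sum(
            node_log_likelihood(ts, n, params[n], parent_means=parent_means)
            for n in structure.nodes
        )
        joint = joint_log_likelihood(ts, structure, params)
        worst = max(worst, abs(joint - total))
    return worst
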