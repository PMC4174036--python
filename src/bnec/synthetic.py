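"""Synthetic multi-subject, two-condition ROI time series with known ground truth.

Data are drawn from a linear Gaussian structural equation model on a known
DAG: rows are i.i.d. samples (the network model treats time points as
exchangeable samples), each node is its parents' weighted sum plus Gaussian
noise.  The default scenario mirrors a two-condition resting/task study at
desk scale: 8 nodes carrying default-mode-network region names, 14 subjects
per condition, 127 retained volumes per subject at TR = 2 s, edge weights of
magnitude 0.3-0.8.  Condition B applies per-edge weight offsets to the base
network; optional artifacts (per-subject linear trends, a shared
low-frequency nuisance component) exercise the preprocessing stages.
Seeding is counter-based per (scenario seed, condition, subject) so that
changing the subject count does not reshuffle existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bn_core import DagStructure, GaussianBnParameters, GaussianNodeParams
from .preprocess import NuisanceRegressors
from .roi_io import RoiTimeSeriesMatrix

__all__ = [
    "ArtifactSpec",
    "SyntheticScenario",
    "sample_random_dag",
    "sample_random_parameters",
    "simulate_gaussian_bn",
    "make_group_scenario",
    "default_scenario",
    "DMN_NODE_LABELS",
]

DMN_NODE_LABELS = ("PCC", "lIPC", "MPFC", "rIPC", "rITC", "lITC", "lHC", "rHC")


@dataclass
class ArtifactSpec:
    """Artifact injection: per-subject linear trend and nuisance component.

    ``trend_slope_range`` is the uniform range (per volume, signal units) of
    each subject/node slope; ``nuisance_amplitude`` scales a smooth
    low-frequency confound shared across nodes within a subject, mixed into
    each node with a random loading.
    """

    trend_slope_range: tuple[float, float] = (-0.02, 0.02)
    nuisance_amplitude: float = 1.0


@dataclass
class SyntheticScenario:
    structure: DagStructure
    base_params: GaussianBnParameters
    condition_deltas: dict[tuple[str, str], float] = field(default_factory=dict)
    n_subjects: int = 14
    volumes_per_subject: int = 127
    seed: int = 0
    sampling_interval: float = 2.0
    artifact_spec: ArtifactSpec | None = None
    ar1_coefficient: float = 0.0  # optional AR(1) contamination, default off

    def __post_init__(self) -> None:
        if self.volumes_per_subject < 10:
            raise ValueError("volumes_per_subject must be >= 10")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for node in self.structure.nodes:
            if self.base_params[node].residual_variance <= 0:
                raise ValueError(f"noise variance of {node!r} must be > 0")
        # deltas may add new edges, but never a cycle
        self.structure_b = self.structure
        for (u, v), _ in sorted(self.condition_deltas.items()):
            if u not in self.structure_b.parents[v]:
                if self.structure_b.creates_cycle(u, v):
                    raise ValueError(f"delta edge {u}->{v} would create a cycle")
                self.structure_b = self.structure_b.with_edge(u, v)

    def params_for_condition(self, condition: str) -> tuple[DagStructure, GaussianBnParameters]:
        """Condition "A" uses the base network; "B" applies the weight deltas."""
        if condition == "A":
            return self.structure, self.base_params
        if condition != "B":
            raise ValueError("condition must be 'A' or 'B'")
        node_params = {}
        for node in self.structure_b.nodes:
            base = self.base_params[node]
            weights = {p: base.weights.get(p, 0.0) for p in self.structure_b.parents[node]}
            for (u, v), delta in self.condition_deltas.items():
                if v == node:
                    weights[u] = weights.get(u, 0.0) + delta
            node_params[node] = GaussianNodeParams(
                mean=base.mean,
                weights=weights,
                residual_variance=base.residual_variance,
            )
        return self.structure_b, GaussianBnParameters(node_params)


def sample_random_dag(
    n_nodes: int,
    edge_prob: float,
    seed: int,
    labels: tuple[str, ...] | None = None,
) -> DagStructure:
    """Random DAG: edges only from earlier to later in a random node order."""
    if not (0 <= edge_prob <= 1):
        raise ValueError("edge_prob must be in [0, 1]")
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if labels is None:
        labels = tuple(f"X{i + 1}" for i in range(n_nodes))
    if len(labels) != n_nodes:
        raise ValueError("labels length must equal n_nodes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_nodes)
    parents: dict[str, set[str]] = {lab: set() for lab in labels}
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            if rng.random() < edge_prob:
                parents[labels[order[b]]].add(labels[order[a]])
    return DagStructure(labels, {n: frozenset(p) for n, p in parents.items()})


def sample_random_parameters(
    structure: DagStructure,
    seed: int,
    weight_magnitude: tuple[float, float] = (0.3, 0.8),
    residual_variance: float = 1.0,
) -> GaussianBnParameters:
    """Random signed weights with |b| in ``weight_magnitude``; zero means."""
    rng = np.random.default_rng(seed)
    node_params = {}
    for node in structure.nodes:
        weights = {}
        for p in sorted(structure.parents[node]):
            mag = rng.uniform(*weight_magnitude)
            weights[p] = float(mag * rng.choice([-1.0, 1.0]))
        node_params[node] = GaussianNodeParams(
            mean=0.0, weights=weights, residual_variance=residual_variance
        )
    return GaussianBnParameters(node_params)


def simulate_gaussian_bn(
    structure: DagStructure,
    params: GaussianBnParameters,
    m: int,
    seed,
    sampling_interval: float = 2.0,
    subject_id: str = "subject0",
    ar1: float = 0.0,
) -> RoiTimeSeriesMatrix:
    """Draw m i.i.d. rows from the linear Gaussian network, ancestrally.

    In topological order, x_i = mu_i + sum_p b_p (x_p - mu_p) + eps,
    eps ~ Normal(0, sigma_i^2).  With ``ar1`` nonzero the noise of each node
    is an AR(1) process of the same marginal variance (robustness probe; the
    default keeps rows independent).
    """
    order = structure.topological_order()
    assert order is not None
    idx = {lab: j for j, lab in enumerate(structure.nodes)}
    rng = np.random.default_rng(seed)
    X = np.zeros((m, len(structure.nodes)))
    for node in order:
        p = params[node]
        if p.residual_variance <= 0:
            raise ValueError(f"noise variance of {node!r} must be > 0")
        eps = rng.normal(0.0, np.sqrt(p.residual_variance), size=m)
        if ar1:
            # AR(1) innovation filter preserving the marginal variance
            innov = eps * np.sqrt(1 - ar1**2)
            out = np.empty(m)
            out[0] = eps[0]
            for t in range(1, m):
                out[t] = ar1 * out[t - 1] + innov[t]
            eps = out
        x = np.full(m, p.mean) + eps
        for parent, b in p.weights.items():
            x = x + b * (X[:, idx[parent]] - params[parent].mean)
        X[:, idx[node]] = x
    return RoiTimeSeriesMatrix(
        values=X,
        node_labels=list(structure.nodes),
        segment_bounds=[(subject_id, 0, m)],
        sampling_interval=sampling_interval,
    )


def _subject_seed(scenario_seed: int, condition: str, subject: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        entropy=scenario_seed, spawn_key=(0 if condition == "A" else 1, subject)
    )


def make_group_scenario(
    scenario: SyntheticScenario, return_nuisance: bool = False
):
    """Generate the two condition groups of a scenario.

    Returns ``(subjects_A, subjects_B)`` lists of per-subject time series;
    with ``return_nuisance=True`` also two lists of the injected
    :class:`NuisanceRegressors` (empty designs when no artifacts are
    injected), so preprocessing can remove exactly what was added.
    """
    groups: dict[str, list[RoiTimeSeriesMatrix]] = {"A": [], "B": []}
    nuisances: dict[str, list[NuisanceRegressors]] = {"A": [], "B": []}
    mvol = scenario.volumes_per_subject
    for condition in ("A", "B"):
        structure, params = scenario.params_for_condition(condition)
        for s in range(scenario.n_subjects):
            ss = _subject_seed(scenario.seed, condition, s)
            sid = f"sub{s:02d}{condition}"
            ts = simulate_gaussian_bn(
                structure,
                params,
                mvol,
                ss,
                sampling_interval=scenario.sampling_interval,
                subject_id=sid,
                ar1=scenario.ar1_coefficient,
            )
            nuis_values = np.zeros((mvol, 0))
            if scenario.artifact_spec is not None:
                art = scenario.artifact_spec
                arng = np.random.default_rng(ss.spawn(1)[0])
                t = np.arange(mvol, dtype=float)
                slopes = arng.uniform(*art.trend_slope_range, size=ts.n_nodes)
                confound = art.nuisance_amplitude * np.sin(
                    2 * np.pi * arng.uniform(0.002, 0.008) * t * scenario.sampling_interval
                    + arng.uniform(0, 2 * np.pi)
                )
                loadings = arng.uniform(0.2, 1.0, size=ts.n_nodes)
                values = (
                    ts.values
                    + np.outer(t - t.mean(), slopes)
                    + np.outer(confound, loadings)
                )
                ts = RoiTimeSeriesMatrix(
                    values=values,
                    node_labels=ts.node_labels,
                    segment_bounds=ts.segment_bounds,
                    sampling_interval=ts.sampling_interval,
                )
                nuis_values = confound[:, None]
            groups[condition].append(ts)
            nuisances[condition].append(
                NuisanceRegressors(
                    values=nuis_values,
                    names=["confound"] if nuis_values.shape[1] else [],
                )
            )
    if return_nuisance:
        return groups["A"], groups["B"], nuisances["A"], nuisances["B"]
    return groups["A"], groups["B"]


def default_scenario(
    seed: int = 0,
    delta_edge: tuple[str, str] | None = None,
    delta: float = 0.0,
    n_subjects: int = 14,
    volumes_per_subject: int = 127,
    edge_prob: float = 0.25,
    artifact_spec: ArtifactSpec | None = None,
) -> SyntheticScenario:
    """The canonical desk-scale scenario: 8 DMN-named nodes, 14 + 14 subjects.

    The network and its weights are drawn from ``seed``; ``delta_edge`` with
    a nonzero ``delta`` makes condition B differ on that edge.
    """
    structure = sample_random_dag(
        len(DMN_NODE_LABELS), edge_prob, seed=seed, labels=DMN_NODE_LABELS
    )
    params = sample_random_parameters(structure, seed=seed + 1)
    deltas = {}
    if delta_edge is not None and delta != 0.0:
        deltas[delta_edge] = delta
    return SyntheticScenario(
        structure=structure,
        base_params=params,
        condition_deltas=deltas,
        n_subjects=n_subjects,
        volumes_per_subject=volumes_per_subject,
        seed=seed,
        artifact_spec=artifact_spec,
    )


def ground_truth_dict(scenario: SyntheticScenario) -> dict:
    """JSON-serializable ground truth: structure, weights, deltas, scale."""
    sa, pa = scenario.params_for_condition("A")
    sb, pb = scenario.params_for_condition("B")
    return {
        "nodes": list(scenario.structure.nodes),
        "edges_A": [
            {"parent": u, "child": v, "weight": pa[v].weights[u]}
            for u, v in sa.edges()
        ],
        "edges_B": [
            {"parent": u, "child": v, "weight": pb[v].weights[u]}
            for u, v in sb.edges()
        ],
        "condition_deltas": [
            {"parent": u, "child": v, "delta": d}
            for (u, v), d in sorted(scenario.condition_deltas.items())
        ],
        "n_subjects": scenario.n_subjects,
        "volumes_per_subject": scenario.volumes_per_subject,
        "sampling_interval": scenario.sampling_interval,
        "seed": scenario.seed,
    }
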