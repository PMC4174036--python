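"""Serialization of learned networks and comparison results.

Models go out as JSON (nodes, edges with weights and residual variances,
score breakdown), DOT and GraphML graphs, and a flat TSV edge table.
Comparison results go out as TSV/JSON plus an annotated DOT graph in which
edges whose weight is significantly stronger in one condition are
highlighted.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .bn_core import BnModel
from .group_compare import GroupComparisonResult

__all__ = [
    "model_to_dict",
    "write_model_json",
    "write_model_dot",
    "write_model_graphml",
    "write_edge_table",
    "write_comparison",
]


def model_to_dict(model: BnModel) -> dict:
    return {
        "nodes": list(model.structure.nodes),
        "edges": [
            {
                "parent": u,
                "child": v,
                "weight": model.params[v].weights[u],
            }
            for u, v in model.structure.edges()
        ],
        "node_params": {
            n: {
                "mean": model.params[n].mean,
                "residual_variance": model.params[n].residual_variance,
            }
            for n in model.structure.nodes
        },
        "score": {
            "per_node_loglik": dict(model.score.per_node_loglik),
            "total_loglik": model.score.total_loglik,
            "d": model.score.d,
            "m": model.score.m,
            "bic": model.score.total,
        },
    }


def write_model_json(model: BnModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2, sort_keys=True))


def _model_graph(model: BnModel) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(model.structure.nodes)
    for (u, v), w in model.edge_weights().items():
        g.add_edge(u, v, weight=round(float(w), 6))
    return g


def write_model_dot(model: BnModel, path) -> None:
    g = _model_graph(model)
    lines = ["digraph bn {"]
    for n in g.nodes:
        lines.append(f'  "{n}";')
    for u, v, data in g.edges(data=True):
        style = "solid" if data["weight"] >= 0 else "dashed"
        lines.append(
            f'  "{u}" -> "{v}" [label="{data["weight"]:.3f}", style={style}];'
        )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_model_graphml(model: BnModel, path) -> None:
    nx.write_graphml(_model_graph(model), str(path))


def write_edge_table(model: BnModel, path) -> None:
    rows = [
        {
            "child": v,
            "parent": u,
            "weight": model.params[v].weights[u],
            "residual_variance": model.params[v].residual_variance,
        }
        for u, v in model.structure.edges()
    ]
    pd.DataFrame(rows, columns=["child", "parent", "weight", "residual_variance"]).to_csv(
        path, sep="\t", index=False
    )


def write_comparison(
    result: GroupComparisonResult,
    out_dir,
    display_alpha: float = 0.05,
    condition_names: tuple[str, str] = ("A", "B"),
) -> None:
    """Write comparison TSV + JSON + annotated DOT under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    a, b = condition_names
    df = result.table.rename(
        columns={
            "weight_A": f"weight_{a}",
            "weight_B": f"weight_{b}",
            "p_A_greater": f"p_{a}_gt_{b}",
            "p_B_greater": f"p_{b}_gt_{a}",
        }
    )
    df.to_csv(out / "comparison.tsv", sep="\t", index=False)
    payload = {
        "n_permutations": result.n_permutations,
        "seed": result.seed,
        "edges": df.to_dict(orient="records"),
    }
    (out / "comparison.json").write_text(json.dumps(payload, indent=2))

    lines = ["digraph comparison {"]
    nodes = sorted(set(df["parent"]) | set(df["child"]))
    for n in nodes:
        lines.append(f'  "{n}";')
    for row in result.table.itertuples():
        if row.p_A_greater <= display_alpha:
            color = "blue"  # stronger in condition A
        elif row.p_B_greater <= display_alpha:
            color = "red"  # stronger in condition B
        else:
            color = "gray"
        lines.append(
            f'  "{row.parent}" -> "{row.child}" '
            f'[color={color}, label="{row.observed_diff:+.3f}"];'
        )
    lines.append("}")
    (out / "comparison.dot").write_text("\n".join(lines) + "\n")
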