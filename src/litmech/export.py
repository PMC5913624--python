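"""Serialization of overlap results: TSV tables, network and Sankey JSON.

Both graph documents are renderer-agnostic JSON. The network document
follows the node-link convention (nodes with id/label/role/semtype, links
with source/target/predicates/weight/articles); parallel relationships
between one node pair collapse into a single link whose weight is the total
supporting-publication count and whose predicate labels are sorted and
joined with ``|``. The Sankey document stages flows left to right:
set A -> subjects -> shared terms -> objects -> set B, with band values
equal to supporting-publication counts and predicates rendered in square
brackets. Flow is NOT conserved per node — bands are independent evidence
counts. All writers are byte-stable on identical input.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from .io import format_float
from .overlap import MechanismChain, SharedTerm

TABLE_COLUMNS = [
    "set_a",
    "subject_id",
    "subject_name",
    "subject_semtype",
    "predicate_1",
    "shared_id",
    "shared_name",
    "shared_semtype",
    "predicate_2",
    "object_id",
    "object_name",
    "object_semtype",
    "set_b",
    "uniq_a",
    "uniq_b",
    "score",
    "mean_p_corrected",
    "p_corrected_a",
    "p_corrected_b",
    "odds_ratio_a",
    "odds_ratio_b",
    "pfr_1",
    "pfr_2",
    "articles_a",
    "articles_b",
]

SHARED_TERM_COLUMNS = [
    "key",
    "name",
    "uniq_a",
    "uniq_b",
    "score",
    "mean_p_corrected",
    "p_corrected_a",
    "p_corrected_b",
    "odds_ratio_a",
    "odds_ratio_b",
    "mesh_depth",
]

_ROLE_ORDER = {"article_set": 0, "subject": 1, "shared": 2, "object": 3}


def _node(node_id: str, label: str, role: str, semtype: str = "") -> dict:
    return {"id": node_id, "label": label, "role": role, "semtype": semtype}


def to_network(chains: Sequence[MechanismChain]) -> dict:
    """Force-directed network document for triple-method results.

    One chain contributes five nodes (two article-set anchors and three
    concept nodes) and four links; nodes shared between chains appear once.
    """
    nodes: dict[str, dict] = {}
    links: dict[tuple[str, str], dict] = {}

    def add_link(source: str, target: str, predicate: str, weight: int, articles):
        link = links.setdefault(
            (source, target),
            {"source": source, "target": target, "predicates": [], "weight": 0,
             "articles": []},
        )
        if predicate and predicate not in link["predicates"]:
            link["predicates"].append(predicate)
        link["weight"] += weight
        link["articles"].extend(articles)

    for chain in chains:
        set_a = f"set:{chain.set_a}"
        set_b = f"set:{chain.set_b}"
        nodes.setdefault(set_a, _node(set_a, chain.set_a, "article_set"))
        nodes.setdefault(set_b, _node(set_b, chain.set_b, "article_set"))
        nodes.setdefault(
            chain.subject_id,
            _node(chain.subject_id, chain.subject_name, "subject", chain.subject_semtype),
        )
        nodes.setdefault(
            chain.shared_id,
            _node(chain.shared_id, chain.shared_name, "shared", chain.shared_semtype),
        )
        nodes.setdefault(
            chain.object_id,
            _node(chain.object_id, chain.object_name, "object", chain.object_semtype),
        )
        add_link(set_a, chain.subject_id, "", chain.uniq_a, chain.articles_a)
        add_link(chain.subject_id, chain.shared_id, chain.predicate_1, chain.uniq_a,
                 chain.articles_a)
        add_link(chain.shared_id, chain.object_id, chain.predicate_2, chain.uniq_b,
                 chain.articles_b)
        add_link(chain.object_id, set_b, "", chain.uniq_b, chain.articles_b)

    node_list = sorted(nodes.values(), key=lambda n: (_ROLE_ORDER[n["role"]], n["id"]))
    link_list = []
    for (source, target), link in sorted(links.items()):
        link_list.append(
            {
                "source": source,
                "target": target,
                "predicates": "|".join(sorted(link["predicates"])),
                "weight": link["weight"],
                "articles": link["articles"],
            }
        )
    return {"directed": True, "multigraph": False, "nodes": node_list,
            "links": link_list}


def to_sankey(chains: Sequence[MechanismChain]) -> dict:
    """Staged Sankey document; band value = supporting-publication count."""
    stages = {"article_set_a": 0, "subject": 1, "shared": 2, "object": 3,
              "article_set_b": 4}
    nodes: dict[str, dict] = {}
    flows: dict[tuple[str, str], dict] = {}

    def add_node(node_id: str, label: str, stage: str):
        nodes.setdefault(
            node_id, {"id": node_id, "label": label, "stage": stages[stage]}
        )

    def add_flow(source: str, target: str, value: int, predicate: str = ""):
        flow = flows.setdefault(
            (source, target),
            {"source": source, "target": target, "value": 0, "predicates": []},
        )
        flow["value"] += value
        if predicate and predicate not in flow["predicates"]:
            flow["predicates"].append(predicate)

    for chain in chains:
        set_a, set_b = f"set:{chain.set_a}", f"set:{chain.set_b}"
        add_node(set_a, chain.set_a, "article_set_a")
        add_node(set_b, chain.set_b, "article_set_b")
        add_node(f"subj:{chain.subject_id}", chain.subject_name, "subject")
        add_node(f"shared:{chain.shared_id}", chain.shared_name, "shared")
        add_node(f"obj:{chain.object_id}", chain.object_name, "object")
        add_flow(set_a, f"subj:{chain.subject_id}", chain.uniq_a)
        add_flow(f"subj:{chain.subject_id}", f"shared:{chain.shared_id}",
                 chain.uniq_a, chain.predicate_1)
        add_flow(f"shared:{chain.shared_id}", f"obj:{chain.object_id}",
                 chain.uniq_b, chain.predicate_2)
        add_flow(f"obj:{chain.object_id}", set_b, chain.uniq_b)

    node_list = sorted(nodes.values(), key=lambda n: (n["stage"], n["id"]))
    link_list = []
    for (source, target), flow in sorted(flows.items()):
        label = "[" + "|".join(sorted(flow["predicates"])) + "]" if flow["predicates"] else ""
        link_list.append(
            {"source": source, "target": target, "value": flow["value"],
             "label": label}
        )
    return {"nodes": node_list, "links": link_list}


def _table_row(item) -> list[str]:
    if isinstance(item, MechanismChain):
        columns = TABLE_COLUMNS
    else:
        columns = SHARED_TERM_COLUMNS
    row = []
    for column in columns:
        value = getattr(item, column)
        if isinstance(value, float):
            row.append(format_float(value))
        elif isinstance(value, list):
            row.append(",".join(str(v) for v in value))
        elif value is None:
            row.append("")
        else:
            row.append(str(value))
    return row


def write_table(results: Sequence[MechanismChain | SharedTerm], path: str | Path) -> None:
    """Write results as TSV with all fields including provenance ID lists."""
    items = list(results)
    if items and isinstance(items[0], SharedTerm):
        columns = SHARED_TERM_COLUMNS
    else:
        columns = TABLE_COLUMNS
    lines = ["\t".join(columns)]
    for item in items:
        lines.append("\t".join(_table_row(item)))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_doc(doc: dict, path: str | Path) -> None:
    """Write a network/Sankey document as deterministic JSON."""
    Path(path).write_text(
        json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_doc(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


# --------------------------------------------------- result (de)serialization

def results_to_json(
    results: Sequence[MechanismChain | SharedTerm], metadata: dict | None = None
) -> dict:
    """Lossless JSON document for a result list, for the filter/export steps."""
    items = list(results)
    kind = "chains" if not items or isinstance(items[0], MechanismChain) else "terms"
    rows = []
    for item in items:
        columns = TABLE_COLUMNS if kind == "chains" else SHARED_TERM_COLUMNS
        rows.append({c: getattr(item, c) for c in columns})
    return {"kind": kind, "metadata": metadata or {}, "results": rows}


def results_from_json(doc: dict) -> list[MechanismChain | SharedTerm]:
    cls = MechanismChain if doc["kind"] == "chains" else SharedTerm
    items = []
    for row in doc["results"]:
        row = dict(row)
        row.pop("mean_p_corrected", None)  # derived property, not an init field
        items.append(cls(**row))
    return items


def write_results(
    results: Sequence[MechanismChain | SharedTerm],
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    write_doc(results_to_json(results, metadata), path)


def read_results(path: str | Path) -> list[MechanismChain | SharedTerm]:
    return results_from_json(read_doc(path))
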