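"""Mass-difference (reaction) networks over consensus formula sets.

Nodes are molecular formulas (with consensus intensities); directed, typed
edges connect formula f to formula g whenever a catalog transformation turns
f into g exactly — element-count arithmetic, no mass-tolerance matching,
since formulas are exact objects after assignment.  Edges point reactant →
product in the direction each reaction type is written (chlorination points
toward the chlorinated formula).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

from .chem import (
    MolecularFormula,
    Transformation,
    TransformationNotApplicable,
    apply_transformation,
    format_formula,
    parse_formula,
)

logger = logging.getLogger(__name__)

__all__ = ["default_catalog", "load_catalog", "save_catalog", "build_network",
           "export_graphml", "import_graphml", "edge_list_frame"]


def default_catalog(
    starting_material: MolecularFormula,
    include_defluorination: bool = False,
) -> list[Transformation]:
    """The chloramination reaction-type catalog.

    Eight transformations: decarboxylation (loss of CO₂), hydration (+H₂O),
    oxidation (+O), chlorination (H → Cl), nitration (H → NO₂), amination
    (+NH), nucleophilic aromatic substitution (Cl → NO₂), and esterification
    with one equivalent of the starting material (+SM - H₂O).  For
    fluorinated starting materials, defluorination (F → H) is added with
    ``include_defluorination=True``.
    """
    if not starting_material:
        raise ValueError("empty starting material")
    sm = dict(starting_material)
    ester = dict(sm)
    ester["H"] = ester.get("H", 0) - 2
    ester["O"] = ester.get("O", 0) - 1
    if ester["H"] < 0 or ester["O"] < 0:
        raise ValueError(
            "esterification delta undefined: starting material smaller than H2O"
        )
    catalog = [
        Transformation("decarboxylation", {"C": -1, "O": -2}),
        Transformation("hydration", {"H": 2, "O": 1}),
        Transformation("oxidation", {"O": 1}),
        Transformation("chlorination", {"H": -1, "Cl": 1}),
        Transformation("nitration", {"H": -1, "N": 1, "O": 2}),
        Transformation("amination", {"N": 1, "H": 1}),
        Transformation("SNAr", {"Cl": -1, "N": 1, "O": 2}),
        Transformation("esterification", ester),
    ]
    if include_defluorination:
        catalog.append(Transformation("defluorination", {"F": -1, "H": 1}))
    return catalog


def load_catalog(path) -> list[Transformation]:
    """Load a transformation catalog from a YAML file of name → delta maps."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or not data:
        raise ValueError(f"catalog file {path} must map names to element deltas")
    catalog = []
    for name, delta in data.items():
        try:
            catalog.append(Transformation(str(name), {str(k): int(v)
                                                      for k, v in delta.items()}))
        except (TypeError, ValueError, AttributeError) as exc:
            raise ValueError(f"malformed catalog entry {name!r}: {exc}") from exc
    return catalog


def save_catalog(catalog: Iterable[Transformation], path) -> None:
    data = {t.name: dict(t.delta) for t in catalog}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def build_network(consensus, catalog: Iterable[Transformation]) -> nx.MultiDiGraph:
    """Connect every formula pair related by a catalog transformation.

    *consensus* is a :class:`~isoreact.assign.ConsensusFormulaSet` or a
    formula → intensity mapping.  Returns a MultiDiGraph whose node keys are
    Hill formula strings with ``intensity`` attributes and whose edges carry
    a ``transformation`` attribute; parallel edges of distinct types are
    kept.
    """
    if isinstance(consensus, Mapping):
        formulas = dict(consensus)
    else:
        formulas = dict(consensus.formulas)
    if not formulas:
        raise ValueError("empty consensus set")
    catalog = list(catalog)
    net = nx.MultiDiGraph()
    by_formula = {f: format_formula(f) for f in formulas}
    for f, name in sorted(by_formula.items(), key=lambda kv: kv[1]):
        net.add_node(name, formula=name, intensity=float(formulas[f]))
    for f in sorted(formulas, key=format_formula):
        for t in catalog:
            try:
                g = apply_transformation(f, t)
            except TransformationNotApplicable:
                continue
            if g in formulas and g != f:
                net.add_edge(by_formula[f], by_formula[g], key=t.name,
                             transformation=t.name)
    logger.info("network: %d nodes, %d edges (%d reaction types)",
                net.number_of_nodes(), net.number_of_edges(), len(catalog))
    return net


def export_graphml(net: nx.MultiDiGraph, path) -> None:
    """Write the network as Cytoscape-compatible GraphML."""
    nx.write_graphml(net, path)


def import_graphml(path) -> nx.MultiDiGraph:
    g = nx.read_graphml(path, force_multigraph=True)
    return nx.MultiDiGraph(g)


def edge_list_frame(net: nx.MultiDiGraph) -> pd.DataFrame:
    """Edge list (source, target, transformation), deterministically sorted."""
    rows = [{"source": u, "target": v,
             "transformation": d.get("transformation", k)}
            for u, v, k, d in net.edges(keys=True, data=True)]
    df = pd.DataFrame(rows, columns=["source", "target", "transformation"])
    return df.sort_values(["source", "target", "transformation"],
                          kind="mergesort").reset_index(drop=True)
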