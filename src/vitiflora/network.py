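"""Enzyme -> product bipartite network with major/minor edges.

Characterized terpene synthases are source nodes, their volatile products
target nodes, and each edge carries the percentage contribution of that
product in the enzyme's heterologous assay.  Edges above the major
threshold (strictly > 10% by default) are classed 'major'; enzyme nodes are
colored by the cation cascade accounting for the largest summed share of
their products.  Percentages are used as printed — no renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .cascades import CascadeMap, UNASSIGNED

__all__ = [
    "ProductProfile",
    "load_product_profiles",
    "load_default_product_profiles",
    "validate_profiles",
    "build_network",
    "export_network",
    "import_graphml",
]

MAJOR, MINOR = "major", "minor"


@dataclass
class ProductProfile:
    """One enzyme's product spectrum: compound -> % contribution."""

    enzyme: str
    products: dict[str, float]
    source: str = "this-study"


def load_product_profiles(
    path: Path | str, source: str = "this-study"
) -> list[ProductProfile]:
    """Read a compounds x enzymes percentage CSV (product-table layout)."""
    df = pd.read_csv(path, comment="#")
    compound_col = df.columns[0]
    profiles = []
    for enzyme in df.columns[1:]:
        col = df[[compound_col, enzyme]].dropna()
        products = {
            str(c): float(v) for c, v in zip(col[compound_col], col[enzyme])
        }
        profiles.append(ProductProfile(enzyme, products, source))
    return profiles


def load_default_product_profiles() -> list[ProductProfile]:
    """The packaged heterologous product-percentage table (7 enzymes)."""
    path = resources.files("vitiflora") / "data" / "product_profiles.csv"
    return load_product_profiles(path)


def validate_profiles(
    profiles: Iterable[ProductProfile],
    tolerance: tuple[float, float] = (90.0, 101.0),
) -> list[dict[str, object]]:
    """Quality gate: flag enzymes whose percentages sum outside the window.

    Sub-100 sums are common in printed product tables (trace products are
    dropped), hence the asymmetric default window.  Negative percentages are
    an error; warnings never mutate the data.
    """
    lo, hi = tolerance
    report = []
    for p in profiles:
        negs = {c: v for c, v in p.products.items() if v < 0}
        if negs:
            raise ValueError(
                f"negative percentage(s) for enzyme {p.enzyme}: {negs}"
            )
        total = sum(p.products.values())
        report.append(
            {
                "enzyme": p.enzyme,
                "sum": round(total, 6),
                "ok": lo <= total <= hi,
            }
        )
    return report


def build_network(
    profiles: Iterable[ProductProfile],
    cascade_map: CascadeMap,
    major_threshold: float = 10.0,
) -> nx.DiGraph:
    """Directed bipartite enzyme -> compound graph.

    Edge attributes: ``weight`` (% as printed) and ``edge_class``
    (major iff weight > major_threshold, strictly).  Enzyme nodes get
    ``color`` = dominant cation class of their products (ties broken
    lexicographically and flagged via ``color_tied``).
    """
    g = nx.DiGraph(major_threshold=major_threshold)
    for p in profiles:
        class_sums: dict[str, float] = {}
        for compound, weight in p.products.items():
            cat = cascade_map.resolve(compound)
            class_sums[cat] = class_sums.get(cat, 0.0) + weight
            if not g.has_node(compound):
                g.add_node(compound, bipartite="compound")
            g.add_edge(
                p.enzyme,
                compound,
                weight=float(weight),
                edge_class=MAJOR if weight > major_threshold else MINOR,
            )
        if class_sums:
            best = max(class_sums.values())
            winners = sorted(c for c, s in class_sums.items() if s == best)
            color, tied = winners[0], len(winners) > 1
        else:
            color, tied = UNASSIGNED, False
        g.add_node(
            p.enzyme,
            bipartite="enzyme",
            source=p.source,
            color=color,
            color_tied=tied,
        )
    return g


def _edge_rows(g: nx.DiGraph) -> list[tuple]:
    rows = [
        (u, v, d["weight"], d["edge_class"]) for u, v, d in g.edges(data=True)
    ]
    rows.sort(key=lambda r: (r[0], -r[2], r[1]))
    return rows


def export_network(g: nx.DiGraph, path: Path | str, fmt: str = "graphml") -> Path:
    """Write the network as graphml (lossless), edge-TSV (lossless) or SIF.

    SIF carries topology and edge class only; edge TSV is sorted by
    (enzyme, weight descending) for deterministic diffs.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edge-tsv":
        rows = _edge_rows(g)
        with open(path, "w") as fh:
            fh.write("enzyme\tcompound\tweight\tedge_class\tenzyme_color\n")
            for u, v, w, cls in rows:
                fh.write(f"{u}\t{v}\t{w}\t{cls}\t{g.nodes[u].get('color','')}\n")
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, w, cls in _edge_rows(g):
                fh.write(f"{u}\t{cls}\t{v}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def import_graphml(path: Path | str) -> nx.DiGraph:
    """Inverse of graphml export (types restored for round-tripping)."""
    g = nx.read_graphml(path)
    out = nx.DiGraph(**{k: v for k, v in g.graph.items()})
    for n, d in g.nodes(data=True):
        out.add_node(n, **d)
    for u, v, d in g.edges(data=True):
        d = dict(d)
        d["weight"] = float(d["weight"])
        out.add_edge(u, v, **d)
    return out
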