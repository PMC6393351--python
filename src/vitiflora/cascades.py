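"""Carbocation cascade classification and biosynthetic flux profiles.

Every sesquiterpene derives from farnesyl diphosphate (FPP) through a small
set of reactive carbocation intermediates: direct deprotonation of the
farnesyl cation yields the linear farnesenes, a 1,11-ring closure through
the humulyl cation yields humulenes/caryophyllenes, a 1,10-closure through
the (E,E)-germacradienyl cation yields the cyclic selinene/valencene/
germacrene group, and FPP->NPP isomerisation opens the nerolidyl/bisabolyl
route.  Grouping an emitted volatile blend by the cascade required for each
compound turns a chemotype into a flux profile: the percentage of total
sesquiterpene output routed through each cation branchpoint.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .volatiles import ConcentrationTable

__all__ = [
    "CascadeMap",
    "FluxProfile",
    "load_default_cascade_map",
    "assign_cascade",
    "compute_flux",
    "flux_range",
    "CATION_CLASSES",
    "UNASSIGNED",
]

CATION_CLASSES = (
    "farnesyl",
    "humulyl",
    "germacradienyl",
    "nerolidyl_bisabolyl",
)
UNASSIGNED = "unassigned"


def _norm(name: str) -> str:
    """Case-insensitive, accent/greek-tolerant key for compound lookup."""
    s = unicodedata.normalize("NFKC", name).strip().lower()
    for greek, latin in (("α", "alpha"), ("β", "beta"), ("γ", "gamma"),
                         ("δ", "delta"), ("ε", "epsilon")):
        s = s.replace(greek, latin)
    return " ".join(s.split())


@dataclass
class CascadeMap:
    """compound -> cation class with an alias table for naming variants."""

    assignments: dict[str, str]
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.assignments.values() if c not in CATION_CLASSES}
        if bad:
            raise ValueError(f"unknown cation class(es): {sorted(bad)}")
        self._lookup = {_norm(k): v for k, v in self.assignments.items()}
        self._alias = {_norm(k): _norm(v) for k, v in self.aliases.items()}

    def resolve(self, compound: str) -> str:
        key = _norm(compound)
        key = self._alias.get(key, key)
        return self._lookup.get(key, UNASSIGNED)

    def reassign(self, compound: str, cation_class: str) -> "CascadeMap":
        """A copy with one compound moved to another class."""
        if cation_class not in CATION_CLASSES:
            raise ValueError(f"unknown cation class {cation_class!r}")
        new = dict(self.assignments)
        key = _norm(compound)
        key = self._alias.get(key, key)
        for k in list(new):
            if _norm(k) == key:
                new[k] = cation_class
                break
        else:
            new[compound] = cation_class
        return CascadeMap(new, dict(self.aliases))


def _read_2col_tsv(path, col_a: str, col_b: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df[col_a].astype(str), df[col_b].astype(str)))


def load_cascade_map(map_path: Path, alias_path: Path | None = None) -> CascadeMap:
    assignments = _read_2col_tsv(map_path, "compound", "cation_class")
    aliases = (
        _read_2col_tsv(alias_path, "alias", "compound") if alias_path else {}
    )
    return CascadeMap(assignments, aliases)


def load_default_cascade_map() -> CascadeMap:
    """The packaged compound -> cascade table (editable TSV under data/)."""
    data = resources.files("vitiflora") / "data"
    return load_cascade_map(
        data / "cascade_map.tsv", data / "cascade_aliases.tsv"
    )


def assign_cascade(compound: str, cascade_map: CascadeMap) -> str:
    """Cation class of a compound; 'unassigned' for unknown names."""
    return cascade_map.resolve(compound)


@dataclass
class FluxProfile:
    """Flux through each cation class, as % of total sesquiterpenes.

    ``label`` identifies the sample or the (cultivar, stage) group;
    ``total`` is the summed sesquiterpene concentration in µg/g FW.
    """

    label: str
    percentages: dict[str, float]
    total: float

    def __post_init__(self) -> None:
        ssum = sum(self.percentages.values())
        if self.total > 0 and abs(ssum - 100.0) > 1e-6:
            raise ValueError(f"percentages sum to {ssum}, not 100")


def compute_flux(
    conc: ConcentrationTable,
    cascade_map: CascadeMap,
    compound_class: list[str] | None = None,
    by_group: bool = False,
) -> list[FluxProfile]:
    """Per-sample (or per cultivar x stage) cascade flux percentages.

    Concentrations are summed by cation class and divided by the total over
    the compound class; with ``by_group`` replicates are averaged on the
    concentration scale before percentages are formed (one profile per
    cultivar x stage cell, as in per-group doughnut summaries).  All-zero
    samples are excluded.
    """
    comps = conc.compounds if compound_class is None else list(compound_class)
    if not comps:
        raise ValueError("compound class is empty")
    vals = conc.wide[comps]
    if by_group:
        grouped = vals.join(conc.wide[["cultivar", "stage"]]).groupby(
            ["cultivar", "stage"], sort=True
        )[comps].mean()
        frames = [
            (f"{cv}|{st}", grouped.loc[(cv, st)])
            for cv, st in grouped.index
        ]
    else:
        frames = [(str(idx), row) for idx, row in vals.iterrows()]

    classes = list(CATION_CLASSES) + [UNASSIGNED]
    profiles: list[FluxProfile] = []
    for label, row in frames:
        total = float(row.sum())
        if total <= 0:
            continue
        sums = {c: 0.0 for c in classes}
        for comp, v in row.items():
            sums[cascade_map.resolve(comp)] += float(v)
        pct = {c: 100.0 * s / total for c, s in sums.items()}
        profiles.append(FluxProfile(label=label, percentages=pct, total=total))
    return profiles


def flux_range(
    profiles: Iterable[FluxProfile], cation_class: str
) -> tuple[float, float]:
    """Inclusive (min, max) of one class's flux percentage across profiles."""
    shares = [p.percentages.get(cation_class, 0.0) for p in profiles]
    if not shares:
        raise ValueError("no flux profiles given")
    return min(shares), max(shares)
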