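"""The packaged study data: 15 drug graphs, their physicochemical properties,
and the published index table with an errata layer.

Fifteen non-oncology drugs with reported anti-cancer potential are shipped as
edge-list fixtures.  Where the published index row is consistent with the
drug's standard 2D structure, the fixture is that structure (hydrogen
suppressed).  For six drugs the published row is *not* consistent with the
standard structure but is internally consistent with a unique edge partition
(recoverable because the exponential-index cells equal ``e^integer``); the
fixture is then a synthetic graph realising that partition, marked
``reconstructed-from-published-partition`` in its sidecar.

The published table is shipped verbatim, including its defective cells; an
errata layer flags each cell that fails hand-verification and records the
value consistent with the rest of the row.  Regressions can be fed any of
three variants of this table (``computed``, ``published``,
``published_with_corrections``).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Literal, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import indices as _indices
from . import molgraph as _molgraph
from .indices import INDEX_NAMES, IndexValue
from .molgraph import MolecularGraph

__all__ = [
    "PROPERTY_NAMES",
    "DrugRecord",
    "PublishedCell",
    "Discrepancy",
    "load_builtin_drugs",
    "computed_index_table",
    "load_published_table",
    "discrepancy_report",
    "regression_input_table",
]

PROPERTY_NAMES = ("MP", "BP", "WS", "D", "VP", "MW")

Source = Literal["computed", "published", "published_with_corrections"]


@dataclass(frozen=True)
class DrugRecord:
    """One drug: its name, molecular graph and six property values."""

    name: str
    graph: MolecularGraph
    properties: Mapping[str, float]

    def __post_init__(self):
        missing = set(PROPERTY_NAMES) - set(self.properties)
        if missing:
            raise ValueError(f"{self.name}: missing properties {sorted(missing)}")
        if self.properties["MW"] <= 0 or self.properties["D"] <= 0:
            raise ValueError(f"{self.name}: MW and D must be positive")


@dataclass(frozen=True)
class PublishedCell:
    """One printed cell of the published index table."""

    drug: str
    index: str
    printed: float
    erratum: bool
    corrected: Optional[float]
    note: str

    @property
    def value(self) -> float:
        """Printed value with the erratum correction applied when available."""
        return self.corrected if (self.erratum and self.corrected is not None) else self.printed


@dataclass(frozen=True)
class Discrepancy:
    drug: str
    index: str
    published: float
    computed: float
    relative_difference: float
    classification: str  # match | rounding | erratum


def _data_text(name: str) -> str:
    return resources.files("topoqspr.data").joinpath(name).read_text()


def load_builtin_drugs() -> List[DrugRecord]:
    """The 15 packaged drugs, in the published table's row order."""
    rows = list(csv.DictReader(_data_text("properties.csv").splitlines()))
    records = []
    for row in rows:
        name = row["Name"]
        slug = name.lower().replace(" ", "_")
        sidecar = json.loads(_data_text(f"structures/{slug}.json"))
        try:
            graph = _molgraph.from_edge_list(_data_text(f"structures/{sidecar['file']}"))
        except _molgraph.GraphValidationError as exc:
            raise _molgraph.GraphValidationError(f"fixture {name!r}: {exc}") from exc
        props = {p: float(row[p]) for p in PROPERTY_NAMES}
        records.append(DrugRecord(name=name, graph=graph, properties=props))
    if len(records) != 15:
        raise ValueError(f"expected 15 drug records, found {len(records)}")
    return records


def computed_index_table(
    drugs: Optional[List[DrugRecord]] = None,
) -> Dict[Tuple[str, str], IndexValue]:
    """Deterministic 15 x 6 descriptor matrix computed from the fixture graphs."""
    if drugs is None:
        drugs = load_builtin_drugs()
    table = {}
    for rec in drugs:
        for idx_name, val in _indices.compute_all(rec.graph).items():
            table[(rec.name, idx_name)] = val
    return table


def load_published_table() -> Dict[Tuple[str, str], PublishedCell]:
    """The printed index table, verbatim, with the errata annotation layer."""
    out = {}
    for row in csv.DictReader(_data_text("published_indices.csv").splitlines()):
        corrected = float(row["Corrected"]) if row["Corrected"] else None
        out[(row["Name"], row["Index"])] = PublishedCell(
            drug=row["Name"],
            index=row["Index"],
            printed=float(row["Printed"]),
            erratum=bool(int(row["Erratum"])),
            corrected=corrected,
            note=row["Note"],
        )
    return out


def discrepancy_report(
    computed: Optional[Mapping[Tuple[str, str], IndexValue]] = None,
    published: Optional[Mapping[Tuple[str, str], PublishedCell]] = None,
) -> List[Discrepancy]:
    """Classify every published cell against the computed value.

    The exponential indices are compared on the natural-log scale (their
    printed forms frequently drop exponents); all others on the linear scale.
    ``match`` requires 5e-4 relative agreement; flagged errata are always
    classified ``erratum``.
    """
    if computed is None:
        computed = computed_index_table()
    if published is None:
        published = load_published_table()
    if set(computed) != set(published):
        raise ValueError("computed and published tables cover different cells")
    report = []
    for key in sorted(published):
        cell = published[key]
        comp = computed[key]
        if comp.index_name in ("EPi1", "EPi2"):
            pub_scale = math.log(cell.printed) if cell.printed > 0 else float("nan")
            comp_scale = comp.ln_value
        else:
            pub_scale = cell.printed
            comp_scale = comp.linear_value
        rel = abs(pub_scale - comp_scale) / max(1.0, abs(comp_scale))
        if cell.erratum:
            cls = "erratum"
        elif rel <= 5e-4:
            cls = "match"
        elif rel <= 5e-3:
            cls = "rounding"
        else:
            cls = "erratum"
        report.append(
            Discrepancy(cell.drug, cell.index, pub_scale, comp_scale, rel, cls)
        )
    return report


def regression_input_table(source: Source = "computed") -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Aligned (index matrix, property matrix) in fixed drug order.

    ``computed``: indices from the fixture graphs (exponential indices on the
    linear scale when representable, else ``inf``).  ``published``: the printed
    table verbatim.  ``published_with_corrections``: printed values with only
    the errata cells replaced.
    """
    drugs = load_builtin_drugs()
    order = [rec.name for rec in drugs]
    props = pd.DataFrame(
        [[rec.properties[p] for p in PROPERTY_NAMES] for rec in drugs],
        index=order,
        columns=list(PROPERTY_NAMES),
    )
    if source == "computed":
        table = computed_index_table(drugs)
        data = {
            idx: [
                table[(name, idx)].linear_value
                if table[(name, idx)].linear_value is not None
                else np.inf
                for name in order
            ]
            for idx in INDEX_NAMES
        }
    elif source in ("published", "published_with_corrections"):
        pub = load_published_table()
        use_corrections = source == "published_with_corrections"
        data = {
            idx: [
                pub[(name, idx)].value if use_corrections else pub[(name, idx)].printed
                for name in order
            ]
            for idx in INDEX_NAMES
        }
    else:
        raise ValueError(f"unknown source {source!r}")
    return pd.DataFrame(data, index=order), props


def ln_index_column(source: Source, index: str) -> pd.Series:
    """Natural-log column of an index for logarithmic-family regressions.

    For the exponential indices under ``source='computed'`` the exact integer
    ``ln`` is used directly rather than ``log(exp(...))``.
    """
    if source == "computed" and index in ("EPi1", "EPi2"):
        table = computed_index_table()
        drugs = [rec.name for rec in load_builtin_drugs()]
        return pd.Series([table[(n, index)].ln_value for n in drugs], index=drugs, name=index)
    idx_mat, _ = regression_input_table(source)
    col = idx_mat[index]
    if (col <= 0).any():
        bad = col.index[col <= 0][0]
        raise ValueError(f"nonpositive {index} value for {bad}; cannot take log")
    return np.log(col)
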