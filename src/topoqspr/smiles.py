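"""Optional SMILES ingestion, layered on RDKit.

Converts a SMILES string to the internal hydrogen-suppressed
:class:`~topoqspr.molgraph.MolecularGraph`: heavy atoms become vertices
labelled ``<element><index>``, bonds become edges regardless of order.  The
core package never imports RDKit; this adapter fails with a clear message
when it is not installed.
"""

from __future__ import annotations

from .molgraph import GraphValidationError, MolecularGraph, from_edge_list

__all__ = ["from_smiles", "to_edge_list_text"]


def _require_rdkit():
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "SMILES ingestion requires the optional rdkit dependency "
            "(pip install topoqspr[smiles])"
        ) from exc
    return Chem


def to_edge_list_text(smiles: str) -> str:
    """Render a SMILES string as the package's edge-list format."""
    Chem = _require_rdkit()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GraphValidationError(f"could not parse SMILES {smiles!r}")
    labels = {a.GetIdx(): f"{a.GetSymbol()}{a.GetIdx() + 1}" for a in mol.GetAtoms()}
    lines = [
        f"{labels[b.GetBeginAtomIdx()]} {labels[b.GetEndAtomIdx()]}"
        for b in mol.GetBonds()
    ]
    if not lines:
        raise GraphValidationError(f"SMILES {smiles!r} has no bonds between heavy atoms")
    return "\n".join(lines) + "\n"


def from_smiles(smiles: str, *, allow_disconnected: bool = False) -> MolecularGraph:
    """Parse a SMILES string into a validated molecular graph."""
    return from_edge_list(to_edge_list_text(smiles), allow_disconnected=allow_disconnected)
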