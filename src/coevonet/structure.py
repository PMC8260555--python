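"""Native contact maps from structures and native-contact filtering.

Two residues are in contact when their Cβ atoms (Cα for glycine) are closer
than 6.5 Å (strict inequality) and are at least ``min_separation`` apart
along the chain.  The coupling tensor or a projected energy matrix can be
filtered to its native contacts, zeroing every non-contact pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

if TYPE_CHECKING:  # pragma: no cover
    from .coevolution import CouplingTensor
    from .energetics import ContactEnergyMatrix

DEFAULT_CUTOFF = 6.5  # Å
DEFAULT_MIN_SEPARATION = 2  # exclude |i−j| < 2 (self and chain neighbours)


@dataclass
class ContactMap:
    """Symmetric boolean residue-pair adjacency with zero diagonal."""

    adj: np.ndarray
    source: str = "synthetic"
    coords: np.ndarray | None = None  # optional embedding, one point per residue

    def __post_init__(self) -> None:
        self.adj = np.asarray(self.adj, dtype=bool)
        n = self.adj.shape[0]
        if self.adj.shape != (n, n):
            raise ValueError("contact map must be square")
        if not np.array_equal(self.adj, self.adj.T):
            raise ValueError("contact map must be symmetric")
        if np.any(np.diag(self.adj)):
            raise ValueError("contact map diagonal must be empty")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 3):
                raise ValueError("coords must be (N, 3)")

    @property
    def n_residues(self) -> int:
        return self.adj.shape[0]

    @property
    def n_contacts(self) -> int:
        return int(self.adj.sum()) // 2

    def contact_pairs(self) -> np.ndarray:
        """Upper-triangle (i, j) index pairs of contacts, 0-based."""
        i, j = np.where(np.triu(self.adj, k=1))
        return np.column_stack([i, j])

    def write_tsv(self, path: str | Path) -> None:
        """Edge list (i, j, 1), 1-based, with a '#N=' header for the size."""
        with open(path, "w") as fh:
            fh.write(f"#N={self.n_residues}\n")
            fh.write("i\tj\tcontact\n")
            for i, j in self.contact_pairs():
                fh.write(f"{i + 1}\t{j + 1}\t1\n")

    @classmethod
    def read_tsv(cls, path: str | Path, source: str = "synthetic") -> "ContactMap":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().strip()
        if not header.startswith("#N="):
            raise ValueError(f"{path} lacks the '#N=<size>' header line")
        n = int(header[3:])
        adj = np.zeros((n, n), dtype=bool)
        import pandas as pd

        table = pd.read_csv(path, sep="\t", skiprows=1)
        for i, j in zip(table["i"], table["j"]):
            adj[i - 1, j - 1] = adj[j - 1, i - 1] = True
        np.fill_diagonal(adj, False)
        return cls(adj=adj, source=source)


def _reference_atoms(chain) -> tuple[np.ndarray, list[str]]:
    """One Cβ (Cα for glycine) coordinate per standard residue."""
    coords, names = [], []
    for res in chain:
        if res.id[0] != " ":  # skip waters / hetero residues
            continue
        resname = res.get_resname()
        atom = None
        if resname != "GLY" and "CB" in res:
            atom = res["CB"]
        elif "CA" in res:
            atom = res["CA"]
        if atom is None:
            raise ValueError(
                f"residue {resname} {res.id[1]} has neither CB nor CA"
            )
        coords.append(atom.coord)
        names.append(resname)
    return np.asarray(coords, dtype=float), names


def contact_map_from_structure(
    structure,
    cutoff: float = DEFAULT_CUTOFF,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    chain_id: str | None = None,
    n_expected: int | None = None,
    source: str = "crystallographic",
) -> ContactMap:
    """Build the contact map of a single-chain structure.

    ``structure`` is a PDB file path or a Bio.PDB entity.  Distances are
    measured between Cβ atoms (Cα for glycine); a residue missing both is
    an error.  ``n_expected`` (e.g. the alignment width) is validated if
    given.
    """
    if isinstance(structure, (str, Path)):
        from Bio.PDB import PDBParser

        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("protein", str(structure))
    model = next(iter(structure))
    chains = list(model)
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
        if not chains:
            raise ValueError(f"chain {chain_id!r} not found")
    if len(chains) != 1:
        raise ValueError("structure must provide exactly one chain (use chain_id)")
    coords, _ = _reference_atoms(chains[0])
    if n_expected is not None and len(coords) != n_expected:
        raise ValueError(
            f"chain length {len(coords)} does not match expected {n_expected}"
        )
    return contact_map_from_coords(coords, cutoff, min_separation, source=source)


def contact_map_from_coords(
    coords: np.ndarray | Sequence,
    cutoff: float = DEFAULT_CUTOFF,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    source: str = "synthetic",
) -> ContactMap:
    """Contact map from one reference point per residue (strict ``<`` cutoff)."""
    coords = np.asarray(coords, dtype=float)
    dist = squareform(pdist(coords))
    adj = dist < cutoff
    n = len(coords)
    sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    adj &= sep >= min_separation
    return ContactMap(adj=adj, source=source, coords=coords)


def filter_to_native(obj, cm: ContactMap):
    """Zero every tensor/matrix element outside the native contacts.

    Accepts a :class:`~coevonet.coevolution.CouplingTensor` or a
    :class:`~coevonet.energetics.ContactEnergyMatrix`; returns the same
    type.  Idempotent, and commutes with the gap re-gauging.
    """
    from .coevolution import CouplingTensor
    from .energetics import ContactEnergyMatrix

    if isinstance(obj, CouplingTensor):
        if obj.n_columns != cm.n_residues:
            raise ValueError("tensor and contact map dimensions disagree")
        eps = obj.eps * cm.adj[:, :, None, None]
        return CouplingTensor(eps=eps, family=obj.family, meta=dict(obj.meta))
    if isinstance(obj, ContactEnergyMatrix):
        if obj.e.shape[0] != cm.n_residues:
            raise ValueError("energy matrix and contact map dimensions disagree")
        support = cm.adj if obj.contacts is None else (obj.contacts & cm.adj)
        return ContactEnergyMatrix(
            e=obj.e * cm.adj, protein_id=obj.protein_id, age=obj.age, contacts=support
        )
    raise TypeError(f"cannot filter object of type {type(obj).__name__}")
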