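"""Synthetic inputs with known ground truth.

Everything the analysis pipeline consumes can be generated here without
downloads: a compact self-avoiding chain on a cubic lattice (whose contact
map has protein-like surface-to-volume behaviour for chain-segment cuts),
a planted Potts model with attractive — and optionally repulsive
("frustrated") — preferred residue pairs on the native contacts, Monte
Carlo equilibrium alignments sampled from that model, and dated
extant-plus-ancestral sequence sets evolved along a random ultrametric
tree with a tunable selection-pressure schedule.

The chain layout starts from a boustrophedon walk filling a near-cubic box
(5 Å lattice spacing, so lattice neighbours sit inside the 6.5 Å contact
cutoff and everything else outside) and is randomised with backbite moves,
which mix the chain through the compact volume the way real globules do.
Sampling runs one independent Markov chain per output sequence, so samples
are exactly independent after the burn-in sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment_io import AlignmentMatrix
from .alphabet import GAP_STATE, N_STATES
from .coevolution import CouplingTensor
from .structure import DEFAULT_MIN_SEPARATION, ContactMap, contact_map_from_coords

LATTICE_SPACING = 5.0  # Å; < 6.5 for neighbours, √2·5 ≈ 7.07 > 6.5 otherwise
N_RES = 20  # synthetic sequences are gap-free


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _box_dimensions(n: int) -> tuple[int, int, int]:
    a = max(2, round(n ** (1 / 3)))
    b = max(2, int(np.ceil(np.sqrt(n / a))))
    c = int(np.ceil(n / (a * b)))
    return a, b, c


def _serpentine(n: int) -> np.ndarray:
    """Boustrophedon Hamiltonian walk through the first n sites of a box."""
    a, b, c = _box_dimensions(n)
    coords = []
    for z in range(c):
        ys = range(b) if z % 2 == 0 else range(b - 1, -1, -1)
        for y in ys:
            flip = (y + z) % 2 == 1
            xs = range(a - 1, -1, -1) if flip else range(a)
            for x in xs:
                coords.append((x, y, z))
    return np.array(coords[:n], dtype=int)


_NEIGHBOUR_STEPS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _backbite_mix(path: np.ndarray, n_moves: int, rng: np.random.Generator) -> np.ndarray:
    """Randomise a self-avoiding lattice path with backbite moves.

    The chain end reconnects to one of its occupied lattice neighbours and
    the loop beyond the reconnection is reversed; the occupied site set
    (hence compactness) is preserved.
    """
    path = [tuple(p) for p in path]
    for _ in range(n_moves):
        if rng.random() < 0.5:
            path.reverse()
        index = {p: k for k, p in enumerate(path)}
        end = np.array(path[-1])
        candidates = []
        for step in _NEIGHBOUR_STEPS:
            v = tuple(end + step)
            j = index.get(v)
            if j is not None and j < len(path) - 2:
                candidates.append(j)
        if not candidates:
            continue
        j = int(rng.choice(candidates))
        path = path[: j + 1] + path[j + 1 :][::-1]
    return np.array(path, dtype=int)


def compact_chain_coords(
    n: int, seed=0, n_backbite: int | None = None
) -> np.ndarray:
    """Coordinates (Å) of a randomised compact lattice chain of n residues."""
    rng = _rng(seed)
    path = _serpentine(n)
    if n_backbite is None:
        n_backbite = 50 * n
    path = _backbite_mix(path, n_backbite, rng)
    return path.astype(float) * LATTICE_SPACING


@dataclass
class PlantedModel:
    """Ground-truth Potts model on a compact-chain contact map.

    Each native contact carries one preferred residue pair with energy
    −coupling_strength; a ``frustration_mix`` fraction instead carries
    +coupling_strength (a repulsive, frustrated preference).  Sequences are
    gap-free, so the gap state never enters generation.
    """

    contact_map: ContactMap
    couplings: CouplingTensor
    fields: np.ndarray
    frustration_mix: float
    planted_pairs: list[dict] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return self.contact_map.n_residues

    @property
    def true_frustrated_fraction(self) -> float:
        if not self.planted_pairs:
            return 0.0
        return float(np.mean([p["sign"] > 0 for p in self.planted_pairs]))

    def sequence_energy(self, codes: np.ndarray) -> float:
        """Planted-model energy of one sequence (ground truth E_N)."""
        eps = self.couplings.eps
        n = self.n_residues
        iu, ju = np.where(np.triu(self.contact_map.adj, k=1))
        pair_e = eps[iu, ju, codes[iu], codes[ju]].sum()
        site_e = self.fields[np.arange(n), codes].sum()
        return float(pair_e + site_e)

    def ground_truth_summary(self) -> dict:
        return {
            "n_residues": self.n_residues,
            "n_contacts": self.contact_map.n_contacts,
            "frustration_mix": self.frustration_mix,
            "planted_pairs": self.planted_pairs,
        }


def make_planted_model(
    n_residues: int,
    contact_density: float = 1.0,
    coupling_strength: float = 2.0,
    frustration_mix: float = 0.0,
    seed=0,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    site_field: float = 0.5,
) -> PlantedModel:
    """Plant a Potts model on a compact-chain contact map.

    Each site i gets a primary residue a_i (favoured by a single-site
    field of depth ``site_field``, the consensus "native sequence") and a
    secondary residue a_i'.  An *attractive* contact (i, j) supports two
    alternative favourable pairings — (a_i, a_j) and (a_i', a_j'), both at
    −coupling_strength — so sequences can switch between them through
    compensatory double mutations, which is exactly the covariation
    signal coevolutionary inference feeds on.  A ``frustration_mix``
    fraction of contacts is instead *frustrated*: +coupling_strength on
    the same two pairings, so whichever phase the attractive network
    holds the two sites in, the repulsive interaction is realised — an
    unfavourable contact evolution cannot escape without breaking the
    surrounding stabilising structure.  ``contact_density`` keeps that
    fraction of the lattice contacts.
    """
    if n_residues < 10:
        raise ValueError("planted models need at least 10 residues")
    if not 0 <= frustration_mix <= 1:
        raise ValueError("frustration_mix must be in [0, 1]")
    if not 0 <= contact_density <= 1:
        raise ValueError("contact_density must be in [0, 1]")
    rng = _rng(seed)
    coords = compact_chain_coords(n_residues, rng)
    cm = contact_map_from_coords(coords, min_separation=min_separation)
    pairs = cm.contact_pairs()
    if contact_density < 1.0:
        keep = rng.random(len(pairs)) < contact_density
        adj = np.zeros_like(cm.adj)
        for i, j in pairs[keep]:
            adj[i, j] = adj[j, i] = True
        cm = ContactMap(adj=adj, source="synthetic", coords=coords)
        pairs = cm.contact_pairs()

    primary = rng.integers(0, N_RES, size=n_residues)
    # distinct secondary residue per site
    secondary = (primary + 1 + rng.integers(0, N_RES - 1, size=n_residues)) % N_RES
    fields = np.zeros((n_residues, N_STATES))
    fields[np.arange(n_residues), primary] = -site_field
    eps = np.zeros((n_residues, n_residues, N_STATES, N_STATES))
    n_frustrated = int(round(frustration_mix * len(pairs)))
    signs = np.array([1.0] * n_frustrated + [-1.0] * (len(pairs) - n_frustrated))
    rng.shuffle(signs)
    planted = []
    for (i, j), sign in zip(pairs, signs):
        a, b = int(primary[i]), int(primary[j])
        a2, b2 = int(secondary[i]), int(secondary[j])
        value = sign * coupling_strength
        # attractive contacts favour both phase-consistent pairings;
        # frustrated contacts penalise the same pairings, so the conflict
        # cannot be escaped while neighbours hold the sites in phase
        eps[i, j, a, b] = eps[j, i, b, a] = value
        eps[i, j, a2, b2] = eps[j, i, b2, a2] = value
        planted.append(
            {"i": int(i), "j": int(j), "a": a, "b": b, "sign": float(sign)}
        )
    couplings = CouplingTensor(eps=eps, family="planted")
    return PlantedModel(
        contact_map=cm,
        couplings=couplings,
        fields=fields,
        frustration_mix=frustration_mix,
        planted_pairs=planted,
    )


def sample_potts_msa(
    model: PlantedModel,
    n_seq: int,
    n_sweeps: int = 50,
    seed=0,
    gap_fraction: float = 0.10,
) -> AlignmentMatrix:
    """Equilibrium alignment sampled from the planted Boltzmann distribution.

    Runs ``n_seq`` independent Gibbs chains for ``n_sweeps`` full sweeps at
    unit temperature (the evolutive temperature of the planted energies)
    and keeps the final state of each chain.  ``gap_fraction`` of the
    cells are then replaced by gaps, emulating the gap content of a family
    alignment: real gap statistics are what anchor the gap-gauge zero of
    the inferred energies, so the inference alignment must not be
    gap-free (the tree-evolved, "reconstructed" sequences are).  Set it
    to 0 for a gap-free alignment.
    """
    rng = _rng(seed)
    n = model.n_residues
    eps = model.couplings.eps[:, :, :N_RES, :N_RES]
    h = model.fields[:, :N_RES]
    nbrs = [np.flatnonzero(model.contact_map.adj[i]) for i in range(n)]
    states = rng.integers(0, N_RES, size=(n_seq, n), dtype=np.int64)
    for _ in range(n_sweeps):
        for i in range(n):
            energy = np.broadcast_to(h[i][:, None], (N_RES, n_seq)).copy()
            for j in nbrs[i]:
                energy += eps[i, j][:, states[:, j]]
            gumbel = rng.gumbel(size=(N_RES, n_seq))
            states[:, i] = np.argmax(-energy + gumbel, axis=0)
    matrix = states.astype(np.int8)
    if gap_fraction > 0:
        mask = rng.random(matrix.shape) < gap_fraction
        matrix[mask] = GAP_STATE
    ids = [f"seq_{k:05d}" for k in range(n_seq)]
    organisms = [f"org_{k:05d}" for k in range(n_seq)]
    return AlignmentMatrix(
        ids=ids, matrix=matrix, organisms=organisms, ages=np.zeros(n_seq)
    )


@dataclass
class DatedSequenceSet:
    """Extant (leaf) and ancestral (internal-node) sequences with ages."""

    ids: list[str]
    matrix: np.ndarray  # (n_nodes, N) state codes
    ages: np.ndarray  # My before present; leaves 0, root maximal
    newick: str

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def to_alignment(self) -> AlignmentMatrix:
        return AlignmentMatrix(
            ids=list(self.ids),
            matrix=self.matrix,
            organisms=[f"org_{i}" for i in self.ids],
            ages=self.ages.copy(),
        )

    def metadata(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": self.ids,
                "organism": [f"org_{i}" for i in self.ids],
                "age_My": self.ages,
            }
        )


def _selection_schedule(schedule, root_age: float):
    """Inverse-selection-temperature β as a function of age.

    β = 1 reproduces the equilibrium ensemble the couplings were planted
    at; lowering β towards the present relaxes selection (energies drift
    up: destabilising), raising it tightens selection (stabilising).
    """
    if callable(schedule):
        return schedule
    if schedule in (None, "neutral"):
        return lambda age: 1.0
    if schedule == "destabilising":
        # strong selection deep in the past, relaxed (slightly inverted)
        # near the present: energies drift up towards extant proteins
        return lambda age: -0.5 + 3.0 * age / root_age
    if schedule == "stabilising":
        return lambda age: 2.5 - 3.0 * age / root_age
    raise ValueError(f"unknown selection schedule: {schedule!r}")


def evolve_on_tree(
    model: PlantedModel,
    tree_shape: tuple[int, float] = (26, 2000.0),
    mutation_rate: float = 0.002,
    seed=0,
    schedule="neutral",
    root_sweeps: int = 100,
) -> DatedSequenceSet:
    """Evolve sequences along a random dated tree.

    ``tree_shape`` is (n_leaves, root age in My); ``mutation_rate`` is in
    substitution attempts per site per My.  A root sequence is drawn from
    the planted equilibrium; along every branch, point mutations are
    proposed at Poisson times and accepted with the Metropolis rule at the
    schedule's inverse selection temperature β(age), so the planted energy
    controls the drift of E_N.  Every internal node's true sequence and
    age are recorded.
    """
    n_leaves, depth = tree_shape
    if n_leaves < 2:
        raise ValueError("tree needs at least 2 leaves")
    rng = _rng(seed)
    n = model.n_residues
    beta = _selection_schedule(schedule, depth)

    # random coalescent-style topology: evenly spaced merge ages
    nodes = [{"id": f"L{k:04d}", "age": 0.0, "children": []} for k in range(n_leaves)]
    lineages = list(range(n_leaves))
    merge_ages = depth * np.arange(1, n_leaves) / (n_leaves - 1)
    for k, age in enumerate(merge_ages):
        a, b = rng.choice(len(lineages), size=2, replace=False)
        left, right = lineages[a], lineages[b]
        nodes.append({"id": f"A{k:04d}", "age": float(age), "children": [left, right]})
        new = len(nodes) - 1
        lineages = [x for m, x in enumerate(lineages) if m not in (a, b)] + [new]
    root = lineages[0]

    eps = model.couplings.eps
    nbrs = [np.flatnonzero(model.contact_map.adj[i]) for i in range(n)]
    # equilibrate the root at the selection strength prevailing at the root
    # age, so the planted energy trend has a well-defined starting ensemble
    beta_root = max(beta(depth), 0.0)
    root_model = PlantedModel(
        contact_map=model.contact_map,
        couplings=CouplingTensor(eps=model.couplings.eps * beta_root, family="root"),
        fields=model.fields * beta_root,
        frustration_mix=model.frustration_mix,
    )
    root_seq = sample_potts_msa(
        root_model, 1, n_sweeps=root_sweeps, seed=rng, gap_fraction=0.0
    ).matrix[0]
    sequences: dict[int, np.ndarray] = {root: root_seq.astype(np.int64)}

    def evolve_branch(parent_seq: np.ndarray, age_hi: float, age_lo: float) -> np.ndarray:
        seq = parent_seq.copy()
        n_events = rng.poisson(mutation_rate * n * (age_hi - age_lo))
        if n_events == 0:
            return seq
        event_ages = np.sort(rng.uniform(age_lo, age_hi, size=n_events))[::-1]
        for age in event_ages:
            i = int(rng.integers(n))
            old = seq[i]
            new = int(rng.integers(N_RES - 1))
            if new >= old:
                new += 1
            delta = model.fields[i, new] - model.fields[i, old]
            for j in nbrs[i]:
                delta += eps[i, j, new, seq[j]] - eps[i, j, old, seq[j]]
            if rng.random() < np.exp(min(0.0, -beta(age) * delta)):
                seq[i] = new
        return seq

    order = [root]
    stack = [root]
    while stack:
        node = stack.pop()
        for child in nodes[node]["children"]:
            sequences[child] = evolve_branch(
                sequences[node], nodes[node]["age"], nodes[child]["age"]
            )
            order.append(child)
            stack.append(child)

    def newick(node: int) -> str:
        info = nodes[node]
        if not info["children"]:
            return info["id"]
        parts = []
        for child in info["children"]:
            length = info["age"] - nodes[child]["age"]
            parts.append(f"{newick(child)}:{length:.6g}")
        return f"({','.join(parts)}){info['id']}"

    order = sorted(sequences, key=lambda k: (-nodes[k]["age"], nodes[k]["id"]))
    return DatedSequenceSet(
        ids=[nodes[k]["id"] for k in order],
        matrix=np.vstack([sequences[k] for k in order]).astype(np.int8),
        ages=np.array([nodes[k]["age"] for k in order]),
        newick=newick(root) + ";",
    )


def write_fixture_structure(
    cm: ContactMap, path, glycine_positions: tuple[int, ...] = ()
) -> None:
    """Write a synthetic PDB whose Cβ geometry reproduces ``cm`` exactly.

    Each residue is an alanine with CA and CB placed on its lattice
    coordinate (glycines get only CA), so re-deriving the map at the
    6.5 Å cutoff is an exact round trip.  Requires an embedded map
    (``cm.coords``); purely synthetic geometry, not a physical model.
    """
    if cm.coords is None:
        raise ValueError("contact map has no embedding coordinates")
    from Bio.PDB import PDBIO
    from Bio.PDB.StructureBuilder import StructureBuilder

    builder = StructureBuilder()
    builder.init_structure("synthetic")
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg("    ")
    glycines = set(glycine_positions)
    for idx, xyz in enumerate(cm.coords):
        resname = "GLY" if idx in glycines else "ALA"
        builder.init_residue(resname, " ", idx + 1, " ")
        builder.init_atom("CA", np.asarray(xyz, dtype=float), 0.0, 1.0, " ", " CA ", element="C")
        if resname != "GLY":
            builder.init_atom("CB", np.asarray(xyz, dtype=float), 0.0, 1.0, " ", " CB ", element="C")
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))
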