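"""Null references: column-bootstrap alignments, random sequences, random graphs.

The column bootstrap permutes the residues of each alignment column
independently across sequences, exactly preserving one-site frequencies
while destroying inter-site correlations — the reference distribution
against which strongly attractive contacts are calibrated.  Null contact
energies are produced by running the *full* inference pipeline (weights,
frequencies, mean-field inversion, native filtering, projection) on the
bootstrapped alignment, not by shuffling final energies.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .alignment_io import AlignmentMatrix, compute_weights
from .coevolution import PseudocountConfig, count_frequencies, infer_couplings
from .energetics import project_energies
from .structure import ContactMap, filter_to_native


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def column_bootstrap(aln: AlignmentMatrix, seed) -> AlignmentMatrix:
    """Independently permute each column across sequences.

    Per-column symbol counts are bit-exactly preserved; two-site
    connected correlations vanish in expectation.
    """
    if aln.n_sequences < 2:
        raise ValueError("column bootstrap needs at least 2 sequences")
    rng = _rng(seed)
    matrix = aln.matrix.copy()
    for j in range(aln.n_columns):
        matrix[:, j] = matrix[rng.permutation(aln.n_sequences), j]
    return AlignmentMatrix(
        ids=[f"boot_{i}" for i in range(aln.n_sequences)],
        matrix=matrix,
        organisms=aln.organisms,
        ages=aln.ages,
    )


def random_sequences(f1: np.ndarray, n: int, seed) -> AlignmentMatrix:
    """Draw ``n`` sequences site-independently from one-site frequencies.

    ``f1`` is an (N, 21) row-normalised table, typically the pseudocount-free
    empirical column frequencies of an alignment.
    """
    f1 = np.asarray(f1, dtype=float)
    if not np.allclose(f1.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("f1 rows must be normalised")
    rng = _rng(seed)
    n_cols = f1.shape[0]
    matrix = np.empty((n, n_cols), dtype=np.int8)
    for j in range(n_cols):
        matrix[:, j] = rng.choice(f1.shape[1], size=n, p=f1[j])
    return AlignmentMatrix(ids=[f"rand_{i}" for i in range(n)], matrix=matrix)


def empirical_frequencies(aln: AlignmentMatrix) -> np.ndarray:
    """Pseudocount-free per-column state frequencies (N, 21)."""
    from .alphabet import N_STATES

    counts = np.stack(
        [np.bincount(aln.matrix[:, j], minlength=N_STATES) for j in range(aln.n_columns)]
    ).astype(float)
    return counts / aln.n_sequences


def null_contact_energies(
    aln: AlignmentMatrix,
    cm: ContactMap,
    pc: PseudocountConfig = PseudocountConfig(),
    identity_threshold: float = 0.70,
    n_projections: int | None = None,
    seed=0,
) -> np.ndarray:
    """Native contact energies of a column-bootstrapped alignment.

    Runs the complete tensor-inference pipeline on the bootstrap replicate
    and projects it onto ``n_projections`` of the bootstrapped sequences
    (all of them by default), returning the pooled energies at native
    contacts.
    """
    rng = _rng(seed)
    boot = column_bootstrap(aln, rng)
    weights = compute_weights(boot, identity_threshold)
    tensor = infer_couplings(count_frequencies(boot, weights, pc), family="null")
    tensor = filter_to_native(tensor, cm)
    m = boot.n_sequences
    if n_projections is None or n_projections >= m:
        idx = np.arange(m)
    else:
        idx = rng.choice(m, size=n_projections, replace=False)
    iu, ju = np.where(np.triu(cm.adj, k=1))
    pool = []
    for s in idx:
        em = project_energies(tensor, boot.matrix[s], cm)
        pool.append(em.e[iu, ju])
    return np.concatenate(pool) if pool else np.empty(0)


def random_graph_null(
    n_nodes: int, n_edges: int, replicates: int, seed
) -> pd.DataFrame:
    """Network statistics of uniform G(n, m) random graphs.

    Returns one row per replicate with columns lcs, orphan_fraction,
    clustering (same definitions as :func:`coevonet.networks.network_stats`).
    """
    if n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ValueError("more edges than a simple graph allows")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    from .networks import graph_stats

    rng = _rng(seed)
    rows = []
    for _ in range(replicates):
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=int(rng.integers(2**31)))
        rows.append(graph_stats(g))
    return pd.DataFrame(rows)
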