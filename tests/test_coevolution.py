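import itertools

import numpy as np
import pytest

from coevonet.alignment_io import AlignmentMatrix, SequenceWeights, compute_weights
from coevonet.alphabet import GAP_STATE, N_STATES, encode_sequence
from coevonet.coevolution import (
    CouplingTensor,
    FrequencyTables,
    PseudocountConfig,
    apply_gap_gauge,
    count_frequencies,
    infer_couplings,
)


def aln_from_strings(seqs):
    return AlignmentMatrix(
        ids=[f"s{k}" for k in range(len(seqs))],
        matrix=np.vstack([encode_sequence(s) for s in seqs]),
    )


def two_site_boltzmann_tables(pair_energy, field_a=0.0, pc=PseudocountConfig(0.05, 0, 0)):
    """Exact-enumeration oracle: frequency tables of a 2-site Potts system
    with energy ``pair_energy`` on the (A, A) state combination, built by
    weighting every state configuration with its Boltzmann probability."""
    h = np.zeros(20)
    h[0] = field_a
    energies = h[:, None] + h[None, :]
    energies[0, 0] += pair_energy
    p = np.exp(-energies)
    p /= p.sum()
    rows = np.array(list(itertools.product(range(20), repeat=2)), dtype=np.int8)
    aln = AlignmentMatrix(ids=[f"c{k}" for k in range(400)], matrix=rows)
    weights = SequenceWeights(w=np.maximum(p.ravel(), 1e-300))
    return count_frequencies(aln, weights, pc)


class TestCountFrequencies:
    def test_single_sequence_no_pseudocount_is_indicator(self):
        aln = aln_from_strings(["ACD"])
        f = count_frequencies(aln, pc=PseudocountConfig(0, 0, 0))
        expected = np.zeros((3, N_STATES))
        expected[0, 0] = expected[1, 1] = expected[2, 2] = 1.0
        assert np.allclose(f.f1, expected)

    def test_large_uniform_pseudocount_limit(self):
        aln = aln_from_strings(["ACD", "ACD"])
        f = count_frequencies(aln, pc=PseudocountConfig(x=1e6, y=0, z=0))
        assert np.allclose(f.f1, 1 / N_STATES, atol=1e-4)

    def test_hand_arithmetic_two_sequences(self):
        # column 1 of AA/AC: n(A)=2, n(C)=... column 0 is AA, column 1 is A,C
        aln = aln_from_strings(["AA", "AC"])
        pc = PseudocountConfig(0.5, 0.1, 1.0)
        f = count_frequencies(aln, pc=pc)
        m_eff = 2.0
        n_col1_A = 1.0
        c_A = 3.0 / 4.0  # 3 of 4 residues are A
        c_site = n_col1_A / m_eff
        expected = (
            n_col1_A + 0.5 * m_eff / 21 + 0.1 * m_eff * c_A + 1.0 * m_eff * c_site
        ) / (m_eff * (1 + 0.5 + 0.1 + 1.0))
        assert f.f1[1, 0] == pytest.approx(expected)

    def test_rows_normalised_and_f2_symmetric(self, sampled_msa):
        sub = sampled_msa.subset(range(50))
        f = count_frequencies(sub)
        assert np.allclose(f.f1.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(f.f2.sum(axis=(2, 3)), 1.0, atol=1e-10)
        assert np.allclose(f.f2, f.f2.transpose(1, 0, 3, 2))

    def test_marginalisation_recovers_f1(self):
        aln = aln_from_strings(["ACDF", "ACDG", "AKDG"])
        f = count_frequencies(aln, pc=PseudocountConfig(0.5, 0.1, 1.0))
        # summing f2(i,j) over the second state recovers f1(i) exactly
        # (the pseudocount mass factorises)
        marg = f.f2[0, 2].sum(axis=1)
        assert np.allclose(marg, f.f1[0], atol=1e-12)

    def test_empty_alignment_errors(self):
        aln = AlignmentMatrix(ids=[], matrix=np.zeros((0, 3), np.int8))
        with pytest.raises(ValueError):
            count_frequencies(aln)


class TestInferCouplings:
    def test_independent_columns_give_zero_couplings(self):
        # factorised f2 = f1 (x) f1 means zero connected correlation
        rng = np.random.default_rng(3)
        f1 = rng.dirichlet(np.ones(N_STATES), size=4)
        f2 = np.einsum("ia,jb->ijab", f1, f1)
        for i in range(4):
            f2[i, i] = np.diag(f1[i])
        t = infer_couplings(FrequencyTables(f1=f1, f2=f2))
        off = t.eps[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-8

    @pytest.mark.parametrize("planted", [-0.4, 0.4])
    def test_two_site_enumeration_recovers_coupling(self, planted):
        """Mean-field inversion of exactly enumerated Boltzmann frequencies
        recovers the planted pair energy (sign exactly, magnitude within
        the 20% mean-field tolerance), read off through the
        gauge-invariant double difference."""
        freqs = two_site_boltzmann_tables(planted)
        t = infer_couplings(freqs)
        block = t.eps[0, 1]
        recovered = block[0, 0] - block[0, 5] - block[5, 0] + block[5, 5]
        assert np.sign(recovered) == np.sign(planted)
        assert recovered == pytest.approx(planted, rel=0.20)

    def test_attraction_is_negative_for_co_occurring_pair(self):
        # co-occurrence above independence (planted negative energy)
        # must infer as negative = attractive
        t = infer_couplings(two_site_boltzmann_tables(-0.4))
        assert t.eps[0, 1, 0, 0] < 0

    def test_strongly_coupled_pair_has_lowest_minimum(self, planted_model):
        """A single pair coupled much more strongly than the rest ranks
        first when pairs are sorted by their strongest attraction."""
        from coevonet.simulate import sample_potts_msa

        model = planted_model
        boosted = CouplingTensor(eps=model.couplings.eps.copy())
        p = model.planted_pairs[0]
        i, j = p["i"], p["j"]
        boosted.eps[i, j] *= 3.0
        boosted.eps[j, i] *= 3.0
        strong = type(model)(
            contact_map=model.contact_map,
            couplings=boosted,
            fields=model.fields,
            frustration_mix=0.0,
        )
        msa = sample_potts_msa(strong, 5000, seed=7)
        t = infer_couplings(count_frequencies(msa, compute_weights(msa)))
        scores = t.eps[:, :, :20, :20].min(axis=(2, 3))
        iu, ju = np.triu_indices(30, k=2)
        best = np.argmin(scores[iu, ju])
        assert (iu[best], ju[best]) == (i, j)

    def test_symmetry_bit_exact(self, inferred_tensor):
        e = inferred_tensor.eps
        assert np.array_equal(e, e.transpose(1, 0, 3, 2))

    def test_gap_gauge_bit_exact(self, inferred_tensor):
        e = inferred_tensor.eps
        assert np.all(e[:, :, GAP_STATE, :] == 0)
        assert np.all(e[:, :, :, GAP_STATE] == 0)
        assert np.all(e[np.arange(30), np.arange(30)] == 0)

    def test_doubled_alignment_leaves_couplings_unchanged(self, sampled_msa):
        sub = sampled_msa.subset(range(300))
        doubled = AlignmentMatrix(
            ids=[f"d{i}" for i in range(600)],
            matrix=np.vstack([sub.matrix, sub.matrix]),
        )
        t1 = infer_couplings(count_frequencies(sub, compute_weights(sub)))
        t2 = infer_couplings(count_frequencies(doubled, compute_weights(doubled)))
        assert np.allclose(t1.eps, t2.eps, atol=1e-8)

    def test_singular_correlation_matrix_errors_with_advice(self):
        aln = aln_from_strings(["ACDEF", "ACDEG"])
        freqs = count_frequencies(aln, pc=PseudocountConfig(0, 0, 0))
        with pytest.raises(np.linalg.LinAlgError, match="pseudocount"):
            infer_couplings(freqs)


class TestGapGauge:
    def test_idempotent_on_inferred_tensor(self, inferred_tensor):
        again = apply_gap_gauge(inferred_tensor)
        assert np.allclose(again.eps, inferred_tensor.eps, atol=1e-14)

    def test_double_differences_invariant(self, rng):
        eps = rng.normal(size=(3, 3, N_STATES, N_STATES))
        eps = 0.5 * (eps + eps.transpose(1, 0, 3, 2))
        t = CouplingTensor(eps=eps)
        g = apply_gap_gauge(t)
        for _ in range(20):
            i, j = rng.integers(3, size=2)
            a, b, c, d = rng.integers(N_STATES, size=4)
            before = eps[i, j, a, b] - eps[i, j, a, d] - eps[i, j, c, b] + eps[i, j, c, d]
            after = (
                g.eps[i, j, a, b] - g.eps[i, j, a, d] - g.eps[i, j, c, b] + g.eps[i, j, c, d]
            )
            assert after == pytest.approx(before, abs=1e-10)

    def test_gap_entries_exactly_zero(self, rng):
        eps = rng.normal(size=(2, 2, N_STATES, N_STATES))
        eps = 0.5 * (eps + eps.transpose(1, 0, 3, 2))
        g = apply_gap_gauge(CouplingTensor(eps=eps))
        assert np.all(g.eps[:, :, GAP_STATE, :] == 0)
        assert np.all(g.eps[:, :, :, GAP_STATE] == 0)

    def test_two_letter_hand_example(self):
        # block [[1,2],[3,4]] with the second letter acting as the gap:
        # gauged value at (0,0) is 1 - 2 - 3 + 4 = 0
        eps = np.zeros((2, 2, N_STATES, N_STATES))
        block = np.zeros((N_STATES, N_STATES))
        block[0, 0], block[0, GAP_STATE] = 1.0, 2.0
        block[GAP_STATE, 0], block[GAP_STATE, GAP_STATE] = 3.0, 4.0
        eps[0, 1] = block
        eps[1, 0] = block.T
        g = apply_gap_gauge(CouplingTensor(eps=eps))
        assert g.eps[0, 1, 0, 0] == pytest.approx(1 - 2 - 3 + 4)
        assert np.all(g.eps[0, 1, GAP_STATE, :] == 0)


class TestSerialisation:
    def test_npz_round_trip(self, tmp_path, inferred_tensor):
        path = tmp_path / "tensor.npz"
        inferred_tensor.save(path)
        back = CouplingTensor.load(path)
        assert np.array_equal(back.eps, inferred_tensor.eps)
        assert back.family == inferred_tensor.family

    def test_pair_summary_table(self, inferred_tensor):
        table = inferred_tensor.pair_summary()
        n = inferred_tensor.n_columns
        assert len(table) == n * (n - 1) // 2
        assert (table["min_eps"] <= table["max_eps"]).all()
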