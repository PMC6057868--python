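"""Policy networks: normalization, equivariance, locality, conditioning."""

import numpy as np
import pytest

from molgraphgen.decoding import canonical_route
from molgraphgen.molgraph import (AtomType, BondType, MolGraph,
                                  graph_from_smiles)
from molgraphgen.policy import (GraphConv, MolMP, MolRNN, PolicyConfig,
                                RnnState)


def _with_latest(smi, latest=0):
    g = graph_from_smiles(smi)
    g.latest = latest
    return g


class TestEmbedding:
    def test_default_embedding_dimension_is_16(self, tiny_vocab):
        pol = MolMP(tiny_vocab, PolicyConfig(), np.random.default_rng(0))
        h = pol.embed_atoms(_with_latest("CCO"))
        assert h.shape == (3, 16)

    def test_latest_flag_changes_embedding(self, tiny_molmp):
        g = _with_latest("CC", latest=1)
        h = tiny_molmp.embed_atoms(g)
        # both atoms are carbon; only the v* flag distinguishes them
        assert not np.allclose(h[0], h[1])

    def test_zeroed_tables_give_zero_embeddings(self, tiny_molmp):
        tiny_molmp.type_table.data[:] = 0.0
        tiny_molmp.latest_vec.data[:] = 0.0
        h = tiny_molmp.embed_atoms(_with_latest("CCO"))
        assert np.all(h == 0.0)


class TestGraphConv:
    def test_isolated_atom_sees_only_self_term(self):
        rng = np.random.default_rng(2)
        conv = GraphConv(3, 2, receptive_field=3, code_dim=None, rng=rng)
        g = MolGraph()
        g.add_atom(AtomType("C"))
        h = rng.normal(size=(1, 3))
        np.testing.assert_allclose(conv.apply_to_graph(h, g),
                                   h @ conv.W.data)

    def test_zero_weights_give_zero_output(self):
        conv = GraphConv(3, 2, 3, None, np.random.default_rng(3))
        for p in [conv.W] + conv.theta + conv.phi:
            p.data[:] = 0.0
        g = graph_from_smiles("CCO")
        out = conv.apply_to_graph(np.ones((3, 3)), g)
        assert np.all(out == 0.0)

    def test_path_graph_hand_computation(self):
        """Scalar-weight evaluation on A-B-C matches the convolution rule:
        h'_v = w h_v + t * sum bond neighbors + f2 * sum distance-2."""
        rng = np.random.default_rng(4)
        conv = GraphConv(1, 1, receptive_field=3, code_dim=None, rng=rng)
        w = conv.W.data[0, 0]
        t = conv.theta[int(BondType.SINGLE)].data[0, 0]
        f2 = conv.phi[0].data[0, 0]
        g = graph_from_smiles("CCO")  # path 0-1-2
        h = np.array([[1.0], [2.0], [4.0]])
        out = conv.apply_to_graph(h, g)
        assert np.isclose(out[1, 0], w * 2 + t * (1 + 4))
        assert np.isclose(out[0, 0], w * 1 + t * 2 + f2 * 4)
        assert np.isclose(out[2, 0], w * 4 + t * 2 + f2 * 1)

    def test_receptive_field_one_is_local(self):
        """With D = 1 an atom's output ignores atoms at distance >= 2."""
        rng = np.random.default_rng(5)
        conv = GraphConv(2, 2, receptive_field=1, code_dim=None, rng=rng)
        g = graph_from_smiles("CCO")
        h1 = rng.normal(size=(3, 2))
        h2 = h1.copy()
        h2[2] += 10.0  # perturb the atom two bonds away from atom 0
        out1 = conv.apply_to_graph(h1, g)
        out2 = conv.apply_to_graph(h2, g)
        np.testing.assert_allclose(out1[0], out2[0])
        assert not np.allclose(out1[1], out2[1])  # direct neighbor moves


class TestNormalization:
    @pytest.mark.parametrize("arch", [MolMP, MolRNN])
    @pytest.mark.parametrize("code_dim", [None, 2])
    def test_output_sums_to_one(self, tiny_vocab, arch, code_dim):
        pol = arch(tiny_vocab, PolicyConfig.desk(code_dim=code_dim),
                   np.random.default_rng(8))
        code = None if code_dim is None else np.array([0.3, -1.2])
        for smi in ("C", "CCO", "CC=O"):
            g = _with_latest(smi)
            out = pol.forward(g, code=code)
            if arch is MolRNN:
                out, _ = out
            assert abs(out.total() - 1.0) < 1e-6
            assert np.all(out.p_append >= 0) and out.p_terminate > 0
            assert out.p_append.shape == (g.num_atoms, len(tiny_vocab), 4)

    def test_strictly_positive_probabilities(self, tiny_molmp):
        out = tiny_molmp.forward(_with_latest("CC"))
        assert np.all(out.p_append > 0) and np.all(out.p_connect > 0)


class TestPermutationEquivariance:
    def test_relabeling_permutes_outputs(self, tiny_vocab):
        pol = MolMP(tiny_vocab, PolicyConfig.desk(),
                    np.random.default_rng(9))
        g = _with_latest("CC=O", latest=1)
        perm = [2, 0, 1]  # new index of each old atom
        g2 = MolGraph()
        inv = np.argsort(perm)
        for i in inv:
            g2.add_atom(g.atoms[i], mark_latest=False)
        for a, b, t in g.bonds:
            g2.add_bond(perm[a], perm[b], t)
        g2.latest = perm[g.latest]
        out1 = pol.forward(g)
        out2 = pol.forward(g2)
        np.testing.assert_allclose(out1.p_append[0], out2.p_append[perm[0]],
                                   atol=1e-10)
        np.testing.assert_allclose(out1.p_connect,
                                   out2.p_connect[np.asarray(perm)],
                                   atol=1e-10)
        assert np.isclose(out1.p_terminate, out2.p_terminate)


class TestConditioning:
    def test_code_changes_output_when_psi_nonzero(self, tiny_vocab):
        pol = MolMP(tiny_vocab, PolicyConfig.desk(code_dim=1),
                    np.random.default_rng(10))
        g = _with_latest("CC")
        a = pol.forward(g, code=np.array([0.0]))
        b = pol.forward(g, code=np.array([5.0]))
        assert not np.allclose(a.p_append, b.p_append)

    def test_code_ignored_when_psi_zero(self, tiny_vocab):
        pol = MolMP(tiny_vocab, PolicyConfig.desk(code_dim=1),
                    np.random.default_rng(11))
        for conv in pol.convs:
            conv.psi.data[:] = 0.0
        pol.init_code.data[:] = 0.0
        g = _with_latest("CC")
        a = pol.forward(g, code=np.array([0.0]))
        b = pol.forward(g, code=np.array([5.0]))
        np.testing.assert_allclose(a.p_append, b.p_append)

    def test_conditional_policy_requires_code(self, tiny_vocab):
        pol = MolMP(tiny_vocab, PolicyConfig.desk(code_dim=1),
                    np.random.default_rng(12))
        with pytest.raises(ValueError):
            pol.forward(_with_latest("CC"))


class TestInitPolicy:
    def test_uniform_weights_give_uniform_distribution(self, tiny_molmp):
        tiny_molmp.init_logits.data[:] = 0.7  # any constant
        p = tiny_molmp.init_distribution()
        np.testing.assert_allclose(p, np.full(len(p), 1 / len(p)))

    def test_distribution_sums_to_one(self, tiny_molrnn):
        assert np.isclose(tiny_molrnn.init_distribution().sum(), 1.0)


class TestMolRNN:
    def test_state_dependence(self, tiny_molrnn):
        """The same graph state scores differently under different
        recurrent histories."""
        g = _with_latest("CC", latest=1)
        out_fresh, state = tiny_molrnn.forward(
            g, state=RnnState.zeros(tiny_molrnn.config))
        out_hist, _ = tiny_molrnn.forward(g, state=state)
        assert not np.allclose(out_fresh.p_append, out_hist.p_append)

    def test_zero_recurrent_weights_reduce_to_constant_context(
            self, tiny_molrnn):
        for cell in tiny_molrnn.gru:
            for p in cell.params:
                p.data[:] = 0.0
        g = _with_latest("CC", latest=1)
        out1, s1 = tiny_molrnn.forward(
            g, state=RnnState.zeros(tiny_molrnn.config))
        out2, _ = tiny_molrnn.forward(g, state=s1)
        # all-zero GRU: state update is h' = (1-z)tanh(0)+z*0 ... = 0
        np.testing.assert_allclose(out1.p_append, out2.p_append)


class TestBatchedScoring:
    def test_batched_equals_individual_in_eval_mode(self, tiny_molrnn):
        routes = [canonical_route(graph_from_smiles(s))
                  for s in ("CCO", "CC=O", "C")]
        vec = tiny_molrnn.score_routes(routes, training=False).data
        for r, lp in zip(routes, vec):
            single = tiny_molrnn.score_route(r, training=False).item()
            assert np.isclose(single, lp), r
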