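"""Transition semantics, canonical routes and the q_alpha sampler."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molgraphgen import fixtures as F
from molgraphgen.decoding import (Append, Connect, Init, Terminate,
                                  TransitionError, apply_transition,
                                  canonical_route, enumerate_routes, replay,
                                  route_length, route_q_logp, route_to_jsonl,
                                  sample_route)
from molgraphgen.molgraph import (AtomType, BondType, MolGraph,
                                  canonical_smiles, graph_from_smiles,
                                  smiles_from_graph)

C = AtomType("C")


class TestApplyTransition:
    def test_init_append_connect_sequence(self):
        g = apply_transition(MolGraph(), Init(C))
        assert (g.num_atoms, g.latest) == (1, 0)
        g = apply_transition(g, Append(0, C, BondType.SINGLE))
        assert (g.num_atoms, g.num_bonds, g.latest) == (2, 1, 1)
        g = apply_transition(g, Append(1, C, BondType.SINGLE))
        g = apply_transition(g, Connect(0, BondType.SINGLE))
        assert g.num_bonds == 3 and g.latest == 2  # cyclopropane skeleton

    def test_structural_errors(self):
        g = apply_transition(MolGraph(), Init(C))
        with pytest.raises(TransitionError):
            apply_transition(g, Init(C))
        with pytest.raises(TransitionError):
            apply_transition(g, Append(5, C, BondType.SINGLE))
        with pytest.raises(TransitionError):
            apply_transition(g, Connect(0, BondType.SINGLE))  # target == v*
        g2 = apply_transition(g, Append(0, C, BondType.SINGLE))
        with pytest.raises(TransitionError):
            apply_transition(g2, Connect(0, BondType.SINGLE))  # bond exists

    def test_chemical_validity_not_enforced(self):
        g = apply_transition(MolGraph(), Init(AtomType("O")))
        for _ in range(4):  # tetravalent oxygen: structurally fine
            g = apply_transition(g, Append(0, C, BondType.SINGLE))
        assert g.num_atoms == 5


class TestCanonicalRoute:
    @pytest.mark.parametrize("smi,length", [
        ("C", 2), ("c1ccccc1", 8), ("CCO", 4)])
    def test_route_length_examples(self, smi, length):
        g = graph_from_smiles(smi)
        assert route_length(g) == length
        assert len(canonical_route(g)) == length

    def test_cimetidine_length_is_edges_plus_two(self):
        g = graph_from_smiles(F.bundled_corpus()[0])
        assert len(canonical_route(g)) == g.num_bonds + 2

    def test_deterministic_and_logq_zero(self):
        g = graph_from_smiles("CC(=O)O")
        r1, r2 = canonical_route(g), canonical_route(g)
        assert r1.transitions == r2.transitions
        assert r1.log_q == 0.0 and r1.n_noncanonical == 0

    def test_starts_with_init_ends_with_terminate(self):
        r = canonical_route(graph_from_smiles("CCN"))
        assert isinstance(r.steps[0][1], Init)
        assert isinstance(r.steps[-1][1], Terminate)
        assert r.steps[0][0].num_atoms == 0

    def test_disconnected_rejected(self):
        g = MolGraph()
        g.add_atom(C)
        g.add_atom(C)
        with pytest.raises(TransitionError):
            canonical_route(g)
        with pytest.raises(TransitionError):
            route_length(g)

    @pytest.mark.parametrize("smi", F.bundled_corpus()[:10])
    def test_replay_reproduces_molecule(self, smi):
        g = graph_from_smiles(smi)
        r = canonical_route(g)
        assert smiles_from_graph(replay(r.transitions).molecule) \
            == canonical_smiles(smi)


class TestSampleRoute:
    def test_alpha_one_equals_canonical(self):
        g = graph_from_smiles("c1ccccc1O")
        rng = np.random.default_rng(0)
        r = sample_route(g, 1.0, rng)
        assert r.transitions == canonical_route(g).transitions
        assert r.log_q == 0.0 and r.n_noncanonical == 0

    def test_methane_has_unique_route(self):
        rng = np.random.default_rng(1)
        r = sample_route(graph_from_smiles("C"), 0.3, rng)
        assert len(r) == 2 and r.log_q == 0.0

    def test_replay_identity_under_randomization(self):
        """200 random (molecule, alpha, seed) draws all replay exactly."""
        mols = F.random_molecules(F.FixtureSpec(n_molecules=20, max_atoms=10,
                                                ring_prob=0.5, seed=21))
        rng = np.random.default_rng(100)
        for i in range(200):
            smi = mols[i % len(mols)]
            g = graph_from_smiles(smi)
            alpha = rng.uniform(0.0, 1.0)
            r = sample_route(g, alpha, rng)
            assert len(r) == g.num_bonds + 2
            assert smiles_from_graph(r.molecule) == canonical_smiles(smi)

    def test_mistake_rate_calibration(self):
        """Non-canonical steps occur at rate 1 - alpha among steps with
        alternatives."""
        g = graph_from_smiles("c1ccccc1")
        rng = np.random.default_rng(7)
        mistakes = choices = 0
        for _ in range(2000):
            r = sample_route(g, 0.6, rng)
            mistakes += r.n_noncanonical
            choices += r.n_choice_steps
        rate = mistakes / choices
        se = math.sqrt(0.4 * 0.6 / choices)
        assert abs(rate - 0.4) < 4 * se

    def test_logq_matches_independent_recomputation(self):
        g = graph_from_smiles("CCO")
        rng = np.random.default_rng(3)
        for _ in range(50):
            r = sample_route(g, 0.5, rng)
            assert np.isclose(r.log_q, route_q_logp(r, g, 0.5))

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            sample_route(graph_from_smiles("CC"), 1.5,
                         np.random.default_rng(0))


class TestRouteEnumeration:
    def test_linear_chain_route_count(self):
        """C-C-O admits exactly 4 routes: start at C(end), C(mid) or O;
        the middle start branches into two append orders."""
        routes = list(enumerate_routes(graph_from_smiles("CCO")))
        assert len(routes) == 4

    def test_symmetric_molecule_routes_deduplicated(self):
        # ethane: both atom orders give the same transition sequence
        routes = list(enumerate_routes(graph_from_smiles("CC")))
        assert len(routes) == 1

    def test_q_is_a_probability_distribution(self):
        """q_alpha sums to one over all routes of a molecule."""
        for smi in ("CCO", "C=O", "CCC", "C1CC1"):
            g = graph_from_smiles(smi)
            for alpha in (0.0, 0.4, 0.8, 1.0):
                total = sum(math.exp(route_q_logp(r, g, alpha))
                            for r in enumerate_routes(g))
                assert np.isclose(total, 1.0), (smi, alpha)

    def test_sampled_route_frequencies_match_q(self):
        g = graph_from_smiles("CCO")
        rng = np.random.default_rng(9)
        counts = {}
        n = 4000
        for _ in range(n):
            r = sample_route(g, 0.6, rng)
            counts[tuple(r.transitions)] = counts.get(
                tuple(r.transitions), 0) + 1
        for r in enumerate_routes(g):
            q = math.exp(route_q_logp(r, g, 0.6))
            freq = counts.get(tuple(r.transitions), 0) / n
            assert abs(freq - q) < 4 * math.sqrt(q * (1 - q) / n)

    def test_size_cap(self):
        with pytest.raises(TransitionError):
            list(enumerate_routes(graph_from_smiles("CCCCCC")))


_PROPERTY_MOLS = F.random_molecules(
    F.FixtureSpec(n_molecules=12, max_atoms=9, ring_prob=0.5, seed=77))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, len(_PROPERTY_MOLS) - 1), st.floats(0.0, 1.0),
       st.integers(0, 2 ** 20))
def test_replay_identity_property(idx, alpha, seed):
    """Any q_alpha draw replays to the molecule it was sampled from, with
    length |E| + 2 and a finite log-probability."""
    smi = _PROPERTY_MOLS[idx]
    g = graph_from_smiles(smi)
    r = sample_route(g, alpha, np.random.default_rng(seed))
    assert len(r) == g.num_bonds + 2
    assert r.log_q <= 0.0
    assert smiles_from_graph(r.molecule) == canonical_smiles(smi)


def test_route_jsonl_dump():
    r = canonical_route(graph_from_smiles("CCO"))
    lines = route_to_jsonl(r).splitlines()
    assert len(lines) == len(r)
    assert '"action_tag": "init"' in lines[0]
    assert '"action_tag": "terminate"' in lines[-1]
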