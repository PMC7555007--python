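import numpy as np
import pytest
from scipy import stats

from synapse_abm import FociParams, build_initial_state, feedback_field, foci_summary, update_foci
from synapse_abm import kinetics
from synapse_abm.foci import FOCI_EMPTY, FOCI_NUCL, FOCI_NUCL_POLY, FOCI_POLY
from synapse_abm.lattice_core import add_agent, bind_pair

from _oracles import count_clusters_bfs
from conftest import make_config


def foci_state_with(pairs=(), lfa_pairs=(), foci=None, radius=1.0):
    cfg = make_config(radius_um=radius, tcr=0.0, pmhc=0.0, lfa1=0.0, icam1=0.0,
                      foci=foci or FociParams(enabled=True))
    st = build_initial_state(cfg, seed=0)
    c = int(cfg.lattice.center)
    for off in pairs:
        node = (c + off[0], c + off[1])
        add_agent(st, "TCR", node)
        add_agent(st, "pMHC", node)
        bind_pair(st, node)
    for off in lfa_pairs:
        node = (c + off[0], c + off[1])
        add_agent(st, "LFA1", node)
        add_agent(st, "ICAM1", node)
        bind_pair(st, node)
    return st, c


class TestTransitions:
    def test_no_complexes_no_foci(self):
        st, _ = foci_state_with()
        for _ in range(50):
            update_foci(st)
        assert (st.foci_state == FOCI_EMPTY).all()

    def test_forced_nucleation_under_complex(self):
        p = FociParams(enabled=True, p_nucleate=1.0, p_decay=0.0)
        st, c = foci_state_with(pairs=[(0, 0)], foci=p)
        update_foci(st)
        assert st.foci_state[c, c] == FOCI_NUCL

    def test_forced_chain_to_polymerization(self):
        # colocalized LFA1-ICAM1 promotes nucleation -> nucleation-polymerized;
        # a second adhesion complex in the neighborhood then drives polymerization
        p = FociParams(enabled=True, p_nucleate=1.0, p_nuc_polymerize=1.0,
                       p_polymerize=1.0, p_decay=0.0)
        st, c = foci_state_with(pairs=[(0, 0)], foci=p)
        update_foci(st)  # empty -> nucleation
        # place the adhesion complexes after nucleation: one on the node is
        # impossible (node taken by the TCR pair), so test via a neighbor that
        # is inside R_neighborhood
        add_agent(st, "LFA1", (c + 1, c))
        add_agent(st, "ICAM1", (c + 1, c))
        bind_pair(st, (c + 1, c))
        update_foci(st)
        assert st.foci_state[c, c] == FOCI_POLY

    def test_nucleation_polymerized_via_colocalization(self):
        # nucleation left by a departed TCR pair, then an adhesion pair arrives
        p = FociParams(enabled=True, p_nucleate=1.0, p_nuc_polymerize=1.0,
                       p_polymerize=1.0, p_decay=0.0)
        st, c = foci_state_with(pairs=[(0, 0)], foci=p)
        update_foci(st)
        assert st.foci_state[c, c] == FOCI_NUCL
        # remove the TCR pair, put an LFA pair on the same node
        st.grid_t[c, c] = -1
        st.grid_a[c, c] = -1
        st.species = st.species[:0]
        st.xs, st.ys, st.partner = st.xs[:0], st.ys[:0], st.partner[:0]
        add_agent(st, "LFA1", (c, c))
        add_agent(st, "ICAM1", (c, c))
        bind_pair(st, (c, c))
        update_foci(st)
        assert st.foci_state[c, c] == FOCI_NUCL_POLY
        update_foci(st)  # colocalized adhesion also lies within R_neighborhood
        assert st.foci_state[c, c] == FOCI_POLY

    def test_neighborhood_radius_respected(self):
        p = FociParams(enabled=True, p_nucleate=1.0, p_nuc_polymerize=1.0,
                       p_polymerize=1.0, p_decay=0.0, r_neighborhood_um=0.16)
        st, c = foci_state_with(pairs=[(0, 0)], lfa_pairs=[(5, 0)], foci=p)
        for _ in range(5):
            update_foci(st)  # LFA pair at 0.4 µm: outside the 0.16 µm radius
        assert st.foci_state[c, c] == FOCI_NUCL

    def test_decay_lifetimes_geometric(self):
        # seed many nucleation nodes, remove the complex source, and check the
        # self-inhibition lifetimes against the geometric law chi-square-wise
        p_decay = 0.2
        p = FociParams(enabled=True, p_nucleate=1.0, p_decay=p_decay)
        cfg = make_config(radius_um=1.6, tcr=0.0, pmhc=0.0, lfa1=0.0, icam1=0.0, foci=p)
        st = build_initial_state(cfg, seed=0)
        ys, xs = np.nonzero(st.active)
        for y, x in list(zip(ys, xs))[:1200]:
            add_agent(st, "TCR", (int(x), int(y)))
            add_agent(st, "pMHC", (int(x), int(y)))
            bind_pair(st, (int(x), int(y)))
        update_foci(st)
        n0 = int((st.foci_state == FOCI_NUCL).sum())
        assert n0 >= 1200
        # remove all complexes so nucleation cannot refresh
        st.grid_t[:] = -1
        st.grid_a[:] = -1
        st.species = st.species[:0]
        st.xs, st.ys, st.partner = st.xs[:0], st.ys[:0], st.partner[:0]
        deaths = []
        while (st.foci_state == FOCI_NUCL).any():
            before = int((st.foci_state == FOCI_NUCL).sum())
            update_foci(st)
            deaths.append(before - int((st.foci_state == FOCI_NUCL).sum()))
        # bin death steps 1..k with a pooled tail; expected geometric(p_decay)
        k = 15
        obs = np.array(deaths[: k - 1] + [sum(deaths[k - 1 :])], dtype=float)
        probs = np.array(
            [(1 - p_decay) ** (i - 1) * p_decay for i in range(1, k)] + [(1 - p_decay) ** (k - 1)]
        )
        chi = stats.chisquare(obs, probs * n0)
        assert chi.pvalue > 0.01
        assert (st.foci_state == FOCI_EMPTY).all()

    def test_empty_after_source_removed(self):
        p = FociParams(enabled=True, p_nucleate=1.0, p_decay=0.05)
        st, c = foci_state_with(pairs=[(0, 0), (2, 0), (0, 3)], foci=p)
        update_foci(st)
        st.partner[:] = -1  # dissociate everything; no bound TCR remains
        st.grid_t[:] = -1
        st.grid_a[:] = -1
        st.species = st.species[:0]
        st.xs, st.ys, st.partner = st.xs[:0], st.ys[:0], st.partner[:0]
        for _ in range(2000):
            update_foci(st)
        assert (st.foci_state == FOCI_EMPTY).all()


class TestFeedbackField:
    def test_empty_lattice_gives_unit_field(self):
        st, _ = foci_state_with()
        f = feedback_field(st.foci_state, st.config.foci)
        assert (f == 1.0).all()

    @pytest.mark.parametrize("b", [0.1, 0.5, 2.0, 10.0])
    def test_field_is_b_at_formed_foci_only(self, b):
        p = FociParams(enabled=True, b=b)
        st, c = foci_state_with(foci=p)
        st.foci_state[c, c] = FOCI_POLY
        st.foci_state[c, c + 2] = FOCI_NUCL  # not a formed focus
        f = feedback_field(st.foci_state, p)
        assert f[c, c] == b
        assert f[c, c + 2] == 1.0
        assert (f[st.foci_state == FOCI_EMPTY] == 1.0).all()

    def test_all_states_option_extends_feedback(self):
        p = FociParams(enabled=True, b=2.0, feedback_states="all")
        st, c = foci_state_with(foci=p)
        st.foci_state[c, c + 2] = FOCI_NUCL
        f = feedback_field(st.foci_state, p)
        assert f[c, c + 2] == 2.0


class TestSummary:
    def test_counts_and_clusters(self):
        st, c = foci_state_with()
        st.foci_state[c, c] = FOCI_POLY
        st.foci_state[c, c + 1] = FOCI_POLY  # adjacent: same cluster
        st.foci_state[c + 4, c] = FOCI_POLY  # distant: own cluster
        st.foci_state[c, c - 3] = FOCI_NUCL
        s = foci_summary(st.foci_state)
        assert s.n_polymerization == 3
        assert s.n_nucleation == 1
        assert s.n_clusters == 2

    def test_cluster_count_matches_bfs_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            grid = (rng.random((30, 30)) < 0.25).astype(np.int8) * FOCI_POLY
            assert foci_summary(grid).n_clusters == count_clusters_bfs(grid == FOCI_POLY)

    def test_two_nodes_distance_two_are_separate_clusters(self):
        st, c = foci_state_with()
        st.foci_state[c, c] = FOCI_POLY
        st.foci_state[c, c + 2] = FOCI_POLY
        assert foci_summary(st.foci_state).n_clusters == 2


class TestEmergentCausality:
    def test_no_tcr_binding_no_foci_ever(self):
        cfg = make_config(tcr_kon=0.0, foci=FociParams(enabled=True))
        st = build_initial_state(cfg, seed=3)
        for _ in range(20):
            kinetics.run(st, n_steps=100)
            assert (st.foci_state == FOCI_EMPTY).all()

    def test_no_icam_no_polymerized_states(self):
        cfg = make_config(icam1=0.0, foci=FociParams(enabled=True, p_nucleate=0.5))
        st = build_initial_state(cfg, seed=3)
        for _ in range(20):
            kinetics.run(st, n_steps=100)
            assert not (st.foci_state >= FOCI_NUCL_POLY).any()
        assert (st.foci_state == FOCI_NUCL).any()  # nucleation alone still occurs
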