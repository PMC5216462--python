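"""Transition path theory: committor closed forms, flux conservation, the
bottleneck path decomposition against exhaustive enumeration, and sign-based
Perron cluster lumping."""

import itertools

import networkx as nx
import numpy as np
import pytest

from narelease import synthetic
from narelease.msm import eigensystem, estimate_tpm, fit_msm, cluster_microstates
from narelease.tpt import (
    committor,
    compute_flux,
    flux_matrix,
    macro_flux_report,
    pcca_lump,
    top_paths,
    MacrostateMap,
)


def _nearest_neighbor_walk(n):
    T = np.zeros((n, n))
    for i in range(n):
        if i == 0:
            T[0, 0] = T[0, 1] = 0.5
        elif i == n - 1:
            T[i, i] = T[i, i - 1] = 0.5
        else:
            T[i, i - 1] = T[i, i + 1] = 0.5
    return T


class TestCommittor:
    def test_gamblers_ruin_closed_form(self):
        q = committor(_nearest_neighbor_walk(5), {0}, {4})
        assert np.allclose(q, [0, 0.25, 0.5, 0.75, 1.0], atol=1e-12)

    def test_boundary_conditions(self):
        T = _nearest_neighbor_walk(4)
        q = committor(T, {0}, {3})
        assert q[0] == 0.0 and q[3] == 1.0
        assert np.all((q >= 0) & (q <= 1))

    def test_disjointness_required(self):
        T = _nearest_neighbor_walk(3)
        with pytest.raises(ValueError, match="disjoint"):
            committor(T, {0}, {0, 2})

    def test_stranded_states_named(self):
        T = np.zeros((4, 4))
        T[0, 1] = T[1, 0] = 1.0
        T[2, 3] = T[3, 2] = 1.0  # states 2,3 cannot reach {0} or {1}
        with pytest.raises(ValueError, match=r"\[2, 3\]"):
            committor(T, {0}, {1})

    def test_matches_monte_carlo_first_visit(self):
        rng = np.random.default_rng(0)
        A = rng.random((6, 6)) + 0.05
        T, pi, _ = estimate_tpm(A + A.T)
        source, target = {0}, {5}
        q = committor(T, source, target)
        n_rep = 3000
        cum = np.cumsum(T, axis=1)
        for state in (1, 3):
            hits = 0
            for r in range(n_rep):
                s = state
                while True:
                    s = int(np.searchsorted(cum[s], rng.random()))
                    if s in target:
                        hits += 1
                        break
                    if s in source:
                        break
            p = hits / n_rep
            sigma = np.sqrt(q[state] * (1 - q[state]) / n_rep)
            assert abs(p - q[state]) < 3 * max(sigma, 1e-3)


class TestFlux:
    def test_three_state_hand_solved_example(self):
        T = np.array([[0.5, 0.5, 0.0], [0.25, 0.5, 0.25], [0.0, 0.5, 0.5]])
        pi = np.array([0.25, 0.5, 0.25])
        q = committor(T, {0}, {2})
        assert np.allclose(q, [0.0, 0.5, 1.0])
        f, net, total = flux_matrix(pi, q, T, {0}, {2})
        assert net[0, 1] == pytest.approx(0.0625)
        assert net[1, 2] == pytest.approx(0.0625)
        assert total == pytest.approx(0.0625)

    def test_stranded_interior_state_propagates_committor_error(self):
        # block-diagonal T: state 2 is an absorbing island that can reach
        # neither boundary, so the committor system is ill-posed
        T = np.zeros((5, 5))
        T[0, 1] = T[1, 0] = 1.0
        T[2, 2] = 1.0
        T[3, 4] = T[4, 3] = 1.0
        with pytest.raises(ValueError, match="no path"):
            compute_flux(T, np.full(5, 0.2), {0}, {4})

    def test_flux_conservation_at_interior_nodes(self):
        rng = np.random.default_rng(1)
        for seed in range(10):
            A = rng.random((8, 8)) + 0.02
            T, pi, _ = estimate_tpm(A + A.T)
            dec = compute_flux(T, pi, {0}, {7}, n_paths=3)
            net = dec.net_flux
            for i in range(1, 7):
                imbalance = net[:, i].sum() - net[i, :].sum()
                assert abs(imbalance) < 1e-10
            # two-cycle-free net flux and committor bounds
            assert np.all(net * net.T <= 1e-20)
            assert np.all((dec.committor >= 0) & (dec.committor <= 1))
            # flux into target equals flux out of source
            out_src = net[0, :].sum() - net[:, 0].sum()
            into_tgt = net[:, 7].sum() - net[7, :].sum()
            assert out_src == pytest.approx(into_tgt, abs=1e-12)
            assert dec.total_flux == pytest.approx(out_src, abs=1e-12)


def _greedy_enumeration_oracle(F, source, target, n_paths):
    """Independent decomposition: enumerate ALL simple source->target paths,
    repeatedly take the one with the widest bottleneck, subtract, repeat."""
    G = nx.DiGraph()
    n = F.shape[0]
    for i in range(n):
        for j in range(n):
            if F[i, j] > 0:
                G.add_edge(i, j)
    all_paths = []
    for s in source:
        for t in target:
            if G.has_node(s) and G.has_node(t):
                all_paths.extend(nx.all_simple_paths(G, s, t))
    W = F.copy()
    out = []
    for _ in range(n_paths):
        widths = [
            (min(W[a, b] for a, b in zip(p[:-1], p[1:])), p) for p in all_paths
        ]
        widths = [(w, p) for w, p in widths if w > 0]
        if not widths:
            break
        best_w = max(w for w, _ in widths)
        # canonical representative among ties: shortest, then lexicographic
        best = min(
            (p for w, p in widths if w == best_w), key=lambda p: (len(p), p)
        )
        for a, b in zip(best[:-1], best[1:]):
            W[a, b] -= best_w
        out.append((list(best), best_w))
    return out


class TestTopPaths:
    def test_single_chain_carries_all_flux(self):
        F = np.zeros((3, 3))
        F[0, 1] = F[1, 2] = 0.5
        paths = top_paths(F, {0}, {2}, 5)
        assert len(paths) == 1
        assert paths[0][0] == [0, 1, 2]
        assert paths[0][1] == pytest.approx(0.5)
        assert paths[0][2] == pytest.approx(1.0)

    def test_two_parallel_branches_ranked(self):
        F = np.zeros((4, 4))
        F[0, 1] = F[1, 3] = 0.6
        F[0, 2] = F[2, 3] = 0.4
        paths = top_paths(F, {0}, {3}, 5)
        assert [p[1] for p in paths] == [pytest.approx(0.6), pytest.approx(0.4)]
        assert paths[-1][2] == pytest.approx(1.0)

    def test_matches_exhaustive_oracle_on_random_dags(self):
        n_match = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 9))
            F = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.45:
                        F[i, j] = rng.random()
            got = top_paths(F, {0}, {n - 1}, 6)
            expect = _greedy_enumeration_oracle(F, {0}, {n - 1}, 6)
            assert len(got) == len(expect)
            for (p1, f1, _), (p2, f2) in zip(got, expect):
                assert p1 == p2
                assert f1 == pytest.approx(f2, abs=1e-10)
            n_match += 1
        assert n_match == 100

    def test_path_fluxes_nonincreasing_and_cumulative_bounded(self):
        rng = np.random.default_rng(7)
        A = rng.random((10, 10)) + 0.02
        T, pi, _ = estimate_tpm(A + A.T)
        dec = compute_flux(T, pi, {0, 1}, {8, 9}, n_paths=10)
        fluxes = [f for _, f, _ in dec.paths]
        assert all(a >= b - 1e-12 for a, b in zip(fluxes, fluxes[1:]))
        assert dec.paths[-1][2] <= 1.0 + 1e-9


class TestPCCA:
    def test_two_block_chain_split_matches_blocks(self):
        eps = 0.02
        C = np.array(
            [
                [10.0, 10.0, eps, eps],
                [10.0, 10.0, eps, eps],
                [eps, eps, 10.0, 10.0],
                [eps, eps, 10.0, 10.0],
            ]
        )
        T, pi, _ = estimate_tpm(C)
        _, right, _ = eigensystem(T, pi)
        mapping = pcca_lump(right, 2, pi=pi)
        assert mapping.labels[0] == mapping.labels[1]
        assert mapping.labels[2] == mapping.labels[3]
        assert mapping.labels[0] != mapping.labels[2]

    def test_identity_map_when_n_macro_equals_k(self):
        T, pi, _ = estimate_tpm(np.ones((5, 5)))
        _, right, _ = eigensystem(T, pi)
        mapping = pcca_lump(right, 5, pi=pi)
        assert np.array_equal(mapping.labels, np.arange(5))

    def test_three_well_msm_macrostates_match_basins(self):
        params = synthetic.ThreeWellParams()
        trajs = synthetic.simulate_three_well_ensemble(params, 10, 20_000, seed=3,
                                                       subsample=10)
        centers, assign = cluster_microstates(trajs, 30, seed=0)
        model = fit_msm(assign, lag_frames=5, centers=centers)
        mapping = pcca_lump(model.right_eigenvectors, 3, pi=model.stationary)
        # frame-level agreement with the generator's basin labels
        X = np.concatenate(trajs)
        truth = synthetic.assign_basins(X, params)
        micro = np.concatenate(assign)
        state_to_active = {s: i for i, s in enumerate(model.active_states)}
        macro = np.array([mapping.labels[state_to_active[m]] for m in micro])
        agree = 0
        for m in range(3):
            # map each macrostate to its majority basin
            vals, counts = np.unique(truth[macro == m], return_counts=True)
            agree += counts.max()
        assert agree / len(truth) >= 0.95


class TestMacroReport:
    def test_identity_map_reproduces_micro_table(self):
        rng = np.random.default_rng(2)
        A = rng.random((6, 6)) + 0.05
        T, pi, _ = estimate_tpm(A + A.T)
        dec = compute_flux(T, pi, {0}, {5}, n_paths=4)
        mapping = MacrostateMap(np.arange(6), 6)
        rep = macro_flux_report(dec, mapping, n_paths=4)
        assert rep["total_flux"] == dec.total_flux
        for (p1, f1, _), (p2, f2, _) in zip(rep["paths"], dec.paths):
            assert p1 == p2 and f1 == pytest.approx(f2)

    def test_aggregation_conserves_total_flux(self):
        rng = np.random.default_rng(3)
        A = rng.random((8, 8)) + 0.05
        T, pi, _ = estimate_tpm(A + A.T)
        dec = compute_flux(T, pi, {0}, {7}, n_paths=4)
        mapping = MacrostateMap(np.array([0, 0, 1, 1, 2, 2, 3, 3]), 4)
        rep = macro_flux_report(dec, mapping, n_paths=4)
        assert rep["total_flux"] == dec.total_flux
        # macro net-flux out of the source macrostate equals the total
        M = np.zeros((4, 4))
        for row in rep["net_flux_table"].itertuples():
            M[row[1], row[2]] = row[3]
        out0 = M[0, :].sum() - M[:, 0].sum()
        assert out0 == pytest.approx(dec.total_flux, rel=1e-10)

    def test_three_well_top_macro_path_passes_intermediate(self):
        params = synthetic.ThreeWellParams()
        trajs = synthetic.simulate_three_well_ensemble(params, 10, 20_000, seed=4,
                                                       subsample=10)
        centers, assign = cluster_microstates(trajs, 30, seed=0)
        # lag short enough to resolve the brief dwell in the shallow
        # intermediate well, so its macrostate appears on the pathway
        model = fit_msm(assign, lag_frames=1, centers=centers)
        act_centers = centers[model.active_states]
        basin_of_state = synthetic.assign_basins(act_centers, params)
        source = set(np.nonzero(basin_of_state == 0)[0].tolist())
        target = set(np.nonzero(basin_of_state == 2)[0].tolist())
        dec = compute_flux(model.transition_matrix, model.stationary,
                           source, target, n_paths=5)
        mapping = pcca_lump(model.right_eigenvectors, 3, pi=model.stationary)
        rep = macro_flux_report(dec, mapping, n_paths=5)
        top = rep["paths"][0][0]
        # the intermediate basin's macrostate lies on the top pathway
        inter_states = np.nonzero(basin_of_state == 1)[0]
        inter_macro = np.bincount(mapping.labels[inter_states]).argmax()
        assert inter_macro in top[1:-1]
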