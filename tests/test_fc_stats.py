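"""Edge-wise paired contrasts, FC graph metrics, G fitting."""

import itertools

import numpy as np
import pytest

from lesionkit import (Connectome, DMFParams, FCMatrix, fc_graph_metrics,
                       fit_global_coupling, hemisphere_edge_mask,
                       paired_edge_ttest)
from lesionkit.fc_stats import weighted_transitivity, _distances


def fc_of(values):
    v = np.asarray(values, dtype=float)
    np.fill_diagonal(v, 1.0)
    return FCMatrix(values=v)


def random_fc(rng, n):
    x = rng.standard_normal((n, n + 5))
    return FCMatrix(np.corrcoef(x))


class TestPairedTTest:
    def test_identical_conditions_give_zero_t(self, rng):
        fcs = [random_fc(rng, 5) for _ in range(4)]
        comp = paired_edge_ttest(fcs, fcs)
        assert np.all(comp.t_stat == 0.0)
        assert not comp.significant.any()

    def test_matches_closed_form_paired_t(self, rng):
        n_sub, n = 4, 4
        fcs_a = [random_fc(rng, n) for _ in range(n_sub)]
        fcs_b = [random_fc(rng, n) for _ in range(n_sub)]
        comp = paired_edge_ttest(fcs_a, fcs_b)
        i, j = 0, 2
        d = np.array([np.arctanh(b.values[i, j]) - np.arctanh(a.values[i, j])
                      for a, b in zip(fcs_a, fcs_b)])
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(n_sub))
        assert comp.t_stat[i, j] == pytest.approx(t_hand, abs=1e-12)

    def test_all_small_p_survive_bh(self, rng):
        # a strong uniform shift: every edge significant, BH keeps them all
        base = [FCMatrix(0.4 * random_fc(rng, 4).values + np.diag(np.full(4, 0.6)))
                for _ in range(5)]
        shifted = [FCMatrix(np.clip(f.values + 0.4 * (1 - np.eye(4)), -1, 1))
                   for f in base]
        comp = paired_edge_ttest(base, shifted, alpha=0.05)
        iu = np.triu_indices(4, 1)
        assert comp.significant[iu].all()

    def test_bh_mask_monotone_in_alpha(self, rng):
        fcs_a = [random_fc(rng, 6) for _ in range(5)]
        fcs_b = [random_fc(rng, 6) for _ in range(5)]
        lo = paired_edge_ttest(fcs_a, fcs_b, alpha=0.01).significant
        hi = paired_edge_ttest(fcs_a, fcs_b, alpha=0.2).significant
        assert np.all(hi[lo])  # discoveries never lost when alpha grows

    def test_requires_three_matched_subjects(self, rng):
        fcs = [random_fc(rng, 4) for _ in range(2)]
        with pytest.raises(ValueError):
            paired_edge_ttest(fcs, fcs)
        with pytest.raises(ValueError):
            paired_edge_ttest(fcs, fcs[:1])


def brute_force_modularity(w):
    """Exhaustive search over all partitions of up to ~10 nodes."""
    n = w.shape[0]
    m2 = w.sum()
    k = w.sum(axis=1)

    def q_of(labels):
        q = 0.0
        for i in range(n):
            for j in range(n):
                if labels[i] == labels[j]:
                    q += w[i, j] - k[i] * k[j] / m2
        return q / m2

    best = -1.0
    # iterate over set partitions via restricted growth strings
    def rgs(prefix, m):
        if len(prefix) == n:
            yield prefix
            return
        for v in range(m + 1):
            yield from rgs(prefix + [v], max(m, v + 1))

    for labels in rgs([0], 1):
        best = max(best, q_of(labels))
    return best


class TestGraphMetrics:
    def test_complete_graph(self):
        n = 6
        w = np.ones((n, n))
        m = fc_graph_metrics(fc_of(w))
        assert m.transitivity == pytest.approx(1.0)
        assert m.char_path_length == pytest.approx(1.0)
        assert m.global_efficiency == pytest.approx(1.0)

    def test_two_cliques_modularity_matches_exhaustive_search(self):
        w = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i, j in itertools.combinations(block, 2):
                w[i, j] = w[j, i] = 1.0
        m = fc_graph_metrics(fc_of(w))
        assert m.modularity == pytest.approx(brute_force_modularity(w), abs=1e-9)

    def test_ring_lattice_paths_match_hand_enumeration(self):
        # ring of 8, nearest neighbours, unit weights: d(i,j) = ring distance
        n = 8
        w = np.zeros((n, n))
        for i in range(n):
            w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0
        m = fc_graph_metrics(fc_of(w))
        dists = [min(abs(i - j), n - abs(i - j))
                 for i in range(n) for j in range(n) if i != j]
        assert m.char_path_length == pytest.approx(np.mean(dists))
        assert m.global_efficiency == pytest.approx(np.mean([1 / d for d in dists]))

    def test_negative_weights_zeroed(self):
        w = np.array([[0.0, 0.5, -0.7],
                      [0.5, 0.0, 0.5],
                      [-0.7, 0.5, 0.0]])
        d = _distances(np.where(w < 0, 0.0, w))
        assert np.isinf(d).sum() == 0  # reachable through positive path
        m = fc_graph_metrics(fc_of(w))
        assert m.defined

    def test_empty_graph_flagged(self):
        w = -np.ones((4, 4))
        with pytest.warns(RuntimeWarning, match="empty"):
            m = fc_graph_metrics(fc_of(w))
        assert not m.defined and np.isnan(m.modularity)

    def test_weighted_transitivity_triangle(self):
        # one weighted triangle: numerator = geometric means, denominator 6
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.8
        w[1, 2] = w[2, 1] = 0.2
        w[0, 2] = w[2, 0] = 0.4
        t = weighted_transitivity(w)
        w_hat = np.cbrt(w / w.max())
        expected = np.trace(w_hat @ w_hat @ w_hat) / 6.0
        assert t == pytest.approx(expected, abs=1e-12)


class TestGlobalCouplingFit:
    def test_self_consistent_grid_recovers_generating_G(self, small_connectome):
        """The grid argmax lands on the G that generated the target FC."""
        p = DMFParams(seed=5)
        kwargs = dict(duration=40.0, transient=10.0, record_stride=10,
                      fic_kwargs={"max_windows": 30}, seed=77)
        target = _target_at(small_connectome, p, 0.8, **kwargs)
        res = fit_global_coupling(small_connectome, p, target,
                                  grid=[0.4, 0.8, 1.2], **kwargs)
        assert res.G == 0.8
        assert res.in_band.any()

    def test_single_value_grid(self, small_connectome):
        p = DMFParams(seed=5)
        target = _target_at(small_connectome, p, 0.6, duration=40.0,
                            transient=10.0, record_stride=10,
                            fic_kwargs={"max_windows": 30}, seed=77)
        res = fit_global_coupling(small_connectome, p, target, grid=[0.6],
                                  duration=40.0, transient=10.0,
                                  record_stride=10,
                                  fic_kwargs={"max_windows": 30}, seed=77)
        assert res.G == 0.6

    def test_empty_grid_rejected(self, small_connectome):
        with pytest.raises(ValueError):
            fit_global_coupling(small_connectome, DMFParams(),
                                FCMatrix(np.eye(20)), grid=[])


def _target_at(c, p, g, **kwargs):
    from lesionkit import run_fic, simulate, bold_from_activity, fc_from_bold
    pg = p.with_(G=g)
    fic = run_fic(c, pg, seed=kwargs["seed"], **kwargs.get("fic_kwargs", {}))
    sim = simulate(c, pg, J=fic.J_final, duration=kwargs["duration"],
                   transient=kwargs["transient"],
                   record_stride=kwargs["record_stride"], seed=kwargs["seed"])
    act = sim.S_E_trace.T - sim.S_E_trace.T.mean(axis=1, keepdims=True)
    bold = bold_from_activity(act, dt=sim.trace_dt, TR=2.0,
                              transient=kwargs["transient"])
    return fc_from_bold(bold)


class TestHemisphereMask:
    def test_within_left_edges_only(self):
        mask = hemisphere_edge_mask(["L", "L", "R", "R"], "L")
        expected = np.zeros((4, 4), bool)
        expected[0, 1] = expected[1, 0] = True
        np.testing.assert_array_equal(mask, expected)

    def test_exclusion_of_lesioned_node(self):
        mask = hemisphere_edge_mask(["L", "L", "L", "R"], "L", exclude=1)
        assert not mask[1].any() and not mask[:, 1].any()
        assert mask[0, 2]
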