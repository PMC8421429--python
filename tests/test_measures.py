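"""Integration, segregation, FCD, mean FCD, Pearson FC."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hopfbrain import (
    Bold,
    FCDMatrix,
    extract_phases,
    fcd,
    integration,
    louvain_modularity,
    mean_fcd,
    pearson_fc,
    phase_interaction_series,
    segregation,
)
from hopfbrain.exceptions import InvalidArgumentError, ShortSeriesError
from hopfbrain.measures import binarize_by_surrogates


def two_cliques(n_cliques=2, size=5):
    n = n_cliques * size
    adj = np.zeros((n, n))
    for k in range(n_cliques):
        adj[k * size : (k + 1) * size, k * size : (k + 1) * size] = 1.0
    np.fill_diagonal(adj, 0.0)
    return adj


def brute_force_modularity(adj):
    """Exhaustive best-partition Newman modularity for tiny graphs."""
    n = adj.shape[0]
    m = adj.sum() / 2
    deg = adj.sum(axis=1)

    def q_of(labels):
        labels = np.asarray(labels)
        q = 0.0
        for c in set(labels.tolist()):
            idx = labels == c
            e_c = adj[np.ix_(idx, idx)].sum() / 2
            q += e_c / m - (deg[idx].sum() / (2 * m)) ** 2
        return q

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [head]] + part[i + 1 :]
            yield part + [[head]]

    best = -np.inf
    for part in partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, block in enumerate(part):
            labels[block] = c
        best = max(best, q_of(labels))
    return best


class TestIntegration:
    def test_fully_connected_is_one(self):
        assert integration(np.ones((10, 10))) == pytest.approx(1.0)

    def test_fully_disconnected_is_one_over_n(self):
        assert integration(np.zeros((10, 10))) == pytest.approx(0.1)

    def test_two_disjoint_cliques_is_half(self):
        assert integration(two_cliques()) == pytest.approx(0.5)

    def test_matches_networkx_component_oracle(self, rng):
        """Independent largest-component oracle over the threshold scan."""
        import networkx as nx

        P = rng.uniform(0, 1, size=(8, 8))
        P = 0.5 * (P + P.T)
        np.fill_diagonal(P, 1.0)
        thresholds = np.arange(0.0, 1.0, 0.01)
        sizes = []
        for thr in thresholds:
            off = P.copy()
            np.fill_diagonal(off, 0.0)
            G = nx.from_numpy_array((off > thr).astype(int))
            sizes.append(max(len(c) for c in nx.connected_components(G)) / 8)
        assert integration(P) == pytest.approx(np.mean(sizes))

    @given(
        hnp.arrays(float, (6, 6), elements=st.floats(0, 1)),
        st.floats(0.0, 0.3),
    )
    def test_monotone_under_pointwise_increase(self, raw, bump):
        P = 0.5 * (raw + raw.T)
        np.fill_diagonal(P, 1.0)
        assert integration(np.clip(P + bump, 0, 1)) >= integration(P) - 1e-12

    def test_rejects_nonsquare(self):
        with pytest.raises(InvalidArgumentError):
            integration(np.zeros((3, 4)))


class TestModularity:
    def test_two_equal_cliques(self):
        assert louvain_modularity(two_cliques(), seed=0) == pytest.approx(0.5)

    def test_complete_graph_is_zero(self):
        adj = np.ones((8, 8)) - np.eye(8)
        assert louvain_modularity(adj, seed=0) == pytest.approx(0.0, abs=1e-12)

    def test_four_equal_cliques(self):
        assert louvain_modularity(two_cliques(4, 2), seed=0) == pytest.approx(0.75)

    @pytest.mark.parametrize(
        "adj", [two_cliques(2, 4), two_cliques(4, 2), two_cliques(2, 3)]
    )
    def test_matches_exhaustive_partition_oracle(self, adj):
        assert louvain_modularity(adj, seed=1) == pytest.approx(
            brute_force_modularity(adj)
        )

    def test_empty_graph_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert louvain_modularity(np.zeros((5, 5))) == 0.0


class TestSegregation:
    def test_modular_synchrony_detected(self, rng):
        """Two independent synchronized blocks binarize into two communities."""
        t = np.arange(300) * 2.0
        block1 = np.cos(2 * np.pi * 0.05 * t) + 0.1 * rng.standard_normal((5, 300))
        block2 = np.cos(2 * np.pi * 0.06 * t + 2.0) + 0.1 * rng.standard_normal((5, 300))
        bold = Bold(np.vstack([block1, block2]), 2.0)
        from hopfbrain import mean_phase_interaction

        mean_P = mean_phase_interaction(extract_phases(bold))
        q = segregation(mean_P, bold, n_surrogates=100, alpha=0.01, seed=0)
        assert q > 0.3

    def test_surrogate_count_must_resolve_alpha(self, rng):
        bold = Bold(rng.standard_normal((4, 300)), 2.0)
        with pytest.raises(InvalidArgumentError):
            binarize_by_surrogates(np.eye(4), bold, 10, 0.01, seed=0)


class TestFCD:
    def test_stationary_pattern_gives_all_ones(self, rng):
        phases = np.tile(rng.uniform(-np.pi, np.pi, size=(6, 1)), (1, 80))
        series = phase_interaction_series(phases)
        out = fcd(series, window=10, step=2)
        np.testing.assert_allclose(out.similarity, 1.0)

    def test_orthogonal_and_antiphase_epochs(self):
        # hand-built window patterns: orthogonal vectors then sign-flipped
        base = np.zeros((40, 3, 3))
        v1 = np.array([1.0, 0.0, 0.0])  # upper triangle has 3 entries
        v2 = np.array([0.0, 1.0, 0.0])
        iu = np.triu_indices(3, k=1)
        for t in range(40):
            vec = v1 if t < 20 else v2
            base[t][iu] = vec
            base[t] = base[t] + base[t].T
            np.fill_diagonal(base[t], 1.0)
        out = fcd(base, window=20, step=20)
        assert out.similarity.shape == (2, 2)
        assert out.similarity[0, 1] == pytest.approx(0.0, abs=1e-12)
        flipped = np.concatenate([base[:20], -base[:20]])
        for t in range(20, 40):
            np.fill_diagonal(flipped[t], 1.0)
        out2 = fcd(flipped, window=20, step=20)
        assert out2.similarity[0, 1] == pytest.approx(-1.0)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ShortSeriesError):
            fcd(np.ones((10, 3, 3)), window=30)

    def test_symmetry_unit_diagonal(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=(5, 100))
        out = fcd(phase_interaction_series(phases), window=30, step=3)
        sim = out.similarity
        np.testing.assert_array_equal(sim, sim.T)
        np.testing.assert_array_equal(np.diag(sim), 1.0)
        assert np.all(sim >= -1.0) and np.all(sim <= 1.0)


class TestMeanFCD:
    def test_all_ones(self):
        assert mean_fcd(FCDMatrix(np.ones((4, 4)), 30, 1)) == 1.0

    def test_two_by_two(self):
        sim = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert mean_fcd(FCDMatrix(sim, 30, 1)) == pytest.approx(0.4)

    def test_exclude_overlap_drops_near_diagonal(self):
        m = 50
        sim = np.full((m, m), 0.5)
        i, j = np.triu_indices(m, k=1)
        near = (j - i) < 30
        sim[i[near], j[near]] = 1.0
        sim[j[near], i[near]] = 1.0
        np.fill_diagonal(sim, 1.0)
        full = mean_fcd(FCDMatrix(sim, 30, 1))
        distant = mean_fcd(FCDMatrix(sim, 30, 1), exclude_overlap=True)
        assert distant == pytest.approx(0.5)
        assert full > distant

    def test_independent_noise_has_low_recurrence(self, rng):
        """White noise has no recurrent synchronization patterns. Pairs of
        overlapping windows share band-passed (hence autocorrelated)
        samples, so the overlap-free mean is the clean null check."""
        bold = Bold(rng.standard_normal((40, 300)), 2.0)
        series = phase_interaction_series(extract_phases(bold))
        out = fcd(series)
        assert mean_fcd(out, exclude_overlap=True) < 0.05
        assert mean_fcd(out) < 0.2


class TestPearsonFC:
    def test_duplicate_row_capped(self, rng):
        x = rng.standard_normal(200)
        z = pearson_fc(Bold(np.vstack([x, x]), 2.0))
        assert np.isfinite(z[0, 1]) and z[0, 1] > 5

    def test_independent_noise_near_zero(self, rng):
        z = pearson_fc(Bold(rng.standard_normal((2, 5000)), 2.0))
        assert abs(z[0, 1]) < 0.1

    def test_anticorrelated_pair(self, rng):
        x = rng.standard_normal(500)
        y = -x + 1e-6 * rng.standard_normal(500)
        z = pearson_fc(Bold(np.vstack([x, y]), 2.0))
        assert z[0, 1] < -5

    def test_zero_variance_row_flagged(self, rng):
        x = np.vstack([np.ones(100), rng.standard_normal(100)])
        with pytest.warns(UserWarning):
            z = pearson_fc(Bold(x, 2.0))
        assert np.isnan(z[0, 1])
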