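"""Multiway cluster calling vs the exhaustive oracle; PS-cluster fusion."""

import numpy as np
import pytest

from hapsmooth.cluster import ClusterParams, call_clusters, ps_cluster
from hapsmooth.smoother import SmootherParams
from hapsmooth.synthetic import generate_copy_group_panel, inject_errors

from conftest import make_panel, oracle_clusters, random_panel


def cluster_keys(clusters):
    return {(c.start, c.end, c.haps) for c in clusters}


class TestCallClusters:
    def test_identical_panel_single_cluster(self):
        panel = make_panel(np.tile([0, 1, 1, 0, 1], (6, 1)))
        (c,) = call_clusters(panel, ClusterParams(2, 3, "sites"))
        assert c.haps == frozenset(range(6)) and (c.start, c.end) == (0, 5)

    def test_nested_blocks_both_reported(self):
        # 3 haplotypes share [10, 40); a 4th joins over [20, 30)
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, (4, 50), dtype=np.int8)
        a[1, 10:40] = a[0, 10:40]
        a[2, 10:40] = a[0, 10:40]
        a[3, 20:30] = a[0, 20:30]
        got = cluster_keys(call_clusters(make_panel(a), ClusterParams(5, 3, "sites")))
        assert (10, 40, frozenset({0, 1, 2})) in got
        assert (20, 30, frozenset({0, 1, 2, 3})) in got

    def test_matches_exhaustive_oracle(self, rng):
        """Cluster set equals brute-force maximal-block enumeration."""
        for _ in range(120):
            panel = random_panel(rng, 10, int(rng.integers(10, 61)), p=0.35)
            got = call_clusters(panel, ClusterParams(3, 2, "sites"))
            assert cluster_keys(got) == oracle_clusters(panel.alleles, 3, 2)

    def test_ternary_matches_oracle_with_sentinels(self, rng):
        for _ in range(120):
            m = rng.integers(0, 2, (8, 30)).astype(np.int8)
            m[rng.random((8, 30)) < 0.3] = -1
            got = call_clusters(m, ClusterParams(3, 2, "sites"))
            assert cluster_keys(got) == oracle_clusters(m, 3, 2)

    def test_minus_one_matches_nothing(self):
        m = np.full((3, 6), -1, dtype=np.int8)
        assert call_clusters(m, ClusterParams(2, 2, "sites")) == []

    def test_members_identical_and_unextendable(self, rng):
        panel = random_panel(rng, 12, 40, p=0.3)
        for c in call_clusters(panel, ClusterParams(4, 2, "sites")):
            members = np.array(sorted(c.haps))
            sub = panel.alleles[members, c.start : c.end]
            assert (sub == sub[0]).all()
            if c.start > 0:
                prev = panel.alleles[members, c.start - 1]
                assert not (prev == prev[0]).all()
            if c.end < panel.N:
                nxt = panel.alleles[members, c.end]
                assert not (nxt == nxt[0]).all()
            others = np.setdiff1d(np.arange(panel.M), members)
            full = panel.alleles[:, c.start : c.end]
            assert not any((full[o] == sub[0]).all() for o in others)

    def test_output_order_and_uniqueness(self, rng):
        panel = random_panel(rng, 10, 50, p=0.4)
        got = call_clusters(panel, ClusterParams(3, 2, "sites"))
        keys = [(c.start, -c.width) for c in got]
        assert keys == sorted(keys)
        assert len(cluster_keys(got)) == len(got)

    def test_cm_threshold_uses_span_of_matched_sites(self):
        panel = make_panel(np.tile([0, 1, 1, 0, 1], (3, 1)), cm_per_site=0.5)
        # cm_len = cm[4] - cm[0] = 2.0
        assert len(call_clusters(panel, ClusterParams(2.0, 2, "cm"))) == 1
        assert call_clusters(panel, ClusterParams(2.1, 2, "cm")) == []

    def test_param_validation(self):
        with pytest.raises(ValueError):
            ClusterParams(0, 2, "sites")
        with pytest.raises(ValueError):
            ClusterParams(1, 1, "sites")


class TestPsCluster:
    def test_error_free_copy_groups_unchanged_by_smoothing(self):
        panel, truth = generate_copy_group_panel(3, 10, 400, (50, 350), seed=2)
        cp = ClusterParams(1.0, 10, "cm")
        clusters, corrections = ps_cluster(panel, cp)
        assert corrections == []
        assert cluster_keys(clusters) == cluster_keys(call_clusters(panel, cp))
        assert cluster_keys(clusters) == cluster_keys(truth)

    def test_smoothing_rescues_fragmented_clusters(self):
        """One mid-segment flip per group: without smoothing each planted
        cluster fragments below threshold; with smoothing it is recovered
        in full length."""
        panel, truth = generate_copy_group_panel(4, 25, 500, (50, 450), seed=7)
        a = panel.alleles.copy()
        for gi in range(4):
            a[gi * 25 + 5, 250] ^= 1
        noisy = panel.with_alleles(a)
        cp = ClusterParams(len_sites := 350, 25, "sites")
        plain = call_clusters(noisy, cp)
        fused, corrections = ps_cluster(noisy, cp, SmootherParams(W=25))
        assert len(corrections) == 4
        assert cluster_keys(fused) == cluster_keys(truth)
        assert len(plain) < len(fused)

    def test_fused_equals_sequential(self, rng):
        for _ in range(60):
            panel, _ = generate_copy_group_panel(
                3, 8, 200, (30, 170), seed=int(rng.integers(1 << 30))
            )
            noisy, _ = inject_errors(panel, 0.01, seed=int(rng.integers(1 << 30)))
            cp = ClusterParams(50, 5, "sites")
            sp = SmootherParams(L=10, W=5)
            fused, cf = ps_cluster(noisy, cp, sp, fused=True)
            seq, cs = ps_cluster(noisy, cp, sp, fused=False)
            assert fused == seq
            assert cf == cs

    def test_smoothing_width_defaults_to_cluster_width(self):
        panel, _ = generate_copy_group_panel(2, 5, 300, (50, 250), seed=3)
        a = panel.alleles.copy()
        a[0, 150] ^= 1
        # rho must allow a 1/5 minority: use explicit params for the check,
        # default W should equal min_width=5 (not the smoothing default 20)
        clusters, corrections = ps_cluster(
            panel.with_alleles(a), ClusterParams(100, 5, "sites"),
            SmootherParams(W=5, rho=0.25),
        )
        assert [(c.hap, c.site) for c in corrections] == [(0, 150)]
        defaulted, _ = ps_cluster(panel.with_alleles(a), ClusterParams(100, 5, "sites"))
        sp_default = SmootherParams(W=5)
        assert defaulted == ps_cluster(panel.with_alleles(a), ClusterParams(100, 5, "sites"), sp_default)[0]

    def test_power_never_hurt_by_smoothing_on_planted_errors(self):
        from hapsmooth.evaluation import cluster_power_accuracy

        panel, truth = generate_copy_group_panel(5, 25, 500, (50, 450), seed=21)
        noisy, _ = inject_errors(panel, 0.002, seed=22)
        cp = ClusterParams(300, 20, "sites")
        plain = call_clusters(noisy, cp)
        smoothed, _ = ps_cluster(noisy, cp, SmootherParams(W=20))
        p_plain = cluster_power_accuracy(truth, plain).power
        p_smooth = cluster_power_accuracy(truth, smoothed).power
        assert p_smooth >= p_plain
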