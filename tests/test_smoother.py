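"""The smoothing rule: the IBD prior, gap corrections, and the scan."""

import numpy as np
import pytest

from hapsmooth.bipbwt import bidirectional_scan
from hapsmooth.smoother import (
    GapSiteCounts,
    SmootherParams,
    ibd_prior,
    smooth_block,
    smooth_panel,
)
from hapsmooth.synthetic import generate_copy_group_panel, inject_errors

from conftest import make_panel, random_panel


def fig_style_panel():
    """4 haplotypes, identical 8-site flanks, 3-site gap with minor-allele
    frequencies 50%, 0% and 25%."""
    left = np.tile([0, 1, 0, 1, 1, 0, 0, 1], (4, 1))
    gap = np.array([[0, 1, 0], [0, 1, 0], [1, 1, 0], [1, 1, 1]])
    right = np.tile([1, 0, 1, 0, 0, 1, 1, 0], (4, 1))
    return make_panel(np.concatenate([left, gap, right], axis=1))


class TestIbdPrior:
    def test_boundary_at_rho(self):
        # AF exactly rho is not below it -> keep (returns 1)
        assert ibd_prior(1, GapSiteCounts(zeros=19, ones=1), W=20, rho=0.05) == 1
        # one more reference haplotype pushes AF below rho -> implausible
        assert ibd_prior(1, GapSiteCounts(zeros=20, ones=1), W=20, rho=0.05) == 0

    def test_small_reference_set_keeps_observed(self):
        assert ibd_prior(0, GapSiteCounts(zeros=1, ones=17), W=20, rho=0.05) == 1
        assert ibd_prior(1, GapSiteCounts(zeros=17, ones=1), W=20, rho=0.05) == 1

    def test_inconclusive_when_both_common(self):
        counts = GapSiteCounts(zeros=12, ones=13)
        assert ibd_prior(0, counts, W=20, rho=0.3) == 1
        assert ibd_prior(1, counts, W=20, rho=0.3) == 1

    def test_rho_validation(self):
        with pytest.raises(ValueError):
            ibd_prior(0, GapSiteCounts(1, 1), W=2, rho=1.5)


class TestSmoothBlock:
    def test_gap_maf_rule_on_flanked_block(self):
        """|B|=4, rho=0.35: gap MAFs 50%/0%/25% -> only the third gap site
        (single minor-allele carrier) is corrected."""
        panel = fig_style_panel()
        (k, (block,)), = list(bidirectional_scan(panel, L=8, W=4, g=3))
        corrections = smooth_block(block, panel, rho=0.35)
        assert [(c.hap, c.site, c.old_allele, c.new_allele) for c in corrections] == [
            (3, 10, 1, 0)
        ]
        assert panel.alleles[3, 10] == 0  # mutated in place

    def test_balanced_site_untouched(self):
        panel = fig_style_panel()
        (k, (block,)), = list(bidirectional_scan(panel, L=8, W=4, g=3))
        smooth_block(block, panel, rho=0.49)
        assert panel.alleles[:, 8].tolist() == [0, 0, 1, 1]  # 50/50 stays

    def test_minority_flips_in_both_directions(self):
        # threshold |B|*rho = 1.4: counts (3,1) -> the 1 becomes 0; (1,3) -> the 0 becomes 1
        for gap_col, fixed in [([0, 0, 0, 1], 0), ([1, 1, 1, 0], 1)]:
            left = np.tile([0, 1, 0, 1, 1, 0, 0, 1], (4, 1))
            right = np.tile([1, 0, 1, 0, 0, 1, 1, 0], (4, 1))
            a = np.concatenate([left, np.array(gap_col)[:, None], right], axis=1)
            panel = make_panel(a)
            (k, (block,)), = list(bidirectional_scan(panel, L=8, W=4, g=1))
            smooth_block(block, panel, rho=0.35)
            assert (panel.alleles[:, 8] == fixed).all()

    def test_strict_threshold_variant(self):
        # |B|=4, counts (3,1): min=1, |B|*rho=1.0 -> non-strict corrects, strict keeps
        left = np.tile([0, 1, 0, 1, 1, 0, 0, 1], (4, 1))
        right = np.tile([1, 0, 1, 0, 0, 1, 1, 0], (4, 1))
        a = np.concatenate([left, np.array([0, 0, 0, 1])[:, None], right], axis=1)
        panel = make_panel(a)
        (k, (block,)), = list(bidirectional_scan(panel, L=8, W=4, g=1))
        assert len(smooth_block(block, panel.copy(), rho=0.25)) == 1
        assert smooth_block(block, panel.copy(), rho=0.25, strict_maf=True) == []


class TestSmoothPanel:
    def test_identical_panel_untouched(self):
        panel = make_panel(np.tile(np.arange(50) % 2, (25, 1)))
        out, corrections = smooth_panel(panel, SmootherParams())
        assert corrections == []
        assert np.array_equal(out.alleles, panel.alleles)

    def test_isolated_error_in_copy_panel_is_reversed(self, rng):
        hap = rng.integers(0, 2, 200, dtype=np.int8)
        a = np.tile(hap, (30, 1))
        a[11, 100] ^= 1
        out, corrections = smooth_panel(make_panel(a), SmootherParams())
        assert [(c.hap, c.site) for c in corrections] == [(11, 100)]
        assert np.array_equal(out.alleles, np.tile(hap, (30, 1)))

    def test_edge_zone_never_corrected(self, rng):
        hap = rng.integers(0, 2, 200, dtype=np.int8)
        for site in (5, 197):
            a = np.tile(hap, (30, 1))
            a[11, site] ^= 1
            out, corrections = smooth_panel(make_panel(a), SmootherParams())
            assert corrections == []

    def test_input_panel_unmodified(self, rng):
        panel = random_panel(rng, 25, 120)
        noisy, _ = inject_errors(panel, 0.01, seed=5)
        before = noisy.alleles.copy()
        smooth_panel(noisy, SmootherParams(W=5))
        assert np.array_equal(noisy.alleles, before)

    def test_correction_log_equals_panel_diff(self, rng):
        panel, _ = generate_copy_group_panel(3, 25, 300, (30, 270), seed=4)
        noisy, _ = inject_errors(panel, 0.005, seed=6)
        out, corrections = smooth_panel(noisy, SmootherParams())
        diff = set(zip(*np.nonzero(out.alleles != noisy.alleles)))
        assert {(c.hap, c.site) for c in corrections} == diff
        for c in corrections:
            assert noisy.alleles[c.hap, c.site] == c.old_allele
            assert out.alleles[c.hap, c.site] == c.new_allele == 1 - c.old_allele

    def test_corrected_blocks_are_stable(self, rng):
        """After the scan, every qualifying block's gap site has minority
        count 0 or above |B|*rho on the output alleles, and a second pass
        on a planted-error panel makes no further corrections."""
        panel, _ = generate_copy_group_panel(2, 25, 400, (50, 350), seed=9)
        a = panel.alleles.copy()
        for hap, site in [(3, 100), (30, 200), (12, 300)]:  # isolated, >L apart
            a[hap, site] ^= 1
        params = SmootherParams()
        once, c1 = smooth_panel(panel.with_alleles(a), params)
        assert len(c1) == 3
        twice, c2 = smooth_panel(once, params)
        assert c2 == []
        for k, blocks in bidirectional_scan(once, params.L, params.W, params.g):
            for b in blocks:
                members = sorted(b.haps)
                for site in range(*b.gap):
                    ones = int(once.alleles[members, site].sum())
                    mn = min(ones, len(members) - ones)
                    assert mn == 0 or mn > len(members) * params.rho

    def test_correction_count_monotone_in_rho(self, rng):
        panel, _ = generate_copy_group_panel(2, 30, 300, (40, 260), seed=12)
        noisy, _ = inject_errors(panel, 0.005, seed=13)
        counts = [
            len(smooth_panel(noisy, SmootherParams(rho=rho))[1])
            for rho in (0.01, 0.05, 0.1)
        ]
        assert counts == sorted(counts)

    def test_short_panel_returned_unchanged_with_warning(self, rng):
        panel = random_panel(rng, 5, 30)
        with pytest.warns(UserWarning):
            out, corrections = smooth_panel(panel, SmootherParams())
        assert corrections == [] and np.array_equal(out.alleles, panel.alleles)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            SmootherParams(rho=0.5)
        with pytest.raises(ValueError):
            SmootherParams(L=0)
        with pytest.raises(ValueError):
            SmootherParams(g=0)
        with pytest.raises(ValueError):
            SmootherParams(W=1)
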