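"""TSS-usage fingerprints, JSD properties, permutation test, gradients."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon

from translatome.io import TranscriptRecord
from translatome.tss import (
    compute_usage,
    gradient_distribution,
    permutation_pvalue,
    usage_divergence,
)


def _tx(tid, gene, tss):
    return TranscriptRecord(tid, gene, tss, "ATGGCCTAA", 0)


@pytest.fixture
def usage_setup(small_sheet):
    transcripts = [
        _tx("t1a", "gA", "tssA1"),
        _tx("t1b", "gA", "tssA1"),  # second splice variant, same TSS
        _tx("t2", "gA", "tssA2"),
        _tx("t3", "gB", "tssB1"),  # single-TSS gene, must be excluded
    ]
    rng = np.random.default_rng(0)
    abundances = pd.DataFrame(
        rng.uniform(1, 100, size=(4, 12)),
        index=["t1a", "t1b", "t2", "t3"],
        columns=small_sheet.sample_ids,
    )
    return abundances, transcripts, small_sheet


class TestJSD:
    def test_zero_iff_equal(self):
        assert usage_divergence([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_disjoint_support_is_one_bit(self):
        assert usage_divergence([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            k = rng.integers(2, 6)
            p = rng.dirichlet(np.ones(k))
            q = rng.dirichlet(np.ones(k))
            expected = jensenshannon(p, q, base=2) ** 2
            assert usage_divergence(p, q) == pytest.approx(expected, abs=1e-10)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            p = rng.dirichlet([0.5, 0.5, 0.5])
            q = rng.dirichlet([0.5, 0.5, 0.5])
            d = usage_divergence(p, q)
            assert d == pytest.approx(usage_divergence(q, p))
            assert 0 <= d <= 1

    def test_rejects_unnormalised(self):
        with pytest.raises(ValueError):
            usage_divergence([0.5, 0.2], [0.5, 0.5])
        with pytest.raises(ValueError):
            usage_divergence([0.5, 0.5], [1.0])


class TestUsage:
    def test_single_tss_gene_excluded(self, usage_setup):
        profiles = compute_usage(*usage_setup)
        assert [p.gene_id for p in profiles] == ["gA"]

    def test_proportions_sum_to_one(self, usage_setup):
        (profile,) = compute_usage(*usage_setup)
        for cell, props in profile.proportions.items():
            assert props.sum() == pytest.approx(1.0)

    def test_transcripts_pool_by_tss(self, usage_setup):
        abundances, transcripts, sheet = usage_setup
        (profile,) = compute_usage(abundances, transcripts, sheet)
        cell = ("case", "total")
        samples = sheet.samples_for(*cell)
        expected_tssA1 = abundances.loc[["t1a", "t1b"], samples].mean(axis=1).sum()
        i = profile.tss_ids.index("tssA1")
        assert profile.abundance[cell][i] == pytest.approx(expected_tssA1)

    def test_equal_abundance_gives_half_half(self, small_sheet):
        transcripts = [_tx("x", "g", "tss1"), _tx("y", "g", "tss2")]
        abundances = pd.DataFrame(
            5.0, index=["x", "y"], columns=small_sheet.sample_ids
        )
        (profile,) = compute_usage(abundances, transcripts, small_sheet)
        for props in profile.proportions.values():
            np.testing.assert_allclose(props, [0.5, 0.5])
        assert all(v == pytest.approx(0.0) for v in profile.divergences.values())

    def test_zero_cell_is_undefined_not_zero(self, small_sheet):
        transcripts = [_tx("x", "g", "tss1"), _tx("y", "g", "tss2")]
        abundances = pd.DataFrame(
            5.0, index=["x", "y"], columns=small_sheet.sample_ids
        )
        abundances[small_sheet.samples_for("case", "total")] = 0.0
        (profile,) = compute_usage(abundances, transcripts, small_sheet)
        assert profile.proportions[("case", "total")] is None
        assert profile.divergences["jsd_total_vs_polysomal_case"] is None
        assert profile.divergences["jsd_total_vs_polysomal_control"] == pytest.approx(0.0)

    def test_scale_invariance_of_proportions(self, usage_setup):
        abundances, transcripts, sheet = usage_setup
        (p1,) = compute_usage(abundances, transcripts, sheet)
        (p2,) = compute_usage(abundances * 7.0, transcripts, sheet)
        for cell in p1.proportions:
            np.testing.assert_allclose(p1.proportions[cell], p2.proportions[cell])


class TestPermutation:
    def test_identical_groups_give_p_one(self):
        a = [[0.5, 0.5]] * 3
        p = permutation_pvalue(a, a, n_perm=99, seed=1)
        assert p == 1.0

    def test_smallest_attainable_p(self):
        a = [[0.9, 0.1], [0.88, 0.12], [0.91, 0.09]]
        b = [[0.1, 0.9], [0.12, 0.88], [0.09, 0.91]]
        p = permutation_pvalue(a, b, n_perm=199, seed=2)
        assert p >= 1 / 200
        assert p < 0.2

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        a = rng.dirichlet([1, 1], size=3)
        b = rng.dirichlet([1, 1], size=3)
        p1 = permutation_pvalue(a, b, n_perm=99, seed=42)
        p2 = permutation_pvalue(a, b, n_perm=99, seed=42)
        assert p1 == p2

    def test_super_uniform_under_null(self):
        """Null p-values exceed the uniform CDF (within sampling tolerance)."""
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(300):
            a = rng.dirichlet([3, 3], size=3)
            b = rng.dirichlet([3, 3], size=3)
            pvals.append(permutation_pvalue(a, b, n_perm=60, seed=int(rng.integers(2**31))))
        pvals = np.array(pvals)
        for alpha in (0.05, 0.1, 0.25):
            assert (pvals <= alpha).mean() <= alpha + 0.05

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue([[0.5, 0.5]], [[0.5, 0.5], [0.4, 0.6]], n_perm=9, seed=0)


class TestGradient:
    def test_rnp_only_signal_has_zero_polysome_share(self):
        prof = gradient_distribution(
            [10, 5, 0, 0, 0, 0],
            [f"f{i}" for i in range(6)],
            [False, False, True, True, True, True],
            [False, False, False, False, True, True],
        )
        assert prof.polysome_share == 0.0
        assert prof.heavy_share == 0.0

    def test_uniform_share_matches_mask_fraction(self):
        prof = gradient_distribution(
            [1.0] * 10,
            [f"f{i}" for i in range(10)],
            [False] * 4 + [True] * 6,
            [False] * 7 + [True] * 3,
        )
        assert prof.polysome_share == pytest.approx(0.6)
        assert prof.heavy_share == pytest.approx(0.3)

    def test_random_vectors_normalise_and_match_mask_sums(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.uniform(0, 10, size=8)
            x[rng.integers(0, 8)] += 1.0  # ensure nonzero
            poly = rng.random(8) < 0.5
            heavy = poly & (rng.random(8) < 0.5)
            prof = gradient_distribution(x, [str(i) for i in range(8)], poly, heavy)
            assert prof.distribution.sum() == pytest.approx(1.0)
            assert prof.polysome_share == pytest.approx((x / x.sum())[poly].sum())
            assert prof.heavy_share == pytest.approx((x / x.sum())[heavy].sum())

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gradient_distribution([0, 0], ["a", "b"], [True, False], [False, False])

    def test_heavy_outside_polysome_rejected(self):
        with pytest.raises(ValueError):
            gradient_distribution([1, 1], ["a", "b"], [True, False], [False, True])
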