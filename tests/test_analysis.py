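import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import hexapure as hp


def rank_oracle(values):
    """Tie-averaged ranks by direct enumeration (independent of scipy)."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2.0)
    return np.array(ranks)


def spearman_rho_oracle(x, y):
    """Pearson correlation of tie-averaged ranks via numpy only."""
    rx, ry = rank_oracle(x), rank_oracle(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def exact_p_oracle(x, y):
    """Two-sided permutation p by brute force over all permutations of y."""
    rho_obs = abs(spearman_rho_oracle(x, y))
    count = total = 0
    for perm in itertools.permutations(y):
        rho = spearman_rho_oracle(x, perm)
        if np.isnan(rho):
            continue
        total += 1
        if abs(rho) >= rho_obs - 1e-12:
            count += 1
    return count / total


class TestSpearman:
    def test_monotone_relation_gives_unit_rho(self):
        x = np.arange(10.0)
        rho, _ = hp.spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho_neg, _ = hp.spearman(x, -x)
        assert rho_neg == pytest.approx(-1.0)

    def test_tied_data_example(self):
        # ranks of y are (1, 2, 3.5, 5, 3.5); Pearson on ranks = 8/sqrt(95)
        rho, _ = hp.spearman([1, 2, 3, 4, 5], [5, 6, 7, 8, 7])
        assert rho == pytest.approx(8 / np.sqrt(95))
        assert rho == pytest.approx(0.8207, abs=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_rho_matches_brute_force_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 8)
        x = rng.integers(0, 4, size=n).astype(float)  # ties likely
        y = rng.integers(0, 4, size=n).astype(float)
        if len(set(x)) < 2 or len(set(y)) < 2:
            x[0] += 10
            y[-1] += 10
        rho, p = hp.spearman(x, y)
        assert rho == pytest.approx(spearman_rho_oracle(x, y), abs=1e-12)
        assert p == pytest.approx(exact_p_oracle(x, y), abs=1e-12)

    def test_matches_scipy_for_large_n(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(size=60)
        rho, p = hp.spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_nan_pairs_are_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0]
        y = [2.0, 4.0, 5.0, 8.0, np.nan, 12.0, 14.0, 16.0, 18.0, 20.0, 22.0]
        rho, _ = hp.spearman(x, y)
        assert rho == pytest.approx(1.0)

    def test_perfect_rho_never_divides_by_zero(self):
        rho, p = hp.spearman(np.arange(20.0), np.arange(20.0) ** 3)
        assert rho == 1.0 and p == 0.0

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match=">= 3"):
            hp.spearman([1.0, 2.0], [1.0, 2.0])

    def test_zero_rank_variance_is_nan(self):
        rho, p = hp.spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(rho) and np.isnan(p)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(hp.benjamini_hochberg([0.03]), [0.03])

    def test_step_up_hand_computation(self):
        # p(i) * 4 / i = 0.04 for every i; the cumulative minimum keeps 0.04
        np.testing.assert_allclose(
            hp.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_order_preserved_and_never_decreases(self):
        p = np.array([0.04, 0.001, 0.8, 0.02])
        adj = hp.benjamini_hochberg(p)
        # smallest raw p stays smallest adjusted p (order statistics preserved)
        assert np.argmin(adj) == np.argmin(p)
        assert np.all(adj >= p)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    @settings(deadline=None, max_examples=60)
    def test_adjusted_ge_raw_and_in_unit_interval(self, ps):
        adj = hp.benjamini_hochberg(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all((adj >= 0) & (adj <= 1))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            hp.benjamini_hochberg([0.5, 1.5])

    def test_nan_passthrough_shrinks_family(self):
        adj = hp.benjamini_hochberg([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        # family size m = 2, not 3
        np.testing.assert_allclose(adj[[0, 2]], [0.02, 0.04])


class TestMetricCorrelationStudy:
    def test_one_row_per_pair_per_system(self, honeybee, bumblebee, default_flora):
        spectra, _ = default_flora
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, corr = hp.metric_correlation_study(
                spectra[:30],
                [honeybee, bumblebee],
                pairs=[("contrast_hex", "purity"), ("contrast_hex", "chroma_endler")],
                include_rnl=False,
                purity_boundary=1.0,
            )
        assert len(corr) == 4
        assert set(corr.visual_system) == {"honeybee", "bumblebee"}

    def test_metric_correlated_with_itself(self, honeybee, default_flora):
        spectra, _ = default_flora
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, corr = hp.metric_correlation_study(
                spectra[:25],
                honeybee,
                pairs=[("contrast_hex", "contrast_hex")],
                include_rnl=False,
                purity_boundary=1.0,
            )
        assert corr.rho.iloc[0] == pytest.approx(1.0)

    def test_refuses_small_stimulus_sets(self, honeybee, default_flora):
        spectra, _ = default_flora
        with pytest.raises(ValueError, match="fewer than 15"):
            hp.metric_correlation_study(spectra[:14], honeybee)

    def test_purity_shares_its_numerator_with_contrast(self, honeybee, default_flora):
        # the structural confound: a in a/(a+b) IS the colour contrast
        spectra, _ = default_flora
        line = hp.monochromatic_line(honeybee, closure_steps=20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in spectra[:15]:
                loc = hp.locus_for_stimulus(s, honeybee)
                res = hp.spectral_purity(loc.xy, line)
                if res.defined:
                    assert res.a == loc.distance_to_centre

    def test_constant_radius_boundary_makes_rho_exactly_one(
        self, honeybee, default_flora
    ):
        # with a constant denominator, purity is a monotone function of
        # contrast and the rank correlation is exactly 1
        spectra, _ = default_flora
        _, corr = hp.metric_correlation_study(
            spectra,
            honeybee,
            pairs=[("contrast_hex", "purity")],
            include_rnl=False,
            purity_boundary=0.8,
        )
        assert corr.rho.iloc[0] == 1.0

    def test_achromatic_stimulus_dropped_pairwise(self, honeybee, default_flora):
        spectra, _ = default_flora
        stimuli = list(spectra[:20]) + [honeybee.background.with_label("bg_copy")]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics, corr = hp.metric_correlation_study(
                stimuli,
                honeybee,
                pairs=[("contrast_hex", "purity")],
                include_rnl=False,
                purity_boundary=1.0,
            )
        assert not metrics.loc[metrics.label == "bg_copy", "purity_defined"].iloc[0]
        assert corr.n_used.iloc[0] == 20

    def test_bh_family_pools_all_rows(self, honeybee, bumblebee, default_flora):
        spectra, _ = default_flora
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, corr = hp.metric_correlation_study(
                spectra[:40], [honeybee, bumblebee], include_rnl=False,
                purity_boundary=1.0,
            )
            expected = hp.benjamini_hochberg(corr.p_raw.to_numpy())
        np.testing.assert_allclose(corr.p_adjusted.to_numpy(), expected)

    def test_unavailable_metric_is_an_error(self, honeybee, default_flora):
        spectra, _ = default_flora
        with pytest.raises(ValueError, match="unavailable"):
            hp.metric_correlation_study(
                spectra[:20],
                honeybee,
                pairs=[("contrast_rnl", "purity")],
                include_rnl=False,
                purity_boundary=1.0,
            )

    def test_study_is_deterministic(self, honeybee, default_flora):
        spectra, _ = default_flora
        kwargs = dict(
            pairs=[("contrast_hex", "purity")], include_rnl=False, purity_boundary=0.9
        )
        _, c1 = hp.metric_correlation_study(spectra[:30], honeybee, **kwargs)
        _, c2 = hp.metric_correlation_study(spectra[:30], honeybee, **kwargs)
        assert c1.equals(c2)
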