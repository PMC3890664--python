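"""Tolerance-interval statistics: frozen oracle values and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq
from scipy.special import gammainc
from scipy.stats import norm

from intdelim.datatypes import ContinuousSummary, ToleranceConfig, ValidationError
from intdelim import fixtures
from intdelim.tolerance import (
    ToleranceInterval,
    binomial_tolerance_bound,
    detect_gap,
    diagnose_discrete,
    howe_k,
    normal_ti,
    wilson_bound,
)


class TestHoweK:
    def test_matches_tabulated_chi_square_quantile(self, two_sided):
        # independently: chi2_{0.05,31} = 19.281, z_{0.975} = 1.95996
        expected = 1.959964 * math.sqrt(31 * (1 + 1 / 32) / 19.281)
        assert howe_k(32, two_sided) == pytest.approx(expected, abs=2e-4)
        assert howe_k(32, two_sided) == pytest.approx(2.5238, abs=1e-4)

    def test_large_n_limit_is_z_quantile(self, two_sided):
        assert howe_k(10**7, two_sided) == pytest.approx(1.95996, abs=1e-3)

    def test_monotonically_decreasing_in_n(self, two_sided):
        ks = [howe_k(n, two_sided) for n in (12, 32, 79)]
        assert ks[0] > ks[1] > ks[2]

    def test_chi_square_quantile_is_exact_inversion(self, two_sided):
        # oracle: invert the regularized-gamma chi-square CDF numerically
        for n in (5, 18, 32, 79):
            df = n - 1
            q = brentq(lambda x: gammainc(df / 2, x / 2) - 0.05, 1e-9, 10 * df, xtol=1e-12)
            expected = norm.ppf(0.975) * math.sqrt(df * (1 + 1 / n) / q)
            assert howe_k(n, two_sided) == pytest.approx(expected, abs=1e-6)

    def test_rejects_tiny_samples(self, two_sided):
        with pytest.raises(ValidationError):
            howe_k(1, two_sided)


class TestNormalTI:
    @pytest.mark.parametrize(
        "mean,sd,n,lower,upper",
        [
            (56.8, 6.1, 32, 41.4, 72.2),
            (76.3, 6.5, 42, 60.5, 92.1),
        ],
    )
    def test_published_scale_count_intervals(self, two_sided, mean, sd, n, lower, upper):
        ti = normal_ti(ContinuousSummary("t", "c", mean, sd, n), two_sided)
        assert round(ti.lower, 1) == lower
        assert round(ti.upper, 1) == upper

    def test_zero_sd_gives_degenerate_interval(self, two_sided):
        ti = normal_ti(ContinuousSummary("t", "c", 5.0, 0.0, 10), two_sided)
        assert ti.lower == ti.upper == 5.0

    def test_coverage_in_simulation_meets_nominal(self, two_sided):
        # 2000 samples of size 20 from N(0,1): the fraction of intervals
        # covering >= 95% of the distribution must reach the nominal 95%
        # confidence up to 3 Monte-Carlo standard errors
        rng = np.random.default_rng(20240917)
        n, reps = 20, 2000
        x = rng.normal(size=(reps, n))
        means, sds = x.mean(axis=1), x.std(axis=1, ddof=1)
        k = howe_k(n, two_sided)
        content = norm.cdf(means + k * sds) - norm.cdf(means - k * sds)
        frac = float((content >= 0.95).mean())
        mc_se = math.sqrt(0.95 * 0.05 / reps)
        assert frac >= 0.95 - 3 * mc_se


class TestWilsonBound:
    def test_closed_form_at_zero_successes(self):
        z = norm.ppf(0.95)
        assert wilson_bound(0, 12, 0.95, "upper") == pytest.approx(z * z / (12 + z * z), abs=1e-6)
        assert wilson_bound(0, 12, 0.95, "upper") == pytest.approx(0.1840, abs=1e-4)

    def test_upper_bound_is_one_at_full_successes(self):
        assert wilson_bound(12, 12, 0.95, "upper") == 1.0

    def test_score_inequality_root_oracle(self):
        # the Wilson bound solves (phat - p)^2 = z^2 p(1-p)/n
        z = norm.ppf(0.95)
        for x, n in [(0, 12), (3, 10), (7, 40), (18, 18)]:
            phat = x / n
            f = lambda p: (phat - p) ** 2 - z * z * p * (1 - p) / n
            got = wilson_bound(x, n, 0.95, "upper")
            if got < 1.0:
                assert f(got) == pytest.approx(0.0, abs=1e-10)
                assert got > phat

    @given(x=st.integers(0, 30), n=st.integers(1, 30), conf=st.floats(0.5, 0.999))
    def test_direction_symmetry(self, x, n, conf):
        x = min(x, n)
        lower = wilson_bound(x, n, conf, "lower")
        upper = wilson_bound(n - x, n, conf, "upper")
        assert lower == pytest.approx(1.0 - upper, abs=1e-12)


class TestBinomialToleranceBound:
    def test_future_sample_count_examples(self, one_sided):
        b = binomial_tolerance_bound(0, 12, 12, one_sided, "upper")
        assert b.count_bound == 5
        assert b.proportion_bound == pytest.approx(5 / 12)
        b2 = binomial_tolerance_bound(12, 12, 12, one_sided, "lower")
        assert b2.count_bound == 7

    def test_bound_collapses_with_massive_evidence(self, one_sided):
        assert binomial_tolerance_bound(0, 10**4, 12, one_sided, "upper").count_bound == 0

    def test_two_sided_config_rejected(self, two_sided):
        with pytest.raises(ValidationError):
            binomial_tolerance_bound(0, 12, 12, two_sided, "upper")


class TestDiagnoseDiscrete:
    def test_precloacal_pores_fixed_between_ancash_and_ayacucho(self):
        m = fixtures.walkeri_character_matrix(males_only=True)
        d = diagnose_discrete(m, "Ancash", "Ayacucho", "precloacal_pores")
        assert d.fixed_difference is True
        assert d.caveat_bounds["Ancash"] == pytest.approx(5 / 12)

    def test_polymorphic_taxon_breaks_fixation(self):
        m = fixtures.walkeri_character_matrix()
        d = diagnose_discrete(m, "Cusco", "walkeri", "lateral_field_marks")
        assert d.fixed_difference is False
        assert d.caveat_bounds == {}

    def test_shared_monomorphic_state_is_not_fixed(self):
        m = fixtures.walkeri_character_matrix()
        d = diagnose_discrete(m, "Ancash", "Ayacucho", "antehumeral_fold")
        assert d.fixed_difference is False

    def test_unscored_character_is_not_assessed(self):
        # female-only matrix has no scored adult-male characters
        m = fixtures.walkeri_character_matrix()
        females = m.data[m.data["sex"] == "female"]
        from intdelim.datatypes import CharacterMatrix

        fm = CharacterMatrix(females.reset_index(drop=True), m.applicability)
        d = diagnose_discrete(fm, "Ancash", "Ayacucho", "precloacal_pores")
        assert d.fixed_difference is None

    def test_symmetric_up_to_swapping(self):
        m = fixtures.walkeri_character_matrix(males_only=True)
        d1 = diagnose_discrete(m, "Ancash", "Ayacucho", "precloacal_pores")
        d2 = diagnose_discrete(m, "Ayacucho", "Ancash", "precloacal_pores")
        assert d1.fixed_difference == d2.fixed_difference
        assert d1.caveat_bounds == d2.caveat_bounds


class TestDetectGap:
    def _ti(self, lo, hi, cfg):
        return ToleranceInterval(lo, hi, k=1.0, config=cfg)

    def test_overlapping_published_intervals(self, two_sided):
        assert not detect_gap(self._ti(41.4, 72.3, two_sided), self._ti(45.6, 62.0, two_sided))

    def test_disjoint_and_touching(self, two_sided):
        assert detect_gap(self._ti(0, 1, two_sided), self._ti(2, 3, two_sided))
        assert not detect_gap(self._ti(0, 1, two_sided), self._ti(1, 2, two_sided))

    @given(
        a=st.tuples(st.floats(-50, 50), st.floats(0, 10)),
        b=st.tuples(st.floats(-50, 50), st.floats(0, 10)),
    )
    def test_symmetry(self, two_sided, a, b):
        ta = self._ti(a[0], a[0] + a[1], two_sided)
        tb = self._ti(b[0], b[0] + b[1], two_sided)
        assert detect_gap(ta, tb) == detect_gap(tb, ta)
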