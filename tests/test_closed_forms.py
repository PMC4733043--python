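import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from orgcount import (
    ClosedFormSpec,
    Family,
    ModelRates,
    RegimeError,
    closed_form_pmf,
    distribution_stats,
    family_moments,
    fano_from_contributions,
    fano_mean_curve,
    peroxisome_fano,
    peroxisome_mean,
    stationary_distribution,
)


def total_variation(dist, spec):
    n = dist.support
    closed = closed_form_pmf(spec, n)
    return 0.5 * (np.abs(dist.probabilities - closed).sum() + dist.tail_bound)


class TestClosedFormPmf:
    def test_poisson_at_zero(self):
        spec = ClosedFormSpec(Family.POISSON, lam=2.0)
        assert closed_form_pmf(spec, 0) == pytest.approx(math.exp(-2.0))

    def test_truncated_poisson_excludes_zero_and_renormalises(self):
        spec = ClosedFormSpec(Family.TRUNCATED_POISSON, lam=1.5)
        assert closed_form_pmf(spec, 0) == 0.0
        n = np.arange(1, 200)
        assert closed_form_pmf(spec, n).sum() == pytest.approx(1.0, abs=1e-12)

    def test_shifted_poisson_is_unit_shift(self):
        spec = ClosedFormSpec(Family.SHIFTED_POISSON, lam=1.0)
        assert closed_form_pmf(spec, 0) == 0.0
        assert closed_form_pmf(spec, 1) == pytest.approx(math.exp(-1.0))
        assert closed_form_pmf(spec, 3) == pytest.approx(math.exp(-1.0) / 2)

    def test_negative_binomial_approaches_poisson_as_fission_vanishes(self):
        """With k_de_novo/gamma fixed, letting k_fission -> 0 removes the
        n-dependence of the birth term and the law tends to Poisson."""
        poisson = ClosedFormSpec(Family.POISSON, lam=2.0)
        n = np.arange(0, 30)
        for kf in (1e-3, 1e-5):
            nb = ClosedFormSpec.from_rates(ModelRates(2.0, kf, 1.0))
            gap = np.abs(closed_form_pmf(nb, n) - closed_form_pmf(poisson, n)).max()
            assert gap < 5 * kf

    def test_invalid_shape_parameters_rejected(self):
        with pytest.raises(ValueError):
            ClosedFormSpec(Family.POISSON, lam=0.0)
        with pytest.raises(ValueError):
            ClosedFormSpec(Family.NEGATIVE_BINOMIAL, r=1.0, p=1.5)


class TestFromRates:
    def test_identifies_each_sub_model(self):
        assert ClosedFormSpec.from_rates(ModelRates(2.0, 0, 1.0, 0)).family is Family.POISSON
        spec = ClosedFormSpec.from_rates(ModelRates(0, 3.0, 0, 1.5))
        assert spec.family is Family.TRUNCATED_POISSON
        assert spec.lam == pytest.approx(2.0)
        spec = ClosedFormSpec.from_rates(ModelRates(2.0, 0.5, 1.0, 0))
        assert spec.family is Family.NEGATIVE_BINOMIAL
        assert (spec.r, spec.p) == (4.0, 0.5)

    def test_divergent_nb_rejected(self):
        with pytest.raises(RegimeError):
            ClosedFormSpec.from_rates(ModelRates(2.0, 1.2, 1.0, 0))

    def test_full_four_process_model_has_no_closed_form(self):
        with pytest.raises(ValueError):
            ClosedFormSpec.from_rates(ModelRates(2.0, 0.9, 1.0, 0.02))


class TestOracleEquivalence:
    """The recurrence solver and the closed forms are independent routes to
    the same laws; they must agree to near round-off."""

    @pytest.mark.parametrize("lam", np.geomspace(0.2, 40, 21).tolist())
    def test_immigration_death_matches_poisson(self, lam):
        rates = ModelRates(k_de_novo=lam, gamma=1.0)
        dist = stationary_distribution(rates)
        assert total_variation(dist, ClosedFormSpec.from_rates(rates)) < 1e-10

    @pytest.mark.parametrize("lam", np.geomspace(0.2, 40, 21).tolist())
    def test_fission_fusion_matches_truncated_poisson(self, lam):
        rates = ModelRates(k_fission=lam, k_fusion=1.0)
        dist = stationary_distribution(rates)
        assert dist.support_min == 1
        assert total_variation(dist, ClosedFormSpec.from_rates(rates)) < 1e-10

    @pytest.mark.parametrize(
        "kd,kf", [(kd, kf) for kd in (0.3, 1.0, 2.7, 8.0, 20.0) for kf in (0.05, 0.3, 0.6, 0.95)]
    )
    def test_de_novo_fission_decay_matches_negative_binomial(self, kd, kf):
        rates = ModelRates(k_de_novo=kd, k_fission=kf, gamma=1.0)
        dist = stationary_distribution(rates)
        assert total_variation(dist, ClosedFormSpec.from_rates(rates)) < 1e-10


class TestFamilyMoments:
    @pytest.mark.parametrize(
        "spec",
        [
            ClosedFormSpec(Family.POISSON, lam=3.7),
            ClosedFormSpec(Family.TRUNCATED_POISSON, lam=0.4),
            ClosedFormSpec(Family.TRUNCATED_POISSON, lam=6.0),
            ClosedFormSpec(Family.SHIFTED_POISSON, lam=2.5),
            ClosedFormSpec(Family.NEGATIVE_BINOMIAL, r=3.0, p=0.6),
            ClosedFormSpec(Family.NEGATIVE_BINOMIAL, r=27.0, p=0.0909),
        ],
    )
    def test_formula_matches_moment_sums(self, spec):
        """Closed-form moments agree with direct sums over the pmf."""
        n = np.arange(spec.support_min, 4000)
        pmf = closed_form_pmf(spec, n)
        keep = pmf > 1e-14
        n, pmf = n[keep].astype(float), pmf[keep]
        pmf = pmf / pmf.sum()
        mean, variance, fano = family_moments(spec)
        assert mean == pytest.approx(float(n @ pmf), rel=1e-8)
        assert variance == pytest.approx(float((n * n) @ pmf) - float(n @ pmf) ** 2, rel=1e-6)
        assert fano == pytest.approx(variance / mean, rel=1e-10)


class TestPeroxisomeMoments:
    def test_mean_formula_values(self):
        assert peroxisome_mean(ModelRates(2.7, 0.1, 1.0)) == pytest.approx(3.0)
        assert peroxisome_mean(ModelRates(2.0, 0.0, 1.0)) == pytest.approx(2.0)
        assert peroxisome_mean(ModelRates(5.0, 0.5, 1.0)) == pytest.approx(10.0)

    def test_fano_formula_values(self):
        assert peroxisome_fano(ModelRates(2.7, 0.1, 1.0)) == pytest.approx(1.0 / 0.9)
        assert peroxisome_fano(ModelRates(1.0, 0.0, 2.0)) == pytest.approx(1.0)
        assert peroxisome_fano(ModelRates(5.0, 0.5, 1.0)) == pytest.approx(2.0)

    def test_contribution_form_values(self):
        assert fano_from_contributions(3.0, ModelRates(2.7, 0.1, 1.0)) == pytest.approx(1.0 / 0.9)
        assert fano_from_contributions(17.0, ModelRates(4.0, 0.0, 1.0)) == 1.0
        assert fano_from_contributions(10.0, ModelRates(5.0, 0.5, 1.0)) == pytest.approx(2.0)

    def test_divergent_regime_refused(self):
        with pytest.raises(RegimeError):
            peroxisome_mean(ModelRates(2.0, 1.0, 1.0))
        with pytest.raises(RegimeError):
            peroxisome_fano(ModelRates(2.0, 1.5, 1.0))
        with pytest.raises(RegimeError):
            peroxisome_mean(ModelRates(2.0, 0.5, 1.0, k_fusion=0.1))

    def test_contribution_form_needs_de_novo(self):
        with pytest.raises(ValueError):
            fano_from_contributions(3.0, ModelRates(0.0, 0.1, 1.0))

    @given(kd=st.floats(0.01, 100), kf=st.floats(0, 0.999), g=st.floats(0.1, 10))
    def test_three_moment_identities_are_mutually_consistent(self, kd, kf, g):
        """The contribution form of the Fano factor evaluated at the
        equilibrium mean equals the direct formula, to machine precision."""
        rates = ModelRates(kd, kf * g, g)
        mean = peroxisome_mean(rates)
        assert fano_from_contributions(mean, rates) == pytest.approx(
            peroxisome_fano(rates), rel=1e-12
        )

    def test_moments_match_recurrence(self):
        rates = ModelRates(5.0, 0.5, 1.0)
        s = distribution_stats(stationary_distribution(rates))
        assert s.mean == pytest.approx(peroxisome_mean(rates), rel=1e-10)
        assert s.fano == pytest.approx(peroxisome_fano(rates), rel=1e-10)

    def test_divergence_as_fission_approaches_decay(self):
        """Mean and Fano factor both grow without bound as k_fission
        approaches gamma from below."""
        kfs = [0.9, 0.99, 0.999, 0.9999]
        means = [peroxisome_mean(ModelRates(2.0, kf, 1.0)) for kf in kfs]
        fanos = [peroxisome_fano(ModelRates(2.0, kf, 1.0)) for kf in kfs]
        assert all(b > a for a, b in zip(means, means[1:]))
        assert all(b > a for a, b in zip(fanos, fanos[1:]))
        assert means[-1] > 1e4 and fanos[-1] > 1e3


class TestFanoMeanCurve:
    def test_shifted_poisson_curve_values(self):
        curve = fano_mean_curve(Family.SHIFTED_POISSON, [1.0])
        assert curve.means[0] == pytest.approx(2.0)
        assert curve.fanos[0] == pytest.approx(0.5)

    def test_truncated_poisson_fano_approaches_one_from_below(self):
        lams = np.geomspace(0.1, 30, 40)
        curve = fano_mean_curve(Family.TRUNCATED_POISSON, lams)
        assert np.all(curve.fanos < 1)
        # the 1 - fano gap shrinks like lam * exp(-lam)
        gap = 1 - curve.fanos[-1]
        assert gap == pytest.approx(lams[-1] * math.exp(-lams[-1]) / (1 - math.exp(-lams[-1])), rel=1e-6)

    def test_truncated_above_shifted_at_equal_mean(self):
        """Over means 1.5-5, the zero-truncated Poisson Fano factor exceeds
        the shifted Poisson's at the same mean (the truncated curve climbs
        to 1 much faster)."""
        for target_mean in np.linspace(1.5, 5.0, 8):
            # invert each family's mean(lam) numerically
            from scipy.optimize import brentq

            lam_t = brentq(
                lambda l: l / (1 - math.exp(-l)) - target_mean, 1e-6, 50.0
            )
            fano_t = family_moments(ClosedFormSpec(Family.TRUNCATED_POISSON, lam=lam_t))[2]
            fano_s = family_moments(
                ClosedFormSpec(Family.SHIFTED_POISSON, lam=target_mean - 1)
            )[2]
            assert fano_t > fano_s

    def test_means_strictly_increasing(self):
        curve = fano_mean_curve(Family.NEGATIVE_BINOMIAL, np.linspace(0.05, 0.9, 20), r=2.0)
        assert np.all(np.diff(curve.means) > 0)

    def test_empty_sweep_rejected(self):
        with pytest.raises(ValueError):
            fano_mean_curve(Family.POISSON, [])

    def test_tsv_output(self, tmp_path):
        curve = fano_mean_curve(Family.TRUNCATED_POISSON, [0.5, 1.0, 2.0])
        path = tmp_path / "curve.tsv"
        curve.to_tsv(path)
        body = path.read_text()
        assert "# family: TRUNCATED_POISSON" in body
        assert len([l for l in body.splitlines() if not l.startswith("#")]) == 4
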