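import numpy as np
import pytest
from scipy.stats import norm

from wmroc import (DesignCell, ModelSpec, ParameterVector, ParamLayout,
                   count_parameters, enumerate_model_space, matched_counterpart,
                   matched_pairs, powerlaw_dprime, predict_aon, predict_raon,
                   predict_sdt_lr, predict_sdt_strength)
from wmroc.data import ValidationError
from wmroc.models import EPS

from conftest import make_design

CELL4 = DesignCell(4, 0, 0.5, 30, 30)
CELL5 = DesignCell(5, 0, 0.5, 30, 30)


class TestPointPredictions:
    @pytest.mark.parametrize(
        "pv,cell,expected",
        [
            (ParameterVector(K=2, a=0.8, g=0.5), CELL4, (0.70, 0.30)),
            (ParameterVector(K=0, a=1.0, g=0.35), CELL4, (0.35, 0.35)),
        ],
    )
    def test_raon(self, pv, cell, expected):
        assert predict_raon(pv, cell) == pytest.approx(expected, abs=1e-9)

    def test_raon_full_storage_clamps(self):
        ph, pf = predict_raon(ParameterVector(K=4, a=1.0, g=0.5), CELL4)
        assert ph == pytest.approx(1.0, abs=2 * EPS)
        assert pf == pytest.approx(0.0, abs=2 * EPS)

    @pytest.mark.parametrize(
        "pv,cell,expected",
        [
            (ParameterVector(K=3, g=0.4), CELL5, (0.76, 0.16)),
            (ParameterVector(K=0, g=0.4), CELL5, (0.4, 0.4)),
        ],
    )
    def test_aon(self, pv, cell, expected):
        assert predict_aon(pv, cell) == pytest.approx(expected, abs=1e-9)

    def test_sdt_lr_values(self):
        ph, pf = predict_sdt_lr(ParameterVector(dprime=2, beta=1), CELL4)
        assert ph == pytest.approx(norm.cdf(1.0), abs=1e-9)
        assert pf == pytest.approx(norm.cdf(-1.0), abs=1e-9)
        ph, pf = predict_sdt_lr(ParameterVector(dprime=2, beta=np.exp(2.0)), CELL4)
        assert ph == pytest.approx(0.5, abs=1e-9)
        assert pf == pytest.approx(norm.cdf(-2.0), abs=1e-9)

    def test_sdt_lr_neutral_criterion_symmetry(self):
        for d in (0.5, 1.7, 3.2):
            ph, pf = predict_sdt_lr(ParameterVector(dprime=d, beta=1.0), CELL4)
            assert pf == pytest.approx(1.0 - ph, abs=1e-12)

    def test_sdt_lr_undefined_at_zero_dprime(self):
        with pytest.raises(ValidationError):
            predict_sdt_lr(ParameterVector(dprime=0.0, beta=1.0), CELL4)

    def test_sdt_strength(self):
        ph, pf = predict_sdt_strength(ParameterVector(dprime=2, c=1.0), CELL4)
        assert (ph, pf) == pytest.approx((norm.cdf(1.0), norm.cdf(-1.0)), abs=1e-9)
        ph, pf = predict_sdt_strength(ParameterVector(dprime=0.0, c=0.3), CELL4)
        assert ph == pf
        _, pf = predict_sdt_strength(ParameterVector(dprime=1.2, c=0.0), CELL4)
        assert pf == pytest.approx(0.5, abs=1e-12)

    def test_powerlaw(self):
        assert powerlaw_dprime(3, 0.5, 4) == pytest.approx(1.5)
        assert powerlaw_dprime(2.2, 0.0, 7) == pytest.approx(2.2)
        assert powerlaw_dprime(2.2, 1.3, 1) == pytest.approx(2.2)
        with pytest.raises(ValidationError):
            powerlaw_dprime(3, 0.5, 0)

    def test_out_of_bounds_parameters_error(self):
        with pytest.raises(ValidationError):
            predict_raon(ParameterVector(K=-1, a=0.5, g=0.5), CELL4)
        with pytest.raises(ValidationError):
            predict_raon(ParameterVector(K=1, a=1.5, g=0.5), CELL4)
        with pytest.raises(ValidationError):
            predict_sdt_lr(ParameterVector(dprime=1, beta=-2.0), CELL4)


class TestModelInvariants:
    def test_all_or_none_roc_is_linear_in_g(self):
        """hit - fa = a*min(K/N,1) for every guessing rate: a slope-1 ROC."""
        for a, K in [(1.0, 3.0), (0.8, 2.0), (0.9, 6.0)]:
            m = min(K / 5, 1.0)
            for g in np.linspace(0.02, 0.98, 25):
                ph, pf = predict_raon(ParameterVector(K=K, a=a, g=g), CELL5)
                assert ph - pf == pytest.approx(a * m, abs=1e-9)

    def test_equal_variance_zroc_identity(self):
        """Phi^-1(hit) - Phi^-1(fa) = d' for any criterion, either rule."""
        d = 1.4
        for lnb in np.linspace(-3, 3, 13):
            ph, pf = predict_sdt_lr(ParameterVector(dprime=d, beta=np.exp(lnb)), CELL4)
            assert norm.ppf(ph) - norm.ppf(pf) == pytest.approx(d, abs=1e-7)
        for c in np.linspace(-2, 3, 13):
            ph, pf = predict_sdt_strength(ParameterVector(dprime=d, c=c), CELL4)
            assert norm.ppf(ph) - norm.ppf(pf) == pytest.approx(d, abs=1e-7)

    def test_lr_strength_rule_equivalence(self):
        """c = d'/2 + ln(beta)/d' maps the two decision rules onto each other."""
        for d in (0.6, 1.8, 3.0):
            for lnb in np.linspace(-2.5, 2.5, 11):
                c = d / 2 + lnb / d
                lr = predict_sdt_lr(ParameterVector(dprime=d, beta=np.exp(lnb)), CELL4)
                st = predict_sdt_strength(ParameterVector(dprime=d, c=c), CELL4)
                assert lr == pytest.approx(st, abs=1e-12)

    def test_monotonicity_in_criterion(self):
        lnbs = np.linspace(-2, 2, 15)
        hits = [predict_sdt_lr(ParameterVector(dprime=1.5, beta=np.exp(b)), CELL4)[0]
                for b in lnbs]
        fas = [predict_sdt_lr(ParameterVector(dprime=1.5, beta=np.exp(b)), CELL4)[1]
               for b in lnbs]
        assert np.all(np.diff(hits) < 0) and np.all(np.diff(fas) < 0)
        cs = np.linspace(-2, 2, 15)
        hits = [predict_sdt_strength(ParameterVector(dprime=1.5, c=c), CELL4)[0]
                for c in cs]
        assert np.all(np.diff(hits) < 0)
        gs = np.linspace(0.05, 0.95, 15)
        hits = [predict_raon(ParameterVector(K=2, a=0.9, g=g), CELL4)[0] for g in gs]
        fas = [predict_raon(ParameterVector(K=2, a=0.9, g=g), CELL4)[1] for g in gs]
        assert np.all(np.diff(hits) > 0) and np.all(np.diff(fas) > 0)


class TestModelSpace:
    def test_factorial_enumeration(self, design33):
        specs = enumerate_model_space(design33)
        assert len(specs) == 12
        assert len(set(specs)) == 12
        pairs = matched_pairs(design33)
        assert len(pairs) == 6
        for a, b in pairs:
            assert a.family == "all_or_none" and b.family == "sdt"
            assert count_parameters(a, design33) == count_parameters(b, design33)

    def test_single_set_size_collapses(self, design_single):
        specs = enumerate_model_space(design_single)
        assert len(specs) == 4
        assert all(s.memory_constraint == "fixed_across_load" for s in specs)
        assert len(matched_pairs(design_single)) == 2

    def test_too_few_base_rates(self):
        design = make_design(base_rates=(0.5,))
        with pytest.raises(ValidationError, match="base-rate"):
            enumerate_model_space(design)

    @pytest.mark.parametrize(
        "spec,expected",
        [
            (ModelSpec("sdt", "free_across_load", "shared_across_load"), 6),
            (ModelSpec("all_or_none", "principled", "shared_across_load"), 5),
            (ModelSpec("all_or_none", "free_across_load", "free_across_load"), 12),
        ],
    )
    def test_parameter_counts(self, design33, spec, expected):
        assert count_parameters(spec, design33) == expected

    def test_principled_pairing(self, design33):
        """Lapse all-or-none pairs with the power-law SDT at equal k."""
        raon = ModelSpec("all_or_none", "principled", "shared_across_load")
        partner = matched_counterpart(raon)
        assert partner.memory_constraint == "principled"
        assert count_parameters(raon, design33) == count_parameters(partner, design33)

    def test_spec_json_round_trip(self):
        spec = ModelSpec("sdt", "principled", "free_across_load", "strength")
        assert ModelSpec.from_json(spec.to_json()) == spec

    def test_labels(self):
        assert ModelSpec("all_or_none", "principled", "shared_across_load").label == "RAoN"
        assert ModelSpec("sdt", "free_across_load", "shared_across_load").label == "EVSDL"
        assert ModelSpec("sdt", "principled", "shared_across_load", "strength").label == "PEVSD"


class TestParamLayout:
    @pytest.mark.parametrize("family", ["all_or_none", "sdt"])
    @pytest.mark.parametrize("mem", ["fixed_across_load", "free_across_load", "principled"])
    @pytest.mark.parametrize("crit", ["shared_across_load", "free_across_load"])
    def test_gradient_matches_finite_differences(self, design33, family, mem, crit):
        spec = ModelSpec(family, mem, crit)
        layout = ParamLayout(spec, design33)
        rng = np.random.default_rng(11)
        lo, hi = layout.bounds[:, 0], layout.bounds[:, 1]
        theta = rng.uniform(np.maximum(lo, -2.5), np.minimum(hi, 3.5))
        ph, pf, dh, df = layout.predict(theta, grad=True)
        eps = 1e-6
        for i in range(layout.n_params):
            t2 = theta.copy()
            t2[i] += eps
            ph2, pf2 = layout.predict(t2)
            assert np.allclose((ph2 - ph) / eps, dh[:, i], atol=1e-4)
            assert np.allclose((pf2 - pf) / eps, df[:, i], atol=1e-4)

    def test_pack_unpack_round_trip(self, design33, evsdl_spec):
        layout = ParamLayout(evsdl_spec, design33)
        pv = ParameterVector(dprime=np.array([2.5, 1.5, 1.0]),
                             beta=np.array([2.0, 1.0, 0.5]))
        theta = layout.pack(pv)
        back = layout.unpack(theta)
        assert np.allclose(np.asarray(back.dprime), [2.5, 1.5, 1.0])
        assert np.allclose(np.asarray(back.beta), [2.0, 1.0, 0.5])
        assert np.allclose(layout.pack(back), theta)

    def test_layout_matches_cell_predictions(self, design33):
        """Vectorized layout predictions agree with the per-cell formulas."""
        spec = ModelSpec("all_or_none", "principled", "shared_across_load")
        layout = ParamLayout(spec, design33)
        pv = ParameterVector(K=2.4, a=0.85, g=np.array([0.3, 0.5, 0.7]))
        ph, pf = layout.predict(layout.pack(pv))
        for i, cell in enumerate(design33.cells):
            expected = predict_raon(pv, cell)
            assert (ph[i], pf[i]) == pytest.approx(expected, abs=1e-12)
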