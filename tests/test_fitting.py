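import numpy as np
import pytest
from sklearn.base import clone

from wmroc import (CellCounts, DesignCell, ModelSpec, ParameterVector,
                   ParamLayout, ParticipantData, ROCModel, fit_mle,
                   negative_log_likelihood, simulate_counts)
from wmroc.data import ValidationError

from conftest import make_design


def participant_from_counts(design, hits, fas, pid="p1"):
    return ParticipantData(
        pid,
        tuple(CellCounts(c, h, f) for c, h, f in zip(design.cells, hits, fas)),
    )


class TestNegativeLogLikelihood:
    def test_hand_value_single_cell(self):
        # one cell, h=7/10, f=3/10, predicted rates (0.7, 0.3):
        # NLL = -(14 ln 0.7 + 6 ln 0.3) = 12.2173
        from scipy.stats import norm
        from wmroc import Design
        design = Design((DesignCell(4, 0, 0.4, 10, 10), DesignCell(4, 1, 0.6, 10, 10)))
        spec = ModelSpec("sdt", "fixed_across_load", "free_across_load", "strength")
        # put the cell rates at exactly (0.7, 0.3) via the strength rule
        c = -norm.ppf(0.3)
        d = norm.ppf(0.7) + c
        pv = ParameterVector(dprime=d, c=np.array([[c, c]]))
        p = participant_from_counts(design, hits=[7, 7], fas=[3, 3])
        nll = negative_log_likelihood(spec, pv, p)
        assert nll == pytest.approx(2 * 12.2173, abs=1e-3)

    def test_chance_rates(self):
        # predicted 0.5 everywhere, h=5/10, f=5/10 -> -20 ln 0.5 per cell
        from wmroc import Design
        design = Design((DesignCell(4, 0, 0.4, 10, 10), DesignCell(4, 1, 0.6, 10, 10)))
        spec = ModelSpec("all_or_none", "fixed_across_load", "shared_across_load")
        pv = ParameterVector(K=0.0, g=np.array([0.5, 0.5]))
        p = participant_from_counts(design, hits=[5, 5], fas=[5, 5])
        got = negative_log_likelihood(spec, pv, p)
        assert got == pytest.approx(-40 * np.log(0.5), abs=1e-9)

    def test_clamping_keeps_nll_finite(self):
        design = make_design(set_sizes=(2,), base_rates=(0.4, 0.6), trials=10)
        spec = ModelSpec("all_or_none", "fixed_across_load", "shared_across_load")
        # K >= N predicts fa = 0; with observed false alarms the clamp keeps
        # the likelihood finite
        pv = ParameterVector(K=2.0, g=np.array([0.5, 0.5]))
        p = participant_from_counts(design, hits=[0, 0], fas=[4, 4])
        assert np.isfinite(negative_log_likelihood(spec, pv, p))


class TestFitMle:
    def test_deterministic_given_seed(self, design33, raon_spec):
        pv = ParameterVector(K=2.5, a=0.9, g=np.array([0.3, 0.5, 0.7]))
        data = simulate_counts(raon_spec, pv, design33, seed=4)
        fit1 = fit_mle(raon_spec, data, n_restarts=8, seed=42)
        fit2 = fit_mle(raon_spec, data, n_restarts=8, seed=42)
        assert fit1.nll == fit2.nll
        assert np.allclose(
            ParamLayout(raon_spec, design33).pack(fit1.params),
            ParamLayout(raon_spec, design33).pack(fit2.params),
        )

    def test_requires_two_base_rates(self):
        design = make_design(base_rates=(0.5,))
        spec = ModelSpec("all_or_none", "fixed_across_load", "shared_across_load")
        pv = ParameterVector(K=2.0, g=0.5)
        data = simulate_counts(spec, pv, design, seed=0)
        with pytest.raises(ValidationError):
            fit_mle(spec, data, n_restarts=2, seed=0)

    def test_on_curve_data_recovers_observed_rates(self):
        """When the observed rates lie (up to count rounding) on a model ROC,
        the MLE reproduces them and approaches the entropy lower bound."""
        design = make_design(set_sizes=(4,), base_rates=(0.4, 0.6), trials=50)
        spec = ModelSpec("sdt", "fixed_across_load", "free_across_load", "strength")
        pv = ParameterVector(dprime=1.5, c=np.array([[1.0, 0.2]]))
        layout = ParamLayout(spec, design)
        ph, pf = layout.predict(layout.pack(pv))
        hits = [int(round(p * c.n_change)) for p, c in zip(ph, design.cells)]
        fas = [int(round(p * c.n_nochange)) for p, c in zip(pf, design.cells)]
        data = participant_from_counts(design, hits, fas)
        fit = fit_mle(spec, data, n_restarts=10, seed=1)
        h = np.array(hits, float)
        f = np.array(fas, float)
        nc = np.array([c.n_change for c in design.cells], float)
        nn = np.array([c.n_nochange for c in design.cells], float)
        rh, rf = h / nc, f / nn

        def ent(p, n):  # binomial log-likelihood at the observed proportion
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(p > 0, p * np.log(p), 0) + np.where(
                    p < 1, (1 - p) * np.log(1 - p), 0
                )
            return -(n * t).sum()

        bound = ent(rh, nc) + ent(rf, nn)
        # count rounding moves the observed proportions slightly off the
        # generating curve, so allow a small gap above the bound
        assert bound - 1e-9 <= fit.nll <= bound + 0.25
        fh, ff = layout.predict(ParamLayout(spec, design).pack(fit.params))
        assert np.allclose(fh, rh, atol=0.03)
        assert np.allclose(ff, rf, atol=0.03)

    def test_fit_beats_generative_parameters(self, design33, evsdl_spec):
        pv = ParameterVector(
            dprime=np.array([2.5, 1.5, 1.0]), beta=np.array([2.0, 1.0, 0.5])
        )
        data = simulate_counts(evsdl_spec, pv, design33, seed=9)
        fit = fit_mle(evsdl_spec, data, n_restarts=10, seed=2)
        assert fit.nll <= negative_log_likelihood(evsdl_spec, pv, data) + 1e-6

    @pytest.mark.parametrize(
        "free,fixed",
        [
            (ModelSpec("all_or_none", "free_across_load", "shared_across_load"),
             ModelSpec("all_or_none", "fixed_across_load", "shared_across_load")),
            (ModelSpec("sdt", "free_across_load", "shared_across_load"),
             ModelSpec("sdt", "fixed_across_load", "shared_across_load")),
            (ModelSpec("sdt", "free_across_load", "free_across_load"),
             ModelSpec("sdt", "free_across_load", "shared_across_load")),
        ],
    )
    def test_nesting_never_hurts(self, design33, free, fixed):
        pv = ParameterVector(
            dprime=np.array([2.5, 1.5, 1.0]), beta=np.array([2.0, 1.0, 0.5])
        )
        gen = ModelSpec("sdt", "free_across_load", "shared_across_load")
        data = simulate_counts(gen, pv, design33, seed=13)
        f_free = fit_mle(free, data, n_restarts=12, seed=3)
        f_fixed = fit_mle(fixed, data, n_restarts=12, seed=3)
        assert f_free.nll <= f_fixed.nll + 1e-6

    def test_parameter_recovery_at_scale(self):
        """With 1e5 trials per cell the capacity estimate pins the truth."""
        design = make_design(trials=100_000)
        spec = ModelSpec("all_or_none", "fixed_across_load", "shared_across_load")
        pv = ParameterVector(K=3.0, g=np.array([0.3, 0.5, 0.7]))
        data = simulate_counts(spec, pv, design, seed=21)
        fit = fit_mle(spec, data, n_restarts=10, seed=5)
        assert float(np.asarray(fit.params.K)) == pytest.approx(3.0, abs=0.1)

    def test_grid_search_oracle(self):
        """MLE matches exhaustive grid search for a small all-or-none model.

        The NLL is separable across base-rate conditions given K, so the
        exhaustive minimum over the (K, g1, g2) grid at resolution 0.005 is
        computed exactly.
        """
        design = make_design(set_sizes=(4,), base_rates=(0.3, 0.7), trials=60)
        spec = ModelSpec("all_or_none", "fixed_across_load", "shared_across_load")
        data = participant_from_counts(design, hits=[11, 33], fas=[22, 11])
        fit = fit_mle(spec, data, n_restarts=10, seed=7)

        Ks = np.arange(0.0, 4.0 + 1e-12, 0.005)
        gs = np.arange(1e-4, 1 - 1e-4 + 1e-12, 0.005)
        m = np.minimum(Ks / 4.0, 1.0)[:, None]  # (K, 1)
        g = gs[None, :]
        eps = 1e-6
        total = np.zeros(len(Ks))
        for cc in data.cells:
            ph = np.clip(m + (1 - m) * g, eps, 1 - eps)
            pf = np.clip((1 - m) * g, eps, 1 - eps)
            h, f = cc.n_hits, cc.n_fas
            nc, nn = cc.cell.n_change, cc.cell.n_nochange
            nll = -(h * np.log(ph) + (nc - h) * np.log1p(-ph)
                    + f * np.log(pf) + (nn - f) * np.log1p(-pf))
            total += nll.min(axis=1)  # best g_j for this condition, per K
        grid_best = total.min()
        assert fit.nll <= grid_best + 1e-4


class TestROCModelEstimator:
    def test_sklearn_protocol(self, design33, raon_spec):
        est = ROCModel(spec=raon_spec, n_restarts=6, seed=1)
        assert est.get_params()["n_restarts"] == 6
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_exposes_attributes(self, design33, raon_spec):
        pv = ParameterVector(K=2.5, a=0.9, g=np.array([0.3, 0.5, 0.7]))
        data = simulate_counts(raon_spec, pv, design33, seed=6)
        est = ROCModel(spec=raon_spec, n_restarts=6, seed=1).fit(data)
        assert est.nll_ >= 0
        assert est.aic_ == pytest.approx(2 * est.n_parameters_ + 2 * est.nll_)
        ph, pf = est.predict(design33)
        assert ph.shape == (9,) and np.all((ph > 0) & (ph < 1))
        assert est.score(data) == pytest.approx(-est.nll_)
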