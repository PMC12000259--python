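"""Binomial maximum-likelihood fitting of ROC models.

Each design cell contributes two independent binomial observations — hits out
of change trials and false alarms out of no-change trials — so the negative
log likelihood is

    NLL = -sum_cells [ h ln p_hit + (n_c - h) ln(1 - p_hit)
                       + f ln p_fa + (n_n - f) ln(1 - p_fa) ]

with predicted rates clamped away from 0 and 1.  Binomial coefficients are
omitted: they are constant across models on the same data, so NLL, AIC, and
BIC *differences* are unaffected.  Estimation is bounded local minimization
(L-BFGS-B with analytic gradients) from several seeded random starting points
within the parameter bounds, keeping the best solution.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .data import Design, ParticipantData, ValidationError
from .models import ModelSpec, ParamLayout, ParameterVector, count_parameters

DEFAULT_RESTARTS = 20

# Random restarts are drawn uniformly from this region (intersected with the
# bounds) rather than the full bounded box: extreme criteria or d' push the
# predicted rates onto the clamp, where the likelihood is flat and a local
# optimizer cannot move.  The first start is data-informed (moment estimates
# from the observed rates); see _smart_start.
START_BOX = {
    "K": (0.1, None),  # upper end at max set size
    "a": (0.5, 1.0),
    "g": (0.05, 0.95),
    "dprime": (0.2, 5.0),
    "alpha": (0.0, 1.5),
    "lnbeta": (-3.0, 3.0),
    "c": (-2.0, 3.0),
}


class FitError(RuntimeError):
    """The optimizer failed on every restart."""


@dataclass(frozen=True)
class FitResult:
    """Best MLE solution for one participant and one model spec."""

    spec: ModelSpec
    params: ParameterVector
    nll: float
    k: int
    n_trials: int
    converged: bool
    n_restarts_used: int
    seed: int

    @property
    def aic(self) -> float:
        return 2.0 * self.k + 2.0 * self.nll

    @property
    def bic(self) -> float:
        return self.k * float(np.log(self.n_trials)) + 2.0 * self.nll

    def metric(self, name: str) -> float:
        name = name.lower()
        if name == "aic":
            return self.aic
        if name == "bic":
            return self.bic
        if name == "nll":
            return self.nll
        raise ValueError(f"unknown metric {name!r}")


def _counts_arrays(data: ParticipantData, design: Design):
    """Hit/FA counts aligned to the design cell order."""
    by_key = {cc.cell.key: cc for cc in data.cells}
    h, nc, f, nn = [], [], [], []
    for cell in design.cells:
        cc = by_key[cell.key]
        h.append(cc.n_hits)
        nc.append(cc.cell.n_change)
        f.append(cc.n_fas)
        nn.append(cc.cell.n_nochange)
    return (np.array(h, float), np.array(nc, float),
            np.array(f, float), np.array(nn, float))


def negative_log_likelihood(
    spec: ModelSpec, params: ParameterVector, data: ParticipantData
) -> float:
    """Binomial NLL of ``params`` under ``spec`` for one participant."""
    layout = ParamLayout(spec, data.design)
    theta = layout.pack(params)
    h, nc, f, nn = _counts_arrays(data, data.design)
    ph, pf = layout.predict(theta)
    return float(_nll_from_rates(ph, pf, h, nc, f, nn))


def _nll_from_rates(ph, pf, h, nc, f, nn):
    return -(
        h @ np.log(ph)
        + (nc - h) @ np.log1p(-ph)
        + f @ np.log(pf)
        + (nn - f) @ np.log1p(-pf)
    )


def _smart_start(layout: ParamLayout, h, nc, f, nn) -> np.ndarray:
    """Moment-based starting point from smoothed observed rates.

    Hit/FA proportions (with add-half smoothing) give per-cell estimates of
    the storage probability (all-or-none) or of d' and the criterion via the
    inverse-normal transform (SDT); these are averaged according to the
    spec's constraints and clipped strictly inside the bounds.
    """
    from scipy.special import ndtri

    design = layout.design
    spec = layout.spec
    S = design.set_sizes
    J = design.base_rate_indices
    s_pos = {s: i for i, s in enumerate(S)}
    j_pos = {j: i for i, j in enumerate(J)}
    ph = np.full((len(S), len(J)), 0.5)
    pf = np.full((len(S), len(J)), 0.3)
    for cell_idx, cell in enumerate(design.cells):
        si, ji = s_pos[cell.set_size], j_pos[cell.base_rate_index]
        ph[si, ji] = (h[cell_idx] + 0.5) / (nc[cell_idx] + 1.0)
        pf[si, ji] = (f[cell_idx] + 0.5) / (nn[cell_idx] + 1.0)
    N = np.asarray(S, dtype=float)

    theta = np.empty(layout.n_params)
    if spec.family == "all_or_none":
        m = np.clip((ph - pf).mean(axis=1), 0.02, 0.95)  # per set size
        K_s = m * N
        if spec.memory_constraint == "free_across_load":
            theta[: layout.n_memory] = K_s
        elif spec.memory_constraint == "principled":
            theta[0] = float(np.mean(K_s)) / 0.95
            theta[1] = 0.95
        else:
            theta[0] = float(np.mean(K_s))
        g_sj = np.clip(pf / np.clip(1.0 - m[:, None], 0.05, 1.0), 0.02, 0.98)
        crit = g_sj
    else:
        z_h = ndtri(np.clip(ph, 0.01, 0.99))
        z_f = ndtri(np.clip(pf, 0.01, 0.99))
        d_sj = np.clip(z_h - z_f, 0.1, 8.0)
        d_s = d_sj.mean(axis=1)
        if spec.memory_constraint == "free_across_load":
            theta[: layout.n_memory] = d_s
        elif spec.memory_constraint == "principled":
            # least-squares power-law profile: ln d = ln d0 - alpha ln N
            lnN = np.log(N)
            alpha = 0.5
            if len(S) > 1:
                alpha = -float(np.polyfit(lnN, np.log(d_s), 1)[0])
            alpha = float(np.clip(alpha, 0.0, 2.9))
            d0 = float(np.exp(np.mean(np.log(d_s) + alpha * lnN)))
            theta[0], theta[1] = d0, alpha
        else:
            theta[0] = float(np.mean(d_s))
        if spec.decision_rule == "likelihood_ratio":
            crit = d_sj * (d_sj / 2.0 - z_h)  # ln(beta) from the hit equation
        else:
            crit = -z_f
    crit = np.asarray(crit, dtype=float)
    if crit.ndim == 1:  # strength rule gives one c per (s, j) too
        crit = np.broadcast_to(crit, (len(S), len(J)))
    if spec.criterion_constraint == "shared_across_load":
        theta[layout.n_memory:] = crit.mean(axis=0)
    else:
        theta[layout.n_memory:] = crit.ravel()
    lo, hi = layout.bounds[:, 0], layout.bounds[:, 1]
    span = hi - lo
    return np.clip(theta, lo + 1e-3 * span, hi - 1e-3 * span)


def spec_seed_offset(spec: ModelSpec) -> int:
    """A stable 32-bit hash of the spec contents, for seed derivation."""
    return zlib.crc32(spec.to_json().encode())


def fit_mle(
    spec: ModelSpec,
    data: ParticipantData,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood fit with multiple seeded random restarts.

    Deterministic given ``(spec, data, n_restarts, seed)``.  Positive scale
    parameters (d') are optimized on the log scale for numerical stability.
    """
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    design = data.design
    if len(design.base_rate_indices) < 2:
        raise ValidationError("fitting requires >= 2 base-rate conditions")
    layout = ParamLayout(spec, design)
    h, nc, f, nn = _counts_arrays(data, design)

    lo = layout.bounds[:, 0].copy()
    hi = layout.bounds[:, 1].copy()
    logs = layout.log_scale
    lo_t, hi_t = lo.copy(), hi.copy()
    lo_t[logs] = np.log(lo[logs])
    hi_t[logs] = np.log(hi[logs])

    def objective(theta_t: np.ndarray):
        theta = np.where(logs, np.exp(theta_t), theta_t)
        ph, pf, d_hit, d_fa = layout.predict(theta, grad=True)
        nll = _nll_from_rates(ph, pf, h, nc, f, nn)
        w_h = -(h / ph - (nc - h) / (1.0 - ph))
        w_f = -(f / pf - (nn - f) / (1.0 - pf))
        grad = w_h @ d_hit + w_f @ d_fa
        grad = np.where(logs, grad * theta, grad)  # chain rule for log scale
        return nll, grad

    # random starts come from a central start box (natural scale), the first
    # start from moment estimates of the observed rates
    box_lo, box_hi = lo.copy(), hi.copy()
    for i, name in enumerate(layout.names):
        kind = name.split("[")[0]
        b_lo, b_hi = START_BOX[kind]
        if b_hi is None:
            b_hi = hi[i]
        box_lo[i] = max(lo[i], b_lo)
        box_hi[i] = min(hi[i], b_hi)

    def to_t(theta):
        out = theta.copy()
        out[logs] = np.log(theta[logs])
        return out

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**32]))
    starts = [to_t(_smart_start(layout, h, nc, f, nn))]
    starts += [to_t(rng.uniform(box_lo, box_hi)) for _ in range(n_restarts - 1)]
    best = None
    any_success = False
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=list(zip(lo_t, hi_t)),
            options={"maxiter": 500},
        )
        if np.isfinite(res.fun):
            any_success = any_success or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise FitError(
            f"optimizer failed on all {n_restarts} restarts for {spec.label}"
        )
    theta = np.where(logs, np.exp(best.x), best.x)
    return FitResult(
        spec=spec,
        params=layout.unpack(theta),
        nll=float(best.fun),
        k=count_parameters(spec, design),
        n_trials=design.n_trials,
        converged=any_success,
        n_restarts_used=n_restarts,
        seed=int(seed),
    )


class ROCModel(BaseEstimator):
    """Estimator-style wrapper around :func:`fit_mle`.

    Parameters
    ----------
    spec : ModelSpec
        The model variant to fit.
    n_restarts : int
        Random restarts for the bounded local optimizer.
    seed : int
        Seed for the restart generator; fits are deterministic given it.

    After ``fit(data)`` the instance exposes ``params_``, ``nll_``, ``aic_``,
    ``bic_``, ``n_parameters_``, and the raw ``result_``.
    """

    def __init__(self, spec: ModelSpec | None = None,
                 n_restarts: int = DEFAULT_RESTARTS, seed: int = 0):
        self.spec = spec
        self.n_restarts = n_restarts
        self.seed = seed

    def fit(self, data: ParticipantData, y=None) -> "ROCModel":
        if self.spec is None:
            raise ValidationError("ROCModel requires a spec")
        self.result_ = fit_mle(self.spec, data, self.n_restarts, self.seed)
        self._design_ = data.design
        self.params_ = self.result_.params
        self.nll_ = self.result_.nll
        self.aic_ = self.result_.aic
        self.bic_ = self.result_.bic
        self.n_parameters_ = self.result_.k
        return self

    def predict(self, design: Design | None = None):
        """Predicted (p_hit, p_fa) per cell of ``design`` at the fitted MLE."""
        if not hasattr(self, "result_"):
            raise ValidationError("ROCModel is not fitted")
        if design is None:
            design = self._design_
        layout = ParamLayout(self.spec, design)
        return layout.predict(layout.pack(self.params_))

    def fit_predict(self, data: ParticipantData):
        return self.fit(data).predict(data.design)

    def score(self, data: ParticipantData, y=None) -> float:
        """Log likelihood (higher is better), for sklearn model selection."""
        if not hasattr(self, "result_"):
            raise ValidationError("ROCModel is not fitted")
        return -negative_log_likelihood(self.spec, self.params_, data)
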