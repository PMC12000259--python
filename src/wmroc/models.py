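"""ROC model family for single-probe change detection.

Two families are implemented, each predicting hit and false-alarm
probabilities per design cell:

* **all_or_none** — discrete-slot storage: the probed item is in memory with
  probability ``min(K/N, 1)`` and otherwise the response is a guess ``g``.
  Predicts linear ROCs with unit slope.  The *principled* variant adds an
  attention-lapse probability ``a`` (with probability ``1-a`` the display is
  not encoded at all and responses are pure guesses).
* **sdt** — equal-variance Gaussian signal detection: memory strength on
  change trials is N(d', 1) and on no-change trials N(0, 1).  Predicts
  curvilinear ROCs.  Under the likelihood-ratio rule with criterion beta,
  hit = Phi(d'/2 - ln(beta)/d') and fa = Phi(-d'/2 - ln(beta)/d'); under the
  strength rule with criterion c, hit = Phi(d' - c) and fa = Phi(-c).  The
  *principled* variant constrains d' across memory load via a power law,
  d'(N) = d0 * N**(-alpha).

Memory parameters can be fixed across load, free per set size, or follow the
principled constraint; criteria (g, beta, or c) are indexed by base-rate
condition, either shared across load or free per (set size x base rate) cell.
The factorial cross of these auxiliary assumptions gives six variants per
family, paired across families so that matched variants have identical
parameter counts and can be compared on raw likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
from scipy.special import ndtr  # standard normal CDF, vectorized

from .data import Design, DesignCell, ValidationError

EPS = 1e-6  # predicted rates are clamped to [EPS, 1-EPS] before any log

FAMILIES = ("all_or_none", "sdt")
MEMORY_CONSTRAINTS = ("fixed_across_load", "free_across_load", "principled")
CRITERION_CONSTRAINTS = ("shared_across_load", "free_across_load")
DECISION_RULES = ("likelihood_ratio", "strength")

# optimizer bounds per parameter kind: (lo, hi, optimize_on_log_scale)
BOUNDS = {
    "K": (0.0, None, False),        # hi filled with max set size at layout build
    "a": (0.0, 1.0, False),
    "g": (1e-4, 1.0 - 1e-4, False),
    "dprime": (1e-3, 10.0, True),
    "alpha": (0.0, 3.0, False),
    "lnbeta": (-10.0, 10.0, False),
    "c": (-10.0, 10.0, False),
}


@dataclass(frozen=True)
class ModelSpec:
    """One point in the factorial model space."""

    family: str
    memory_constraint: str
    criterion_constraint: str
    decision_rule: str | None = "likelihood_ratio"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")
        if self.memory_constraint not in MEMORY_CONSTRAINTS:
            raise ValidationError(f"unknown memory_constraint {self.memory_constraint!r}")
        if self.criterion_constraint not in CRITERION_CONSTRAINTS:
            raise ValidationError(
                f"unknown criterion_constraint {self.criterion_constraint!r}"
            )
        if self.family == "sdt":
            if self.decision_rule not in DECISION_RULES:
                raise ValidationError(f"unknown decision_rule {self.decision_rule!r}")
        else:
            # decision rule is meaningless for all-or-none; canonicalize
            object.__setattr__(self, "decision_rule", None)

    @property
    def label(self) -> str:
        if self.family == "all_or_none":
            base = {
                "fixed_across_load": "AoN-K0",
                "free_across_load": "AoN",
                "principled": "RAoN",
            }[self.memory_constraint]
        else:
            base = "EVSD" + ("L" if self.decision_rule == "likelihood_ratio" else "")
            if self.memory_constraint == "principled":
                base = "P" + base
            elif self.memory_constraint == "fixed_across_load":
                base = base + "-d0"
        if self.criterion_constraint == "free_across_load":
            base += "-cfree"
        return base

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.family,
                "memory_constraint": self.memory_constraint,
                "criterion_constraint": self.criterion_constraint,
                "decision_rule": self.decision_rule,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class ParameterVector:
    """Named parameters for one model instance.

    ``g``, ``beta``, and ``c`` may be scalars, 1-D arrays indexed by base-rate
    condition, or 2-D arrays indexed (set size, base-rate condition); ``K``
    and ``dprime`` may be scalars or 1-D arrays indexed by set size.  Exactly
    one of ``beta`` / ``c`` is populated for an SDT model, matching its
    decision rule.
    """

    K: float | np.ndarray | None = None
    a: float | None = None
    g: float | np.ndarray | None = None
    dprime: float | np.ndarray | None = None
    alpha: float | None = None
    beta: float | np.ndarray | None = None
    c: float | np.ndarray | None = None


def _crit(value, cell: DesignCell, name: str):
    """Resolve a criterion parameter for a single cell (scalar or 1-D by j)."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return float(arr)
    if arr.ndim == 1:
        return float(arr[cell.base_rate_index])
    raise ValidationError(
        f"{name}: 2-D criterion arrays need the full design; use a ParamLayout"
    )


def _clamp(p: float) -> float:
    return min(max(p, EPS), 1.0 - EPS)


def predict_raon(params: ParameterVector, cell: DesignCell) -> tuple[float, float]:
    """Attention-lapse all-or-none rates for one cell.

    hit = a*(m + (1-m)*g) + (1-a)*g and fa = a*(1-m)*g + (1-a)*g with
    m = min(K/N, 1): with probability ``a`` the display is attended and the
    probe is stored with probability ``m``; otherwise responses are guesses.
    """
    K = float(np.asarray(params.K))
    a = float(params.a)
    g = _crit(params.g, cell, "g")
    if K < 0 or not 0.0 <= a <= 1.0 or not 0.0 < g < 1.0:
        raise ValidationError("parameter out of bounds for all-or-none model")
    m = min(K / cell.set_size, 1.0)
    p_hit = a * (m + (1.0 - m) * g) + (1.0 - a) * g
    p_fa = a * (1.0 - m) * g + (1.0 - a) * g
    return _clamp(p_hit), _clamp(p_fa)


def predict_aon(params: ParameterVector, cell: DesignCell) -> tuple[float, float]:
    """Standard all-or-none rates: hit = m + (1-m)*g, fa = (1-m)*g."""
    K = params.K
    if np.ndim(K) == 1:
        raise ValidationError("per-set-size K needs the full design; use a ParamLayout")
    pv = ParameterVector(K=float(np.asarray(K)), a=1.0, g=params.g)
    return predict_raon(pv, cell)


def predict_sdt_lr(params: ParameterVector, cell: DesignCell) -> tuple[float, float]:
    """Equal-variance SDT with the likelihood-ratio rule.

    hit = Phi(d'/2 - ln(beta)/d'), fa = Phi(-d'/2 - ln(beta)/d').  The rule is
    undefined at d' = 0 (the likelihood ratio is flat), which is an error.
    """
    d = float(np.asarray(params.dprime))
    beta = _crit(params.beta, cell, "beta")
    if d <= 0.0:
        raise ValidationError("likelihood-ratio rule undefined for dprime <= 0")
    if beta <= 0.0:
        raise ValidationError("beta must be > 0")
    lnb = np.log(beta)
    p_hit = float(ndtr(d / 2.0 - lnb / d))
    p_fa = float(ndtr(-d / 2.0 - lnb / d))
    return _clamp(p_hit), _clamp(p_fa)


def predict_sdt_strength(params: ParameterVector, cell: DesignCell) -> tuple[float, float]:
    """Equal-variance SDT with a criterion on the strength axis.

    hit = Phi(d' - c), fa = Phi(-c); d' = 0 is allowed (hit = fa).
    """
    d = float(np.asarray(params.dprime))
    c = _crit(params.c, cell, "c")
    if d < 0.0:
        raise ValidationError("dprime must be >= 0")
    p_hit = float(ndtr(d - c))
    p_fa = float(ndtr(-c))
    return _clamp(p_hit), _clamp(p_fa)


def powerlaw_dprime(dprime_base: float, alpha: float, set_size: int) -> float:
    """Power-law resource constraint: d'(N) = d0 * N**(-alpha)."""
    if set_size < 1:
        raise ValidationError(f"set_size must be >= 1, got {set_size}")
    if dprime_base <= 0 or alpha < 0:
        raise ValidationError("dprime_base must be > 0 and alpha >= 0")
    return float(dprime_base * set_size ** (-alpha))


def predict_cell(spec: ModelSpec, params: ParameterVector, cell: DesignCell):
    """Dispatch to the right per-cell prediction for ``spec``."""
    if spec.family == "all_or_none":
        if spec.memory_constraint == "principled":
            return predict_raon(params, cell)
        return predict_aon(params, cell)
    d = params.dprime
    if spec.memory_constraint == "principled":
        d = powerlaw_dprime(float(np.asarray(d)), float(params.alpha), cell.set_size)
    pv = ParameterVector(dprime=d, beta=params.beta, c=params.c)
    if spec.decision_rule == "likelihood_ratio":
        return predict_sdt_lr(pv, cell)
    return predict_sdt_strength(pv, cell)


# ---------------------------------------------------------------------------
# Parameter layout: flat vector <-> named parameters, vectorized prediction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamLayout:
    """Resolves a ModelSpec against a design grid.

    Defines the flat parameter ordering (memory parameters first, then
    criteria, set-size major), optimizer bounds, and the vectorized mapping
    from a flat parameter vector to per-cell (p_hit, p_fa) with analytic
    gradients.
    """

    spec: ModelSpec
    design: Design

    @cached_property
    def _grid(self):
        S = self.design.set_sizes
        J = self.design.base_rate_indices
        s_pos = {s: i for i, s in enumerate(S)}
        j_pos = {j: i for i, j in enumerate(J)}
        cells = self.design.cells
        s_idx = np.array([s_pos[c.set_size] for c in cells])
        j_idx = np.array([j_pos[c.base_rate_index] for c in cells])
        N = np.array([c.set_size for c in cells], dtype=float)
        return S, J, s_idx, j_idx, N

    @cached_property
    def names(self) -> tuple[str, ...]:
        S, J, *_ = self._grid
        spec = self.spec
        mem: list[str] = []
        if spec.family == "all_or_none":
            if spec.memory_constraint == "fixed_across_load":
                mem = ["K"]
            elif spec.memory_constraint == "free_across_load":
                mem = [f"K[{s}]" for s in S]
            else:
                mem = ["K", "a"]
        else:
            if spec.memory_constraint == "fixed_across_load":
                mem = ["dprime"]
            elif spec.memory_constraint == "free_across_load":
                mem = [f"dprime[{s}]" for s in S]
            else:
                mem = ["dprime", "alpha"]
        crit_kind = self.criterion_kind
        if spec.criterion_constraint == "shared_across_load":
            crit = [f"{crit_kind}[{j}]" for j in J]
        else:
            crit = [f"{crit_kind}[{s},{j}]" for s in S for j in J]
        return tuple(mem + crit)

    @property
    def criterion_kind(self) -> str:
        if self.spec.family == "all_or_none":
            return "g"
        return "lnbeta" if self.spec.decision_rule == "likelihood_ratio" else "c"

    @cached_property
    def n_memory(self) -> int:
        if self.spec.memory_constraint == "fixed_across_load":
            return 1
        if self.spec.memory_constraint == "principled":
            return 2
        return len(self.design.set_sizes)

    @property
    def n_params(self) -> int:
        return len(self.names)

    @cached_property
    def bounds(self) -> np.ndarray:
        """(n_params, 2) bounds on the natural scale."""
        out = np.empty((self.n_params, 2))
        for i, name in enumerate(self.names):
            kind = name.split("[")[0]
            lo, hi, _ = BOUNDS[kind]
            if kind == "K":
                hi = float(max(self.design.set_sizes))
            out[i] = (lo, hi)
        return out

    @cached_property
    def log_scale(self) -> np.ndarray:
        return np.array([BOUNDS[n.split("[")[0]][2] for n in self.names])

    @cached_property
    def _crit_cols(self) -> np.ndarray:
        S, J, s_idx, j_idx, _ = self._grid
        if self.spec.criterion_constraint == "shared_across_load":
            cols = j_idx
        else:
            cols = s_idx * len(J) + j_idx
        return self.n_memory + cols

    def predict(self, theta: np.ndarray, grad: bool = False):
        """Per-cell (p_hit, p_fa) and, optionally, their Jacobians.

        ``theta`` is on the natural scale in layout order.  Returns
        ``(p_hit, p_fa)`` or ``(p_hit, p_fa, d_hit, d_fa)`` where the
        Jacobians have shape (n_cells, n_params).  Rates are clamped to
        [EPS, 1-EPS] with zero gradient where clamped.
        """
        theta = np.asarray(theta, dtype=float)
        S, J, s_idx, j_idx, N = self._grid
        nm = self.n_memory
        n_cells = len(N)
        crit = theta[self._crit_cols]
        if grad:
            d_hit = np.zeros((n_cells, self.n_params))
            d_fa = np.zeros((n_cells, self.n_params))
        spec = self.spec

        if spec.family == "all_or_none":
            if spec.memory_constraint == "free_across_load":
                K_cell = theta[s_idx]
                mem_col = s_idx
                a = 1.0
            elif spec.memory_constraint == "principled":
                K_cell = np.full(n_cells, theta[0])
                mem_col = np.zeros(n_cells, dtype=int)
                a = theta[1]
            else:
                K_cell = np.full(n_cells, theta[0])
                mem_col = np.zeros(n_cells, dtype=int)
                a = 1.0
            m = np.minimum(K_cell / N, 1.0)
            g = crit
            ph = a * m * (1.0 - g) + g
            pf = g * (1.0 - a * m)
            if grad:
                rows = np.arange(n_cells)
                dm_dK = np.where(K_cell < N, 1.0 / N, 0.0)
                d_hit[rows, mem_col] = a * (1.0 - g) * dm_dK
                d_fa[rows, mem_col] = -a * g * dm_dK
                if spec.memory_constraint == "principled":
                    d_hit[rows, 1] = m * (1.0 - g)
                    d_fa[rows, 1] = -m * g
                d_hit[rows, self._crit_cols] = 1.0 - a * m
                d_fa[rows, self._crit_cols] = 1.0 - a * m
        else:
            if spec.memory_constraint == "free_across_load":
                d_cell = theta[s_idx]
            elif spec.memory_constraint == "principled":
                d0, alpha = theta[0], theta[1]
                d_cell = d0 * N ** (-alpha)
            else:
                d_cell = np.full(n_cells, theta[0])
            if spec.decision_rule == "likelihood_ratio":
                L = crit
                u = d_cell / 2.0 - L / d_cell
                v = -d_cell / 2.0 - L / d_cell
                ph = ndtr(u)
                pf = ndtr(v)
                if grad:
                    rows = np.arange(n_cells)
                    phi_u = _phi(u)
                    phi_v = _phi(v)
                    du_dd = 0.5 + L / d_cell**2
                    dv_dd = -0.5 + L / d_cell**2
                    dph_dd = phi_u * du_dd
                    dpf_dd = phi_v * dv_dd
                    self._scatter_mem_grad(d_hit, d_fa, dph_dd, dpf_dd, theta, N, s_idx)
                    d_hit[rows, self._crit_cols] = -phi_u / d_cell
                    d_fa[rows, self._crit_cols] = -phi_v / d_cell
            else:
                c = crit
                ph = ndtr(d_cell - c)
                pf = ndtr(-c)
                if grad:
                    rows = np.arange(n_cells)
                    phi_h = _phi(d_cell - c)
                    phi_f = _phi(c)
                    self._scatter_mem_grad(
                        d_hit, d_fa, phi_h, np.zeros(n_cells), theta, N, s_idx
                    )
                    d_hit[rows, self._crit_cols] = -phi_h
                    d_fa[rows, self._crit_cols] = -phi_f

        lo_h = ph < EPS
        hi_h = ph > 1.0 - EPS
        lo_f = pf < EPS
        hi_f = pf > 1.0 - EPS
        ph = np.clip(ph, EPS, 1.0 - EPS)
        pf = np.clip(pf, EPS, 1.0 - EPS)
        if grad:
            d_hit[lo_h | hi_h] = 0.0
            d_fa[lo_f | hi_f] = 0.0
            return ph, pf, d_hit, d_fa
        return ph, pf

    def _scatter_mem_grad(self, d_hit, d_fa, dph_dd, dpf_dd, theta, N, s_idx):
        spec = self.spec
        rows = np.arange(len(N))
        if spec.memory_constraint == "free_across_load":
            d_hit[rows, s_idx] = dph_dd
            d_fa[rows, s_idx] = dpf_dd
        elif spec.memory_constraint == "principled":
            d0, alpha = theta[0], theta[1]
            scale = N ** (-alpha)
            d_cell = d0 * scale
            d_hit[rows, 0] = dph_dd * scale
            d_fa[rows, 0] = dpf_dd * scale
            d_hit[rows, 1] = dph_dd * (-d_cell * np.log(N))
            d_fa[rows, 1] = dpf_dd * (-d_cell * np.log(N))
        else:
            d_hit[rows, 0] = dph_dd
            d_fa[rows, 0] = dpf_dd

    # -- pack / unpack ------------------------------------------------------

    def pack(self, params: ParameterVector) -> np.ndarray:
        """ParameterVector -> flat vector on the natural (layout) scale."""
        S, J, *_ = self._grid
        spec = self.spec
        mem: list[float] = []
        if spec.family == "all_or_none":
            if spec.memory_constraint == "free_across_load":
                K = np.broadcast_to(np.asarray(params.K, dtype=float), (len(S),))
                mem = list(K)
            elif spec.memory_constraint == "principled":
                mem = [float(np.asarray(params.K)), float(params.a)]
            else:
                mem = [float(np.asarray(params.K))]
            crit_src = params.g
        else:
            if spec.memory_constraint == "free_across_load":
                d = np.broadcast_to(np.asarray(params.dprime, dtype=float), (len(S),))
                mem = list(d)
            elif spec.memory_constraint == "principled":
                mem = [float(np.asarray(params.dprime)), float(params.alpha)]
            else:
                mem = [float(np.asarray(params.dprime))]
            if spec.decision_rule == "likelihood_ratio":
                crit_src = np.log(np.asarray(params.beta, dtype=float))
            else:
                crit_src = params.c
        crit_arr = np.asarray(crit_src, dtype=float)
        if spec.criterion_constraint == "shared_across_load":
            crit = np.broadcast_to(crit_arr, (len(J),)).ravel()
        else:
            crit = np.broadcast_to(crit_arr, (len(S), len(J))).ravel()
        theta = np.concatenate([np.asarray(mem, dtype=float), crit])
        if len(theta) != self.n_params:
            raise ValidationError(
                f"parameter vector has {len(theta)} entries, layout expects {self.n_params}"
            )
        return theta

    def unpack(self, theta: np.ndarray) -> ParameterVector:
        """Flat vector -> ParameterVector (beta on the natural beta scale)."""
        S, J, *_ = self._grid
        spec = self.spec
        theta = np.asarray(theta, dtype=float)
        nm = self.n_memory
        crit = theta[nm:]
        if spec.criterion_constraint == "free_across_load":
            crit = crit.reshape(len(S), len(J))
        kwargs: dict = {}
        if spec.family == "all_or_none":
            if spec.memory_constraint == "free_across_load":
                kwargs["K"] = theta[:nm].copy()
            elif spec.memory_constraint == "principled":
                kwargs["K"] = float(theta[0])
                kwargs["a"] = float(theta[1])
            else:
                kwargs["K"] = float(theta[0])
            kwargs["g"] = crit.copy()
        else:
            if spec.memory_constraint == "free_across_load":
                kwargs["dprime"] = theta[:nm].copy()
            elif spec.memory_constraint == "principled":
                kwargs["dprime"] = float(theta[0])
                kwargs["alpha"] = float(theta[1])
            else:
                kwargs["dprime"] = float(theta[0])
            if spec.decision_rule == "likelihood_ratio":
                kwargs["beta"] = np.exp(crit)
            else:
                kwargs["c"] = crit.copy()
        return ParameterVector(**kwargs)


def _phi(x):
    return np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Model-space enumeration and parameter counting
# ---------------------------------------------------------------------------


def count_parameters(spec: ModelSpec, design: Design) -> int:
    """Exact free-parameter count of ``spec`` resolved against ``design``."""
    S = len(design.set_sizes)
    J = len(design.base_rate_indices)
    mem = {"fixed_across_load": 1, "principled": 2, "free_across_load": S}[
        spec.memory_constraint
    ]
    crit = J if spec.criterion_constraint == "shared_across_load" else S * J
    return mem + crit


def enumerate_model_space(
    design: Design, decision_rule: str = "likelihood_ratio"
) -> list[ModelSpec]:
    """The factorial model space resolved against a design.

    Returns 12 specs (2 families x 3 memory constraints x 2 criterion
    constraints) for multi-set-size designs.  For a single set size the
    memory constraints are unidentifiable against each other and collapse to
    ``fixed_across_load``, leaving 4 distinct specs.
    """
    if len(design.base_rate_indices) < 2:
        raise ValidationError(
            "at least 2 base-rate conditions are required to trace an ROC"
        )
    single = len(design.set_sizes) == 1
    mems = ("fixed_across_load",) if single else MEMORY_CONSTRAINTS
    specs: list[ModelSpec] = []
    for family in FAMILIES:
        for mem in mems:
            for crit in CRITERION_CONSTRAINTS:
                specs.append(
                    ModelSpec(
                        family=family,
                        memory_constraint=mem,
                        criterion_constraint=crit,
                        decision_rule=decision_rule,
                    )
                )
    return specs


def matched_counterpart(spec: ModelSpec, decision_rule: str = "likelihood_ratio") -> ModelSpec:
    """The equal-parameter-count partner in the other family.

    fixed <-> fixed, free <-> free, and the two principled constraints
    (attention lapse <-> power law) map onto each other, with the criterion
    constraint preserved — so matched pairs always have identical parameter
    counts and can be compared on raw NLL.
    """
    other = "sdt" if spec.family == "all_or_none" else "all_or_none"
    return ModelSpec(
        family=other,
        memory_constraint=spec.memory_constraint,
        criterion_constraint=spec.criterion_constraint,
        decision_rule=decision_rule if other == "sdt" else None,
    )


def matched_pairs(
    design: Design, decision_rule: str = "likelihood_ratio"
) -> list[tuple[ModelSpec, ModelSpec]]:
    """All (all_or_none, sdt) matched pairs for ``design``."""
    specs = enumerate_model_space(design, decision_rule)
    return [
        (s, matched_counterpart(s, decision_rule))
        for s in specs
        if s.family == "all_or_none"
    ]
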