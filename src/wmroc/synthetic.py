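"""Synthetic change-detection cohorts emulating the classic study designs.

Presets reproduce the *structure* of the original experiments — number of
base-rate conditions, set sizes, participants, and trial counts — not their
unpublished numeric details.  The exact base-rate levels, set sizes, and
trials per cell are configurable placeholders (defaults: set sizes {2,5,8},
base rates {0.3,0.5,0.7} or {0.1,...,0.9}, 60 trials per cell).

Participant heterogeneity is modelled as independent truncated-normal draws
per parameter (truncated at the optimizer bounds), the simplest structure
that supports per-participant fitting and paired t tests across a cohort.
Counts are then binomially sampled from the chosen generative model, so every
generated dataset validates against the data-model invariants and closes the
loop for parameter- and model-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data import CellCounts, Dataset, Design, DesignCell, ParticipantData, ValidationError
from .models import ModelSpec, ParamLayout, ParameterVector
from .recovery import _child_seed, simulate_counts

PRESET_NAMES = ("rouder08", "donkin_e1", "donkin_e2", "donkin_e3", "custom")

_THREE_RATES = (0.3, 0.5, 0.7)
_FIVE_RATES = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class DesignPreset:
    """A named experimental design template."""

    name: str
    set_sizes: tuple[int, ...]
    base_rates: tuple[float, ...]
    trials_per_cell: int
    n_participants: int

    def __post_init__(self) -> None:
        if len(self.base_rates) < 2:
            raise ValidationError("a preset needs >= 2 base-rate conditions")
        if any(not 0.0 < r < 1.0 for r in self.base_rates):
            raise ValidationError("base rates must be in (0,1)")
        if self.trials_per_cell < 2 or self.n_participants < 1:
            raise ValidationError("trials_per_cell >= 2 and n_participants >= 1 required")

    @property
    def n_cells(self) -> int:
        return len(self.set_sizes) * len(self.base_rates)

    def to_design(self) -> Design:
        """Build the design grid; change trials = round(rate * trials)."""
        cells = []
        rates = sorted(self.base_rates)
        for s in self.set_sizes:
            for j, r in enumerate(rates):
                n_change = int(round(self.trials_per_cell * r))
                cells.append(
                    DesignCell(
                        set_size=s,
                        base_rate_index=j,
                        base_rate=r,
                        n_change=n_change,
                        n_nochange=self.trials_per_cell - n_change,
                    )
                )
        return Design(tuple(cells))


_PRESETS: dict[str, DesignPreset] = {
    # 3 base rates x 3 set sizes, 23 participants (original cohort size)
    "rouder08": DesignPreset("rouder08", (2, 5, 8), _THREE_RATES, 60, 23),
    # same grid, larger cohort (> 90 participants)
    "donkin_e1": DesignPreset("donkin_e1", (2, 5, 8), _THREE_RATES, 60, 91),
    # 5 base rates x 3 set sizes, > 2000 trials per participant, trial-powered
    "donkin_e2": DesignPreset("donkin_e2", (2, 5, 8), _FIVE_RATES, 140, 10),
    # 5 base rates at a single set size
    "donkin_e3": DesignPreset("donkin_e3", (5,), _FIVE_RATES, 300, 20),
}


def make_design_preset(name: str, **overrides) -> DesignPreset:
    """Look up a named preset, optionally overriding any field.

    ``custom`` requires explicit ``set_sizes``, ``base_rates``,
    ``trials_per_cell``, and ``n_participants``.
    """
    if name == "custom":
        try:
            return DesignPreset(name="custom", **overrides)
        except TypeError as exc:
            raise ValidationError(f"custom preset needs all fields: {exc}") from None
    if name not in _PRESETS:
        raise ValidationError(
            f"unknown preset {name!r}; choose one of {sorted(_PRESETS) + ['custom']}"
        )
    preset = _PRESETS[name]
    return replace(preset, **overrides) if overrides else preset


@dataclass(frozen=True)
class GroundTruth:
    """Population-level generative settings plus (optionally) sampled draws.

    ``population_means`` / ``population_sds`` are flat vectors on the model's
    natural parameter scale, aligned with ``ParamLayout(spec, design).names``
    (criteria for the likelihood-ratio rule are on the ln(beta) scale).
    """

    spec: ModelSpec
    population_means: tuple[float, ...]
    population_sds: tuple[float, ...]
    seed: int = 0
    participant_params: tuple[ParameterVector, ...] = ()

    def names(self, design: Design) -> tuple[str, ...]:
        return ParamLayout(self.spec, design).names


def _default_dprime_per_set_size(set_sizes: Sequence[int]) -> np.ndarray:
    if tuple(set_sizes) == (2, 5, 8):
        return np.array([2.5, 1.5, 1.0])
    # power-law profile through the canonical grid values
    return 3.95 * np.asarray(set_sizes, dtype=float) ** (-0.66)


def default_population(spec: ModelSpec, design: Design) -> tuple[np.ndarray, np.ndarray]:
    """Realistic population means and SDs for ``spec`` on ``design``.

    Capacity ~3 items (lapse rate 0.9 where applicable); d' falling from 2.5
    to 1.0 across set sizes; guessing rates tracking the base rates
    (probability matching); likelihood-ratio criteria at the base-rate-optimal
    beta = (1-r)/r.
    """
    layout = ParamLayout(spec, design)
    rates = sorted({c.base_rate_index: c.base_rate for c in design.cells}.items())
    rate_by_j = np.array([r for _, r in rates])
    S = design.set_sizes
    d_free = _default_dprime_per_set_size(S)
    means, sds = [], []
    for name in layout.names:
        kind = name.split("[")[0]
        if kind == "K":
            means.append(3.0), sds.append(0.5)
        elif kind == "a":
            means.append(0.9), sds.append(0.05)
        elif kind == "dprime":
            if "[" in name:
                s = int(name[name.index("[") + 1 : -1])
                means.append(float(d_free[S.index(s)]))
            elif spec.memory_constraint == "principled":
                means.append(3.5)
            else:
                means.append(2.0)
            sds.append(0.2)
        elif kind == "alpha":
            means.append(0.6), sds.append(0.1)
        elif kind in ("g", "lnbeta", "c"):
            inside = name[name.index("[") + 1 : -1]
            j = int(inside.split(",")[-1])
            r = rate_by_j[design.base_rate_indices.index(j)]
            if kind == "g":
                means.append(float(r)), sds.append(0.05)
            elif kind == "lnbeta":
                means.append(float(np.log((1.0 - r) / r))), sds.append(0.3)
            else:
                means.append(1.0 + float(np.log((1.0 - r) / r)) / 2.0), sds.append(0.2)
        else:  # pragma: no cover
            raise ValidationError(f"no default for parameter {name}")
    return np.array(means), np.array(sds)


def make_ground_truth(
    spec: ModelSpec,
    design: Design,
    means: Mapping[str, float] | Sequence[float] | None = None,
    sds: Mapping[str, float] | Sequence[float] | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Ground truth with default population settings, optionally overridden.

    ``means`` / ``sds`` may be full vectors in layout order or mappings from
    parameter kind (``"K"``, ``"a"``, ``"g"``, ``"dprime"``, ``"alpha"``,
    ``"lnbeta"``, ``"c"``) or exact entry name to values.
    """
    layout = ParamLayout(spec, design)
    m0, s0 = default_population(spec, design)

    def _apply(base: np.ndarray, user) -> np.ndarray:
        if user is None:
            return base
        if isinstance(user, Mapping):
            out = base.copy()
            for i, name in enumerate(layout.names):
                kind = name.split("[")[0]
                if name in user:
                    out[i] = user[name]
                elif kind in user:
                    val = np.asarray(user[kind], dtype=float)
                    if val.ndim == 0:
                        out[i] = float(val)
                    else:
                        # positional within this kind's block
                        pos = [n for n in layout.names if n.split("[")[0] == kind].index(name)
                        out[i] = float(val.ravel()[pos])
            return out
        arr = np.asarray(user, dtype=float)
        if arr.shape != base.shape:
            raise ValidationError(
                f"expected {base.shape[0]} population values, got {arr.shape}"
            )
        return arr

    return GroundTruth(
        spec=spec,
        population_means=tuple(_apply(m0, means)),
        population_sds=tuple(_apply(s0, sds)),
        seed=seed,
    )


def sample_participant_params(
    spec: ModelSpec,
    design: Design,
    means: Sequence[float],
    sds: Sequence[float],
    n: int,
    seed: int = 0,
) -> list[ParameterVector]:
    """Independent truncated-normal draws per parameter for ``n`` participants.

    Truncation is at the parameter bounds; an SD of zero yields the mean
    exactly.  Means must lie strictly within bounds.
    """
    layout = ParamLayout(spec, design)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if means.shape != (layout.n_params,) or sds.shape != (layout.n_params,):
        raise ValidationError("means/sds do not match the parameter layout")
    lo, hi = layout.bounds[:, 0], layout.bounds[:, 1]
    if np.any(means < lo) or np.any(means > hi):
        raise ValidationError("population mean outside parameter bounds")
    if np.any(sds < 0):
        raise ValidationError("population sds must be >= 0")
    rng = np.random.default_rng(seed)
    draws = np.empty((n, layout.n_params))
    for i in range(layout.n_params):
        if sds[i] == 0.0:
            draws[:, i] = means[i]
        else:
            a = (lo[i] - means[i]) / sds[i]
            b = (hi[i] - means[i]) / sds[i]
            draws[:, i] = stats.truncnorm.rvs(
                a, b, loc=means[i], scale=sds[i], size=n, random_state=rng
            )
    return [layout.unpack(draws[p]) for p in range(n)]


def generate_cohort(
    preset: DesignPreset, truth: GroundTruth, seed: int = 0
) -> tuple[Dataset, GroundTruth]:
    """Generate a full cohort: sample parameters, then binomial counts.

    Returns the dataset and a copy of ``truth`` carrying the per-participant
    true parameter vectors, for recovery scoring.
    """
    design = preset.to_design()
    params = sample_participant_params(
        truth.spec,
        design,
        truth.population_means,
        truth.population_sds,
        preset.n_participants,
        seed=_child_seed(seed, truth.seed, 1),
    )
    participants = []
    for p, pv in enumerate(params):
        sim = simulate_counts(
            truth.spec, pv, design, seed=_child_seed(seed, truth.seed, 2, p)
        )
        participants.append(
            ParticipantData(participant_id=f"p{p + 1:03d}", cells=sim.cells)
        )
    dataset = Dataset(tuple(participants), design)
    return dataset, replace(truth, participant_params=tuple(params), seed=seed)
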