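"""Domain types for change-detection count data, CSV I/O, and empirical ROCs.

The experimental unit is a *design cell*: one (set size, base-rate condition)
combination with a fixed number of change and no-change trials.  A
participant's data are the hit and false-alarm counts in every cell of the
design grid.  All likelihood computation downstream works on these aggregated
counts; trial-level tables are supported only through
:func:`aggregate_trial_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import pandas as pd

CSV_COLUMNS = [
    "participant",
    "set_size",
    "base_rate",
    "n_change",
    "n_nochange",
    "n_hits",
    "n_fas",
]


class FormatError(ValueError):
    """Malformed input file (missing columns, bad labels)."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


@dataclass(frozen=True, order=True)
class DesignCell:
    """One (set size, base-rate condition) cell of the experimental grid.

    ``base_rate`` is the probability that a trial in this cell is a change
    trial; ``base_rate_index`` is the 0-based label of the base-rate condition
    (criteria are indexed by this label, the numeric rate is metadata).
    """

    set_size: int
    base_rate_index: int
    base_rate: float
    n_change: int
    n_nochange: int

    def __post_init__(self) -> None:
        if self.set_size < 1:
            raise ValidationError(f"set_size must be >= 1, got {self.set_size}")
        if not 0.0 < self.base_rate < 1.0:
            raise ValidationError(f"base_rate must be in (0,1), got {self.base_rate}")
        if self.n_change < 0 or self.n_nochange < 0:
            raise ValidationError("trial counts must be nonnegative")
        if self.n_change == 0 and self.n_nochange == 0:
            raise ValidationError("cell must contain at least one trial")

    @property
    def key(self) -> tuple[int, int]:
        return (self.set_size, self.base_rate_index)

    @property
    def n_trials(self) -> int:
        return self.n_change + self.n_nochange


@dataclass(frozen=True)
class CellCounts:
    """Observed hits and false alarms for one design cell."""

    cell: DesignCell
    n_hits: int
    n_fas: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_hits <= self.cell.n_change:
            raise ValidationError(
                f"n_hits={self.n_hits} outside [0, n_change={self.cell.n_change}] "
                f"in cell {self.cell.key}"
            )
        if not 0 <= self.n_fas <= self.cell.n_nochange:
            raise ValidationError(
                f"n_fas={self.n_fas} outside [0, n_nochange={self.cell.n_nochange}] "
                f"in cell {self.cell.key}"
            )


@dataclass(frozen=True)
class Design:
    """The common grid of design cells shared by every participant."""

    cells: tuple[DesignCell, ...]

    def __post_init__(self) -> None:
        keys = [c.key for c in self.cells]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (set_size, base_rate_index) cells in design")
        if not self.cells:
            raise ValidationError("design must contain at least one cell")

    @cached_property
    def set_sizes(self) -> tuple[int, ...]:
        return tuple(sorted({c.set_size for c in self.cells}))

    @cached_property
    def base_rate_indices(self) -> tuple[int, ...]:
        return tuple(sorted({c.base_rate_index for c in self.cells}))

    @cached_property
    def grid_keys(self) -> frozenset[tuple[int, int]]:
        return frozenset(c.key for c in self.cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_trials(self) -> int:
        return sum(c.n_trials for c in self.cells)


@dataclass(frozen=True)
class ParticipantData:
    """All cell counts for a single participant."""

    participant_id: str
    cells: tuple[CellCounts, ...]

    def __post_init__(self) -> None:
        keys = [cc.cell.key for cc in self.cells]
        if len(set(keys)) != len(keys):
            raise ValidationError(
                f"participant {self.participant_id}: duplicate design cells"
            )

    @cached_property
    def design(self) -> Design:
        return Design(tuple(cc.cell for cc in self.cells))

    @property
    def n_trials(self) -> int:
        return self.design.n_trials


@dataclass(frozen=True)
class Dataset:
    """A cohort of participants sharing one design grid."""

    participants: tuple[ParticipantData, ...]
    design: Design

    def __post_init__(self) -> None:
        for p in self.participants:
            if p.design.grid_keys != self.design.grid_keys:
                raise ValidationError(
                    f"participant {p.participant_id} cells do not match the design grid"
                )

    @property
    def participant_ids(self) -> tuple[str, ...]:
        return tuple(p.participant_id for p in self.participants)

    def participant(self, participant_id: str) -> ParticipantData:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)


@dataclass(frozen=True)
class ROCPoint:
    set_size: int
    base_rate_index: int
    fa_rate: float
    hit_rate: float


def _dataset_from_frame(df: pd.DataFrame) -> Dataset:
    participants = []
    design: Design | None = None
    for pid, grp in df.groupby("participant", sort=False):
        # base_rate_index = rank of the numeric base rate, ascending
        rates = sorted(grp["base_rate"].unique())
        idx_of = {r: i for i, r in enumerate(rates)}
        cells = []
        for row in grp.itertuples(index=False):
            cell = DesignCell(
                set_size=int(row.set_size),
                base_rate_index=idx_of[row.base_rate],
                base_rate=float(row.base_rate),
                n_change=int(row.n_change),
                n_nochange=int(row.n_nochange),
            )
            cells.append(CellCounts(cell, n_hits=int(row.n_hits), n_fas=int(row.n_fas)))
        pdata = ParticipantData(str(pid), tuple(cells))
        if design is None:
            design = pdata.design
        participants.append(pdata)
    assert design is not None
    return Dataset(tuple(participants), design)


def read_counts_csv(path) -> Dataset:
    """Read an aggregated-counts CSV into a validated :class:`Dataset`.

    Expected header: ``participant,set_size,base_rate,n_change,n_nochange,
    n_hits,n_fas``.  Row order is preserved within participant.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns in {path}: {missing}")
    if df.empty:
        raise FormatError(f"no data rows in {path}")
    try:
        return _dataset_from_frame(df)
    except ValidationError:
        # re-run row by row to name the offending row
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                cell = DesignCell(
                    set_size=int(row.set_size),
                    base_rate_index=0,
                    base_rate=float(row.base_rate),
                    n_change=int(row.n_change),
                    n_nochange=int(row.n_nochange),
                )
                CellCounts(cell, n_hits=int(row.n_hits), n_fas=int(row.n_fas))
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from None
        raise


def to_frame(data: Dataset) -> pd.DataFrame:
    """Dataset as a long-format DataFrame with the canonical CSV columns."""
    rows = []
    for p in data.participants:
        for cc in p.cells:
            c = cc.cell
            rows.append(
                (p.participant_id, c.set_size, c.base_rate, c.n_change,
                 c.n_nochange, cc.n_hits, cc.n_fas)
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_counts_csv(data: Dataset, path) -> None:
    """Write ``data`` so that :func:`read_counts_csv` round-trips losslessly."""
    to_frame(data).to_csv(path, index=False)


def aggregate_trial_table(
    rows: Iterable[tuple[str, int, float, str, str]],
) -> Dataset:
    """Aggregate trial-level rows into cell counts.

    Each row is ``(participant, set_size, base_rate, trial_type, response)``
    with ``trial_type`` and ``response`` in ``{"change", "nochange"}``.  A hit
    is a "change" response on a change trial; a false alarm is a "change"
    response on a no-change trial.
    """
    rows = list(rows)
    if not rows:
        raise ValidationError("empty trial table")
    valid = {"change", "nochange"}
    tallies: dict[tuple[str, int, float], dict[str, int]] = {}
    order: list[tuple[str, int, float]] = []
    for i, (pid, set_size, base_rate, trial_type, response) in enumerate(rows):
        if trial_type not in valid:
            raise ValidationError(f"row {i}: invalid trial_type {trial_type!r}")
        if response not in valid:
            raise ValidationError(f"row {i}: invalid response {response!r}")
        key = (str(pid), int(set_size), float(base_rate))
        if key not in tallies:
            tallies[key] = {"n_change": 0, "n_nochange": 0, "n_hits": 0, "n_fas": 0}
            order.append(key)
        t = tallies[key]
        if trial_type == "change":
            t["n_change"] += 1
            if response == "change":
                t["n_hits"] += 1
        else:
            t["n_nochange"] += 1
            if response == "change":
                t["n_fas"] += 1
    frame = pd.DataFrame(
        [
            (pid, ss, br, t["n_change"], t["n_nochange"], t["n_hits"], t["n_fas"])
            for (pid, ss, br) in order
            for t in [tallies[(pid, ss, br)]]
        ],
        columns=CSV_COLUMNS,
    )
    return _dataset_from_frame(frame)


def empirical_roc(p: ParticipantData) -> list[ROCPoint]:
    """Raw-ratio ROC points, grouped by set size, ordered by base rate.

    No smoothing and no extreme-rate correction are applied: the rates are the
    exact count ratios.  Cells with a zero denominator are an error because
    they define no rate.
    """
    for cc in p.cells:
        if cc.cell.n_change == 0 or cc.cell.n_nochange == 0:
            raise ValidationError(
                f"cell {cc.cell.key}: zero trial count, no ROC point defined"
            )
    ordered = sorted(p.cells, key=lambda cc: (cc.cell.set_size, cc.cell.base_rate))
    return [
        ROCPoint(
            set_size=cc.cell.set_size,
            base_rate_index=cc.cell.base_rate_index,
            fa_rate=cc.n_fas / cc.cell.n_nochange,
            hit_rate=cc.n_hits / cc.cell.n_change,
        )
        for cc in ordered
    ]
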