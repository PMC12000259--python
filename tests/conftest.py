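import numpy as np
import pytest

from wmroc import (CellCounts, Dataset, Design, DesignCell, ModelSpec,
                   ParticipantData)


def make_design(set_sizes=(2, 5, 8), base_rates=(0.3, 0.5, 0.7), trials=60):
    cells = []
    for s in set_sizes:
        for j, r in enumerate(sorted(base_rates)):
            n_change = int(round(trials * r))
            cells.append(DesignCell(s, j, r, n_change, trials - n_change))
    return Design(tuple(cells))


def make_participant(design, rng, pid="p1", p_hit=0.7, p_fa=0.3):
    cells = tuple(
        CellCounts(c, int(rng.binomial(c.n_change, p_hit)),
                   int(rng.binomial(c.n_nochange, p_fa)))
        for c in design.cells
    )
    return ParticipantData(pid, cells)


@pytest.fixture
def design33():
    """3 set sizes x 3 base rates, 60 trials per cell."""
    return make_design()


@pytest.fixture
def design_single():
    """1 set size x 5 base rates."""
    return make_design(set_sizes=(5,), base_rates=(0.1, 0.3, 0.5, 0.7, 0.9))


@pytest.fixture
def small_dataset(design33):
    rng = np.random.default_rng(7)
    participants = tuple(
        make_participant(design33, rng, pid=f"p{i}") for i in range(3)
    )
    return Dataset(participants, design33)


@pytest.fixture
def raon_spec():
    return ModelSpec("all_or_none", "principled", "shared_across_load")


@pytest.fixture
def evsdl_spec():
    return ModelSpec("sdt", "free_across_load", "shared_across_load", "likelihood_ratio")
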