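import numpy as np
import pandas as pd
import pytest

from dropout3d import (
    Category,
    CountMatrix,
    GuideLibrary,
    GuideRecord,
    SampleInfo,
    ScreenDesign,
    SimConfig,
    simulate_library,
    simulate_screen,
)
from dropout3d.screen import CONTROL_GENE, Condition


def _spacer(i: int, length: int = 18) -> str:
    rng = np.random.default_rng(10_000 + i)
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))


@pytest.fixture
def toy_library() -> GuideLibrary:
    """Two genes x 3 guides plus 2 safe and 2 non-targeting controls."""
    records = []
    i = 0
    for gene in ("GENEA", "GENEB"):
        for _ in range(3):
            records.append(GuideRecord(f"{gene}_g{i}", gene, _spacer(i), Category.TARGETING))
            i += 1
    for k in range(2):
        records.append(GuideRecord(f"safe_{k}", CONTROL_GENE, _spacer(i), Category.SAFE))
        i += 1
    for k in range(2):
        records.append(
            GuideRecord(f"nt_{k}", CONTROL_GENE, _spacer(i), Category.NON_TARGETING)
        )
        i += 1
    return GuideLibrary(records)


@pytest.fixture
def toy_design() -> ScreenDesign:
    samples = [
        SampleInfo(f"{cond.value}_D{day}_R{rep}", cond, day, rep)
        for cond in (Condition.TWO_D, Condition.THREE_D)
        for day in (0, 7, 14)
        for rep in (1, 2)
    ]
    return ScreenDesign(samples)


@pytest.fixture
def toy_counts(toy_library, toy_design) -> CountMatrix:
    rng = np.random.default_rng(7)
    frame = pd.DataFrame(
        rng.integers(50, 500, size=(len(toy_library), len(toy_design))),
        index=toy_library.guide_ids,
        columns=toy_design.sample_ids,
    )
    return CountMatrix(frame, library=toy_library, design=toy_design)


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured simulated screen, shared across tests."""
    cfg = SimConfig(
        n_neutral=30,
        n_common_essential=6,
        n_2d_essential=6,
        n_3d_essential=6,
        n_safe=30,
        n_nontargeting=30,
        seed=11,
    )
    library, truth = simulate_library(cfg)
    counts, design = simulate_screen(library, truth, cfg)
    return cfg, library, truth, counts, design
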