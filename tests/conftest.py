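import numpy as np
import pandas as pd
import pytest

from sensikit.quant import CountMatrix, HairpinLibrary, SampleSheet
from sensikit.simulate import (
    PlantedSensitizer,
    ScreenSimConfig,
    simulate_screen,
)


@pytest.fixture(scope="session")
def tiny_library():
    return HairpinLibrary(
        pd.DataFrame(
            {
                "hairpin_id": ["94", "96", "159", "161", "201", "202"],
                "gene": ["ROCK1", "ROCK1", "ROCK1", "ROCK1", "AAK1", "AAK1"],
                "target_sequence": [
                    "ATTTACCTCTTGTTCTAACCG",
                    "TATGTCCAATACCATAGATGG",
                    "TACTTTGTGTTCATTTACCTC",
                    "ACGTACGTACGTACGTACGTA",
                    "TTTTACGTACGTACGTACGTA",
                    "GGGGACGTACGTACGTACGTA",
                ],
                "pool": ["pool1"] * 6,
            }
        )
    )


@pytest.fixture(scope="session")
def tiny_sheet():
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["ref_r1", "dmso_d7_r1", "plx_d7_r1"],
                "index": ["AAAAAA", "CCCCCC", "GGGGGG"],
                "condition": ["reference", "DMSO", "treated"],
                "treatment": ["none", "none", "PLX"],
                "day": [0, 7, 7],
                "replicate": [1, 1, 1],
            }
        )
    )


@pytest.fixture(scope="session")
def tiny_counts(tiny_library, tiny_sheet):
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.poisson(50, size=(len(tiny_library), len(tiny_sheet))),
        index=pd.Index(tiny_library.hairpin_ids, name="hairpin_id"),
        columns=tiny_sheet.sample_ids,
    )
    return CountMatrix(counts, tiny_sheet)


@pytest.fixture(scope="session")
def planted_screen():
    """Small screen with one dual-arm planted sensitizer gene."""
    cfg = ScreenSimConfig(
        n_genes=12,
        hairpins_per_gene=3,
        depth_mean=300,
        dispersion=0.05,
        n_replicates=3,
        planted_sensitizers=(PlantedSensitizer("HIT1", fc_day7=0.35, fc_day4=0.7),),
        seed=11,
    )
    lib, sheet, cm, truth = simulate_screen(cfg)
    return cfg, lib, sheet, cm, truth
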