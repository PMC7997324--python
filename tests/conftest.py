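"""Shared fixtures: small synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lcdbench.phantom_sim import (
    NoiseModel,
    generate_test_set,
    generate_training_set,
)


@pytest.fixture(scope="session")
def small_test_set():
    """A reduced factorial test set (2 per cell, full 16-cell grid)."""
    return generate_test_set(
        per_cell_present=2, per_cell_absent=2, model=NoiseModel(), seed=42
    )


@pytest.fixture(scope="session")
def small_training_set():
    return generate_training_set(n_images=40, model=NoiseModel(), seed=7)


def synthetic_manifest(
    n_cases: int,
    seed: int = 0,
    mas: float = 200.0,
    recon: str = "FBP",
    diameter_mm: float = 9.0,
) -> pd.DataFrame:
    """A manifest without rendered images, for reader/statistics tests."""
    rng = np.random.default_rng(seed)
    present = np.zeros(n_cases, dtype=bool)
    present[: n_cases // 2] = True
    rng.shuffle(present)
    return pd.DataFrame(
        {
            "case_id": [f"case-{i:05d}" for i in range(n_cases)],
            "split": "test",
            "present": present,
            "diameter_mm": diameter_mm,
            "contrast_hu": 10.0,
            "center_x_mm": 25.0,
            "center_y_mm": 25.0,
            "mas": mas,
            "recon": recon,
            "seed": np.arange(n_cases),
        }
    )
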