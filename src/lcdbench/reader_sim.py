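"""Simulated confidence-rating readers.

Each reader follows an equal-variance binormal decision model: on each
case a latent variable is drawn from N(0, 1), shifted by the reader's
detectability index d' for that case's condition cell when an object
is present, and converted to a 5-point confidence rating (1 definitely
absent ... 5 definitely present) through four increasing cutpoints.
The closed-form AUC of such a reader is Phi(d'/sqrt(2)), which makes
the multi-reader statistics testable against an analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "ReaderProfile",
    "make_profiles",
    "simulate_ratings",
    "binormal_auc",
    "DEFAULT_CUTPOINTS",
]

DEFAULT_CUTPOINTS = (-1.0, 0.0, 1.0, 2.0)

#: Descriptive presets mirroring the two experience strata of a typical
#: reader panel (experienced attendings vs trainees); the numbers are
#: generator defaults, not estimates of any particular panel.
EXPERIENCE_DPRIME = {"attending": 1.5, "trainee": 1.0}


def binormal_auc(dprime: float) -> float:
    """Equal-variance binormal AUC, Phi(d'/sqrt(2))."""
    from scipy.stats import norm

    return float(norm.cdf(dprime / np.sqrt(2.0)))


@dataclass(frozen=True)
class ReaderProfile:
    """Per-reader skill map and rating cutpoints.

    ``dprime_by_cell`` maps (mas, recon, diameter_mm) cells to d';
    cells not listed fall back to ``dprime_default``. Cutpoints must be
    strictly increasing.
    """

    reader_id: str
    dprime_default: float = 1.0
    dprime_by_cell: dict = field(default_factory=dict)
    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS

    def __post_init__(self) -> None:
        if self.dprime_default < 0 or any(v < 0 for v in self.dprime_by_cell.values()):
            raise InputError("d' must be >= 0")
        if not all(a < b for a, b in zip(self.cutpoints, self.cutpoints[1:])):
            raise InputError("cutpoints must be strictly increasing")

    def dprime_for(self, cell: tuple) -> float:
        return float(self.dprime_by_cell.get(cell, self.dprime_default))


def make_profiles(
    n_readers: int = 12,
    dprime: float | None = None,
    experience: str | None = None,
    jitter: float = 0.0,
    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS,
    seed: int = 0,
) -> list[ReaderProfile]:
    """Build a homogeneous panel, optionally with reader-to-reader d'
    jitter (uniform +/- ``jitter``) and an experience preset."""
    if dprime is None:
        dprime = EXPERIENCE_DPRIME.get(experience or "trainee", 1.0)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x5EAD)))
    profiles = []
    for i in range(n_readers):
        d = max(0.0, dprime + (rng.uniform(-jitter, jitter) if jitter else 0.0))
        profiles.append(
            ReaderProfile(
                reader_id=f"reader-{i + 1:02d}",
                dprime_default=d,
                cutpoints=cutpoints,
            )
        )
    return profiles


def simulate_ratings(
    profiles: list[ReaderProfile],
    manifest: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Complete reader x case crossing of 5-point ratings.

    rating = 1 + number of cutpoints below the latent value; the table
    has exactly one row per (reader, case).
    """
    if not profiles:
        raise InputError("profiles must be non-empty")
    present = manifest["present"].to_numpy().astype(bool)
    if present.all() or not present.any():
        raise InputError("manifest must contain both classes")
    cells = list(
        zip(
            manifest["mas"].to_numpy(dtype=float),
            manifest["recon"].to_numpy(),
            manifest["diameter_mm"].to_numpy(dtype=float),
        )
    )
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x12EAD)))
    frames = []
    case_ids = manifest["case_id"].to_numpy()
    for profile in profiles:
        shift = np.array([profile.dprime_for(c) for c in cells]) * present
        latent = rng.standard_normal(len(manifest)) + shift
        ratings = 1 + np.sum(
            latent[:, None] > np.asarray(profile.cutpoints)[None, :], axis=1
        )
        frames.append(
            pd.DataFrame(
                {
                    "reader_id": profile.reader_id,
                    "case_id": case_ids,
                    "rating": ratings.astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
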