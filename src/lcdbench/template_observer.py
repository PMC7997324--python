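"""Template-matching observer.

A disk template is slid over the patch; at every offset the
zero-normalized cross-correlation (ZNCC) between template and window
is computed, and the case score is the maximum correlation mapped from
[-1, 1] to [0, 1]. ZNCC makes the score invariant to the window's mean
(background level) and to positive rescaling, which is the natural
matched-filter reading of a low-contrast detection task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedROCError
from .phantom_sim import ImagePatch, ObjectSpec, PatchGeometry, render_object

__all__ = [
    "Template",
    "make_template",
    "template_match_score",
    "roc_ten_thresholds",
    "score_manifest",
    "RocCurve",
]


@dataclass(frozen=True)
class Template:
    pixels: np.ndarray
    diameter_mm: float
    contrast_hu: float
    spacing_mm: float


def make_template(
    diameter_mm: float, contrast_hu: float, spacing_mm: float
) -> Template:
    """Noise-free anti-aliased disk on a zero background.

    Rendered by the same disk kernel as the simulator, on the smallest
    square grid that contains the disk plus a one-pixel margin (a tiny
    diameter collapses to a single-pixel template, degenerate but
    valid).
    """
    if diameter_mm <= 0:
        raise InputError(f"diameter must be positive, got {diameter_mm}")
    side_px = int(np.ceil(diameter_mm / spacing_mm)) + 2
    base = ImagePatch(
        pixels=np.zeros((side_px, side_px)), spacing_mm=spacing_mm
    )
    center = side_px * spacing_mm / 2.0
    spec = ObjectSpec(
        present=True,
        diameter_mm=diameter_mm,
        contrast_hu=contrast_hu,
        center_mm=(center, center),
    )
    rendered = render_object(base, spec)
    return Template(
        pixels=rendered.pixels.astype(np.float64),
        diameter_mm=diameter_mm,
        contrast_hu=contrast_hu,
        spacing_mm=spacing_mm,
    )


def zncc_map(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """ZNCC at every valid offset (exhaustive sliding window).

    Zero-variance windows (and a zero-variance template) score 0: a
    flat region carries no evidence either way.
    """
    image = np.asarray(image, dtype=np.float64)
    t = np.asarray(template, dtype=np.float64)
    if t.shape[0] > image.shape[0] or t.shape[1] > image.shape[1]:
        raise InputError(
            f"template {t.shape} larger than image {image.shape}"
        )
    t0 = t - t.mean()
    tnorm = np.sqrt((t0**2).sum())
    n = t.size
    windows = np.lib.stride_tricks.sliding_window_view(image, t.shape)
    num = np.tensordot(windows, t0, axes=([2, 3], [0, 1]))
    s1 = windows.sum(axis=(2, 3))
    s2 = (windows**2).sum(axis=(2, 3))
    var = np.maximum(s2 - s1**2 / n, 0.0)
    denom = np.sqrt(var) * tnorm
    out = np.zeros_like(num)
    ok = denom > 1e-12 * max(tnorm, 1.0)
    np.divide(num, denom, out=out, where=ok)
    return np.clip(out, -1.0, 1.0)


def template_match_score(
    image: ImagePatch | np.ndarray, template: Template
) -> float:
    """Maximum ZNCC over all offsets, mapped to [0, 1] via (max+1)/2."""
    pixels = image.pixels if isinstance(image, ImagePatch) else image
    return float((zncc_map(pixels, template.pixels).max() + 1.0) / 2.0)


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_ten_thresholds(
    scores: np.ndarray, labels: np.ndarray, n_thresholds: int = 10
) -> RocCurve:
    """ROC from a fixed grid of thresholds spanning [0, 1].

    Thresholds are k/(n-1) for k = 0..n-1 (ten values by default,
    endpoints included); a case is called positive when its score is
    >= the threshold. AUC is the trapezoid over the operating points
    sorted by FPR, anchored at (0,0) and (1,1).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise UndefinedROCError("both classes required for an ROC")
    thresholds = np.linspace(0.0, 1.0, n_thresholds)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    tpr = np.array([(scores[labels] >= t).mean() for t in thresholds])
    fpr = np.array([(scores[~labels] >= t).mean() for t in thresholds])
    pts = sorted(set(zip(fpr, tpr)) | {(0.0, 0.0), (1.0, 1.0)})
    fx = np.array([p[0] for p in pts])
    fy = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(fy, fx))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def score_manifest(
    manifest: pd.DataFrame,
    images: np.ndarray,
    diameter_mode: str = "matched",
    fixed_diameter_mm: float | None = None,
    contrast_hu: float = 10.0,
    spacing_mm: float = PatchGeometry.spacing_mm,
) -> np.ndarray:
    """Score every manifest row.

    ``matched`` mode builds, per row, the template of that row's cell
    diameter (the matched-filter reading); ``fixed`` mode uses a single
    ``fixed_diameter_mm`` template for all rows.
    """
    if diameter_mode not in ("matched", "fixed"):
        raise InputError(f"unknown diameter_mode {diameter_mode!r}")
    if diameter_mode == "fixed" and fixed_diameter_mm is None:
        raise InputError("fixed mode requires fixed_diameter_mm")
    cache: dict[float, Template] = {}
    scores = np.empty(len(manifest), dtype=np.float64)
    diameters = manifest["diameter_mm"].to_numpy(dtype=float)
    for i in range(len(manifest)):
        d = fixed_diameter_mm if diameter_mode == "fixed" else diameters[i]
        if not np.isfinite(d):
            raise InputError(f"row {i} has no diameter for matched mode")
        if d not in cache:
            cache[d] = make_template(d, contrast_hu, spacing_mm)
        scores[i] = template_match_score(images[i], cache[d])
    return scores
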