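"""ROC/AUC statistics for the observer comparison.

Implements the statistical machinery of a multi-reader multi-case
(MRMC) detectability comparison:

* rank-based empirical AUC (ties credited 0.5), with the Hanley-McNeil
  closed-form standard error and normal 95% CIs;
* paired z-comparisons of two AUCs;
* MRMC pooling as the unweighted mean of per-reader empirical AUCs,
  with uncertainty from a case-level bootstrap (readers fixed, cases
  resampled with replacement);
* Benjamini-Hochberg step-up adjustment;
* a bootstrap test comparing the AUC *reduction* between two imaging
  conditions across two observer modalities (e.g. an algorithmic
  observer vs a pooled reader panel), 2000 replicates by default.

The MRMC variance here is deliberately a case bootstrap, not the
U-statistic variance decomposition of full MRMC software: pooling is
reader-averaged AUC, and readers are treated as fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import InputError, UndefinedROCError

__all__ = [
    "AUCResult",
    "ComparisonResult",
    "empirical_auc",
    "auc_from_labels",
    "hanley_mcneil_se",
    "compare_auc",
    "mrmc_auc",
    "bh_adjust",
    "bootstrap_auc_reduction",
]

# Fixed significance thresholds used alongside BH adjustment in reports.
ALPHA_PRIMARY = 0.00625
ALPHA_POSTHOC = 0.0125


@dataclass(frozen=True)
class AUCResult:
    auc: float
    n_pos: int
    n_neg: int
    se: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class ComparisonResult:
    estimate: float
    z: float
    p_raw: float
    ci95: tuple[float, float]
    p_adjusted: float | None = None


def _auc_rows(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Empirical AUC per row of a 2-D score array (vectorized ranks)."""
    labels = labels.astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    ranks = rankdata(scores, axis=-1)
    r_pos = ranks[..., labels].sum(axis=-1)
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auc_from_labels(scores: np.ndarray, labels: np.ndarray) -> float:
    """Empirical AUC of one score vector against binary labels."""
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise UndefinedROCError("both classes required")
    return float(_auc_rows(np.asarray(scores, dtype=float), labels))


def empirical_auc(pos_scores, neg_scores) -> AUCResult:
    """All-pairs empirical AUC with ties credited 0.5.

    Computed via the rank-sum identity (equivalent to the mean over
    all (pos, neg) pairs of 1/0.5/0, and to the trapezoid over the
    exhaustive-threshold ROC). SE is Hanley-McNeil; the 95% CI is the
    normal interval clipped to [0, 1].
    """
    pos = np.asarray(pos_scores, dtype=float).ravel()
    neg = np.asarray(neg_scores, dtype=float).ravel()
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedROCError("both score lists must be non-empty")
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos), bool), np.zeros(len(neg), bool)])
    auc = float(_auc_rows(scores, labels))
    se = hanley_mcneil_se(auc, len(pos), len(neg))
    lo, hi = auc - 1.959963984540054 * se, auc + 1.959963984540054 * se
    return AUCResult(
        auc=auc,
        n_pos=len(pos),
        n_neg=len(neg),
        se=se,
        ci95=(max(0.0, lo), min(1.0, hi)),
    )


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil closed-form SE of an empirical AUC.

    Q1 = A/(2-A), Q2 = 2A^2/(1+A),
    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos n_neg).
    """
    if not (0.0 <= auc <= 1.0):
        raise InputError(f"auc must be in [0, 1], got {auc}")
    if n_pos < 1 or n_neg < 1:
        raise InputError("class counts must be >= 1")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def compare_auc(a1: AUCResult, a2: AUCResult) -> ComparisonResult:
    """Two-sided z-test for a difference of two AUCs (Hanley-McNeil SEs)."""
    diff = a1.auc - a2.auc
    denom = float(np.hypot(a1.se, a2.se))
    if denom == 0.0:
        if diff == 0.0:
            return ComparisonResult(estimate=0.0, z=0.0, p_raw=1.0, ci95=(0.0, 0.0))
        raise InputError("both SEs are zero with unequal AUCs (infinite z)")
    z = diff / denom
    p = float(2.0 * norm.sf(abs(z)))
    half = 1.959963984540054 * denom
    return ComparisonResult(estimate=diff, z=float(z), p_raw=p, ci95=(diff - half, diff + half))


def _ratings_matrix(
    ratings: pd.DataFrame, manifest: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Pivot a long rating table to (readers x cases) aligned with the
    manifest order; errors on an incomplete crossing."""
    wide = ratings.pivot(index="reader_id", columns="case_id", values="rating")
    case_ids = manifest["case_id"].to_numpy()
    missing = set(case_ids) - set(wide.columns)
    if missing or wide.isna().any().any():
        raise InputError("incomplete reader x case crossing")
    mat = wide.loc[:, case_ids].to_numpy(dtype=float)
    labels = manifest["present"].to_numpy().astype(bool)
    return mat, labels


def mrmc_auc(
    ratings: pd.DataFrame,
    truth: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> AUCResult:
    """Reader-averaged (pooled) AUC with case-bootstrap SE/CI.

    The pooled estimate is the unweighted mean of per-reader empirical
    AUCs over the shared cases. Readers are fixed; cases are resampled
    with replacement (degenerate single-class resamples are redrawn).
    """
    mat, labels = _ratings_matrix(ratings, truth)
    if labels.all() or not labels.any():
        raise UndefinedROCError("truth must contain both classes")
    pooled = float(_auc_rows(mat, labels).mean())
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xB007)))
    n = len(labels)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, n)
            lb = labels[idx]
            if lb.any() and not lb.all():
                break
        else:
            raise InputError("could not draw a two-class bootstrap resample")
        reps[b] = _auc_rows(mat[:, idx], lb).mean()
    se = float(reps.std(ddof=1))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return AUCResult(
        auc=pooled,
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
        se=se,
        ci95=(max(0.0, float(lo)), min(1.0, float(hi))),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def bootstrap_auc_reduction(
    scores_a_cond1: np.ndarray,
    labels_cond1: np.ndarray,
    scores_a_cond2: np.ndarray,
    labels_cond2: np.ndarray,
    ratings_b_cond1: np.ndarray,
    ratings_b_cond2: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    max_redraw: int = 100,
    paired: bool | str = "auto",
) -> ComparisonResult:
    """Bootstrap comparison of AUC reductions between two modalities.

    Condition 1 is the reference (e.g. 200 mAs), condition 2 the
    degraded arm (e.g. 26 mAs). Modality A is a single score vector
    per arm; modality B is a (readers x cases) rating matrix per arm,
    pooled by reader-averaging. Cases within an arm are shared between
    the modalities, so one resample per arm per replicate is applied
    to both. With ``paired="auto"`` (the default) the two arms reuse
    the same index draw whenever they have equal case counts — the
    factorial design produces parallel arms, and pairing makes the
    degenerate identical-arms null exactly zero; pass ``paired=False``
    to resample the arms independently. The statistic is

        delta = (AUC_A1 - AUC_A2) - (AUC_B1 - AUC_B2),

    with z = mean(delta*)/sd(delta*) over replicates, a two-sided
    normal p, and a percentile 95% CI.
    """
    if n_boot < 2:
        raise InputError("n_boot must be >= 2")
    l1 = np.asarray(labels_cond1).astype(bool)
    l2 = np.asarray(labels_cond2).astype(bool)
    a1 = np.asarray(scores_a_cond1, dtype=float)
    a2 = np.asarray(scores_a_cond2, dtype=float)
    b1 = np.atleast_2d(np.asarray(ratings_b_cond1, dtype=float))
    b2 = np.atleast_2d(np.asarray(ratings_b_cond2, dtype=float))
    for arr, lab, name in ((a1, l1, "cond1"), (a2, l2, "cond2")):
        if arr.shape[-1] != lab.size:
            raise InputError(f"scores/labels length mismatch in {name}")
    for mat, lab, name in ((b1, l1, "cond1"), (b2, l2, "cond2")):
        if mat.shape[1] != lab.size:
            raise InputError(f"ratings/labels length mismatch in {name}")

    def reduction(idx1: np.ndarray, idx2: np.ndarray) -> float:
        red_a = float(_auc_rows(a1[idx1], l1[idx1])) - float(
            _auc_rows(a2[idx2], l2[idx2])
        )
        red_b = float(_auc_rows(b1[:, idx1], l1[idx1]).mean()) - float(
            _auc_rows(b2[:, idx2], l2[idx2]).mean()
        )
        return red_a - red_b

    estimate = reduction(np.arange(l1.size), np.arange(l2.size))
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x2ED0)))
    if paired == "auto":
        paired = l1.size == l2.size
    elif paired and l1.size != l2.size:
        raise InputError("paired resampling requires equal arm sizes")

    def resample(labels: np.ndarray) -> np.ndarray:
        n = labels.size
        for _ in range(max_redraw):
            idx = rng.integers(0, n, n)
            lb = labels[idx]
            if lb.any() and not lb.all():
                return idx
        raise InputError("could not draw a two-class bootstrap resample")

    def resample_pair() -> tuple[np.ndarray, np.ndarray]:
        for _ in range(max_redraw):
            idx = rng.integers(0, l1.size, l1.size)
            a, b = l1[idx], l2[idx]
            if a.any() and not a.all() and b.any() and not b.all():
                return idx, idx
        raise InputError("could not draw a two-class bootstrap resample")

    deltas = np.empty(n_boot)
    for b in range(n_boot):
        if paired:
            idx1, idx2 = resample_pair()
        else:
            idx1, idx2 = resample(l1), resample(l2)
        deltas[b] = reduction(idx1, idx2)
    sd = float(deltas.std(ddof=1))
    if sd == 0.0:
        z = 0.0
        p = 1.0
    else:
        z = float(deltas.mean() / sd)
        p = float(2.0 * norm.sf(abs(z)))
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return ComparisonResult(
        estimate=float(estimate), z=z, p_raw=p, ci95=(float(lo), float(hi))
    )
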