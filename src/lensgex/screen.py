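"""Differential-screen primitives: low-signal filtering, single-array-pair
contrasts and group contrasts.

The study design pits single treated arrays against single galactose arrays
and a single control array, so no between-replicate variance exists for those
contrasts.  P-values for such pairs are computed at the *probe* level: a
two-tailed equal-variance Student's t-test on the log2 probe intensities of a
gene between the two arrays.  Probe replication is the only within-pair
variance source available.  When only a gene-level matrix exists, contrasts
degrade to fold-change-only mode (p = NaN) with an explicit warning.

Fold changes are always ratios of *linear* means (B relative to A); fold
thresholds are applied two-sidedly (fc > k or fc < 1/k).  Raw P thresholds
are used throughout — no multiple-testing correction is applied anywhere in
the pipeline, by design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateInputError
from .io import DEFAULT_EPSILON, ProbeLevelArray, SignalMatrix

log = logging.getLogger(__name__)


@dataclass
class ContrastResult:
    """Per-gene outcome of a two-sample contrast (B relative to A)."""

    gene_id: str
    p_value: float
    fold_change: float
    direction: str  # up | down | flat
    contrast: tuple[str, str]
    flagged: bool = False  # zero variance on both sides

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise DataError(f"p-value {self.p_value} outside [0,1]")
        if not self.fold_change > 0:
            raise DataError(f"fold change must be positive, got {self.fold_change}")


def _direction(fc: float) -> str:
    if fc > 1:
        return "up"
    if fc < 1:
        return "down"
    return "flat"


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def low_signal_filter(
    matrix: SignalMatrix,
    cutoff: float = 5.0,
    scope: Sequence[str] | None = None,
) -> SignalMatrix:
    """Drop genes whose signal is below ``cutoff`` in *every* sample of ``scope``.

    Blank or unnamed gene ids (empty strings, NaN-like placeholders) are also
    removed.  ``scope`` defaults to all samples; an explicitly empty scope is
    an argument error.
    """
    if scope is not None and len(scope) == 0:
        raise ValueError("low_signal_filter: empty scope")
    scope = list(scope) if scope is not None else matrix.sample_ids
    unknown = [s for s in scope if s not in matrix.sample_ids]
    if unknown:
        raise ValueError(f"scope samples not in matrix: {unknown}")
    named = np.array(
        [bool(str(g).strip()) and str(g).lower() not in ("nan", "na", "---") for g in matrix.values.index]
    )
    above = (matrix.values[scope] >= cutoff).any(axis=1).to_numpy()
    keep = matrix.values.index[named & above]
    n_in, n_out = matrix.shape[0], len(keep)
    log.info("low_signal_filter: retained %d of %d genes (cutoff=%g)", n_out, n_in, cutoff)
    return SignalMatrix(matrix.values.loc[keep], matrix.sample_meta)


# ---------------------------------------------------------------------------
# vectorised t machinery
# ---------------------------------------------------------------------------

def _rows_ttest(log_a: np.ndarray, log_b: np.ndarray) -> np.ndarray:
    """Row-wise two-tailed equal-variance Student's t on two (G, n) arrays.

    NaN entries mark ragged probe sets and are omitted.  Degenerate rows
    (zero variance on both sides) get p = 1 when the means agree and p = 0
    when they differ — the limit of the t statistic.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(log_a, log_b, axis=1, equal_var=True, nan_policy="omit")
    p = np.asarray(p, dtype=float)
    var_a = np.nanvar(log_a, axis=1)
    var_b = np.nanvar(log_b, axis=1)
    mean_a = np.nanmean(log_a, axis=1)
    mean_b = np.nanmean(log_b, axis=1)
    degenerate = (var_a == 0) & (var_b == 0)
    p[degenerate & np.isclose(mean_a, mean_b)] = 1.0
    p[degenerate & ~np.isclose(mean_a, mean_b)] = 0.0
    return p


def _counts(x: np.ndarray) -> np.ndarray:
    return np.isfinite(x).sum(axis=1)


def pair_contrast_frame(
    a: ProbeLevelArray,
    b: ProbeLevelArray,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """All-genes contrast between two single arrays (vectorised).

    Returns a DataFrame indexed by gene with columns ``p_value``,
    ``fold_change`` (linear mean of b over linear mean of a), ``direction``
    and ``flagged``.  Genes are the intersection of the two arrays, in the
    order of ``a``.
    """
    b_genes = set(b.probes.index)
    common = [g for g in a.probes.index if g in b_genes]
    if not common:
        raise DataError("pair_contrast: no genes in common")
    A = a.probes.loc[common].to_numpy(dtype=float)
    B = b.probes.loc[common].to_numpy(dtype=float)
    if ((_counts(A) < 2) | (_counts(B) < 2)).any():
        raise DegenerateInputError("pair_contrast: a gene has <2 probes on one side")
    log_a = np.log2(np.clip(A, epsilon, None))
    log_b = np.log2(np.clip(B, epsilon, None))
    p = _rows_ttest(log_a, log_b)
    mean_a = np.nanmean(A, axis=1)
    mean_b = np.nanmean(B, axis=1)
    fc = np.clip(mean_b, epsilon, None) / np.clip(mean_a, epsilon, None)
    flagged = (np.nanvar(log_a, axis=1) == 0) & (np.nanvar(log_b, axis=1) == 0)
    return pd.DataFrame(
        {
            "p_value": p,
            "fold_change": fc,
            "direction": [_direction(f) for f in fc],
            "flagged": flagged,
        },
        index=pd.Index(common, name="gene_id"),
    )


def pair_contrast(a: ProbeLevelArray, b: ProbeLevelArray, gene: str) -> ContrastResult:
    """Single-gene contrast between two single arrays (probe-level t-test)."""
    for arr in (a, b):
        if gene not in arr.probes.index:
            raise DataError(f"gene {gene!r} absent from array {arr.sample_id}")
        if len(arr.gene_probes(gene)) < 2:
            raise DegenerateInputError(f"gene {gene!r} has <2 probes in {arr.sample_id}")
    frame = pair_contrast_frame(
        ProbeLevelArray(a.sample_id, a.probes.loc[[gene]]),
        ProbeLevelArray(b.sample_id, b.probes.loc[[gene]]),
    )
    row = frame.iloc[0]
    return ContrastResult(
        gene_id=gene,
        p_value=float(row["p_value"]),
        fold_change=float(row["fold_change"]),
        direction=row["direction"],
        contrast=(a.sample_id, b.sample_id),
        flagged=bool(row["flagged"]),
    )


def group_contrast(
    matrix: SignalMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Per-gene contrast between two sample groups of a signal matrix.

    Fold change is the ratio of group mean linear signals (B over A); the
    p-value is a two-tailed equal-variance Student's t on log2 signals across
    samples.  With a single sample on either side the contrast runs in
    fold-change-only mode (p = NaN) and a warning is logged.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("group_contrast: groups overlap")
    for g in group_a + group_b:
        if g not in matrix.sample_ids:
            raise ValueError(f"sample {g!r} not in matrix")
    A = matrix.values[group_a].to_numpy(dtype=float)
    B = matrix.values[group_b].to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    fc = np.clip(mean_b, epsilon, None) / np.clip(mean_a, epsilon, None)
    if len(group_a) >= 2 and len(group_b) >= 2:
        p = _rows_ttest(
            np.log2(np.clip(A, epsilon, None)), np.log2(np.clip(B, epsilon, None))
        )
    else:
        log.warning("group_contrast: n=1 group, running fold-change-only mode")
        p = np.full(len(fc), np.nan)
    return pd.DataFrame(
        {
            "p_value": p,
            "fold_change": fc,
            "direction": [_direction(f) for f in fc],
        },
        index=matrix.values.index.rename("gene_id"),
    )
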