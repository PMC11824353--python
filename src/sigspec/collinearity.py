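"""Collinearity analyses on exposure matrices.

Two orthogonal views: Pearson correlation between signatures across all
samples pooled (cancer types combined), and pairwise cosine similarity
between samples within each cancer type.  Highly correlated signature pairs
use a strict ``r > threshold`` rule with a default threshold of 0.7.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CohortLabels, ExposureMatrix

CORRELATION_THRESHOLD = 0.7


@dataclass
class CorrelationReport:
    """Signature x signature Pearson matrix plus the high-correlation pairs.

    Entries for constant signature rows are NaN (undefined correlation) and
    never appear in ``pairs``; pairs are each reported once, signature ids in
    input order, sorted by r descending.
    """

    matrix: pd.DataFrame
    pairs: pd.DataFrame
    threshold: float


def signature_correlation(
    e: ExposureMatrix, threshold: float = CORRELATION_THRESHOLD
) -> CorrelationReport:
    if len(e.sample_ids) < 3:
        raise ValueError("need at least 3 samples for a meaningful correlation")
    X = e.values
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        names = [e.signature_ids[i] for i in np.flatnonzero(constant)]
        warnings.warn(
            f"constant exposure rows (correlation undefined): {names}", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.asarray(corr, dtype=float)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, np.where(constant, np.nan, 1.0))

    rows = []
    k = len(e.signature_ids)
    for a in range(k):
        for b in range(a + 1, k):
            r = corr[a, b]
            if np.isfinite(r) and r > threshold:
                rows.append((e.signature_ids[a], e.signature_ids[b], r))
    pairs = pd.DataFrame(rows, columns=["signature_a", "signature_b", "r"])
    pairs = pairs.sort_values("r", ascending=False, kind="mergesort").reset_index(drop=True)
    matrix = pd.DataFrame(corr, index=e.signature_ids, columns=e.signature_ids)
    return CorrelationReport(matrix, pairs, threshold)


@dataclass
class SimilaritySummary:
    """Five-number summaries of within-cancer pairwise sample cosines."""

    table: pd.DataFrame  # index cancer_type; n_pairs, min, q1, median, q3, max
    values: dict[str, np.ndarray]  # raw pairwise cosines per cancer type


def _pairwise_cosines(X: np.ndarray) -> np.ndarray:
    """Upper-triangle cosines between the columns of X (all non-zero)."""
    norms = np.linalg.norm(X, axis=0)
    U = X / norms
    gram = U.T @ U
    iu = np.triu_indices(X.shape[1], k=1)
    return np.clip(gram[iu], -1.0, 1.0)


def sample_cosine_by_cancer(
    e: ExposureMatrix, labels: CohortLabels
) -> SimilaritySummary:
    """Pairwise cosine similarity between samples, grouped by cancer type.

    All-zero exposure columns are excluded (cosine undefined); cancer types
    with fewer than two usable samples are omitted.  Exposures are
    non-negative so every cosine lies in [0, 1].
    """
    lab = labels.for_samples(list(e.sample_ids)).table
    values: dict[str, np.ndarray] = {}
    rows = []
    for cancer, group in lab.groupby("cancer_type", sort=True):
        idx = [e.sample_ids.index(s) for s in group.index]
        X = e.values[:, idx]
        nonzero = np.linalg.norm(X, axis=0) > 0
        if (~nonzero).any():
            warnings.warn(
                f"{(~nonzero).sum()} all-zero exposure column(s) excluded for {cancer}",
                stacklevel=2,
            )
        X = X[:, nonzero]
        if X.shape[1] < 2:
            warnings.warn(
                f"cancer type {cancer} has < 2 usable samples; omitted", stacklevel=2
            )
            continue
        cos = _pairwise_cosines(X)
        values[cancer] = cos
        q1, med, q3 = np.percentile(cos, [25, 50, 75])
        rows.append((cancer, cos.size, cos.min(), q1, med, q3, cos.max()))
    table = pd.DataFrame(
        rows, columns=["cancer_type", "n_pairs", "min", "q1", "median", "q3", "max"]
    ).set_index("cancer_type")
    return SimilaritySummary(table, values)
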