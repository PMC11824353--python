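"""Mismatched-cancer F1 background and negative-binomial significance test.

The null for "does this cancer-type model perform better than chance" is
built by scoring each cancer type's model against every *other* cancer
type's one-vs-rest test labels: for T cancer types this yields T*(T-1)
background F1 values per method.  The background F1 values, discretized to
integer counts via round(100 * F1), are fitted with a negative binomial by
the method of moments (Poisson fallback when the counts are underdispersed),
and each matched model's F1 receives a one-sided upper-tail p-value.  The
empirical plus-one tail fraction is always reported alongside the parametric
p, since the negative-binomial form is a modeling convention rather than a
derived law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import nbinom, poisson

from .ml import EvalMetrics, FeatureTable, TrainedModel, evaluate

ALPHA = 0.05
_MIN_BACKGROUND = 10


@dataclass
class NBParams:
    """Fitted background law: ``nb`` (r, p), ``poisson`` (mean) or ``point``."""

    kind: str  # "nb" | "poisson" | "point"
    r: float | None = None
    p: float | None = None
    mean: float | None = None

    def sf_at(self, count: int) -> float:
        """P(X >= count) under the fitted law."""
        if self.kind == "nb":
            return float(nbinom.sf(count - 1, self.r, self.p))
        if self.kind == "poisson":
            return float(poisson.sf(count - 1, self.mean))
        # point mass at self.mean
        return 1.0 if count <= self.mean else 0.0


@dataclass
class BackgroundDistribution:
    scores: np.ndarray  # raw mismatched F1 values in [0, 1]
    counts: np.ndarray  # round(100 * F1) integer discretization
    nb_params: NBParams
    pairs: list[tuple[str, str]] | None = None  # (model cancer, test cancer)

    @property
    def n(self) -> int:
        return int(self.scores.size)


def fit_negative_binomial(scores) -> NBParams:
    """Method-of-moments negative-binomial fit to round(100*F1) counts.

    With sample mean m and variance v of the counts: p = m/v and
    r = m^2/(v - m) when v > m; when v <= m the negative binomial is
    undefined and a Poisson(m) is used instead; an all-equal sample falls
    back to a point mass.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot fit a background to zero scores")
    counts = np.round(100.0 * scores)
    m = counts.mean()
    v = counts.var()  # population variance; moment estimator
    if v == 0:
        warnings.warn(
            "all background scores identical; using a point-mass fallback", stacklevel=2
        )
        return NBParams(kind="point", mean=float(m))
    if v > m:
        r = m * m / (v - m)
        p = m / v
        return NBParams(kind="nb", r=float(r), p=float(p))
    warnings.warn(
        "background counts are underdispersed (var <= mean); Poisson fallback",
        stacklevel=2,
    )
    return NBParams(kind="poisson", mean=float(m))


def background_f1(
    models: Mapping[str, TrainedModel],
    test_sets: Mapping[str, FeatureTable],
) -> BackgroundDistribution:
    """F1 scores of every mismatched (model A, test labels B) pairing, A != B.

    ``models`` maps cancer type -> trained model; ``test_sets`` maps cancer
    type -> the test FeatureTable whose labels are one-vs-rest for that type.
    Returns one pooled BackgroundDistribution (models of one method).
    """
    cancers = [c for c in models if c in test_sets]
    if len(cancers) < 2:
        raise ValueError("background needs at least 2 cancer types")
    scores = []
    pairs = []
    for a in cancers:
        for b in cancers:
            if a == b:
                continue
            metrics = evaluate(models[a], test_sets[b])
            scores.append(metrics.f1)
            pairs.append((a, b))
    scores = np.asarray(scores)
    if scores.size < _MIN_BACKGROUND:
        warnings.warn(
            f"only {scores.size} background values; the negative-binomial fit "
            "may be unstable",
            stacklevel=2,
        )
    params = fit_negative_binomial(scores)
    return BackgroundDistribution(scores, np.round(100.0 * scores), params, pairs)


class PValue(NamedTuple):
    parametric: float
    empirical: float


def nb_pvalue(observed_f1: float, bg: BackgroundDistribution) -> PValue:
    """One-sided upper-tail p-value of an observed matched F1.

    Parametric: P(X >= round(100*F1)) under the fitted background law.
    Empirical: plus-one-corrected tail fraction
    (1 + #{background >= observed}) / (1 + n_background).
    """
    count = int(np.round(100.0 * observed_f1))
    parametric = min(max(bg.nb_params.sf_at(count), 0.0), 1.0)
    empirical = (1 + int((bg.scores >= observed_f1).sum())) / (1 + bg.n)
    return PValue(parametric, empirical)


def significance_table(
    matched_metrics: list[tuple[str, str, str, EvalMetrics]],
    backgrounds: Mapping[str, BackgroundDistribution],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """One row per (cancer, region, method) model, sorted by parametric p.

    ``matched_metrics`` rows are (cancer, region, method, metrics);
    ``backgrounds`` maps method -> its pooled background.  Rows with
    p < alpha carry ``significant = True``.
    """
    rows = []
    for cancer, region, method, metrics in matched_metrics:
        pv = nb_pvalue(metrics.f1, backgrounds[method])
        rows.append(
            {
                "cancer_type": cancer,
                "region": region,
                "method": method,
                "f1": metrics.f1,
                "p_value": pv.parametric,
                "p_empirical": pv.empirical,
                "significant": pv.parametric < alpha,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("p_value", ascending=True, kind="mergesort").reset_index(
            drop=True
        )
    return df
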