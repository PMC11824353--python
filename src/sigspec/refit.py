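"""Non-negative refitting of motif catalogs to known reference signatures.

Each sample's 96-motif count vector m_j is decomposed against the fixed
signature profiles S by non-negative least squares,

    e_j = argmin_{e >= 0} || m_j - S e ||_2 ,

so the coefficients (exposures) are signature-to-sample contribution
strengths in mutation-count units.  The solver is the classical active-set
NNLS, which returns exact zeros for inactive signatures and therefore makes
the downstream presence/absence dichotomization well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import (
    DimensionError,
    ExposureMatrix,
    MotifCatalog,
    PresenceMatrix,
    SignatureMatrix,
)

DICHOTOMIZE_TOL = 1e-8


def fit_exposures(cat: MotifCatalog, sig: SignatureMatrix) -> ExposureMatrix:
    """Solve one NNLS problem per sample against the signature profiles."""
    S = sig.profiles
    if cat.counts.shape[0] != S.shape[0]:
        raise DimensionError("catalog and signature matrix motif dimensions differ")
    zero_cols = np.flatnonzero(S.sum(axis=0) == 0)
    if zero_cols.size:
        names = [sig.signature_ids[i] for i in zero_cols]
        raise ValueError(f"all-zero signature columns: {names}")
    values = np.zeros((S.shape[1], cat.n_samples))
    for j in range(cat.n_samples):
        m = cat.counts[:, j].astype(float)
        if not m.any():
            continue
        values[:, j], _ = nnls(S, m)
    return ExposureMatrix(list(sig.signature_ids), list(cat.sample_ids), values)


def dichotomize(e: ExposureMatrix, tol_fraction: float = DICHOTOMIZE_TOL) -> PresenceMatrix:
    """Binarize exposures: 0 when a contribution is numerically zero, else 1.

    An entry counts as zero when it is below ``tol_fraction`` of its sample's
    total exposure (or of 1 for an all-zero sample); the active-set solver
    produces exact zeros, the tolerance only guards against round-off.
    """
    if np.any(e.values < 0):
        raise ValueError("exposures must be non-negative")
    totals = e.values.sum(axis=0)
    thresholds = tol_fraction * np.where(totals > 0, totals, 1.0)
    values = (e.values >= thresholds[np.newaxis, :]).astype(np.int8)
    return PresenceMatrix(list(e.signature_ids), list(e.sample_ids), values)


def reconstruction_cosine(
    cat: MotifCatalog, sig: SignatureMatrix, e: ExposureMatrix
) -> np.ndarray:
    """Per-sample cosine between the observed catalog and S @ e (fit QC)."""
    recon = sig.profiles @ e.values
    obs = cat.counts.astype(float)
    num = (recon * obs).sum(axis=0)
    denom = np.linalg.norm(recon, axis=0) * np.linalg.norm(obs, axis=0)
    out = np.zeros(cat.n_samples)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    if (~ok).any():
        warnings.warn(
            f"{(~ok).sum()} sample(s) with a zero catalog or zero reconstruction; "
            "cosine reported as 0",
            stacklevel=2,
        )
    return out


class SignatureRefit:
    """Refitting model: a motif catalog against fixed reference signatures.

    Parameters
    ----------
    catalog : MotifCatalog
        96 x N observed mutation counts.
    signatures : SignatureMatrix
        96 x K reference profiles (columns sum to 1).

    ``fit()`` returns a :class:`SignatureRefitResults` carrying the exposure
    matrix, its dichotomized presence form, and per-sample reconstruction
    quality.
    """

    def __init__(self, catalog: MotifCatalog, signatures: SignatureMatrix):
        if catalog.counts.shape[0] != signatures.profiles.shape[0]:
            raise DimensionError("catalog and signatures must share the motif axis")
        self.catalog = catalog
        self.signatures = signatures

    @classmethod
    def from_files(cls, catalog_path, signatures_path) -> "SignatureRefit":
        from .io import read_catalog, read_signature_matrix

        return cls(read_catalog(catalog_path), read_signature_matrix(signatures_path))

    def fit(self, tol_fraction: float = DICHOTOMIZE_TOL) -> "SignatureRefitResults":
        exposures = fit_exposures(self.catalog, self.signatures)
        presence = dichotomize(exposures, tol_fraction)
        cosines = reconstruction_cosine(self.catalog, self.signatures, exposures)
        return SignatureRefitResults(self, exposures, presence, cosines)


@dataclass
class SignatureRefitResults:
    model: SignatureRefit
    exposures: ExposureMatrix
    presence: PresenceMatrix
    reconstruction_cosines: np.ndarray

    def per_signature(self) -> pd.DataFrame:
        """Total attributed mutations and cohort prevalence per signature."""
        total = self.exposures.values.sum(axis=1)
        n = max(self.presence.values.shape[1], 1)
        prevalence = self.presence.values.sum(axis=1) / n
        return pd.DataFrame(
            {"total_exposure": total, "prevalence": prevalence},
            index=self.exposures.signature_ids,
        )

    def summary(self) -> str:
        cos = self.reconstruction_cosines
        lines = [
            "Signature refitting (non-negative least squares)",
            "=" * 48,
            f"samples:            {self.exposures.values.shape[1]}",
            f"signatures:         {self.exposures.values.shape[0]}",
            f"mean recon. cosine: {cos.mean():.4f}" if cos.size else "mean recon. cosine: n/a",
            f"min  recon. cosine: {cos.min():.4f}" if cos.size else "",
            "",
            "Top signatures by total attributed mutations:",
        ]
        top = self.per_signature().sort_values("total_exposure", ascending=False).head(10)
        for sig_id, row in top.iterrows():
            lines.append(
                f"  {sig_id:<12} total={row.total_exposure:12.1f}  "
                f"prevalence={row.prevalence:6.3f}"
            )
        return "\n".join(line for line in lines if line != "")

    def save(self, directory) -> None:
        from pathlib import Path

        from .io import write_exposures

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_exposures(self.exposures, directory / "exposures.tsv")
        self.presence.to_frame().rename_axis("Signature").to_csv(
            directory / "presence.tsv", sep="\t"
        )
        pd.Series(
            self.reconstruction_cosines, index=self.exposures.sample_ids, name="cosine"
        ).rename_axis("sample_id").to_csv(directory / "reconstruction_cosine.tsv", sep="\t")
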