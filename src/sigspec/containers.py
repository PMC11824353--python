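"""In-memory containers shared by every pipeline stage.

All 96-row matrices (catalogs, signature profiles) use the canonical motif
order from :mod:`sigspec.motifs`; exposure and presence matrices share the
signature and sample orderings of the objects they were derived from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .motifs import MOTIF_ORDER

N_MOTIFS = 96


class DimensionError(ValueError):
    pass


@dataclass
class MotifCatalog:
    """Per-sample counts over the 96 trinucleotide substitution classes.

    ``counts`` is a 96 x N non-negative integer matrix; column j sums to the
    number of classified SNVs of sample j.
    """

    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != N_MOTIFS:
            raise DimensionError(
                f"catalog must have {N_MOTIFS} motif rows, got shape {self.counts.shape}"
            )
        if self.counts.shape[1] != len(self.sample_ids):
            raise DimensionError("number of columns must match number of sample ids")
        if np.any(self.counts < 0):
            raise ValueError("catalog counts must be non-negative")
        self.counts = self.counts.astype(np.int64, copy=False)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(MOTIF_ORDER), columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MotifCatalog":
        missing = set(MOTIF_ORDER) - set(df.index)
        if missing:
            raise ValueError(f"catalog frame is missing {len(missing)} motifs")
        df = df.loc[list(MOTIF_ORDER)]
        return cls(list(df.columns), df.to_numpy())


@dataclass
class SignatureMatrix:
    """Reference signature profiles: 96 motif rows x K signature columns.

    Every column is a probability distribution over the 96 motifs (sums to 1).
    """

    signature_ids: list[str]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[0] != N_MOTIFS:
            raise DimensionError(
                f"signature matrix must have {N_MOTIFS} rows, got {self.profiles.shape}"
            )
        if self.profiles.shape[1] != len(self.signature_ids):
            raise DimensionError("number of columns must match number of signature ids")
        if np.any(self.profiles < 0):
            raise ValueError("signature profiles must be non-negative")
        sums = self.profiles.sum(axis=0)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
        if bad.size:
            offenders = [self.signature_ids[i] for i in bad]
            raise ValueError(f"signature columns do not sum to 1: {offenders}")

    @property
    def n_signatures(self) -> int:
        return len(self.signature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles, index=list(MOTIF_ORDER), columns=self.signature_ids
        )


@dataclass
class ExposureMatrix:
    """Signature-to-sample contribution strengths (mutations attributed).

    K signature rows x N sample columns, non-negative, sharing orderings with
    the source :class:`SignatureMatrix` and :class:`MotifCatalog`.
    """

    signature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.signature_ids), len(self.sample_ids)):
            raise DimensionError(
                f"exposure matrix shape {self.values.shape} does not match "
                f"{len(self.signature_ids)} signatures x {len(self.sample_ids)} samples"
            )
        if np.any(self.values < 0):
            raise ValueError("exposures must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.signature_ids, columns=self.sample_ids)


@dataclass
class PresenceMatrix:
    """Dichotomized exposures: 1 where a signature contributes, else 0."""

    signature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.signature_ids), len(self.sample_ids)):
            raise DimensionError("presence matrix shape mismatch")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("presence values must be 0 or 1")
        self.values = self.values.astype(np.int8, copy=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.signature_ids, columns=self.sample_ids)


@dataclass
class CohortLabels:
    """Sample-level annotations: cancer type, region (cohort) and split.

    Backed by a DataFrame indexed by sample id with columns
    ``cancer_type``, ``region`` and ``split`` (``train`` or ``test``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cancer_type", "region", "split"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"labels table missing columns {sorted(missing)}")
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in labels: {dupes[:5]}")
        bad = set(self.table["split"]) - {"train", "test"}
        if bad:
            raise ValueError(f"split values must be train/test, got {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def cancer_types(self, split: str | None = None) -> list[str]:
        t = self.table if split is None else self.table[self.table["split"] == split]
        return sorted(t["cancer_type"].unique())

    def for_samples(self, sample_ids: list[str]) -> "CohortLabels":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples without labels: {missing[:5]}")
        return CohortLabels(self.table.loc[sample_ids].copy())

    def subset(self, mask: pd.Series) -> "CohortLabels":
        return CohortLabels(self.table[mask].copy())

    @classmethod
    def from_records(
        cls, records: Mapping[str, tuple[str, str, str]]
    ) -> "CohortLabels":
        df = pd.DataFrame.from_dict(
            records, orient="index", columns=["cancer_type", "region", "split"]
        )
        df.index.name = "sample_id"
        return cls(df)


@dataclass
class CategoryMap:
    """Signature id -> etiology category, used to collapse exposure rows."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, signature_id: str) -> str:
        return self.mapping[signature_id]

    def categories(self) -> list[str]:
        seen: list[str] = []
        for cat in self.mapping.values():
            if cat not in seen:
                seen.append(cat)
        return seen


class UnmappedSignatureError(KeyError):
    pass


def aggregate_by_category(e: ExposureMatrix, cmap: CategoryMap) -> pd.DataFrame:
    """Collapse exposure rows into etiology categories.

    Each category row is the sum of its member signatures' exposures, so
    per-sample totals are conserved.  Raises if any signature in *e* lacks a
    category.
    """
    unmapped = [s for s in e.signature_ids if s not in cmap.mapping]
    if unmapped:
        raise UnmappedSignatureError(f"signatures without a category: {unmapped}")
    cats = [c for c in cmap.categories() if c in {cmap.mapping[s] for s in e.signature_ids}]
    out = np.zeros((len(cats), len(e.sample_ids)))
    cat_pos = {c: i for i, c in enumerate(cats)}
    for row, sig in enumerate(e.signature_ids):
        out[cat_pos[cmap.mapping[sig]]] += e.values[row]
    return pd.DataFrame(out, index=cats, columns=e.sample_ids)
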