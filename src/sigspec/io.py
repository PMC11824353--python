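"""Readers and writers for signature, catalog, exposure and label tables.

All on-disk formats are plain TSV.  Signature files accept two common
dialects: a single context column with ``A[C>A]A``-style labels, or separate
substitution-type (``C>A``) and trinucleotide (``ACA``) columns as in the
COSMIC v2 distribution.  Rows are always re-ordered to the canonical motif
order on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CategoryMap, CohortLabels, ExposureMatrix, MotifCatalog, SignatureMatrix
from .motifs import MOTIF_ORDER, _LABEL_RE

COLUMN_SUM_TOL = 1e-3


class SignatureFormatError(ValueError):
    pass


def _motif_labels_from_columns(df: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    """Locate the motif labels; return (labels, consumed column names)."""
    # dialect 1: one column of A[C>A]A labels
    for col in df.columns:
        vals = df[col].astype(str).str.strip()
        if vals.map(lambda s: bool(_LABEL_RE.match(s))).all():
            return vals, [col]
    # dialect 2: substitution type + trinucleotide context
    sub_col = tri_col = None
    for col in df.columns:
        vals = df[col].astype(str).str.strip()
        if vals.str.fullmatch(r"[CT]>[ACGT]").all():
            sub_col = col
        elif vals.str.fullmatch(r"[ACGT]{3}").all():
            tri_col = col
    if sub_col is not None and tri_col is not None:
        tri = df[tri_col].astype(str).str.strip()
        sub = df[sub_col].astype(str).str.strip()
        labels = tri.str[0] + "[" + sub + "]" + tri.str[2]
        return labels, [sub_col, tri_col]
    raise SignatureFormatError(
        "could not locate motif labels: need either an 'A[C>A]A' context column "
        "or substitution-type plus trinucleotide columns"
    )


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    """Read a COSMIC-style signature TSV.

    Rows are reindexed to the canonical motif order; each numeric column must
    sum to 1 within ``1e-3`` and is renormalized to exactly 1.
    """
    df = pd.read_csv(path, sep="\t")
    labels, consumed = _motif_labels_from_columns(df)
    df = df.drop(columns=consumed)
    df.index = labels.values
    numeric = df.select_dtypes(include=[np.number])
    if numeric.shape[1] == 0:
        raise SignatureFormatError("no numeric signature columns found")
    missing = set(MOTIF_ORDER) - set(numeric.index)
    if missing:
        raise SignatureFormatError(
            f"signature file is missing {len(missing)} motifs, e.g. {sorted(missing)[:3]}"
        )
    if numeric.index.has_duplicates:
        raise SignatureFormatError("duplicate motif rows in signature file")
    numeric = numeric.loc[list(MOTIF_ORDER)]
    values = numeric.to_numpy(dtype=float)
    if np.any(values < 0):
        raise SignatureFormatError("negative entries in signature file")
    sums = values.sum(axis=0)
    off = np.flatnonzero(np.abs(sums - 1.0) > COLUMN_SUM_TOL)
    if off.size:
        names = [numeric.columns[i] for i in off]
        raise SignatureFormatError(
            f"signature columns far from sum 1 (tol {COLUMN_SUM_TOL}): {names}"
        )
    values = values / sums
    return SignatureMatrix(list(numeric.columns), values)


def write_signature_matrix(sig: SignatureMatrix, path: str | Path) -> None:
    df = sig.to_frame()
    df.insert(0, "MutationType", list(MOTIF_ORDER))
    df.to_csv(path, sep="\t", index=False)


def write_catalog(cat: MotifCatalog, path: str | Path) -> None:
    df = cat.to_frame()
    df.index.name = "MutationType"
    df.to_csv(path, sep="\t")


def read_catalog(path: str | Path) -> MotifCatalog:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.map(lambda v: float(v).is_integer()).all().all():
        raise ValueError("catalog cells must be integers")
    return MotifCatalog.from_frame(df.astype(np.int64))


def write_exposures(e: ExposureMatrix, path: str | Path) -> None:
    df = e.to_frame()
    df.index.name = "Signature"
    # repr-precision floats so that write -> read is lossless
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_exposures(path: str | Path) -> ExposureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"malformed numeric cell in exposure file: {exc}") from exc
    return ExposureMatrix(list(df.index), list(df.columns), values)


def write_labels(labels: CohortLabels, path: str | Path) -> None:
    labels.table.rename_axis("sample_id").to_csv(path, sep="\t")


def read_labels(path: str | Path) -> CohortLabels:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return CohortLabels(df)


def read_category_map(path: str | Path) -> CategoryMap:
    """Category map from a YAML/JSON mapping ``signature_id: category``."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("category map file must contain a mapping")
    return CategoryMap({str(k): str(v) for k, v in data.items()})


def write_category_map(cmap: CategoryMap, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cmap.mapping, indent=2, sort_keys=True))
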