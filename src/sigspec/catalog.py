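"""Classify somatic SNVs into the 96 motif classes and build per-sample catalogs.

Input is MAF-like: 1-based positions, single-base ref/alt, optionally an
inline 3-mer context centered on the mutated site.  Purine-reference records
are collapsed onto the pyrimidine strand by reverse complement, the standard
COSMIC convention.  Context comes from the inline column when no FASTA is
given; when a FASTA is given it is authoritative and an inline context that
contradicts it is an error, not silently trusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .containers import MotifCatalog, N_MOTIFS
from .motifs import BASES, COMPLEMENT, MotifClass, motif_index, reverse_complement

logger = logging.getLogger(__name__)

ContextSource = Callable[[str, int], str]


class ContextMismatchError(ValueError):
    """Inline context (or FASTA) disagrees with the record's reference base."""


class SkipRecord(Exception):
    """Record cannot be classified (ambiguous base, missing context, ...)."""


@dataclass
class MutationRecord:
    """One somatic single-nucleotide variant.

    ``position`` is 1-based and refers to the mutated base; ``context`` when
    present is the 3-mer reference sequence centered on it.
    """

    sample_id: str
    chromosome: str
    position: int
    ref: str
    alt: str
    context: str | None = None
    cancer_type: str | None = None
    region: str | None = None


class FastaContext:
    """3-mer context lookup from an indexed genome FASTA (1-based query)."""

    def __init__(self, path: str | Path):
        from pyfaidx import Fasta

        self._fa = Fasta(str(path), sequence_always_upper=True)

    def __call__(self, chromosome: str, position: int) -> str:
        # pyfaidx slices are 0-based half-open
        seq = self._fa[chromosome][position - 2 : position + 1]
        return str(seq)


def classify_mutation(
    r: MutationRecord, context_source: ContextSource | None = None
) -> MotifClass:
    """Map an SNV to its pyrimidine-collapsed motif class.

    Raises :class:`SkipRecord` for ambiguous/unusable records and
    :class:`ContextMismatchError` when the context contradicts the record.
    """
    ref, alt = r.ref.upper(), r.alt.upper()
    if len(ref) != 1 or len(alt) != 1:
        raise SkipRecord("not a single-nucleotide substitution")
    if ref not in BASES or alt not in BASES:
        raise SkipRecord(f"ambiguous or invalid allele {ref}>{alt}")
    if ref == alt:
        raise SkipRecord("ref equals alt")

    if context_source is not None:
        context = context_source(r.chromosome, r.position).upper()
        if r.context is not None and r.context.upper() != context:
            raise ContextMismatchError(
                f"inline context {r.context!r} contradicts FASTA context {context!r} "
                f"at {r.chromosome}:{r.position}"
            )
    elif r.context is not None:
        context = r.context.upper()
    else:
        raise SkipRecord("no context available (no inline context and no FASTA)")

    if len(context) != 3:
        raise SkipRecord(f"context {context!r} is not a 3-mer")
    if any(b not in BASES for b in context):
        raise SkipRecord(f"ambiguous base in context {context!r}")
    if context[1] != ref:
        raise ContextMismatchError(
            f"context middle base {context[1]!r} does not match ref {ref!r}"
        )

    if ref in "AG":  # purine reference: collapse to the pyrimidine strand
        context = reverse_complement(context)
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return MotifClass(ref, alt, context[0], context[2])


def build_catalog(
    records: Iterable[MutationRecord], context_source: ContextSource | None = None
) -> tuple[MotifCatalog, int]:
    """Count motif classes per sample.

    Samples are ordered by first appearance.  Returns the catalog and the
    number of records skipped (ambiguous bases, missing context, non-SNVs);
    a context that contradicts the record is a hard error.
    """
    sample_pos: dict[str, int] = {}
    columns: list[np.ndarray] = []
    skipped = 0
    for r in records:
        if r.sample_id not in sample_pos:
            sample_pos[r.sample_id] = len(columns)
            columns.append(np.zeros(N_MOTIFS, dtype=np.int64))
        try:
            motif = classify_mutation(r, context_source)
        except SkipRecord as exc:
            skipped += 1
            logger.debug("skipping %s:%s (%s)", r.chromosome, r.position, exc)
            continue
        columns[sample_pos[r.sample_id]][motif_index(motif)] += 1
    counts = (
        np.stack(columns, axis=1) if columns else np.zeros((N_MOTIFS, 0), dtype=np.int64)
    )
    return MotifCatalog(list(sample_pos), counts), skipped


DEFAULT_COLUMN_ALIASES = {
    "sample": "sample_id",
    "sample_id": "sample_id",
    "tumor_sample_barcode": "sample_id",
    "chromosome": "chromosome",
    "chrom": "chromosome",
    "position": "position",
    "start_position": "position",
    "pos": "position",
    "ref": "ref",
    "reference_allele": "ref",
    "alt": "alt",
    "tumor_seq_allele2": "alt",
    "context": "context",
    "trinucleotide_context": "context",
    "cancer_type": "cancer_type",
    "project": "cancer_type",
    "region": "region",
    "cohort": "region",
}

MANDATORY_FIELDS = ("sample_id", "chromosome", "position", "ref", "alt")


class MafFormatError(ValueError):
    pass


def read_maf(
    path: str | Path, column_map: dict[str, str] | None = None
) -> tuple[list[MutationRecord], int]:
    """Read a MAF-like TSV into mutation records.

    ``column_map`` maps file column names to the canonical fields
    (sample_id, chromosome, position, ref, alt, context, cancer_type, region);
    common MAF spellings are recognized automatically.  Only single-nucleotide
    substitution rows (both alleles a single A/C/G/T, ref != alt) are
    returned; the second element counts the rows skipped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    rename: dict[str, str] = {}
    for col in df.columns:
        if column_map and col in column_map:
            rename[col] = column_map[col]
        elif col.lower() in DEFAULT_COLUMN_ALIASES:
            rename[col] = DEFAULT_COLUMN_ALIASES[col.lower()]
    df = df.rename(columns=rename)
    missing = [f for f in MANDATORY_FIELDS if f not in df.columns]
    if missing:
        raise MafFormatError(f"MAF file missing mandatory columns: {missing}")

    keep = [
        f
        for f in ("sample_id", "chromosome", "position", "ref", "alt", "context",
                  "cancer_type", "region")
        if f in df.columns
    ]
    records: list[MutationRecord] = []
    skipped = 0
    for d in df[keep].to_dict("records"):
        ref = str(d["ref"]).upper()
        alt = str(d["alt"]).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES or ref == alt:
            skipped += 1
            continue
        def _opt(key: str) -> str | None:
            v = d.get(key)
            return None if v is None or (isinstance(v, float) and pd.isna(v)) or v == "" else str(v)

        records.append(
            MutationRecord(
                sample_id=str(d["sample_id"]),
                chromosome=str(d["chromosome"]),
                position=int(d["position"]),
                ref=ref,
                alt=alt,
                context=_opt("context"),
                cancer_type=_opt("cancer_type"),
                region=_opt("region"),
            )
        )
    if skipped:
        logger.info("read_maf: skipped %d non-SNV rows", skipped)
    return records, skipped
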