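"""Canonical SBS-96 trinucleotide motif space.

A single-base substitution is described by its pyrimidine-strand mutation
(``C>A`` ... ``T>G``) together with the bases immediately 5' and 3' of the
mutated site, giving 6 x 4 x 4 = 96 classes.  The canonical ordering used
throughout the package is the COSMIC one: substitution blocks C>A, C>G, C>T,
T>A, T>C, T>G; inside a block the 5' flank cycles A,C,G,T as the major key
and the 3' flank A,C,G,T as the minor key, so

    index = 16 * substitution + 4 * five_prime + three_prime.

Every matrix in the package (catalogs, signature profiles) shares this row
order.
"""

from __future__ import annotations

from dataclasses import dataclass
import re

BASES = "ACGT"
PYRIMIDINES = "CT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_LABEL_RE = re.compile(r"^([ACGT])\[([CT])>([ACGT])\]([ACGT])$")


class InvalidMotifError(ValueError):
    """A motif with a purine reference, ref == alt, or a non-ACGT base."""


@dataclass(frozen=True)
class MotifClass:
    """One of the 96 pyrimidine-centered trinucleotide substitution classes."""

    ref_base: str
    alt_base: str
    five_prime: str
    three_prime: str

    def __post_init__(self) -> None:
        if self.ref_base not in PYRIMIDINES:
            raise InvalidMotifError(
                f"reference base must be a pyrimidine (C/T), got {self.ref_base!r}"
            )
        if self.alt_base not in BASES or self.alt_base == self.ref_base:
            raise InvalidMotifError(
                f"alternate base must be in ACGT and differ from the reference, "
                f"got {self.ref_base!r}>{self.alt_base!r}"
            )
        for flank in (self.five_prime, self.three_prime):
            if flank not in BASES:
                raise InvalidMotifError(f"flanking base {flank!r} not in ACGT")

    @property
    def substitution(self) -> str:
        return f"{self.ref_base}>{self.alt_base}"

    @property
    def label(self) -> str:
        """COSMIC-style label, e.g. ``A[C>A]A``."""
        return f"{self.five_prime}[{self.substitution}]{self.three_prime}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def motif_index(m: MotifClass) -> int:
    """Rank of *m* in the canonical COSMIC ordering (0..95)."""
    sub = SUBSTITUTIONS.index(m.substitution)
    return 16 * sub + 4 * BASES.index(m.five_prime) + BASES.index(m.three_prime)


def all_motifs() -> list[MotifClass]:
    """The 96 motif classes in canonical order."""
    out = []
    for sub in SUBSTITUTIONS:
        ref, alt = sub.split(">")
        for five in BASES:
            for three in BASES:
                out.append(MotifClass(ref, alt, five, three))
    return out


MOTIF_ORDER: tuple[str, ...] = tuple(m.label for m in all_motifs())


def parse_motif_label(label: str) -> MotifClass:
    """Parse a ``A[C>A]A``-style label into a :class:`MotifClass`."""
    match = _LABEL_RE.match(label.strip().upper().replace("→", ">"))
    if match is None:
        raise InvalidMotifError(f"cannot parse motif label {label!r}")
    five, ref, alt, three = match.groups()
    return MotifClass(ref, alt, five, three)


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))
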