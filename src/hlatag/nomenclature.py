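"""HLA allele nomenclature at two- and four-digit resolution.

HLA alleles are written ``LOCUS*FF`` (intermediate / antigen-level
resolution, e.g. ``A*02``) or ``LOCUS*FFFF`` / ``LOCUS*FF:FF``
(high / allele-level resolution, e.g. ``A*0201`` or ``A*02:01``).
Serological typing frequently cannot distinguish certain allele groups;
such calls are represented as an :class:`AlleleSet` of alternatives, and
a prediction is credited if it matches any member of the set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

LOCI = ("A", "B", "C", "DRB1", "DQB1", "DPB1")

INTERMEDIATE = "intermediate"
HIGH = "high"


class NomenclatureError(ValueError):
    """Raised for malformed allele text or locus/resolution mismatches."""


@dataclass(frozen=True, order=True)
class HlaAllele:
    """A locus-qualified HLA allele.

    ``field2 is None`` means intermediate (two-digit) resolution;
    otherwise the allele is at high (four-digit) resolution.
    """

    locus: str
    field1: str
    field2: str | None = None

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise NomenclatureError(f"unknown HLA locus {self.locus!r}")
        if not (len(self.field1) == 2 and self.field1.isdigit()):
            raise NomenclatureError(f"bad allele field {self.field1!r}")
        if self.field2 is not None and not (
            len(self.field2) == 2 and self.field2.isdigit()
        ):
            raise NomenclatureError(f"bad allele field {self.field2!r}")

    @property
    def resolution(self) -> str:
        return INTERMEDIATE if self.field2 is None else HIGH

    def __str__(self) -> str:
        if self.field2 is None:
            return f"{self.locus}*{self.field1}"
        return f"{self.locus}*{self.field1}:{self.field2}"


def parse_allele(text: str, locus: str | None = None) -> HlaAllele:
    """Parse allele text such as ``A*0201``, ``A*02:01`` or bare ``0201``.

    Colon and no-colon spellings parse identically. A bare digit string
    requires ``locus``; a ``LOCUS*...`` spelling must agree with ``locus``
    when both are given.
    """
    text = text.strip()
    if "*" in text:
        loc, _, rest = text.partition("*")
        if locus is not None and loc != locus:
            raise NomenclatureError(
                f"allele {text!r} does not belong to locus {locus}"
            )
        locus = loc
    else:
        rest = text
    if locus is None:
        raise NomenclatureError(f"no locus given for allele text {text!r}")
    digits = rest.replace(":", "")
    if not digits.isdigit():
        raise NomenclatureError(f"malformed allele text {text!r}")
    if len(digits) == 2:
        return HlaAllele(locus, digits)
    if len(digits) == 4:
        return HlaAllele(locus, digits[:2], digits[2:])
    raise NomenclatureError(
        f"allele text {text!r} has {len(digits)} digits; expected 2 or 4"
    )


def to_intermediate(allele: HlaAllele) -> HlaAllele:
    """Reduce a four-digit allele to its two-digit group (idempotent)."""
    if allele.field2 is None:
        return allele
    return HlaAllele(allele.locus, allele.field1)


@dataclass(frozen=True)
class AlleleSet:
    """A non-empty set of alternative alleles at one locus and resolution.

    A singleton set is an unambiguous call; a larger set records typing
    ambiguity that a downstream match credits to any alternative.
    """

    alternatives: frozenset[HlaAllele]

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise NomenclatureError("AlleleSet must be non-empty")
        loci = {a.locus for a in self.alternatives}
        resolutions = {a.resolution for a in self.alternatives}
        if len(loci) != 1 or len(resolutions) != 1:
            raise NomenclatureError(
                "AlleleSet alternatives must share one locus and resolution"
            )

    @classmethod
    def of(cls, *alleles: HlaAllele) -> "AlleleSet":
        return cls(frozenset(alleles))

    @classmethod
    def parse(cls, text: str, locus: str | None = None) -> "AlleleSet":
        """Parse ``A*0201`` or an ambiguity set ``A*0201/A*0205``."""
        parts = [p for p in text.strip().split("/") if p]
        return cls(frozenset(parse_allele(p, locus) for p in parts))

    @property
    def locus(self) -> str:
        return next(iter(self.alternatives)).locus

    @property
    def resolution(self) -> str:
        return next(iter(self.alternatives)).resolution

    @property
    def is_ambiguous(self) -> bool:
        return len(self.alternatives) > 1

    def to_intermediate(self) -> "AlleleSet":
        return AlleleSet(frozenset(to_intermediate(a) for a in self.alternatives))

    def at_resolution(self, resolution: str) -> "AlleleSet":
        if resolution == INTERMEDIATE:
            return self.to_intermediate()
        if resolution == HIGH and self.resolution != HIGH:
            raise NomenclatureError(
                "cannot raise an intermediate-resolution set to high resolution"
            )
        return self

    def __iter__(self) -> Iterable[HlaAllele]:
        return iter(sorted(self.alternatives))

    def __len__(self) -> int:
        return len(self.alternatives)

    def __str__(self) -> str:
        return "/".join(str(a) for a in sorted(self.alternatives))


def alleles_match(pred: HlaAllele, truth: AlleleSet) -> bool:
    """True iff ``pred``, reduced to the truth's resolution, matches any
    alternative in the truth set.

    ``pred`` must be at a resolution at least as fine as the truth's.
    """
    if pred.locus != truth.locus:
        raise NomenclatureError(
            f"locus mismatch: prediction {pred.locus}, truth {truth.locus}"
        )
    if truth.resolution == HIGH and pred.resolution != HIGH:
        raise NomenclatureError(
            "prediction is coarser than the truth it is scored against"
        )
    if truth.resolution == INTERMEDIATE:
        pred = to_intermediate(pred)
    return pred in truth.alternatives
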