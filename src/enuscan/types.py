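"""Domain types shared across the toolkit.

The screen's data flow is: per-sample variant call tables (one affected,
one unaffected exome), a genotype/phenotype panel of family members typed
for candidate variants, and peptide sequences with protein-level mutation
specifications. Every record here is a plain frozen dataclass; parsing and
validation against file formats live in :mod:`enuscan.io`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence


class LocationClass(str, enum.Enum):
    """Genomic context of a variant, as annotated upstream (consumed, not computed)."""

    EXONIC = "exonic"
    INTRONIC = "intronic"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    SPLICING = "splicing"
    INTERGENIC = "intergenic"


#: Location classes counted as lying inside a gene region.
GENIC_CLASSES = frozenset(
    {
        LocationClass.EXONIC,
        LocationClass.INTRONIC,
        LocationClass.UTR5,
        LocationClass.UTR3,
        LocationClass.SPLICING,
    }
)


class EffectClass(str, enum.Enum):
    """Coding consequence; meaningful only for exonic variants."""

    NONSYNONYMOUS = "nonsynonymous"
    SYNONYMOUS = "synonymous"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    UNKNOWN = "unknown"


class GenotypeCall(str, enum.Enum):
    """Sanger genotype of one mouse at one candidate variant.

    The three-symbol alphabet mirrors the panel notation: ``+`` carrier,
    ``-`` non-carrier, ``?`` not sequenced. Unicode minus (U+2212) is
    normalised to the ASCII hyphen-minus before validation.
    """

    CARRIER = "+"
    NONCARRIER = "-"
    MISSING = "?"

    @classmethod
    def parse(cls, symbol: str) -> "GenotypeCall":
        sym = symbol.strip().replace("−", "-")
        try:
            return cls(sym)
        except ValueError:
            raise ValueError(
                f"illegal genotype symbol {symbol!r}; expected one of '+', '-', '?'"
            ) from None


class Phenotype(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"


class Laterality(str, enum.Enum):
    """Limb expressivity of the polydactyly phenotype."""

    BILATERAL = "bilateral"
    UNILATERAL = "unilateral"
    NONE = "none"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class VariantCall:
    """One called variant with read support and annotation.

    Coordinates are 1-based inclusive (VCF convention). ``fraction`` is the
    allelic fraction alt_reads/depth; for a germline heterozygote it is
    expected near 0.5. When a source table prints only fraction and depth,
    ``alt_reads`` is derived as round(fraction * depth).
    """

    chrom: str
    start: int
    end: int
    ref: str
    alt: str
    depth: int
    alt_reads: int
    fraction: float
    location_class: LocationClass
    effect_class: EffectClass = EffectClass.UNKNOWN
    gene: str = ""
    validated_by_sanger: Optional[bool] = None
    present_in_backcross_affected: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.depth < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction {self.fraction} outside [0, 1]")
        if self.depth > 0 and abs(self.fraction - self.alt_reads / self.depth) > 0.5 / self.depth:
            raise ValueError(
                f"fraction {self.fraction} inconsistent with "
                f"{self.alt_reads}/{self.depth} beyond rounding"
            )

    @property
    def variant_id(self) -> str:
        return self.gene if self.gene else f"{self.chrom}:{self.start}"

    @property
    def allele_key(self) -> tuple:
        """Exact matching key used for presence-in-another-sample tests."""
        return (self.chrom, self.start, self.ref, self.alt)

    @property
    def is_genic(self) -> bool:
        return self.location_class in GENIC_CLASSES


@dataclass(frozen=True)
class PanelMouse:
    """One family member typed on the candidate panel."""

    mouse_id: str
    phenotype: Phenotype
    generation: Optional[str] = None
    laterality: Laterality = Laterality.UNKNOWN


@dataclass
class SegregationPanel:
    """Mice x candidate-variants genotype matrix.

    ``calls[variant_id]`` holds one :class:`GenotypeCall` per mouse, aligned
    with ``mice`` order.
    """

    mice: Sequence[PanelMouse]
    variants: Sequence[str]
    calls: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.mice)
        for vid in self.variants:
            row = self.calls.get(vid)
            if row is None or len(row) != n:
                raise ValueError(
                    f"panel row {vid!r} has {0 if row is None else len(row)} calls, "
                    f"expected {n}"
                )
            for c in row:
                if not isinstance(c, GenotypeCall):
                    raise ValueError(f"panel row {vid!r} contains non-genotype value {c!r}")

    @property
    def n_affected(self) -> int:
        return sum(1 for m in self.mice if m.phenotype is Phenotype.AFFECTED)

    @property
    def n_unaffected(self) -> int:
        return sum(1 for m in self.mice if m.phenotype is Phenotype.UNAFFECTED)

    def row(self, variant_id: str) -> list:
        return list(self.calls[variant_id])


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals.

    Report percentages use half-up rounding (so 84.15 -> 84.2), not the
    banker's rounding of the builtin ``round``.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
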