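"""Candidate-variant filtering for a dominant exome screen.

A raw affected-exome call becomes a candidate only when it clears three
criteria: (a) more than ``min_alt_reads_exclusive`` alt-supporting reads,
(b) an allelic fraction strictly inside the heterozygous band
(``fraction_low``, ``fraction_high``) while the same allele is absent from
the unaffected exome, and (c) a functional annotation class (nonsynonymous,
stop-gain, stop-loss, or splice-site). All comparisons are strict
inequalities.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from pydantic import BaseModel, Field, model_validator

from .types import GENIC_CLASSES, EffectClass, LocationClass, VariantCall

#: Criterion labels attached to rejected variants.
SUPPORT = "support"
FRACTION_BAND = "fraction_band"
PRESENT_IN_UNAFFECTED = "present_in_unaffected"
NOT_FUNCTIONAL = "not_functional"


class FilterConfig(BaseModel):
    """Thresholds for the three candidate criteria.

    Defaults mirror the screen's filter: supporting reads > 4 and allelic
    fraction strictly between 0.3 and 0.8, absent from the unaffected
    sample, functional annotation class.
    """

    min_alt_reads_exclusive: int = Field(default=4, ge=0)
    fraction_low: float = Field(default=0.3, ge=0.0)
    fraction_high: float = Field(default=0.8, le=1.0)
    functional_effects: FrozenSet[EffectClass] = frozenset(
        {EffectClass.NONSYNONYMOUS, EffectClass.STOPGAIN, EffectClass.STOPLOSS}
    )
    functional_locations: FrozenSet[LocationClass] = frozenset({LocationClass.SPLICING})
    unaffected_noise_floor: float = Field(default=0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _band_ordered(self):
        if not self.fraction_low < self.fraction_high:
            raise ValueError("fraction_low must be < fraction_high")
        return self

    model_config = {"frozen": True}


@dataclass
class CandidateSet:
    """Partition of the input calls into candidates and labelled rejects."""

    candidates: List[VariantCall]
    rejected: List[Tuple[VariantCall, Set[str]]]

    def __len__(self) -> int:
        return len(self.candidates) + len(self.rejected)


def passes_support(v: VariantCall, cfg: Optional[FilterConfig] = None) -> bool:
    """Criterion (a): strictly more alt-supporting reads than the threshold."""
    cfg = cfg or FilterConfig()
    return v.alt_reads > cfg.min_alt_reads_exclusive


def passes_fraction_band(v: VariantCall, cfg: Optional[FilterConfig] = None) -> bool:
    """Criterion (b), band part: allelic fraction strictly inside (low, high)."""
    cfg = cfg or FilterConfig()
    return cfg.fraction_low < v.fraction < cfg.fraction_high


def absent_in_unaffected(
    v: VariantCall,
    unaffected_calls: Iterable[VariantCall],
    cfg: Optional[FilterConfig] = None,
) -> bool:
    """Criterion (b), absence part: no matching allele in the unaffected sample.

    Matching is on the exact allele key (chrom, start, ref, alt); a match
    only counts as "present" when its fraction exceeds the noise floor
    (default 0, i.e. any call counts).
    """
    cfg = cfg or FilterConfig()
    key = v.allele_key
    return not any(
        u.allele_key == key and u.fraction > cfg.unaffected_noise_floor
        for u in unaffected_calls
    )


def is_functional(v: VariantCall, cfg: Optional[FilterConfig] = None) -> bool:
    """Criterion (c): splice-site, or exonic with a protein-changing effect."""
    cfg = cfg or FilterConfig()
    if v.location_class in cfg.functional_locations:
        return True
    return (
        v.location_class is LocationClass.EXONIC
        and v.effect_class in cfg.functional_effects
    )


def apply_criteria(
    affected_calls: Sequence[VariantCall],
    unaffected_calls: Sequence[VariantCall],
    cfg: Optional[FilterConfig] = None,
) -> CandidateSet:
    """Partition the affected-exome calls into candidates and labelled rejects.

    Deterministic and order-preserving: every input call appears exactly
    once, either in ``candidates`` or in ``rejected`` with the set of
    criteria it failed.
    """
    cfg = cfg or FilterConfig()
    # index the unaffected sample once; absence checks are then O(1)
    present = {
        u.allele_key for u in unaffected_calls if u.fraction > cfg.unaffected_noise_floor
    }
    candidates: List[VariantCall] = []
    rejected: List[Tuple[VariantCall, Set[str]]] = []
    for v in affected_calls:
        failed: Set[str] = set()
        if not passes_support(v, cfg):
            failed.add(SUPPORT)
        if not passes_fraction_band(v, cfg):
            failed.add(FRACTION_BAND)
        if v.allele_key in present:
            failed.add(PRESENT_IN_UNAFFECTED)
        if not is_functional(v, cfg):
            failed.add(NOT_FUNCTIONAL)
        if failed:
            rejected.append((v, failed))
        else:
            candidates.append(v)
    return CandidateSet(candidates=candidates, rejected=rejected)


@dataclass
class CallSummary:
    n_total: int
    by_location: dict
    by_effect: dict
    genic_fraction: Optional[float]


def summarize_calls(calls: Sequence[VariantCall]) -> CallSummary:
    """Counts per location/effect class and the share of calls in gene regions.

    The gene-region share is (exonic + intronic + UTR + splicing) / total;
    it is ``None`` for an empty input.
    """
    by_loc = Counter(v.location_class for v in calls)
    by_eff = Counter(
        v.effect_class for v in calls if v.location_class is LocationClass.EXONIC
    )
    n = len(calls)
    genic = sum(by_loc[c] for c in GENIC_CLASSES)
    return CallSummary(
        n_total=n,
        by_location={c: by_loc.get(c, 0) for c in LocationClass},
        by_effect={c: by_eff.get(c, 0) for c in EffectClass},
        genic_fraction=(genic / n) if n else None,
    )
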