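"""Penetrance and expressivity arithmetic for carrier cohorts.

Penetrance is the fraction of genotyped carriers of an allele expressing
the phenotype; expressivity is summarised here as the unilateral/bilateral
composition of the limb phenotype among affected animals. Report
percentages are rounded half-up to one decimal; full precision is retained
internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

from scipy.stats import binomtest

from .types import (
    GenotypeCall,
    Laterality,
    PanelMouse,
    Phenotype,
    SegregationPanel,
    round_half_up,
)


@dataclass
class LateralityRecord:
    n_bilateral: int
    n_unilateral: int
    pct_bilateral: float
    pct_unilateral: float


@dataclass
class TraitRecord:
    n_scored: int
    n_positive: int
    pct: float


@dataclass
class PenetranceReport:
    variant_id: str
    n_carriers: int
    n_affected_carriers: int
    penetrance_pct: float
    ci95: Optional[Tuple[float, float]] = None
    laterality: Optional[LateralityRecord] = None
    traits: Dict[str, TraitRecord] = field(default_factory=dict)


def penetrance(
    panel: SegregationPanel,
    variant_id: str,
    with_ci: bool = False,
) -> PenetranceReport:
    """Penetrance of a variant over the panel's genotyped carriers.

    Missing genotypes are excluded from numerator and denominator; obligate
    carriers inferred from the pedigree are out of scope. ``with_ci`` adds a
    95% Wilson score interval.
    """
    if variant_id not in panel.calls:
        raise KeyError(f"variant {variant_id!r} not in panel")
    carriers = affected_carriers = 0
    for call, mouse in zip(panel.calls[variant_id], panel.mice):
        if call is not GenotypeCall.CARRIER:
            continue
        carriers += 1
        if mouse.phenotype is Phenotype.AFFECTED:
            affected_carriers += 1
    if carriers == 0:
        raise ValueError(
            f"no genotyped carriers of {variant_id!r}: penetrance undefined"
        )
    ci = None
    if with_ci:
        lo, hi = binomtest(affected_carriers, carriers).proportion_ci(
            confidence_level=0.95, method="wilson"
        )
        ci = (100.0 * lo, 100.0 * hi)
    return PenetranceReport(
        variant_id=variant_id,
        n_carriers=carriers,
        n_affected_carriers=affected_carriers,
        penetrance_pct=100.0 * affected_carriers / carriers,
        ci95=ci,
    )


def laterality_expressivity(cohort: Sequence[PanelMouse]) -> LateralityRecord:
    """Unilateral/bilateral composition among affected mice with known laterality."""
    n_bi = sum(1 for m in cohort if m.laterality is Laterality.BILATERAL)
    n_uni = sum(1 for m in cohort if m.laterality is Laterality.UNILATERAL)
    known = n_bi + n_uni
    if known == 0:
        raise ValueError("no mouse with known laterality")
    return LateralityRecord(
        n_bilateral=n_bi,
        n_unilateral=n_uni,
        pct_bilateral=round_half_up(100.0 * n_bi / known, 1),
        pct_unilateral=round_half_up(100.0 * n_uni / known, 1),
    )


def trait_penetrance(
    cohort: Sequence[PanelMouse],
    trait_scores: Mapping[str, bool],
) -> TraitRecord:
    """Per-trait penetrance over the scored subset of a cohort."""
    if not trait_scores:
        raise ValueError("empty trait scores")
    ids = {m.mouse_id for m in cohort}
    unknown = set(trait_scores) - ids
    if unknown:
        raise KeyError(f"trait scores for mice not in cohort: {sorted(unknown)}")
    n_scored = len(trait_scores)
    n_pos = sum(bool(v) for v in trait_scores.values())
    return TraitRecord(
        n_scored=n_scored,
        n_positive=n_pos,
        pct=round_half_up(100.0 * n_pos / n_scored, 1),
    )


def penetrance_report(
    panel: SegregationPanel,
    variant_id: str,
    laterality_cohort: Optional[Sequence[PanelMouse]] = None,
    traits: Optional[Mapping[str, Mapping[str, bool]]] = None,
    with_ci: bool = False,
) -> PenetranceReport:
    """Assemble the full report: penetrance plus optional laterality and traits."""
    report = penetrance(panel, variant_id, with_ci=with_ci)
    if laterality_cohort is not None:
        report.laterality = laterality_expressivity(laterality_cohort)
    if traits:
        cohort = laterality_cohort if laterality_cohort is not None else panel.mice
        for name, scores in traits.items():
            report.traits[name] = trait_penetrance(cohort, scores)
    return report
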