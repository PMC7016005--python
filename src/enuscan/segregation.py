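"""Pedigree co-segregation exclusion mapping.

Under a fully penetrant dominant model every affected family member must
carry the causal allele and every unaffected member must not. A candidate
variant is *excluded* as soon as one genotyped mouse contradicts that
expectation; untyped (missing) cells are skipped but tracked so that a row
with too little information can be flagged as vacuously consistent rather
than treated as support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from .types import GenotypeCall, PanelMouse, Phenotype, SegregationPanel


@dataclass
class SegregationResult:
    variant_id: str
    consistent: bool
    contradictions: List[Tuple[str, GenotypeCall, GenotypeCall]] = field(default_factory=list)
    informative_affected: int = 0
    informative_unaffected: int = 0
    vacuous: bool = False

    @property
    def n_informative(self) -> int:
        return self.informative_affected + self.informative_unaffected


@dataclass
class CosegregationReport:
    results: List[SegregationResult]
    surviving: List[str]
    excluded: List[str]


def expected_genotype(phenotype: Phenotype) -> GenotypeCall:
    return (
        GenotypeCall.CARRIER
        if phenotype is Phenotype.AFFECTED
        else GenotypeCall.NONCARRIER
    )


def evaluate_variant(
    calls: Sequence[GenotypeCall],
    mice: Sequence[PanelMouse],
    min_informative: int = 2,
    variant_id: str = "",
    tolerate_unaffected_carriers: bool = False,
) -> SegregationResult:
    """Judge one variant's genotypes against the dominant expectation.

    ``tolerate_unaffected_carriers`` switches to an incomplete-penetrance
    reading in which only affected non-carriers contradict.
    """
    if len(calls) != len(mice):
        raise ValueError(f"{len(calls)} calls for {len(mice)} mice")
    contradictions: List[Tuple[str, GenotypeCall, GenotypeCall]] = []
    inf_aff = inf_unaff = 0
    for call, mouse in zip(calls, mice):
        if call is GenotypeCall.MISSING:
            continue
        if mouse.phenotype is Phenotype.AFFECTED:
            inf_aff += 1
        else:
            inf_unaff += 1
        expected = expected_genotype(mouse.phenotype)
        if call is not expected:
            if tolerate_unaffected_carriers and mouse.phenotype is Phenotype.UNAFFECTED:
                continue
            contradictions.append((mouse.mouse_id, call, expected))
    n_inf = inf_aff + inf_unaff
    return SegregationResult(
        variant_id=variant_id,
        consistent=not contradictions,
        contradictions=contradictions,
        informative_affected=inf_aff,
        informative_unaffected=inf_unaff,
        vacuous=n_inf < min_informative,
    )


def evaluate_panel(
    panel: SegregationPanel,
    min_informative: int = 2,
    tolerate_unaffected_carriers: bool = False,
) -> CosegregationReport:
    """Evaluate every panel variant; partition into surviving and excluded.

    ``surviving`` holds variants that are consistent and informative enough;
    ``excluded`` holds contradicted variants. A consistent-but-vacuous
    variant falls in neither list (it appears only in ``results``). Multiple
    survivors are all reported; the tool never auto-picks one.
    """
    if not panel.variants:
        raise ValueError("empty panel")
    results = [
        evaluate_variant(
            panel.calls[vid],
            panel.mice,
            min_informative=min_informative,
            variant_id=vid,
            tolerate_unaffected_carriers=tolerate_unaffected_carriers,
        )
        for vid in panel.variants
    ]
    surviving = [r.variant_id for r in results if r.consistent and not r.vacuous]
    excluded = [r.variant_id for r in results if not r.consistent]
    return CosegregationReport(results=results, surviving=surviving, excluded=excluded)


def backcross_genotype(v) -> GenotypeCall:
    """Genotype of the late-backcross affected animal recorded on a variant.

    Maps the variant table's appearance-in-affected-mouse flag to a
    genotype call; an unrecorded flag is MISSING.
    """
    if v.present_in_backcross_affected is None:
        return GenotypeCall.MISSING
    return GenotypeCall.CARRIER if v.present_in_backcross_affected else GenotypeCall.NONCARRIER


def disassociation_check(genotype: GenotypeCall) -> bool:
    """Backcross disassociation verdict from a late-generation affected animal.

    After n backcrosses to wildtype, a passenger variant unlinked to the
    causal locus is expected to be lost from phenotype-selected animals;
    observing the variant absent (non-carrier) in an affected G_n mouse
    disassociates it from the phenotype. Returns True iff disassociated.
    A missing genotype is an indeterminate signal, not a verdict.
    """
    if genotype is GenotypeCall.MISSING:
        raise ValueError("genotype missing: disassociation is indeterminate")
    return genotype is GenotypeCall.NONCARRIER
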