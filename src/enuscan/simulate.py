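"""Synthetic dominant ENU-screen generator.

Emulates the full screen that the analysis modules consume: a Poisson
mutation load in the sequenced affected exome with a transition-biased
substitution spectrum, one planted dominant causal allele, Mendelian
transmission of passenger variants through the family, phenotype
assignment under a penetrance parameter, binomial sampling of
alt-supporting reads at log-uniform depth, missing-at-random Sanger
genotyping, and repeated backcrossing to wildtype for disassociation.

Every stage draws from a generator seeded from ``ScreenConfig.seed`` plus a
fixed per-stage tag, so identical configurations reproduce bit-identical
outputs regardless of call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .types import (
    EffectClass,
    GenotypeCall,
    Laterality,
    LocationClass,
    PanelMouse,
    Phenotype,
    SegregationPanel,
    VariantCall,
)

#: Transition-biased ENU substitution spectrum (A:T->G:C and A:T->T:A
#: enriched), as a normalisable weight table over strand-symmetric pairs.
DEFAULT_SUBSTITUTION_WEIGHTS: Dict[str, float] = {
    "A>G": 0.22, "T>C": 0.22,   # A:T -> G:C transitions
    "A>T": 0.12, "T>A": 0.12,   # A:T -> T:A transversions
    "G>A": 0.08, "C>T": 0.08,   # G:C -> A:T transitions
    "A>C": 0.04, "T>G": 0.04,
    "G>T": 0.02, "C>A": 0.02,
    "G>C": 0.02, "C>G": 0.02,
}

DEFAULT_GENIC_LOCATION_WEIGHTS: Dict[LocationClass, float] = {
    LocationClass.EXONIC: 0.30,
    LocationClass.INTRONIC: 0.55,
    LocationClass.UTR5: 0.05,
    LocationClass.UTR3: 0.095,
    LocationClass.SPLICING: 0.005,
}

DEFAULT_EXONIC_EFFECT_WEIGHTS: Dict[EffectClass, float] = {
    EffectClass.NONSYNONYMOUS: 0.35,
    EffectClass.SYNONYMOUS: 0.62,
    EffectClass.STOPGAIN: 0.02,
    EffectClass.STOPLOSS: 0.01,
}

_N_CHROMOSOMES = 19
_STAGE_VARIANTS, _STAGE_PANEL, _STAGE_BACKCROSS = 11, 13, 17


class ScreenConfig(BaseModel):
    """Study conditions for one simulated screen.

    Defaults reproduce the screen being emulated: an expected 160-mutation
    exome load, 97% of it genic, a 7-affected/5-unaffected Sanger panel
    whose cells are untyped at the published panel's density (110/192),
    heterozygous allelic fractions centred on 0.5 at log-uniform depth
    over [7, 244], full penetrance, and ten backcross generations.
    """

    n_variants: float = Field(default=160.0, gt=0)
    genic_fraction: float = Field(default=0.97, ge=0.0, le=1.0)
    genic_location_weights: Dict[LocationClass, float] = Field(
        default_factory=lambda: dict(DEFAULT_GENIC_LOCATION_WEIGHTS)
    )
    exonic_effect_weights: Dict[EffectClass, float] = Field(
        default_factory=lambda: dict(DEFAULT_EXONIC_EFFECT_WEIGHTS)
    )
    substitution_weights: Dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_SUBSTITUTION_WEIGHTS)
    )
    n_affected: int = Field(default=7, ge=0)
    n_unaffected: int = Field(default=5, ge=0)
    missing_prob: float = Field(default=110 / 192, ge=0.0, le=1.0)
    depth_min: int = Field(default=7, ge=1)
    depth_max: int = Field(default=244, ge=1)
    het_fraction_mean: float = Field(default=0.5, gt=0.0, lt=1.0)
    penetrance: float = Field(default=1.0, ge=0.0, le=1.0)
    phenocopy_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    bilateral_prob: float = Field(default=0.842, ge=0.0, le=1.0)
    backcross_generations: int = Field(default=10, ge=1)
    linked_recomb_fraction: float = Field(default=0.5, ge=0.0, le=0.5)
    causal_always_callable: bool = True
    callable_min_alt_exclusive: int = 4
    callable_band: Tuple[float, float] = (0.3, 0.8)
    seed: int

    @model_validator(mode="after")
    def _depth_ordered(self):
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min must be <= depth_max")
        return self


@dataclass
class ScreenTruth:
    """Ground truth for recovery tests: what was planted and who carries it."""

    causal_variant_id: str
    variant_ids: List[str]
    chrom: Dict[str, str]
    recomb_fraction: Dict[str, float]
    unaffected_carries: Dict[str, bool]
    panel_carriers: Dict[str, List[bool]] = field(default_factory=dict)


def _stage_rng(cfg: ScreenConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def _draw_depth(rng: np.random.Generator, cfg: ScreenConfig) -> int:
    lo, hi = math.log(cfg.depth_min), math.log(cfg.depth_max)
    return int(round(math.exp(rng.uniform(lo, hi))))


def _callable_het(alt: int, depth: int, cfg: ScreenConfig) -> bool:
    lo, hi = cfg.callable_band
    return alt > cfg.callable_min_alt_exclusive and lo < alt / depth < hi


def simulate_variants(
    cfg: ScreenConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[VariantCall], List[VariantCall], ScreenTruth]:
    """Generate the affected and unaffected exome call sets plus the truth.

    The affected call list is that animal's full mutation load (count ~
    Poisson(n_variants)) with exactly one planted causal variant: genic,
    exonic, protein-changing, heterozygous in the founder. The unaffected
    littermate carries each passenger independently with probability 1/2
    (linkage-adjusted on the causal chromosome) and the causal allele only
    as an unexpressing carrier under incomplete penetrance; its call set
    contains only the variants it carries. When ``causal_always_callable``
    is set, the causal variant's reads are drawn from the binomial
    conditioned on a confidently callable heterozygote, modelling a screen
    that succeeded in detecting its causal allele; passenger reads are
    always unconditional binomial draws.
    """
    rng = rng or _stage_rng(cfg, _STAGE_VARIANTS)
    n = max(1, int(rng.poisson(cfg.n_variants)))
    causal_idx = int(rng.integers(n))

    loc_classes = list(cfg.genic_location_weights)
    loc_w = np.array([cfg.genic_location_weights[c] for c in loc_classes], float)
    loc_w /= loc_w.sum()
    eff_classes = list(cfg.exonic_effect_weights)
    eff_w = np.array([cfg.exonic_effect_weights[c] for c in eff_classes], float)
    eff_w /= eff_w.sum()
    subs = list(cfg.substitution_weights)
    sub_w = np.array([cfg.substitution_weights[s] for s in subs], float)
    sub_w /= sub_w.sum()

    causal_chrom = str(rng.integers(1, _N_CHROMOSOMES + 1))

    affected: List[VariantCall] = []
    unaffected: List[VariantCall] = []
    chrom_map: Dict[str, str] = {}
    r_map: Dict[str, float] = {}
    unaff_carries: Dict[str, bool] = {}
    causal_id = ""

    # unaffected littermate: causal-bearing gamete probability conditioned
    # on the animal not expressing the phenotype
    p_causal_gamete = (
        0.5 * (1 - cfg.penetrance) / (1 - 0.5 * cfg.penetrance)
        if cfg.penetrance < 1
        else 0.0
    )
    unaff_has_causal = bool(rng.random() < p_causal_gamete)

    for i in range(n):
        is_causal = i == causal_idx
        sub = subs[int(rng.choice(len(subs), p=sub_w))]
        ref, alt = sub.split(">")
        if is_causal:
            chrom = causal_chrom
            location = LocationClass.EXONIC
            effect = EffectClass.NONSYNONYMOUS
        else:
            chrom = str(rng.integers(1, _N_CHROMOSOMES + 1))
            if rng.random() < cfg.genic_fraction:
                location = loc_classes[int(rng.choice(len(loc_classes), p=loc_w))]
            else:
                location = LocationClass.INTERGENIC
            effect = (
                eff_classes[int(rng.choice(len(eff_classes), p=eff_w))]
                if location is LocationClass.EXONIC
                else EffectClass.UNKNOWN
            )
        pos = int(rng.integers(1, 200_000_000))
        gene = f"Gene{i:04d}" if location is not LocationClass.INTERGENIC else ""

        depth = _draw_depth(rng, cfg)
        alt_reads = int(rng.binomial(depth, cfg.het_fraction_mean))
        if is_causal and cfg.causal_always_callable:
            while not _callable_het(alt_reads, depth, cfg):
                alt_reads = int(rng.binomial(depth, cfg.het_fraction_mean))
        call = VariantCall(
            chrom=chrom,
            start=pos,
            end=pos,
            ref=ref,
            alt=alt,
            depth=depth,
            alt_reads=alt_reads,
            fraction=alt_reads / depth,
            location_class=location,
            effect_class=effect,
            gene=gene,
        )
        affected.append(call)
        vid = call.variant_id
        chrom_map[vid] = chrom
        r_map[vid] = (
            0.0
            if is_causal
            else (cfg.linked_recomb_fraction if chrom == causal_chrom else 0.5)
        )
        if is_causal:
            causal_id = vid

        # transmission to the sequenced unaffected littermate
        if is_causal:
            carries = unaff_has_causal
        else:
            r = r_map[vid]
            p = (1 - r) if unaff_has_causal else r
            carries = bool(rng.random() < p) if chrom == causal_chrom else bool(rng.random() < 0.5)
        unaff_carries[vid] = carries
        if carries:
            u_depth = _draw_depth(rng, cfg)
            u_alt = int(rng.binomial(u_depth, cfg.het_fraction_mean))
            unaffected.append(
                VariantCall(
                    chrom=chrom,
                    start=pos,
                    end=pos,
                    ref=ref,
                    alt=alt,
                    depth=u_depth,
                    alt_reads=u_alt,
                    fraction=u_alt / u_depth,
                    location_class=location,
                    effect_class=effect,
                    gene=gene,
                )
            )

    truth = ScreenTruth(
        causal_variant_id=causal_id,
        variant_ids=[v.variant_id for v in affected],
        chrom=chrom_map,
        recomb_fraction=r_map,
        unaffected_carries=unaff_carries,
    )
    return affected, unaffected, truth


def simulate_panel(
    truth: ScreenTruth,
    cfg: ScreenConfig,
    variant_ids: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
) -> SegregationPanel:
    """Genotype a family panel of affected and unaffected mice.

    Each panel mouse is one meiosis from the founder (coupling phase for
    everything). An ascertained-affected mouse carries the causal allele
    with probability penetrance/(penetrance + phenocopy_rate); passenger
    variants co-transmit with the causal gamete at (1 - r) for linked
    variants and independently at 1/2 otherwise. Cells are set to MISSING
    independently at ``missing_prob``, emulating sparse Sanger follow-up.
    """
    rng = rng or _stage_rng(cfg, _STAGE_PANEL)
    vids = list(variant_ids) if variant_ids is not None else list(truth.variant_ids)
    if not vids:
        raise ValueError("no variants to genotype")

    mice: List[PanelMouse] = []
    carrier_cols: List[Dict[str, bool]] = []

    denom = cfg.penetrance + cfg.phenocopy_rate
    p_carrier_given_aff = cfg.penetrance / denom if denom > 0 else 0.0
    p_gamete_given_unaff = (
        0.5 * (1 - cfg.penetrance) / (1 - 0.5 * cfg.penetrance - 0.5 * cfg.phenocopy_rate)
        if (1 - 0.5 * cfg.penetrance - 0.5 * cfg.phenocopy_rate) > 0
        else 0.0
    )

    def transmit(has_causal_gamete: bool) -> Dict[str, bool]:
        col: Dict[str, bool] = {}
        for vid in vids:
            if vid == truth.causal_variant_id:
                col[vid] = has_causal_gamete
                continue
            r = truth.recomb_fraction.get(vid, 0.5)
            if r >= 0.5:
                col[vid] = bool(rng.random() < 0.5)
            else:
                p = (1 - r) if has_causal_gamete else r
                col[vid] = bool(rng.random() < p)
        return col

    for i in range(cfg.n_affected):
        has_causal = bool(rng.random() < p_carrier_given_aff)
        lat = (
            Laterality.BILATERAL
            if rng.random() < cfg.bilateral_prob
            else Laterality.UNILATERAL
        )
        mice.append(
            PanelMouse(
                mouse_id=f"A{i + 1}",
                phenotype=Phenotype.AFFECTED,
                generation="G2",
                laterality=lat,
            )
        )
        carrier_cols.append(transmit(has_causal))
    for i in range(cfg.n_unaffected):
        has_causal = bool(rng.random() < p_gamete_given_unaff)
        mice.append(
            PanelMouse(
                mouse_id=f"U{i + 1}",
                phenotype=Phenotype.UNAFFECTED,
                generation="G2",
                laterality=Laterality.NONE,
            )
        )
        carrier_cols.append(transmit(has_causal))

    calls: Dict[str, List[GenotypeCall]] = {}
    for vid in vids:
        row: List[GenotypeCall] = []
        for col in carrier_cols:
            if rng.random() < cfg.missing_prob:
                row.append(GenotypeCall.MISSING)
            else:
                row.append(
                    GenotypeCall.CARRIER if col[vid] else GenotypeCall.NONCARRIER
                )
        calls[vid] = row
        truth.panel_carriers[vid] = [col[vid] for col in carrier_cols]

    return SegregationPanel(mice=mice, variants=vids, calls=calls)


def simulate_backcross(
    truth: ScreenTruth,
    cfg: ScreenConfig,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, bool]:
    """Presence of every variant in a generation-n backcross affected animal.

    Simulated meiosis by meiosis: at each generation the next affected
    animal inherits the causal-bearing gamete, a still-present linked
    passenger co-transmits with probability (1 - r), an unlinked one with
    probability 1/2, and a lost variant stays lost. Analytically an
    unlinked passenger therefore persists with probability 2^(-n) and a
    linked one with (1 - r)^n; the causal allele always persists.
    """
    rng = rng or _stage_rng(cfg, _STAGE_BACKCROSS)
    present = {vid: True for vid in truth.variant_ids}
    for _ in range(cfg.backcross_generations):
        for vid in truth.variant_ids:
            if vid == truth.causal_variant_id or not present[vid]:
                continue
            r = truth.recomb_fraction.get(vid, 0.5)
            p = 0.5 if r >= 0.5 else (1 - r)
            present[vid] = bool(rng.random() < p)
    present[truth.causal_variant_id] = True
    return present


@dataclass
class SimulatedScreen:
    """All artifacts of one simulated screen run."""

    config: ScreenConfig
    affected_calls: List[VariantCall]
    unaffected_calls: List[VariantCall]
    truth: ScreenTruth
    panel: SegregationPanel
    backcross: Dict[str, bool]


def simulate_screen(
    cfg: ScreenConfig,
    panel_variant_ids: Optional[Sequence[str]] = None,
) -> SimulatedScreen:
    """Run all stages: exomes, family panel, and backcross disassociation."""
    affected, unaffected, truth = simulate_variants(cfg)
    panel = simulate_panel(truth, cfg, variant_ids=panel_variant_ids)
    backcross = simulate_backcross(truth, cfg)
    return SimulatedScreen(
        config=cfg,
        affected_calls=affected,
        unaffected_calls=unaffected,
        truth=truth,
        panel=panel,
        backcross=backcross,
    )
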