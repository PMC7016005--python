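"""The three candidate criteria and their combination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enuscan.filtering import (
    FRACTION_BAND,
    NOT_FUNCTIONAL,
    PRESENT_IN_UNAFFECTED,
    SUPPORT,
    FilterConfig,
    absent_in_unaffected,
    apply_criteria,
    is_functional,
    passes_fraction_band,
    passes_support,
    summarize_calls,
)
from enuscan.types import EffectClass, LocationClass, VariantCall


def make_call(alt_reads=8, depth=16, location=LocationClass.EXONIC,
              effect=EffectClass.NONSYNONYMOUS, chrom="1", start=100,
              ref="T", alt="C", gene="g"):
    return VariantCall(
        chrom=chrom, start=start, end=start, ref=ref, alt=alt,
        depth=depth, alt_reads=alt_reads, fraction=alt_reads / depth,
        location_class=location, effect_class=effect, gene=gene,
    )


class TestPredicates:
    @pytest.mark.parametrize("alt_reads,expected", [(7, True), (5, True), (4, False), (0, False)])
    def test_support_is_strictly_greater(self, alt_reads, expected):
        assert passes_support(make_call(alt_reads=alt_reads, depth=16)) is expected

    @pytest.mark.parametrize(
        "alt_reads,depth,expected",
        [
            (7, 16, True),      # fraction 0.4375, the mapped candidate's value
            (4, 7, True),       # 0.5714
            (6, 20, False),     # 0.3 exactly: strict lower bound
            (16, 20, False),    # 0.8 exactly: strict upper bound
            (17, 20, False),
            (7, 20, True),
        ],
    )
    def test_fraction_band_is_open(self, alt_reads, depth, expected):
        assert passes_fraction_band(make_call(alt_reads=alt_reads, depth=depth)) is expected

    def test_absent_in_empty_unaffected(self):
        assert absent_in_unaffected(make_call(), [])

    def test_present_same_allele(self):
        v = make_call()
        u = make_call(alt_reads=8, depth=16)
        assert not absent_in_unaffected(v, [u])

    def test_same_locus_different_alt_does_not_match(self):
        """Matching is on the full (chrom, start, ref, alt) key — oracle:
        exhaustive pairwise comparison over all key fields."""
        v = make_call(alt="C")
        u = make_call(alt="G")
        assert v.allele_key != u.allele_key
        assert absent_in_unaffected(v, [u])
        for field in ("chrom", "start", "ref", "alt"):
            assert v.allele_key[("chrom", "start", "ref", "alt").index(field)] == getattr(v, field)

    def test_noise_floor_ignores_low_fraction_presence(self):
        v = make_call()
        u = make_call(alt_reads=1, depth=100)
        cfg = FilterConfig(unaffected_noise_floor=0.05)
        assert absent_in_unaffected(v, [u], cfg)
        assert not absent_in_unaffected(v, [u])  # default floor 0: any call counts

    @pytest.mark.parametrize(
        "location,effect,expected",
        [
            (LocationClass.EXONIC, EffectClass.NONSYNONYMOUS, True),
            (LocationClass.EXONIC, EffectClass.STOPGAIN, True),
            (LocationClass.EXONIC, EffectClass.STOPLOSS, True),
            (LocationClass.EXONIC, EffectClass.SYNONYMOUS, False),
            (LocationClass.SPLICING, EffectClass.UNKNOWN, True),
            (LocationClass.INTRONIC, EffectClass.UNKNOWN, False),
            (LocationClass.INTERGENIC, EffectClass.UNKNOWN, False),
        ],
    )
    def test_functional_classes(self, location, effect, expected):
        assert is_functional(make_call(location=location, effect=effect)) is expected


class TestApplyCriteria:
    def test_backcross_fixture_single_candidate(self, backcross_calls):
        """Of the four backcross-checked variants only the exonic one is a
        candidate; the intronic ones are rejected as non-functional."""
        result = apply_criteria(backcross_calls, [])
        assert [v.gene for v in result.candidates] == ["Twist1"]
        assert len(result.rejected) == 3
        for v, labels in result.rejected:
            assert v.location_class is LocationClass.INTRONIC
            assert NOT_FUNCTIONAL in labels

    def test_empty_input(self):
        result = apply_criteria([], [])
        assert result.candidates == [] and result.rejected == []

    def test_failure_labels(self):
        bad = make_call(alt_reads=2, depth=16, location=LocationClass.INTRONIC,
                        effect=EffectClass.UNKNOWN)
        result = apply_criteria([bad], [bad])
        (_, labels), = result.rejected
        assert labels == {SUPPORT, FRACTION_BAND, PRESENT_IN_UNAFFECTED, NOT_FUNCTIONAL}


def _random_calls(rng, n):
    calls = []
    locations, effects = list(LocationClass), list(EffectClass)
    for i in range(n):
        depth = int(rng.integers(1, 60))
        alt = int(rng.integers(0, depth + 1))
        calls.append(
            make_call(
                alt_reads=alt, depth=depth,
                location=locations[int(rng.integers(len(locations)))],
                effect=effects[int(rng.integers(len(effects)))],
                chrom=str(rng.integers(1, 5)), start=int(rng.integers(1, 50)),
                ref=str(rng.choice(["A", "C", "G", "T"])),
                alt=str(rng.choice(["A", "C", "G", "T"])) + "X",
                gene=f"g{i}",
            )
        )
    return calls


def _reference_filter(affected, unaffected, cfg):
    """Straight-line reference: re-evaluates the three criteria independently
    per variant, with no shared indexing."""
    cand, rej = [], []
    for v in affected:
        failed = set()
        if not (v.alt_reads > cfg.min_alt_reads_exclusive):
            failed.add(SUPPORT)
        if not (cfg.fraction_low < v.fraction < cfg.fraction_high):
            failed.add(FRACTION_BAND)
        for u in unaffected:
            if (
                (u.chrom, u.start, u.ref, u.alt) == (v.chrom, v.start, v.ref, v.alt)
                and u.fraction > cfg.unaffected_noise_floor
            ):
                failed.add(PRESENT_IN_UNAFFECTED)
                break
        functional = v.location_class is LocationClass.SPLICING or (
            v.location_class is LocationClass.EXONIC
            and v.effect_class in (EffectClass.NONSYNONYMOUS, EffectClass.STOPGAIN,
                                   EffectClass.STOPLOSS)
        )
        if not functional:
            failed.add(NOT_FUNCTIONAL)
        (rej if failed else cand).append((v, failed) if failed else v)
    return cand, rej


class TestProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_inputs(self, seed):
        """apply_criteria matches the independent three-predicate scan."""
        rng = np.random.default_rng(seed)
        affected = _random_calls(rng, 1000)
        unaffected = _random_calls(rng, 300)
        cfg = FilterConfig()
        result = apply_criteria(affected, unaffected, cfg)
        ref_cand, ref_rej = _reference_filter(affected, unaffected, cfg)
        assert result.candidates == ref_cand
        assert result.rejected == ref_rej

    @pytest.mark.parametrize("seed", range(3))
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        affected = _random_calls(rng, 200)
        result = apply_criteria(affected, _random_calls(rng, 50))
        assert len(result.candidates) + len(result.rejected) == len(affected)
        recovered = list(result.candidates) + [v for v, _ in result.rejected]
        assert sorted(id(v) for v in recovered) == sorted(id(v) for v in affected)

    @given(
        seed=st.integers(0, 10_000),
        low=st.floats(0.0, 0.29),
        high=st.floats(0.81, 1.0),
        min_alt=st.integers(0, 4),
    )
    @settings(max_examples=40, deadline=None)
    def test_widening_thresholds_never_shrinks_candidates(self, seed, low, high, min_alt):
        rng = np.random.default_rng(seed)
        affected = _random_calls(rng, 60)
        base = {v.variant_id for v in apply_criteria(affected, []).candidates}
        wide_cfg = FilterConfig(
            min_alt_reads_exclusive=min_alt, fraction_low=low, fraction_high=high
        )
        wide = {v.variant_id for v in apply_criteria(affected, [], wide_cfg).candidates}
        assert base <= wide


class TestSummarize:
    def test_backcross_fixture_all_genic(self, backcross_calls):
        summary = summarize_calls(backcross_calls)
        assert summary.n_total == 4
        assert summary.genic_fraction == 1.0
        assert summary.by_location[LocationClass.INTRONIC] == 3

    def test_empty_input(self):
        summary = summarize_calls([])
        assert summary.n_total == 0
        assert summary.genic_fraction is None
        assert all(c == 0 for c in summary.by_location.values())

    def test_counts_sum_to_total(self):
        rng = np.random.default_rng(0)
        calls = _random_calls(rng, 160)
        summary = summarize_calls(calls)
        assert sum(summary.by_location.values()) == 160
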