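# Methods

## Scope and model

`enuscan` implements the analysis stages of a dominant ENU screen:
candidate filtering from affected/unaffected exome calls, pedigree
co-segregation exclusion, backcross disassociation, penetrance and
expressivity statistics, and Chou–Fasman helix-propensity scoring of
candidate missense substitutions. Read alignment, duplicate marking and
functional annotation are upstream of this package: location and effect
classes are consumed as input fields, never computed. Likelihood-based
linkage (LOD scores), genotype imputation and 3-D structure modelling are
out of scope.

The genetic model throughout is a single autosomal dominant causal allele,
heterozygous in the G1 founder, with configurable penetrance. The default
co-segregation rule assumes full penetrance (an unaffected carrier is a
contradiction); an incomplete-penetrance mode, in which only affected
non-carriers contradict, sits behind `tolerate_unaffected_carriers` and is
off by default because the emulated screen was fully penetrant.

## Candidate filter

All three thresholds are strict inequalities: supporting reads > 4, and
0.3 < alt/depth < 0.8. "Supporting reads" means alternate-allele-supporting
reads — the fraction's definition (supporting reads over locus depth)
forces this reading. Absence from the unaffected sample matches on the
exact allele key (chrom, start, ref, alt); a configurable
`unaffected_noise_floor` (default 0, i.e. any unaffected call counts as
presence) accommodates callers that emit low-fraction noise. Stop-loss is
included in the functional classes alongside stop-gain by analogy; splicing
is functional regardless of effect annotation. With several unaffected
samples the default policy is any-sample-presence excludes; pass a merged
call list to get it.

## Co-segregation and vacuity

A variant row is consistent iff no genotyped mouse contradicts the dominant
expectation. Missing cells are vacuously consistent but excluded from the
informativeness count; a row with fewer than `min_informative` (default 2)
informative genotypes is flagged `vacuous`, because an all-"?" row is
formally consistent yet evidentially empty. The report never auto-picks a
single causal variant: all non-vacuous consistent variants are listed as
surviving. On the bundled 16-candidate panel this leaves exactly one
survivor with all 12 mice informative.

The bundled panel preserves the published matrix verbatim, including its
row order (one chromosome-6 row appears out of order) and its typographic
mix of Unicode minus and ASCII hyphen, both parsed as non-carrier. Its
missing-cell tally is 110 of 192 (density ≈ 0.573), which is also the
simulator's default genotyping missingness.

## Percentages

Report percentages are rounded half-up to one decimal (full precision is
kept internally). The worked laterality composition, 16 bilateral + 3
unilateral, is the unique cohort of size ≤ 30 printing 84.2%/15.8% at that
rounding; tests verify uniqueness by brute force. One upstream source
prints 16.8% for the unilateral share in one place and 15.8% in another;
the internally consistent pair (84.2/15.8) is used, and the discrepancy is
noted here rather than resolved. Penetrance denominators are genotyped
carriers only — obligate carriers inferred from pedigree are not imputed.
The optional confidence interval is a 95% Wilson score interval.

## Helix scoring

The per-residue scale is the Chou & Fasman (1978) α-helix propensity Pα,
shipped as a versioned data file; alternative scales can be registered by
name. Profiles are ProtScale-style sliding means with uniform weights,
reported only where the full window fits (no padded edges), in protein
coordinates 1-based from the initiator methionine; peptide inputs carry an
explicit offset. The default window is 9 (the ProtScale default; the
emulated analysis did not state its window), and the impact ranking is
required by tests to be window-invariant across odd windows 5–11. Because
weights are uniform, every window covering a substituted site shifts by
exactly (Pα(alt) − Pα(ref))/window; the implementation computes both
profiles and subtracts, keeping the closed form available as an independent
cross-check. Ties in |ΔPα| are broken by smaller position, then notation.
Full Chou–Fasman secondary-structure *assignment* (nucleation/extension
calls) is deliberately not implemented — only the propensity profile the
impact ranking needs.

The bundled 13-mer `ERLSYAFSVWRME` (residues 185–197 of mouse Twist1) is
reconstructed by translating the published site-directed mutagenesis
primers; each primer carries one mutant codon, so the wildtype sequence is
spliced from the wildtype regions of two primers, and a test reproduces
that derivation with Biopython's translator.

## Synthetic screen generator

The generator emulates the study conditions of the mapped screen; defaults
are the screen's own scale and are not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `n_variants` | 160 | Poisson mean of the affected exome's mutation load |
| `genic_fraction` | 0.97 | probability a variant falls in a gene region |
| genic location split | exonic 0.30, intronic 0.55, UTR5 0.05, UTR3 0.095, splicing 0.005 | chosen once so E[nonsynonymous] ≈ 16 of 160 |
| exonic effect split | nonsyn 0.35, syn 0.62, stopgain 0.02, stoploss 0.01 | same calibration |
| substitution spectrum | transition-biased (A:T→G:C and A:T→T:A enriched) | documented, overridable table |
| `n_affected`, `n_unaffected` | 7, 5 | panel sizes |
| `missing_prob` | 110/192 | per-cell genotyping missingness |
| depth | log-uniform on [7, 244] | the observed depth range; the true per-site distribution is unknown, so this is a declared convention |
| `het_fraction_mean` | 0.5 | binomial success rate for alt reads |
| `penetrance` | 1.0 | P(carrier is affected) |
| `bilateral_prob` | 0.842 | laterality assignment among affected |
| `backcross_generations` | 10 | disassociation depth |

Transmission: every panel mouse is one meiosis from the founder, with all
founder variants in coupling phase. Passengers co-transmit with the causal
gamete at (1 − r) when linked (same chromosome; `linked_recomb_fraction`,
default 0.5 = effectively unlinked) and independently at 1/2 otherwise.
Treating G3 animals as G2-like is a simplification; extra meioses only push
passenger co-transmission closer to independence, which makes the exclusion
power estimates conservative. Backcrossing is simulated meiosis by meiosis,
so the analytic persistence rates (2⁻ⁿ unlinked, (1−r)ⁿ linked) are
emergent, not hard-coded, and tests compare the simulation against the
closed form. Phenocopies are off by default (`phenocopy_rate`) and exist
for stress-testing the co-segregation logic. Homozygous lethality of the
causal allele is noted but not simulated.

**Causal-allele callability.** Passenger alt reads are unconditional
Binomial(depth, 0.5) draws, and a realism test checks their fraction-band
mass against the exact binomial at fixed depth. An unconditional draw at
the low end of the depth range, however, frequently leaves even a true
heterozygote outside the callable band (at depth 7 only 5/7 qualifies), and
a screen whose causal allele was never called produces no family to map.
The generator therefore models a *successful* screen: with
`causal_always_callable` (default on), the planted causal variant's reads
are drawn from the binomial conditioned on a confidently callable
heterozygote (> 4 alt reads, fraction strictly inside (0.3, 0.8)). Disable
it to study detection failure itself. Under the defaults the pipeline
recovers the planted causal variant in every seed, and unlinked false
survivors appear at roughly (candidate count) × 2⁻¹² per screen.

All randomness flows from the single mandatory seed; each stage derives its
generator from (seed, stage tag), so identical configurations are
bit-reproducible regardless of stage call order.

## Numerical and interface choices

File formats go through established libraries: the minimal VCF dialect
through pysam (INFO keys DP, AO/AD, LOC, EFF, GENE; positions 1-based
inclusive), FASTA through Biopython, configs through pydantic with YAML
loading. Multi-allelic records and FORMAT genotype fields are not
supported. The TSV variant dialect prints only fraction and depth, so alt
reads are derived as round(fraction × depth); a record invariant enforces
|fraction − alt/depth| ≤ 0.5/depth, which tolerates fractions printed to
four decimals. Writers emit full-precision fractions so a write/read cycle
is bit-exact in both dialects.

## Problem sizes in the test suite

Stochastic checks use sizes chosen for tight-but-cheap Monte-Carlo error:
200 seeds for mutation-load and genic-share recovery (3 standard errors),
~16,000 passenger replicates for the 2⁻¹⁰ backcross rate, 100 seeds for
end-to-end causal recovery, 1,000-animal cohorts for penetrance estimator
recovery at p ∈ {0.25, 0.82, 1.0} (the null-allele-, S192P- and F191S-like
values). The full suite runs in well under a minute on one CPU.

## Known limitations

- Exactly one causal locus; no modifier loci, no epistasis, no strain
  background effects on penetrance.
- No genetic map: linkage is binary (same chromosome at a single r vs
  unlinked), with no position-dependent recombination.
- Read-level artifacts (mapping error, strand bias, contamination) are not
  modelled; depth and allelic fraction are the only sequencing noise.
- Passing the simulator-based tests shows the pipeline's logic is correct
  under these idealised conditions; it does not validate caller or
  annotation quality on real exomes.
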