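# Methods

## Study design and unit of analysis

The package analyses retrospective case-control cohorts: patients who
developed maculopapular exanthema (MPE) on an aromatic antiepileptic drug,
against drug-tolerant controls (same drug for ≥3 months without cutaneous
reaction). The unit of analysis is *carriage* of a two-field HLA allele —
at least one copy at the locus, homozygotes counted once — because the
hypothesised mechanism (drug binding altering the HLA peptide groove) is
present as soon as the molecule is expressed, and because published
comparisons are carrier rates, not allele doses. Alleles are handled at
two-field (protein-level) resolution; higher-field suffixes are truncated
with a warning since typing beyond the protein does not change the
molecule's binding surface.

Genotyping can fail per locus (insufficient DNA). A missing locus removes
the individual from denominators *at that locus only*, so carrier-table
denominators legitimately differ between loci within one cohort. A locus
with exactly one call present is rejected as a data error. When cohorts for
different drugs are pooled, individuals tolerant to several drugs are
counted once by sample id; an individual appearing as case for one drug and
control for another is kept as a case and the conflict logged (a reaction
to any aromatic drug makes "tolerant control" the wrong pooled label; the
choice is exposed in logs rather than silent).

## Association testing

Each allele's 2×2 carrier table is tested with the Pearson chi-square
(1 df, two-sided, no continuity correction) when every expected cell count
is at least 5, and with the Yates continuity-corrected statistic otherwise.
This explicit switch reproduces standard small-sample practice for sparse
carrier tables; Fisher's exact test is provided as a diagnostic alternative
but is not the default, being markedly more conservative on these margins.
Effect size is the cross-product odds ratio with the Woolf log-scale
interval using z = Φ⁻¹(0.975) ≈ 1.959964 (the exact quantile, not the
rounded 1.96 — at extreme upper bounds the difference is visible in the
second decimal). Tables with a zero cell get the Haldane–Anscombe +0.5 on
all four cells for both point estimate and interval, flagged in the result;
an allele carried by nobody in either arm has no defined OR and errors
instead.

Multiplicity within a locus scan is handled by Bonferroni: the corrected p
is min(1, n·p) where n is the number of *distinct alleles observed at the
locus in the cohort* (cases and controls together). Scans skip alleles with
fewer than `min_carriers` (default 3) pooled carriers as noise, but n
always counts the unfiltered enumeration, so the correction is not weakened
by filtering. Protective alleles (OR < 1) are retained.

## Screening metrics

Sensitivity and specificity come from the carrier table directly. Because
case-control sampling fixes the case fraction by design, PPV, NPV and NNT
require an external population incidence of the reaction; the package
defaults are the reported incidences of drug-induced MPE — 3.7% (CBZ),
4.8% (LTG), 9% (OXC) and 2.8% (aromatic AEDs pooled) — and are ordinary
configuration inputs. PPV/NPV follow Bayes' rule at that prevalence. NNT,
the expected number of prospective patients genotyped per case prevented
(assuming carriers avoid the drug), is 1/(prevalence × sensitivity),
reported as the ceiling — a "number needed" is conventionally the smallest
integer achieving the expectation — with the raw value kept to one decimal
alongside. Allele sets use OR-union carriage ("carries any"); an individual
is excluded from a union marker's denominators only when its status is
undecidable (no known-carrier locus and at least one untyped locus).

Full-precision PPV for the OXC DRB1*04:06 marker is 59.32%; quoting
rounded-percent sensitivity/specificity as inputs gives 59.41%, a
reporting-precision artefact worth knowing when comparing against printed
tables. Likewise the ceiling convention yields 545 where a printed table
shows 544 for the pooled DRB1*04:06 row (544.1 raw) — the one printed NNT
inconsistent with the other seven, which the ceiling reproduces exactly.

## Interaction decomposition

For two risk alleles at different loci, individuals typed at both loci are
cross-classified into four strata (both, A only, B only, neither); each
stratum's OR is taken against the double-negative reference. Two
no-interaction benchmarks are computed: multiplicative, expected joint
OR = OR_A·OR_B with interaction ratio OR_joint/(OR_A·OR_B); and additive on
the OR scale, expected joint OR = OR_A+OR_B−1 with excess risk
OR_joint−(OR_A+OR_B−1). An optional `rounding` parameter rounds the
component ORs (typically to 2 decimals) before combining, reproducing
arithmetic done on ORs as printed; analysis use defaults to full precision
(the two differ by at most one unit in the last printed decimal on the
bundled table).

The logistic model — intercept, two carrier indicators, product term — is
fitted to the grouped stratum counts by Newton/IRLS (binomial likelihood,
score tolerance 1e-10, ≤100 iterations; identical MLE to the
per-individual fit, but deterministic and cheap). With four parameters on
four strata the model is saturated, so the fitted ORs must equal the
empirical cross-product ratios; the tests exploit this identity, plus a
grid-search likelihood oracle, as independent checks. A stratum containing
only cases or only controls implies an infinite MLE; the fit is then
flagged non-converged rather than reported.

## Meta-analysis

Per-study Woolf log-ORs and variances (with +0.5 on all cells of any study
containing a zero) feed: Cochran's Q with inverse-variance weights, I² =
max(0,(Q−df)/Q)·100, and the DerSimonian–Laird moment estimator τ². Fixed-
effect pooling is Mantel–Haenszel on the *uncorrected* counts (the MH
estimator is stable under sparse cells; standard practice) with the
Robins–Breslow–Greenland variance; random-effects pooling is inverse-
variance with weights 1/(vᵢ+τ²). Model selection follows the common
systematic-review screen — random iff p_Q < 0.1 AND I² > 50% — read as a
conjunction; both sub-conditions are reported separately so a disjunctive
reading can be audited. With k = 1 both estimators reduce to the single
study's OR. Forest-table export carries per-study ORs, CIs and percent
weights under the selected model.

Because the original per-study counts behind the published forest plots
are not available as text, the meta-analysis module is validated by
construction properties (k = 1 identity, Q = 0 on identical studies, DL →
inverse-variance-fixed at τ² = 0, collapsibility for identical-margin
studies), by cross-checks against independent generic implementations
(stratified-table MH and generic DL combination), and by simulation:
pooled-OR recovery within 5% of a planted common OR, Q false-positive rate
≈ 0.1 under homogeneity, and random-effects interval coverage near 95%
under planted τ (DL coverage is known to run a little below nominal at
moderate k; the tests allow for that).

## Synthetic cohort generator

The generator emulates exactly the structure the analysis assumes:
genotypes are two independent draws per locus from a per-locus allele
frequency profile (Hardy–Weinberg, loci independent — consistent with the
risk alleles not clustering as a haplotype), with unassigned frequency mass
spread over filler alleles so draws cover a closed universe. The default
profile is shaped like southern Han Chinese class I/II frequencies (e.g.
DRB1*04:06 at 2.1%, A*24:02 at 16%). Disease status is Bernoulli from a
logistic model over carrier indicators with optional product terms;
case-control cohorts are then drawn by rejection from a large simulated
source population (default 40× the requested cohort), which reproduces
retrospective ascertainment and relies on the invariance of the OR under
outcome-dependent sampling. Baseline intercepts around −2.4 put non-carrier
risk near the reported MPE incidences. Per-locus missingness is applied
independently of genotype and outcome. Multi-study tables draw true study
log-ORs Normal(μ, τ²) and binomial carrier counts per arm; default study
sizes (≈49 cases/128 controls per study, 10 studies) mirror the published
multi-population pooling of ~488 cases and ~1277 controls.

What the generator does *not* emulate: linkage disequilibrium and
haplotype structure, population stratification, genotyping error,
covariates (age, sex, dose) correlated with outcome, and
informative missingness. Passing recovery tests therefore shows the
estimators are correct under the design assumptions, not that real cohorts
are free of confounding.

All randomness descends from a single integer seed via numpy Generators;
outputs are byte-reproducible given (config, seed).

## Problem sizes and numerical conventions

The test suite and the acceptance script use moderate, fixed problem sizes
chosen to make Monte-Carlo error small relative to the assertions: 500
replicates for meta-analysis calibration/recovery, 400 for coverage, 20–40
replicate cohorts of 2 000/arm (averaging log-effects across replicates)
for planted-effect recovery, 150 null cohorts for scan calibration. Ties
and degenerate inputs: equal-proportion tables return statistic 0 and
p = 1; the Yates correction floors |O−E|−0.5 at 0; alleles carried by
everyone (no contrast) are skipped in scans; NNT is undefined at zero
sensitivity or prevalence and errors rather than returning infinity.

## Known limitations

Crude (unadjusted) 2×2 association only, matching the design it
implements; no covariate adjustment, haplotype tests, or permutation-based
multiplicity control. Screening metrics carry no confidence intervals. The
additive benchmark is expressed on the OR scale (ORs approximate risk
ratios only for rare outcomes). Meta-analysis assumes independent studies
and carries no publication-bias diagnostics.
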