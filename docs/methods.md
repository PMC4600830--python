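# Methods

`cpgburden` implements a stratified rare-variant burden analysis for a
single coding transcript: variants are classified by coding consequence
and CpG-dinucleotide impact, pooled into per-ancestry case/control
allele-count tables, and tested with exact and Mantel-Haenszel
statistics. This note records the statistical model, the conventions and
numerical choices behind it, what the synthetic-data generator does and
does not emulate, and the design decisions that were genuinely open.

## Counting model

The unit of counting is the **allele**: a stratum of N diploid
individuals contributes 2N alleles, and a heterozygous carrier
contributes one variant allele. Distinct rare variants within a stratum
and variant class are pooled by summing carrier alleles (a collapsing
burden). Each ancestry stratum s yields a 2×2 table

|            | variant alleles | reference alleles |
|------------|-----------------|-------------------|
| cases      | a_s             | b_s = 2N_case − a_s |
| controls   | c_s             | d_s = 2N_ctrl − c_s |

Strata are never mixed across ancestry: the rarity filter and the 2×2
tables are built within each ancestry separately, and evidence is
combined across strata only through the Mantel-Haenszel machinery. This
is the standard guard against population stratification when the case
and control panels come from differently ascertained sources.

An allele-count table treats carriers as independent draws, which is
accurate in the rare-variant regime (carrier counts ≪ 2N, essentially no
homozygotes). The same convention is applied to the "CpG-affecting vs
non-affecting" split, where the 2×2 table compares the two variant
classes between cases and controls rather than variant vs reference
alleles.

## Variant classification

**Consequence.** The reference and alternate codons are translated with
the standard genetic code. Equal residues ⇒ `synonymous`; differing
non-stop residues ⇒ `nonsynonymous`; any stop involvement ⇒ `other`.
`other` is excluded from both coding classes so the class counts
partition exactly (NS + synonymous + other = all).

**CpG impact.** A single-base substitution can create or destroy only a
5′-CG-3′ dinucleotide that overlaps the substituted base, so the ±1-base
context is sufficient: with window (x, base, y), the reference window
contains a relevant CG iff (x = C and ref = G) or (ref = C and y = G),
and likewise for the alternate. Reference-only ⇒ `disrupted`,
alternate-only ⇒ `gained`, both or neither ⇒ `none` (a substitution that
shifts a CG within the window, e.g. CCG→CGG, nets to `none`: it changes
no CpG count). Because CG is its own reverse complement the rule is
strand-symmetric, which the test suite verifies exhaustively over all
192 context×SNV combinations.

Unknown context bases (an exon-edge variant whose intronic neighbour was
not supplied) are marginalised over all four bases: if every completion
yields the same label the site is classified anyway, otherwise it is
`indeterminate`. Indeterminate sites are excluded from both CpG classes
(with a logged warning) rather than guessed — so the CpG classes
partition the total only up to the indeterminate remainder. Intronic
context is always supplied as explicit flank bases, never modelled
sequence.

## Rarity filter

An observation is retained iff its reference minor-allele frequency
*within its own ancestry stratum* is strictly below the threshold
(default 1%); an unknown MAF is treated as rare and retained. The strict
"<" at the boundary is a deliberate resolution of the two natural
readings of a "<1% MAF" filter; at realistic thresholds no observation
sits exactly on the boundary, so the choice is inert in practice but is
pinned down by a test.

## Exact 2×2 statistics

Conventions deliberately match the standard exact-test implementation
(R's `fisher.test`), since that is what practitioners will compare
against:

* **Two-sided p** — minimum-likelihood rule: the sum of all
  hypergeometric point probabilities (at fixed margins) not exceeding
  that of the observed table, with a relative tie tolerance of 1e−7.
  The doubling rule is *not* used.
* **Odds ratio** — the conditional MLE ψ̂ of the Fisher noncentral
  hypergeometric likelihood, solving E[a | ψ] = a by monotone bisection
  on log ψ to a tolerance of 1e−8, with ψ̂ = +∞ (or 0) when the observed
  count sits on the upper (lower) edge of its support, and NaN when the
  margins admit a single table. The raw cross-product ratio ad/bc is
  also reported for transparency (the two differ visibly in sparse
  tables, e.g. 2.377 vs 2.378 on the flagship stratum table).
* **Confidence interval** — inversion of one-sided tail tests at
  (1 − level)/2 per tail; edge cases give one-sided intervals with a 0
  or +∞ bound.

All point probabilities are accumulated through log-factorials
(`lgamma`), so tables with ~1e5 alleles — needed by the power search —
remain exact. An exhaustive sweep in the test suite checks the p-value
against a direct enumeration oracle for every table with total n ≤ 60,
and spot checks against `scipy.stats.contingency.odds_ratio` and
`scipy.stats.fisher_exact` on larger tables.

## Mantel-Haenszel combination

The common odds ratio is OR_MH = Σ(a_s d_s / n_s) / Σ(b_s c_s / n_s)
with a Robins-Breslow-Greenland variance for the log-scale confidence
interval. The score test uses the conditional hypergeometric moments,
χ² = (|Σ a_s − Σ E_s| − ½)² / Σ V_s on 1 df, with the continuity
correction **on by default** (matching the reference implementation and
the published p = 0.03 for the all-variant combination; it is
switchable in the run configuration). A Σ b_s c_s / n_s = 0 denominator
returns +∞ rather than an error.

A known reporting quirk: recombining the printed synonymous stratum
counts yields a combined OR of ≈4.95 against a printed 4.93; that cell
is treated as irreproducible-from-counts and is not asserted anywhere.

## Power search

The power question is retrospective: holding the observed case table
fixed and the control *carrier count* fixed (not the control
frequency), find the smallest control-allele total N at which the
two-sided exact test reaches a given α (default 0.05/3 for three disease
cohorts). The count-fixed model is the one consistent with both printed
requirements (~50,000 alleles for a case-only singleton, ~100,000 with
one control carrier); holding the control *frequency* fixed instead
would contradict the second figure.

The search doubles N and then bisects, starting from a *regime floor* —
the smallest N at which the control carrier frequency does not exceed
the case frequency. Below that floor a small two-sided p would signal
control enrichment, the opposite of the question asked. Minimality is
verified directly at the returned N. Two numerical details:

* a table whose exact p equals α as a rational number is significant;
  a 1e−9 relative slack absorbs log-factorial float rounding at such
  ties (e.g. at α = 1/60 the boundary table has p = 1/60 exactly);
* the two-sided rule has a genuine discontinuity when the control arm
  is smaller than the case arm: the opposite-tail table then has the
  smaller point probability and keeps p ≈ 1. For one case carrier and
  zero control carriers the closed form N = ⌈case_total/α⌉ − case_total
  is therefore valid only for α < ½; at α = ½ exactly the two point
  probabilities tie and one extra control allele is needed. The search
  implements the two-sided rule faithfully rather than the one-sided
  shortcut.

For presentation, results are reported both exactly and rounded to two
significant figures.

## Synthetic-data generator

The generator exists so that every pipeline stage is testable without
access to restricted cohort data. It emulates:

* a coding sequence (default 1200 codons) with no internal stop and a
  binomial fraction (default 15%) of CGN arginine codons — the CpG-rich
  sites where C>T / G>A deamination substitutions concentrate — split
  into 5 exons with explicit intronic flank bases, a regulatory-domain
  region registered on the 3′ third, and a +69 nt / +23 aa alternate
  isoform offset;
* multi-stratum case/control cohorts at the study sizes (427/1214,
  1892/4300, 82/2203 individuals) with site frequencies of 0.04-0.7%, a
  configurable consequence/CpG class mix, and 20% common (>1%) sites to
  exercise the rarity filter;
* binomial(2N, freq) carrier-allele draws — cohort sizes dwarf carrier
  counts, so sampling with replacement is an adequate model of the
  rare-variant regime.

Each requested site is realized by searching the transcript near the
requested relative position for a ref/alt/context combination whose
annotation matches the requested classes exactly, making the generator
an adversarial fixture for the annotator (verified for 100% of sites in
tests). A single global seed drives everything through a documented
split (reference: seed; cohort draws: seed + 1), and generated files are
byte-identical per seed.

The generator does **not** emulate: linkage disequilibrium, sequencing
or variant-calling error, genotype-quality structure, relatedness,
de-novo vs inherited status, or cross-pipeline batch effects between
differently processed case and control panels. Passing tests therefore
demonstrate the correctness of the statistical machinery under the
stated sampling model, not robustness to those real-data artefacts — in
particular the caveat that case and control panels processed by
different pipelines can bias a burden comparison is outside what the
simulation can show.

## Interfaces and reporting conventions

Transcript input is FASTA (CDS) + exon TSV + YAML metadata (accessions,
isoform offsets, named regions, flanks); cohort input is a manifest TSV
(label, role, n_individuals) and an observations TSV (transcript_id,
pos_c, ref, alt, ctx5, ctx3, rs_id, stratum_label, role,
carrier_alleles, maf_reference; "." for missing). The TSV dialect is the
single canonical observation format; coordinates are 1-based HGVS-c.
style on the coding sequence only — no genomic coordinates are modelled,
since region bounds are published on protein accessions without a
genome build, and guessing one would add nothing the analysis uses.

Reports are byte-identical across re-runs: stable ordering, p and OR to
2 decimals, CI bounds to 1 decimal, frequencies to 2 decimals, "Inf"
literal for infinite bounds, and p < 0.01 rendered in scientific
notation with a one-decimal mantissa.

## Problem sizes used in the test suite

The exhaustive Fisher oracle sweep covers all margins with n ≤ 30 in the
unit tests and n ≤ 60 in the headline checks (~6×10⁵ tables, about a
minute on one core); the CpG oracle is exhaustive over its 192-case
space; interval-coverage and parameter-recovery properties use 100
seeded replicates at the study's stratum sizes. These sizes were chosen
to make every property check exact or tightly bounded while keeping the
default test run in the low minutes.

## Known limitations

* Only single-nucleotide substitutions are modelled — no indels, MNVs,
  or splice variants; "other" consequences are limited to stop
  gain/loss (start-loss is not treated specially).
* The CpG rule is deliberately local (±1 base); it cannot see CpG
  islands or methylation state, and is not intended to.
* The Mantel-Haenszel test assumes a common odds ratio across strata;
  no homogeneity (Breslow-Day) test is provided.
* Exact mid-p variants and permutation/SKAT-style burden tests are out
  of scope.
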