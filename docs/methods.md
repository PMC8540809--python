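# Methods

## The analysis model

`nafcflow` links the transcriptomic response of *Pseudomonas* cultures to the
chemistry of the naphthenic acid fraction compounds (NAFCs) they degrade.
The chain of inference is:

1. **Up-regulated gene sets.** The RNA-seq libraries are SSH (suppression
   subtractive hybridization) tester libraries, i.e. already enriched for
   transcripts up-regulated on NAFC exposure. No differential-expression
   test is performed; instead, a gene counts as up-regulated in a culture
   when its library coverage passes the retention rule
   *covered_bases ≥ 150 **or** covered_bases/length ≥ 0.9*. The rule is a
   disjunction by design: short genes can never reach 150 covered bases but
   are rescued by the fractional clause.
2. **Expression values.** TPM with the standard length-normalized-rate
   definition: rate_g = count_g/length_g, tpm_g = 10⁶·rate_g/Σrates over
   retained genes. For the co-culture library, which is aligned to a
   composite two-strain genome, the default normalizes **within each
   strain** so that per-organism TPM values are comparable between pure and
   co-culture libraries; a `joint` mode normalizes the library as a whole.
   Consortium-vs-pure comparisons use M = log₂((t_c+ψ)/(t_i+ψ)) and
   A = ½·log₂((t_c+ψ)(t_i+ψ)) with pseudocount ψ = 0.5 TPM by default
   (configurable); ψ > 0 is required because SSH libraries contain genes
   absent from one condition. The identity log₂(t_c+ψ) = A + M/2 holds
   exactly and is property-tested. Pathway ranking counts member genes with
   M > 0 (or < 0), descending, ties broken lexicographically on pathway ID
   for deterministic output.
3. **Enzyme annotation.** EC numbers from two sources are consolidated by
   union with a per-EC agreement flag (default; keeps recall and preserves
   evidence) or by intersection. Partial ECs (`1.1.-.-`) are counted in the
   top-level class census — their leading digit is unambiguous — but are
   excluded from reaction matching, where only complete four-field ECs have
   an unambiguous lookup. The class census counts **genes**, at most once
   per top-level class per gene. GO over-representation uses the exact
   hypergeometric upper tail P(X ≥ k) with BH adjustment across tested
   terms; the GeneRatio column is k/K, with k/n as `de_ratio`.
4. **Substrate chemistry.** Complete ECs are matched against a local
   reaction store (one row per reaction substrate), substrates resolved to
   molecular formulas via a local compound store, and classified into the
   eight heteroatom classes — the 2³ presence patterns of N, O, S. Class
   distributions count **distinct CIDs** (a compound reached via several
   ECs counts once). Distributions of two cultures are compared with
   Pearson's chi-square on the 2×k table, no continuity correction,
   zero-total columns dropped (df = k−1 over usable classes); expected
   counts below 5 raise a warning, not an error. Only reaction substrates
   are fetched; product sides and reaction reversibility are out of scope.
5. **Pathway presence.** Every (CID, EC) pair is interrogated against
   pathway step sets; pairs split into a with-pathway table (one row per
   matching pathway) and a without-pathway table — a partition of the input
   pairs, property-tested. Presence for (culture, heteroatom group,
   pathway) requires ≥ 1 supporting hit by default (configurable); the four
   display panels are N+NO, O, NOS and S+SO, with CH and NS routed to a
   residual panel rather than dropped.

### Formula conventions

Formulas are neutral Hill-style strings over C, H, N, O, S only; any other
element is an error rather than silently dropped, which keeps class
assignment sound. DBE = c + ½(n−h) + 1 — divalent O and S contribute
nothing. Half-integral DBE (odd n+h, radical/ion compositions) is returned
unrounded and can be flagged via `has_integral_dbe`. Species labels use
element order N, O, S and omit zero counts and the subscript 1 (`NO`, not
`N1O1`); a sulfur-first habit like "S2O3" is therefore canonicalized to
`O3S2`. A strict carbon-range helper flags compounds outside 7–26 carbons
without dropping them, since classic-NA surveys extend from 5 to 25.

## The synthetic-data generator

The generator emulates the inputs of a two-strain (+ co-culture) study:
per-strain gene catalogs, SSH library counts and coverage, two-source EC/GO
annotations with partial agreement, a reaction/compound/pathway store, and
before/after MS feature tables. One integer seed drives a root
`SeedSequence`; each output draws from its own named spawn-key stream, so
the same seed yields byte-identical bundles and adding a new output never
perturbs existing ones.

Default problem sizes, chosen so the full suite runs in seconds: 200 genes
per strain (lengths 200–3000 bp), 25 % of genes up-regulated per culture
(disjoint sets across the three cultures), 40 distinct ECs per pure culture
and 60 for the co-culture (the co-culture expresses the largest gene-product
set), 1–3 substrates per reaction, 25 pathways, 30 GO terms.

Planted effects (the study conditions):

- **MS tables:** 131 unique classic NAs totalling 28.2 mg/L in the
  untreated sample, carbons 5–25 and DBE 1–10 weighted toward C16 and
  DBE 4; classic-NA removal of 11 %, 12 % and 31 % for the two pure
  cultures and the co-culture. Removal is exact in aggregate — per-compound
  truncated-normal factors are rescaled so the classic total
  after treatment is exactly (1−r)× the total before — while individual
  compounds vary. Species S, N₂S₃, NOS₂ and N₂OS₂ are completely removed;
  O₇, O₈, N₂O₂ and O₃S₂ appear only after treatment. Concentration noise is
  a truncated normal (σ = 0.15 of the mean, floored away from zero); no
  empirical noise model exists for these tables, so this is a documented
  stand-in.
- **Substrate class mixture:** pure cultures draw substrate classes iid
  from (CH .01, N .06, NS .02, NO .30, O .46, NOS .04, S .06, SO .05) —
  O+NO = 0.76, matching the dominance of oxygenated classes among degraded
  compounds — and the co-culture from (CH .005, N .08, NS .005, NO .18,
  O .66, NOS .06, S 0, SO .01), i.e. a shift toward O and complete loss of
  the S/SO classes, the qualitative signature of consortial metabolism.
  Because every substrate compound is unique to its reaction, distinct-CID
  class counts are multinomial conditional on their total, which keeps the
  chi-square comparison calibrated; a design-stage Monte-Carlo check of
  these defaults measured type-I error 0.039 and power 0.94 at α = 0.05.
  The three cultures' EC sets are disjoint, so the two samples entering
  each comparison are independent.
- **Pathways:** one pathway whose steps come only from co-culture O-class
  pairs (present only in the co-culture's O panel), one from pure-culture
  O-class pairs only, and one with an N/NO-class step from every culture;
  remaining pathways mix real pairs with decoy steps no culture reaches.
- **Annotations:** each (gene, term) record appears in both sources with
  probability 0.7, else in exactly one — partial cross-source agreement
  whose union recovers the planted truth. One GO term per culture is
  planted enriched (12 of its 15 members drawn from that culture's
  up-regulated set).

A `null_config`/`null_fixture` variant removes every planted effect
(identical class mixture for all cultures, zero removal, no
removed/produced species, no enriched terms) and is used for calibration:
over 200 null draws of the class-count process the chi-square type-I error
must sit inside the binomial 95 % CI of α = 0.05, and the planted shift must
be detected with power ≥ 0.8 at the default sizes.

### What the fixtures do not emulate

Raw reads, alignment and duplicate marking; mass-spectral peak picking and
formula assignment from m/z; SSH subtraction chemistry; correlated
annotation errors between sources; shared ECs between cultures (real pure
and co-cultures share genes, which would correlate the chi-square samples);
and any toxicity endpoint. Passing recovery tests therefore demonstrates
correctness of the analytics on well-formed inputs, not robustness to
upstream measurement artifacts.

## Numerical and design notes

- Hypergeometric p-values are discrete and hence super-uniform under the
  null; calibration tests check validity (no anti-conservatism, one-sided
  KS) rather than exact uniformity, which no discrete statistic can attain.
- A classic NA with a given DBE is uniquely determined by its carbon count,
  so at most 21 unique formulas (C5–C25) can share one DBE value; modal
  shares of the classic-NA population are therefore capped by formula
  uniqueness, and the generator's C16/DBE-4 weighting respects that cap.
- Interval arithmetic is 0-based half-open everywhere; GFF3 (1-based,
  closed) is converted at the reader boundary. The interval-union coverage
  helper is equality-tested against a per-base marking oracle.
- Percentages are kept unrounded in the library; display rounding happens
  only at the CLI/reporting layer.
- `scripts/acceptance.py` runs the default conditions end to end (400
  genes, ~280 substrate compounds, 131 classic NAs, 25 pathways) in about a
  second; the statistical calibration test uses 200 null and 200 effect
  draws of the class-count process.

## Known limitations

The EC→substrate mapping trusts the local reaction store; no gap-filling,
reversibility or flux reasoning is attempted. The unspecified
molecular-descriptor filter applied to candidate substrates is exposed as a
configurable hook (carbon range, DBE range, required heteroatoms), default
off. GO terms are used as flat sets — no DAG propagation. Pathway presence
is qualitative (≥ 1 supporting pair) and says nothing about completeness of
the pathway's step set.
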