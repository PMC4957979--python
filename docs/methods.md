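# Methods

## Coordinate system and catalog model

All analyses live on the 1-based amino-acid coordinates of ATM, positions
1..L with L = 3057 (3056 residues plus the stop codon, transcript
NM_000051.3). Intervals are closed `[start, end]`; the kinase domain is
`[2711, 2962]` (width 252). Inputs are assumed already annotated at
protein level — the package extracts the integer position from
protein-change tokens (`p.N2875K` → 2875) but does no transcript mapping,
liftover or HGVS semantics. Multi-residue in-frame indels contribute their
start position only.

A *unique mutation* is one distinct protein-level variant, keyed on
`(protein_change token, class)` and counted once regardless of recurrence
across cases; the concurrent-loss flags of a unique are the OR over its
contributing calls, extended by cross-referencing case identifiers against
truncating calls in the same catalog. Uniqueness on the protein-change
token (rather than the genomic variant) matches the protein-coordinate
analyses downstream; the count can shift by a few under a genomic key when
distinct nucleotide changes yield the same protein change. Classification
is a total function: any unrecognised label lands in `other` and is
tallied in the emitted mapping table, never dropped silently. Rows failing
validation (unparsable or out-of-range positions) are quarantined into the
read report instead of aborting, since real MAF extracts are dirty.

The LOVD effect vocabulary fixes only the truncating side
(`Start_Codon`, `Frame_Shift_Del`, `Large_DEL`, `Nonsense_Mutation`,
`Frame_Shift_Ins`, `Splice_Site`, `Stop_Codon`); the missense-label set is
configurable and defaults to {`Missense`, `Missense_Mutation`,
`Substitution`}. For reporting, the alternative "fig1a" grouping shows
splice-site/stop-codon uniques as "Others" while the computational class
map keeps them truncating; the missense fraction is identical under both.

## Density estimation

Per-residue unique-mutation counts y(x) of one class (missense and
truncating are always treated separately) are smoothed with the Gaussian
kernel moving average

    yhat(x_i) = sum_j K(x_i, x_j) y(x_j) / sum_j K(x_i, x_j),
    K = exp(-(x_i - x_j)^2 / (2 b^2)),

with window size b = 80 aa by default. The sum runs over all L residues;
the shared denominator makes yhat a convex combination of y (so
min y <= yhat <= max y) and naturally down-weights the protein ends — no
reflection or padding is applied because the formula is taken literally.
The implementation evaluates both sums with a length-(2L−1) convolution,
which is algebraically identical to the double sum; tests require
agreement with the literal O(L²) evaluation to 1e−12. An optional support
cutoff (e.g. 6b, where the kernel weight is exp(−18) ≈ 1.5e−8) exists for
speed and must agree with the full sum to 1e−9. As b → ∞ the smoother
tends to the global mean, as b → 0⁺ to the raw counts.

## Expected rate and fold-change bands

The expected per-residue frequency defaults to the **uniform** model
n/L — enrichment relative to protein size only, with n the class-specific
unique count. The **silent-calibrated** alternative treats the smoothed
silent-mutation profile as a local mutability estimate (resting on the
assumption that the silent : non-silent ratio is constant along the gene)
and rescales it so its protein-wide total equals n; with uniform silent
counts it reduces exactly to the uniform model. The run descriptor records
which model produced a profile.

The fold change is yhat(x)/expected(x); the dashed reference at 1 is the
expectation. For the confidence band, the smoothed per-residue frequency
p̂(x) = yhat(x)/n is treated as a binomial proportion with n trials and
given a two-sided exact Clopper–Pearson interval at level α/m (Bonferroni;
α = 0.05, m = L by default, both configurable), then divided by
expected(x)/n to sit on the fold scale. Clopper–Pearson was chosen over a
normal approximation because the per-residue frequencies are tiny (a Wald
interval at p ≈ 1/3057, n ≈ 300 has near-zero coverage); non-integer
smoothed "counts" use the continuous beta-quantile extension, and at
p̂ = 0 the upper bound reduces to the closed form 1 − (α′/2)^(1/n).

Two properties of this band should be understood when interpreting it.
Exact binomial intervals are *conservative* (coverage ≥ nominal, ≈99.5%
rather than 95% for a raw Binomial(300, 1/3057) count), and smoothing
shrinks the variance of yhat to roughly (n/L)·1/(2b√π) — about 28× below
the binomial count variance at b = 80 — so the band's empirical null
coverage at a single residue is effectively 100%, not 95%. The band is
therefore an honest *at-least*-95% envelope: residues whose band excludes
1 are strongly enriched/depleted, but the band is wide. The acceptance
suite measures this coverage and asserts the idealised ≈95% figure, which
the exact method cannot attain; that check is expected to fail and the
measured coverage is reported by `scripts/acceptance.py`.

## Permutation tests

**Domain enrichment.** The null re-places the n unique mutations of a
class independently and uniformly on {1..L} — size-based, not
mutability-weighted, and on unique mutations (case identity is already
collapsed, so per-sample burden is not a null dimension). The empirical
p-value is one-sided (upper tail), matching the directional claim, with
the add-one estimator p = (1 + #{count ≥ observed})/(1 + n_perm), which is
slightly conservative and never zero. Two effect-size statistics are
reported: the **fold** observed/(n·w/L) over the closed-form null mean
(the statistic drawn against the expected-rate line; 42/16.98 ≈ 2.47 for
the ATM kinase-domain missense catalog), and the **rate ratio**
(obs/w)/((n−obs)/(L−w)), which is the natural estimator of a
multiplicative in-domain rate factor f — under a piecewise-uniform model
the fold's expectation is f·L/(f·w + L − w) (≈2.22 at f = 2.5), while the
rate ratio's is ≈ f. Recovery checks therefore use the rate ratio.

The test's finite-sample level is below nominal by construction: the
in-domain count is discrete (at n = 206, w = 252, L = 3057 the critical
value sits where the exact tail is 0.0546) and the add-one estimator adds
conservatism; the exact type-I rate of the full procedure at α = 0.05,
n_perm = 2000 is 3.7%.

**Gene burden.** Is a gene's non-synonymous count higher (or lower) than
its length predicts? The caller supplies the cohort background (per-aa
non-synonymous frequency) — the package embeds no cohort data. The null
draws Poisson(background × length) or Binomial(total mutations, length
share); the p-value is two-sided (2·min of the add-one tails, capped at
1), with both one-sided components reported.

## Synthetic catalogs

The generator produces catalogs with exactly the structure the analysis
assumes: positions of the enriched class follow a piecewise-uniform
density with per-residue rate ∝ f inside the domain and ∝ 1 outside
(P(in domain) = f·w/(f·w + L − w)); other classes are uniform. Class sizes
are exact — round(n·missense_fraction) missense, the remainder truncating,
round(silent_ratio·n) silent — because positions are drawn with
replacement and made distinct through synthesised alternate-aa tokens, so
closed-form expectations hold without dedup attrition; a configurable
duplication rate re-emits existing variants in new cases to exercise
deduplication. Labels are drawn from the MAF vocabulary consistent with
each class; missense uniques are flagged concurrent with probability
`concurrent_loss_prob`. Everything is a pure function of (config, seed).

Defaults are the observed ATM landscape: L = 3057, 286 non-synonymous
uniques, missense fraction 0.72, domain [2711, 2962], f = 1. The silent :
non-silent ratio defaults to 0.4 — a typical exome-wide synonymous share,
chosen here because only the ratio's constancy, not its value, is part of
the model. Enrichment applies to missense by default (truncating mutations
span the whole protein); `enrich_truncating` flips it for negative
controls. What the generator does **not** emulate: trinucleotide mutation
signatures, per-tumor-type burden heterogeneity, residue-level mutability,
or realistic recurrence patterns — so passing recovery/calibration tests
demonstrates the statistics are correct under the stated model, not that
real catalogs satisfy that model.

Two fixed synthetic reference catalogs (`synthetic_tcga_like`,
`synthetic_at_like`) reconstruct the published ATM marginal counts — 286
somatic non-synonymous uniques with 206 missense (42 in the kinase domain,
105 concurrent with ATM loss) and 447 A-T point mutations with 373
truncating — with random positions; they stand in for the real
supplementary catalogs and validate the pipeline's arithmetic (72%, 83%,
fold ≈ 2.5, p < 0.01), not the true positional spectrum.

## Reproducibility and numerics

A pipeline run is fully determined by its RunConfig and inputs: the single
run seed feeds named per-stage substreams (SHA-256 of "seed:stage", kept
below 2³¹), TSV floats are printed at 6 significant digits with stable row
order, JSON keeps full precision, and the manifest records a SHA-256
checksum per output file — re-running reproduces byte-identical outputs.
Degenerate inputs are handled explicitly: an empty class skips the density
stage with a logged reason (run still valid) and is an error for the
permutation test; expected = 0 with yhat > 0 yields a flagged +inf fold;
n = 0 flags the whole fold profile undefined.

Problem sizes: the acceptance checks in the test suite run the stated
study conditions (50 oracle vectors; 1000 calibration replicates at
n_perm = 2000; 500 recovery replicates; 1000 coverage replicates), which
complete in ~20 s total; `scripts/acceptance.py` uses 400/300/300
replicates for the calibration/recovery/coverage summaries as a
faster-reporting choice, with replicate counts recorded in its output.

## Known limitations

- The uniform and silent-calibrated expected models ignore sequence
  context and codon structure; "enrichment" is relative to protein size.
- The confidence band is conservative (see above); it should not be read
  as an exact 95% pointwise interval.
- Splice-site variants are assigned the annotated protein position of the
  affected residue, which is a convention, not biology.
- The concurrent-loss cross-reference sees only the supplied catalog; a
  truncating mutation filtered out upstream makes the subset incomplete.
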