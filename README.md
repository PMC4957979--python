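# atmhotspot

Protein-coordinate hotspot analysis of cancer-associated **ATM** mutations.

ATM is a serine/threonine kinase central to the DNA damage response and a
tumor suppressor recurrently mutated in lymphoid and solid cancers (3056 aa
plus the stop codon on transcript NM_000051.3, so positions run 1–3057).
Whereas the germline mutations of ataxia-telangiectasia (A-T) patients are
mostly truncating and spread over the whole protein, somatic cancer
mutations are dominated by missense substitutions that cluster around the
C-terminal kinase domain (residues 2711–2962). This package provides the
statistical machinery to quantify that pattern from any variant catalog on
protein coordinates, and a synthetic-catalog simulator so every stage can
be exercised and power-checked without any data download.

## What it computes

Given a MAF-like somatic table or an LOVD-style germline list, the pipeline

1. **classifies** raw variant labels into missense / truncating / silent /
   other (MAF dialect: `Missense_Mutation`, `In_Frame_Del`, `In_Frame_Ins`
   → missense; `Nonsense_Mutation`, `Frame_Shift_*`, `Splice_Site` →
   truncating; LOVD dialect adds `Start_Codon`, `Large_DEL`, `Stop_Codon`
   to the truncating set) and deduplicates calls to *unique* protein-level
   mutations keyed on the protein-change token;
2. **smooths** the per-residue unique-mutation count y(x) with a Gaussian
   kernel moving average

   ŷ(xᵢ) = Σⱼ K(xᵢ,xⱼ) y(xⱼ) / Σⱼ K(xᵢ,xⱼ),  K(xᵢ,xⱼ) = exp(−(xᵢ−xⱼ)²/2b²),

   with window size b = 80 aa, separately per class, and compares it with
   an expected per-residue frequency (uniform n/L, or calibrated on the
   smoothed silent-mutation profile). The fold change ŷ/expected carries a
   95% confidence band obtained by treating ŷ(x)/n as a binomial
   proportion with n trials (exact Clopper–Pearson) at a
   Bonferroni-corrected level α/m, m = L by default;
3. **tests enrichment** of a class in an interval (default: the kinase
   domain [2711, 2962]) by permutation: mutations re-placed uniformly over
   the L residues, one-sided empirical p with add-one smoothing, reporting
   both the fold over the null mean (observed / n·w/L) and the
   in-domain/out-domain rate ratio; a gene-level burden test against a
   size-based Poisson or binomial null is also included;
4. optionally restricts missense mutations to the subset **concurrent**
   with a shallow ATM deletion or a truncating ATM mutation in the same
   case — the calls where the missense allele is the only expressed copy.

## Worked example

Simulate a catalog with a known 2.5-fold kinase-domain missense enrichment
and analyse it:

```sh
$ atmhotspot simulate --out catalog.tsv --enrichment-factor 2.5 --seed 7
wrote 400 records to catalog.tsv

$ atmhotspot classify catalog.tsv
missense        206     0.5150
silent          114     0.2850
truncating      80      0.2000

$ atmhotspot enrich catalog.tsv --n-perm 10000 --seed 7
{
  "class": "missense",
  "domain": {"end": 2962, "name": "domain", "start": 2711},
  "expected_mean": 16.9328,
  "fold": 2.126051214211471,
  "n": 206,
  "n_perm": 10000,
  "observed": 36,
  "p_value": 0.00019998000199980003,
  "rate_ratio": 2.3571428571428568,
  ...
}
```

Reading the output: 36 of the 206 unique missense mutations fall in the
252-aa kinase domain, against 16.93 expected if mutations were uniform
over the 3057 residues — a 2.13-fold excess over the null mean, a
2.36 in-domain/out-domain rate ratio (the estimator of the simulated
factor 2.5, here one noisy replicate), and an empirical p ≈ 2×10⁻⁴: the
clustering would essentially never arise by chance. `atmhotspot run-all`
additionally writes the per-residue density/fold-change profile TSVs, a
classification report, and a checksummed manifest; `atmhotspot density`
writes a single profile.

The same analysis in Python:

```python
from atmhotspot import (SyntheticConfig, generate_catalog,
                        deduplicate_unique, domain_permutation_test,
                        density_profile)
catalog = deduplicate_unique(generate_catalog(SyntheticConfig(enrichment_factor=2.5, seed=7)))
res = domain_permutation_test(catalog, "missense", n_perm=10_000, seed=7)
profile = density_profile(catalog, "missense")   # y, ŷ, expected, fold, CI bands
```

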