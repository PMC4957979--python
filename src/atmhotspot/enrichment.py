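"""Permutation tests for gene burden and domain enrichment.

The domain test asks whether unique mutations of one class cluster in an
interval of the protein (default: the ATM kinase domain, residues
2711–2962). The null re-places the n unique mutations independently and
uniformly over the L residues; the empirical p-value is the upper-tail
probability of the observed in-domain count with add-one smoothing, so it
is never exactly zero. The gene-level burden test compares a gene's
mutation count with a size-based expectation supplied by the caller (the
package embeds no cohort data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.random import Generator, default_rng

from .catalog import ATM_LENGTH, ClassifiedCatalog, DataError

#: ATM kinase-domain interval tested for enrichment (1-based, closed).
KINASE_DOMAIN_START = 2711
KINASE_DOMAIN_END = 2962


@dataclass(frozen=True)
class DomainSpec:
    """A named closed interval [start, end] of 1-based residue positions."""

    name: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid domain interval [{self.start}, {self.end}]")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def contains(self, positions) -> np.ndarray:
        p = np.asarray(positions)
        return (p >= self.start) & (p <= self.end)


def kinase_domain() -> DomainSpec:
    return DomainSpec("kinase_domain", KINASE_DOMAIN_START, KINASE_DOMAIN_END)


@dataclass(frozen=True)
class DomainEnrichmentResult:
    """Observed vs permutation-expected in-domain mutation count.

    fold = observed / expected_mean compares the in-domain count with the
    uniform-null mean (the statistic plotted against the dashed
    expected-rate line). rate_ratio is the in-domain vs out-of-domain
    per-residue rate ratio, the natural estimator of a multiplicative
    enrichment factor. p_value is the one-sided (upper tail) empirical
    probability with add-one smoothing.
    """

    observed: int
    expected_mean: float
    fold: float
    rate_ratio: float
    p_value: float
    n: int
    n_perm: int
    seed: int
    mclass: str
    domain: DomainSpec

    def to_dict(self) -> dict:
        return {
            "domain": {"name": self.domain.name, "start": self.domain.start, "end": self.domain.end},
            "class": self.mclass,
            "n": self.n,
            "observed": self.observed,
            "expected_mean": self.expected_mean,
            "fold": self.fold,
            "rate_ratio": self.rate_ratio,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def closed_form_expected(n: int, domain: DomainSpec, L: int = ATM_LENGTH) -> float:
    """Analytic mean in-domain count under the uniform null: n * width / L."""
    if domain.end > L:
        raise ValueError(f"domain end {domain.end} exceeds protein length {L}")
    return n * domain.width / L


def _permuted_domain_counts(
    n: int, domain: DomainSpec, L: int, n_perm: int, rng: Generator, chunk: int = 200
) -> np.ndarray:
    """In-domain counts of n_perm uniform re-placements of n positions."""
    counts = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        pos = rng.integers(1, L + 1, size=(size, n))
        counts[done : done + size] = domain.contains(pos).sum(axis=1)
        done += size
    return counts


def domain_permutation_test(
    catalog: ClassifiedCatalog,
    mclass: str,
    domain: DomainSpec | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> DomainEnrichmentResult:
    """Permutation test for enrichment of a mutation class in a domain.

    Unique mutations are the permutation unit (case identity is already
    collapsed by deduplication). Fully reproducible from
    (catalog, domain, n_perm, seed).
    """
    domain = domain or kinase_domain()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if domain.end > catalog.L:
        raise ValueError(f"domain end {domain.end} exceeds protein length {catalog.L}")
    positions = np.asarray(catalog.unique_positions(mclass))
    n = len(positions)
    if n == 0:
        raise DataError(f"empty class {mclass!r}: nothing to permute")
    observed = int(domain.contains(positions).sum())
    rng = default_rng(seed)
    counts = _permuted_domain_counts(n, domain, catalog.L, n_perm, rng)
    expected_mean = float(counts.mean())
    p_value = (1.0 + float((counts >= observed).sum())) / (1.0 + n_perm)
    fold = observed / expected_mean if expected_mean > 0 else np.inf
    out = n - observed
    w, Lw = domain.width, catalog.L - domain.width
    rate_ratio = (observed / w) / (out / Lw) if out > 0 else np.inf
    return DomainEnrichmentResult(
        observed=observed,
        expected_mean=expected_mean,
        fold=float(fold),
        rate_ratio=float(rate_ratio),
        p_value=p_value,
        n=n,
        n_perm=n_perm,
        seed=seed,
        mclass=mclass,
        domain=domain,
    )


@dataclass(frozen=True)
class GeneBurdenResult:
    """Gene-level mutation burden against a size-based null."""

    observed: int
    null_mean: float
    fold: float
    p_upper: float
    p_lower: float
    p_two_sided: float
    null: str
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "fold": self.fold,
            "p_upper": self.p_upper,
            "p_lower": self.p_lower,
            "p_two_sided": self.p_two_sided,
            "null": self.null,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def gene_burden_test(
    gene_count: int,
    gene_length_aa: int,
    background: float | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    null: str = "poisson",
    total_mutations: int | None = None,
    total_length_aa: int | None = None,
) -> GeneBurdenResult:
    """Is a gene mutated more (or less) than its size predicts?

    background is the per-aa non-synonymous mutation frequency of the
    cohort (required for the Poisson null, mean = background * length). The
    binomial null instead draws Binomial(total_mutations, length share) and
    needs total_mutations and total_length_aa. The reported p is two-sided
    (2 * min(tail probabilities), capped at 1), each tail with add-one
    smoothing; the one-sided components are also returned.
    """
    if gene_count < 0 or gene_length_aa < 1:
        raise ValueError("gene_count must be >= 0 and gene_length_aa >= 1")
    rng = default_rng(seed)
    if null == "poisson":
        if background is None or background <= 0:
            raise DataError(
                "gene_burden_test needs a positive per-aa background frequency "
                "(the test is relative to the cohort by construction)"
            )
        draws = rng.poisson(background * gene_length_aa, size=n_perm)
    elif null == "binomial":
        if total_mutations is None or total_length_aa is None:
            raise DataError("binomial null needs total_mutations and total_length_aa")
        draws = rng.binomial(total_mutations, gene_length_aa / total_length_aa, size=n_perm)
    else:
        raise ValueError(f"unknown null {null!r} (expected 'poisson' or 'binomial')")
    null_mean = float(draws.mean())
    p_upper = (1.0 + float((draws >= gene_count).sum())) / (1.0 + n_perm)
    p_lower = (1.0 + float((draws <= gene_count).sum())) / (1.0 + n_perm)
    p_two = min(1.0, 2.0 * min(p_upper, p_lower))
    fold = gene_count / null_mean if null_mean > 0 else np.inf
    return GeneBurdenResult(
        observed=gene_count,
        null_mean=null_mean,
        fold=float(fold),
        p_upper=p_upper,
        p_lower=p_lower,
        p_two_sided=p_two,
        null=null,
        n_perm=n_perm,
        seed=seed,
    )
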