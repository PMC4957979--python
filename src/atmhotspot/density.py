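"""Mutation-density estimation along the protein.

The per-residue mutation count y(x) is smoothed with a Gaussian kernel
moving average,

    yhat(x_i) = sum_j K(x_i, x_j) y(x_j) / sum_j K(x_i, x_j),
    K(x_i, x_j) = exp(-(x_i - x_j)^2 / (2 b^2)),

with window size b = 80 aa by default. Missense and truncating mutations
are smoothed separately. The smoothed density is compared with an expected
per-residue frequency under a null model (uniform n/L by default, or
calibrated on the smoothed silent-mutation profile); the ratio is the fold
change, with a 95% confidence band obtained by treating the smoothed
per-residue frequency as a binomial proportion with n trials
(Clopper–Pearson) at a Bonferroni-corrected level.

The denominator sum_j K naturally down-weights the protein ends; no
reflection or truncation padding is applied — the formula is evaluated
literally over all L residues (an optional distance cutoff exists purely
for speed and must agree with the full sum to ~1e-9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .catalog import ATM_LENGTH, MISSENSE, TRUNCATING, SILENT, ClassifiedCatalog, DataError


@dataclass(frozen=True)
class SmootherConfig:
    """Gaussian-kernel smoother parameters.

    b is the kernel window size in amino acids; cutoff (optional, in aa)
    truncates kernel support at |xi - xj| > cutoff for speed.
    """

    b: float = 80.0
    L: int = ATM_LENGTH
    cutoff: float | None = None

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError(f"window size b must be > 0, got {self.b}")
        if self.L < 1:
            raise ValueError(f"protein length L must be >= 1, got {self.L}")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be positive when given")


def gaussian_kernel(xi, xj, b: float):
    """K(xi, xj) = exp(-(xi - xj)^2 / (2 b^2)); symmetric, 1 iff xi == xj."""
    if b <= 0:
        raise ValueError(f"window size b must be > 0, got {b}")
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    out = np.exp(-((xi - xj) ** 2) / (2.0 * b * b))
    return out if out.ndim else float(out)


def count_per_position(catalog: ClassifiedCatalog, mclass: str) -> np.ndarray:
    """Per-residue count of unique mutations of a class (length-L vector).

    Only the classes that are density-profiled (missense, truncating) are
    accepted; silent counts are reached through expected_rate.
    """
    if mclass not in (MISSENSE, TRUNCATING):
        raise DataError(
            f"density profiles are computed for missense/truncating only, got {mclass!r}"
        )
    return _counts_for(catalog, mclass)


def _counts_for(catalog: ClassifiedCatalog, mclass: str) -> np.ndarray:
    y = np.zeros(catalog.L, dtype=np.int64)
    for pos in catalog.unique_positions(mclass):
        y[pos - 1] += 1
    return y


def smooth_density(y: np.ndarray, config: SmootherConfig) -> np.ndarray:
    """Gaussian-kernel smoothing of a per-residue count vector.

    Evaluates the kernel weighted average at every residue via a full-length
    convolution, mathematically identical to the O(L^2) double sum. The
    result is a convex combination of y, so min(y) <= yhat <= max(y).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != config.L:
        raise ValueError(f"count vector must have length L={config.L}, got shape {y.shape}")
    L, b = config.L, config.b
    half = L - 1 if config.cutoff is None else min(L - 1, int(np.floor(config.cutoff)))
    d = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-(d * d) / (2.0 * b * b))
    num = np.convolve(y, k)[half : half + L]
    den = np.convolve(np.ones(L), k)[half : half + L]
    return num / den


def expected_rate(
    catalog: ClassifiedCatalog,
    mclass: str,
    mode: str = "uniform",
    ratio: float | None = None,
    config: SmootherConfig | None = None,
) -> tuple[np.ndarray, dict]:
    """Per-residue expected mutation frequency under a null model.

    uniform: expected(x) = n/L, where n is the unique-mutation count of the
    class — enrichment relative to protein size only.

    silent_calibrated: the smoothed silent-mutation profile is taken as a
    local mutability estimate (the silent : non-silent ratio is assumed
    constant along the protein) and rescaled so the protein-wide total
    equals n; a supplied ratio is recorded but the rescaling makes the
    totals match exactly.

    Returns (expected vector, descriptor dict). n = 0 yields an all-zero
    vector flagged degenerate (fold is undefined there).
    """
    config = config or SmootherConfig(L=catalog.L)
    n = catalog.n_unique(mclass)
    descriptor: dict = {"mode": mode, "class": mclass, "n": n, "L": catalog.L}
    if n == 0:
        descriptor["degenerate"] = True
        return np.zeros(catalog.L), descriptor
    if mode == "uniform":
        return np.full(catalog.L, n / catalog.L), descriptor
    if mode == "silent_calibrated":
        silent = _counts_for(catalog, SILENT).astype(float)
        n_silent = int(silent.sum())
        if n_silent == 0:
            raise DataError("silent_calibrated expected rate needs silent-class records")
        smooth_silent = smooth_density(silent, config)
        expected = smooth_silent * (n / smooth_silent.sum())
        descriptor.update({"n_silent": n_silent, "ratio": ratio, "b": config.b})
        return expected, descriptor
    raise ValueError(f"unknown expected-rate mode {mode!r}")


def clopper_pearson(k, n: int, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact (Clopper–Pearson) two-sided CI for a binomial proportion.

    Accepts non-integer "counts" k (the smoothed values) through the
    continuous beta-quantile extension:

        lower = BetaInv(alpha/2; k, n - k + 1)        (0 when k = 0)
        upper = BetaInv(1 - alpha/2; k + 1, n - k)    (1 when k = n)

    At k = 0 the upper bound reduces to the closed form 1 - (alpha/2)^(1/n).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    k = np.atleast_1d(np.asarray(k, dtype=float))
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("counts must lie in [0, n]")
    lo = np.zeros_like(k)
    hi = np.ones_like(k)
    pos = k > 0
    lo[pos] = beta_dist.ppf(alpha / 2.0, k[pos], n - k[pos] + 1)
    below = k < n
    hi[below] = beta_dist.ppf(1.0 - alpha / 2.0, k[below] + 1, n - k[below])
    return lo, hi


@dataclass
class DensityProfile:
    """Observed, smoothed and expected mutation density along the protein.

    fold = yhat/expected with ci_low/ci_high the two-sided Clopper–Pearson
    band at level alpha/m_tests, expressed on the fold scale. Residues where
    expected = 0 but yhat > 0 carry fold = +inf and are flagged.
    """

    y: np.ndarray
    y_hat: np.ndarray
    expected: np.ndarray
    fold: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int
    mclass: str
    config: SmootherConfig
    alpha: float = 0.05
    m_tests: int | None = None
    expected_descriptor: dict = field(default_factory=dict)
    undefined_fold: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.y) + 1),
                "y": self.y,
                "y_hat": self.y_hat,
                "expected": self.expected,
                "fold": self.fold,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def fold_profile(
    y_hat: np.ndarray,
    expected: np.ndarray,
    n: int,
    alpha: float = 0.05,
    m_tests: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fold change and Bonferroni-corrected binomial confidence band.

    The smoothed per-residue frequency p_hat(x) = yhat(x)/n is treated as a
    binomial proportion with n trials; the two-sided Clopper–Pearson
    interval at level alpha/m_tests is divided by expected(x)/n to express
    it on the fold scale. m_tests defaults to the profile length (one test
    per residue).

    Returns (fold, ci_low, ci_high, undefined_mask).
    """
    y_hat = np.asarray(y_hat, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if y_hat.shape != expected.shape:
        raise ValueError("y_hat and expected must have identical shapes")
    if n < 1:
        raise ValueError("n (trials) must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    m = len(y_hat) if m_tests is None else int(m_tests)
    if m < 1:
        raise ValueError("m_tests must be >= 1")
    alpha_corr = alpha / m
    p_lo, p_hi = clopper_pearson(np.clip(y_hat, 0.0, n), n, alpha_corr)

    with np.errstate(divide="ignore", invalid="ignore"):
        rate = expected / n
        fold = np.where(expected > 0, y_hat / expected, np.where(y_hat > 0, np.inf, np.nan))
        ci_low = np.where(expected > 0, p_lo / rate, np.nan)
        ci_high = np.where(expected > 0, p_hi / rate, np.nan)
    undefined = ~(expected > 0)
    return fold, ci_low, ci_high, undefined


def density_profile(
    catalog: ClassifiedCatalog,
    mclass: str,
    config: SmootherConfig | None = None,
    mode: str = "uniform",
    ratio: float | None = None,
    alpha: float = 0.05,
    m_tests: int | None = None,
) -> DensityProfile:
    """Full per-class density profile: count, smooth, expect, fold + CI."""
    config = config or SmootherConfig(L=catalog.L)
    y = count_per_position(catalog, mclass)
    n = int(y.sum())
    y_hat = smooth_density(y, config)
    expected, descriptor = expected_rate(catalog, mclass, mode=mode, ratio=ratio, config=config)
    if n == 0:
        nanv = np.full(catalog.L, np.nan)
        return DensityProfile(
            y=y, y_hat=y_hat, expected=expected, fold=nanv, ci_low=nanv, ci_high=nanv,
            n=0, mclass=mclass, config=config, alpha=alpha, m_tests=m_tests,
            expected_descriptor=descriptor, undefined_fold=np.ones(catalog.L, dtype=bool),
        )
    m = config.L if m_tests is None else m_tests
    fold, ci_low, ci_high, undefined = fold_profile(y_hat, expected, n, alpha=alpha, m_tests=m)
    return DensityProfile(
        y=y, y_hat=y_hat, expected=expected, fold=fold, ci_low=ci_low, ci_high=ci_high,
        n=n, mclass=mclass, config=config, alpha=alpha, m_tests=m,
        expected_descriptor=descriptor, undefined_fold=undefined,
    )
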