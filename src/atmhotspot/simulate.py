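"""Synthetic mutation-catalog generation.

Generates catalogs with exactly the statistical structure the analysis
assumes: a uniform background over the L residues, one enriched interval
with a known multiplicative rate factor f (applied to the missense class
by default), a fixed silent : non-silent count ratio, and per-record labels
drawn from the MAF vocabulary. Positions are drawn with replacement and
then made distinct through synthesised alternate-amino-acid tokens, so the
requested class sizes are exact and closed-form expectations hold exactly.

Every generator here is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import Generator, default_rng

from .catalog import ATM_LENGTH, MutationRecord, ConfigurationError, DataError
from .enrichment import DomainSpec, kinase_domain

_AA = "ACDEFGHIKLMNPQRSTVWY"

_MISSENSE_LABELS = ("Missense_Mutation", "In_Frame_Del", "In_Frame_Ins")
_MISSENSE_WEIGHTS = (0.92, 0.04, 0.04)
_TRUNCATING_LABELS = ("Nonsense_Mutation", "Frame_Shift_Del", "Frame_Shift_Ins", "Splice_Site")
_TRUNCATING_WEIGHTS = (0.35, 0.35, 0.10, 0.20)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic catalog generator.

    Defaults echo the observed ATM landscape: protein length 3057 aa, 286
    non-synonymous uniques of which 72% are missense, the kinase domain
    [2711, 2962] as the candidate enriched interval, and a silent :
    non-silent ratio of 0.4 (a typical exome-wide synonymous share).
    enrichment_factor multiplies the per-residue rate inside the domain for
    the missense class (or for truncating when enrich_truncating is set,
    for negative-control experiments); f = 1 is the uniform null.
    """

    L: int = ATM_LENGTH
    n_nonsilent: int = 286
    missense_fraction: float = 0.72
    domain: DomainSpec = field(default_factory=kinase_domain)
    enrichment_factor: float = 1.0
    silent_ratio: float = 0.4
    concurrent_loss_prob: float = 0.0
    duplication_rate: float = 0.0
    enrich_truncating: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.L < 1:
            raise ConfigurationError(f"L must be >= 1, got {self.L}")
        if self.n_nonsilent < 0:
            raise ConfigurationError("n_nonsilent must be >= 0")
        if self.enrichment_factor <= 0:
            raise ConfigurationError(f"enrichment_factor must be > 0, got {self.enrichment_factor}")
        for name in ("missense_fraction", "concurrent_loss_prob", "duplication_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.silent_ratio < 0:
            raise ConfigurationError("silent_ratio must be >= 0")
        if self.domain.end > self.L:
            raise ConfigurationError(
                f"domain end {self.domain.end} exceeds protein length {self.L}"
            )

    @property
    def n_missense(self) -> int:
        return int(round(self.n_nonsilent * self.missense_fraction))

    @property
    def n_truncating(self) -> int:
        return self.n_nonsilent - self.n_missense

    @property
    def n_silent(self) -> int:
        return int(round(self.silent_ratio * self.n_nonsilent))

    def in_domain_probability(self) -> float:
        """P(position in domain) for the enriched class: f*w / (f*w + L - w)."""
        f, w = self.enrichment_factor, self.domain.width
        return f * w / (f * w + (self.L - w))


def _piecewise_positions(n: int, config: SyntheticConfig, rng: Generator) -> np.ndarray:
    """Positions with per-residue rate ∝ f inside the domain, ∝ 1 outside."""
    d = config.domain
    inside = rng.random(n) < config.in_domain_probability()
    pos = np.empty(n, dtype=np.int64)
    n_in = int(inside.sum())
    pos[inside] = rng.integers(d.start, d.end + 1, size=n_in)
    # uniform over the two flanks, proportional to their lengths
    left = d.start - 1
    outside_len = config.L - d.width
    if n - n_in:
        u = rng.integers(0, outside_len, size=n - n_in)
        pos[~inside] = np.where(u < left, u + 1, u - left + d.end + 1)
    return pos


def _tokens(positions: np.ndarray, truncating: bool, rng: Generator, used: dict) -> list[str]:
    """Distinct protein-change tokens, one per drawn position."""
    out = []
    for pos in positions:
        ref = _AA[int(pos) % len(_AA)]
        k = used.get((int(pos), truncating), 0)
        used[(int(pos), truncating)] = k + 1
        if truncating:
            alt = "*" if k == 0 else f"fs{k}"
        else:
            alt = _AA[k % len(_AA)] + ("" if k < len(_AA) else str(k // len(_AA)))
        out.append(f"p.{ref}{int(pos)}{alt}")
    return out


def generate_catalog(config: SyntheticConfig) -> list[MutationRecord]:
    """Draw one synthetic catalog of MutationRecords.

    Missense positions follow the piecewise-uniform enriched density
    (truncating instead when enrich_truncating is set); the other classes
    are uniform on {1..L}. Tokens are synthesised distinct, so deduplication
    keeps every record unless duplication_rate > 0, in which case a record
    is, with that probability, an extra call of an already-emitted variant
    in a new case.
    """
    config.validate()
    rng = default_rng(config.seed)
    uniform = lambda n: rng.integers(1, config.L + 1, size=n)

    if config.enrich_truncating:
        mis_pos = uniform(config.n_missense)
        tru_pos = _piecewise_positions(config.n_truncating, config, rng)
    else:
        mis_pos = _piecewise_positions(config.n_missense, config, rng)
        tru_pos = uniform(config.n_truncating)
    sil_pos = uniform(config.n_silent)

    used: dict = {}
    records: list[MutationRecord] = []
    case = 0

    def emit(positions, tokens, labels, weights, flags=None):
        nonlocal case
        lab = rng.choice(labels, size=len(positions), p=weights)
        for i, pos in enumerate(positions):
            case += 1
            records.append(
                MutationRecord(
                    case_id=f"SYN-{case:05d}",
                    protein_position=int(pos),
                    raw_label=str(lab[i]),
                    protein_change=tokens[i],
                    concurrent_shallow_deletion=bool(flags[i]) if flags is not None else False,
                )
            )

    mis_flags = rng.random(config.n_missense) < config.concurrent_loss_prob
    emit(mis_pos, _tokens(mis_pos, False, rng, used), _MISSENSE_LABELS, _MISSENSE_WEIGHTS, mis_flags)
    emit(tru_pos, _tokens(tru_pos, True, rng, used), _TRUNCATING_LABELS, _TRUNCATING_WEIGHTS)
    emit(sil_pos, _tokens(sil_pos, False, rng, used), ("Silent",), (1.0,))

    if config.duplication_rate > 0 and records:
        n_dup = rng.binomial(len(records), config.duplication_rate)
        for idx in rng.integers(0, len(records), size=n_dup):
            case += 1
            records.append(replace(records[int(idx)], case_id=f"SYN-{case:05d}"))
    return records


def generate_cohort_background(config: SyntheticConfig) -> dict:
    """Per-aa background non-synonymous frequency matching a generated catalog.

    For f = 1 this is simply n/L. For an enriched configuration the
    background is estimated from the out-of-domain rate only (the enriched
    interval would otherwise inflate it) and flagged as such.
    """
    config.validate()
    if config.n_nonsilent == 0:
        raise DataError("degenerate background: configuration generates no mutations")
    if config.enrichment_factor == 1.0:
        return {
            "frequency": config.n_nonsilent / config.L,
            "basis": "uniform",
            "n": config.n_nonsilent,
            "L": config.L,
        }
    w = config.domain.width
    n_enriched = config.n_truncating if config.enrich_truncating else config.n_missense
    p_out = 1.0 - config.in_domain_probability()
    expected_outside = n_enriched * p_out + (config.n_nonsilent - n_enriched) * (config.L - w) / config.L
    return {
        "frequency": expected_outside / (config.L - w),
        "basis": "outside_domain_only",
        "n": config.n_nonsilent,
        "L": config.L,
        "domain": {"start": config.domain.start, "end": config.domain.end},
    }


def synthetic_tcga_like(seed: int = 0, n_silent: int = 114) -> list[MutationRecord]:
    """Synthetic stand-in for the somatic (TCGA-style) ATM catalog.

    Reconstructs the published summary counts — 286 unique non-synonymous
    mutations, 206 (72%) missense of which 42 fall in the kinase domain
    [2711, 2962] and 105 are concurrent with shallow deletion or a
    truncating mutation in the same case — with positions drawn uniformly
    within/outside the domain. It reproduces the marginal counts, not the
    real per-residue mutation positions.
    """
    rng = default_rng(seed)
    d = kinase_domain()
    used: dict = {}
    records: list[MutationRecord] = []

    mis_in = rng.integers(d.start, d.end + 1, size=42)
    left = d.start - 1
    outside_len = ATM_LENGTH - d.width
    u = rng.integers(0, outside_len, size=206 - 42)
    mis_out = np.where(u < left, u + 1, u - left + d.end + 1)
    mis_pos = np.concatenate([mis_in, mis_out])
    flagged = np.zeros(206, dtype=bool)
    flagged[rng.choice(206, size=105, replace=False)] = True

    tokens = _tokens(mis_pos, False, rng, used)
    for i, pos in enumerate(mis_pos):
        records.append(
            MutationRecord(
                case_id=f"SYNTCGA-{i:04d}",
                protein_position=int(pos),
                raw_label="Missense_Mutation",
                protein_change=tokens[i],
                concurrent_shallow_deletion=bool(flagged[i]),
            )
        )
    tru_pos = rng.integers(1, ATM_LENGTH + 1, size=286 - 206)
    tokens = _tokens(tru_pos, True, rng, used)
    for i, pos in enumerate(tru_pos):
        records.append(
            MutationRecord(
                case_id=f"SYNTCGA-{1000 + i:04d}",
                protein_position=int(pos),
                raw_label="Nonsense_Mutation",
                protein_change=tokens[i],
            )
        )
    sil_pos = rng.integers(1, ATM_LENGTH + 1, size=n_silent)
    tokens = _tokens(sil_pos, False, rng, used)
    for i, pos in enumerate(sil_pos):
        records.append(
            MutationRecord(
                case_id=f"SYNTCGA-{2000 + i:04d}",
                protein_position=int(pos),
                raw_label="Silent",
                protein_change=tokens[i],
            )
        )
    return records


def synthetic_at_like(seed: int = 0) -> list[MutationRecord]:
    """Synthetic stand-in for the germline A-T (LOVD-style) ATM catalog.

    Reconstructs the published class mix — 447 unique point mutations, 373
    (83%) truncating — with uniform positions and LOVD effect labels
    (including splice-site/stop-codon labels, which the reporting option
    can regroup as "Others").
    """
    rng = default_rng(seed)
    records: list[MutationRecord] = []
    used: dict = {}
    tru_labels = ["Nonsense_Mutation"] * 150 + ["Frame_Shift_Del"] * 120 + [
        "Splice_Site"
    ] * 70 + ["Stop_Codon"] * 20 + ["Large_DEL"] * 13
    tru_pos = rng.integers(1, ATM_LENGTH + 1, size=373)
    tokens = _tokens(tru_pos, True, rng, used)
    for i, pos in enumerate(tru_pos):
        records.append(
            MutationRecord(
                case_id="",
                protein_position=int(pos),
                raw_label=tru_labels[i],
                protein_change=tokens[i],
            )
        )
    mis_pos = rng.integers(1, ATM_LENGTH + 1, size=447 - 373)
    tokens = _tokens(mis_pos, False, rng, used)
    for i, pos in enumerate(mis_pos):
        records.append(
            MutationRecord(
                case_id="",
                protein_position=int(pos),
                raw_label="Missense",
                protein_change=tokens[i],
            )
        )
    return records
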