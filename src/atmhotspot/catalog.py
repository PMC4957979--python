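"""Reading and classifying ATM variant catalogs on protein coordinates.

Somatic calls arrive as MAF-like tab-separated tables (one row per mutation
call in one case); germline A-T variants arrive as LOVD-style lists (protein
position or protein-change token plus an effect label, no case identity).
Both are reduced to *unique* protein-level mutations: one distinct
protein change counted once regardless of how many cases carry it.

Coordinates are 1-based amino-acid positions on the 3057-residue ATM
coordinate system (3056 aa + stop codon, transcript NM_000051.3); all
intervals in this package are closed ``[start, end]``.
"""

from __future__ import annotations

import logging
import re
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: ATM protein length in amino acids, including the stop codon.
ATM_LENGTH = 3057

MISSENSE = "missense"
TRUNCATING = "truncating"
SILENT = "silent"
OTHER = "other"
CLASSES = (MISSENSE, TRUNCATING, SILENT, OTHER)

# MAF (TCGA-style) variant-classification vocabulary.
TCGA_MISSENSE_LABELS = frozenset({"Missense_Mutation", "In_Frame_Del", "In_Frame_Ins"})
TCGA_TRUNCATING_LABELS = frozenset(
    {"Nonsense_Mutation", "Frame_Shift_Del", "Frame_Shift_Ins", "Splice_Site"}
)
TCGA_SILENT_LABELS = frozenset({"Silent"})

# LOVD effect vocabulary.  Only the truncating side is fixed; which labels
# count as missense substitutions is configurable (see classify_label).
LOVD_TRUNCATING_LABELS = frozenset(
    {
        "Start_Codon",
        "Frame_Shift_Del",
        "Large_DEL",
        "Nonsense_Mutation",
        "Frame_Shift_Ins",
        "Splice_Site",
        "Stop_Codon",
    }
)
LOVD_MISSENSE_LABELS = frozenset({"Missense", "Missense_Mutation", "Substitution"})
LOVD_SILENT_LABELS = frozenset({"Silent", "Synonymous"})

#: Labels grouped as "Others" in the reporting option that mirrors the
#: classification-pie grouping (splice-site and stop-codon changes).
FIG_OTHERS_LABELS = frozenset({"Splice_Site", "Stop_Codon"})

_POSITION_RE = re.compile(r"(\d+)")


class ConfigurationError(ValueError):
    """A run or dialect configuration is invalid (missing column, bad value)."""


class DataError(ValueError):
    """Input data cannot support the requested computation."""


@dataclass(frozen=True)
class MutationRecord:
    """One annotated variant call on protein coordinates.

    ``protein_change`` is the token identifying the substitution/indel at
    protein level (e.g. ``p.N2875K``); it is the uniqueness key downstream.
    The concurrent flags mark missense calls whose case also carries a
    shallow (heterozygous) ATM deletion or a truncating ATM mutation.
    """

    case_id: str
    protein_position: int
    raw_label: str
    protein_change: str = ""
    concurrent_shallow_deletion: bool = False
    concurrent_truncating: bool = False


@dataclass(frozen=True)
class MafDialect:
    """Column-name map for a MAF-like tab-separated table.

    ``position_col`` may point at a plain integer column or at a
    protein-change token column such as ``p.N2875K``; the first integer run
    in the token is taken as the amino-acid position.
    """

    case_col: str = "Tumor_Sample_Barcode"
    position_col: str = "Protein_position"
    label_col: str = "Variant_Classification"
    protein_change_col: str | None = "HGVSp_Short"
    shallow_deletion_col: str | None = None
    concurrent_truncating_col: str | None = None
    name: str = "tcga"


@dataclass
class ReadReport:
    """Per-row validation outcome of a catalog read.

    Rows that fail validation are quarantined here (index, reason, raw row)
    rather than aborting the run — real MAF extracts are dirty.
    """

    n_rows: int = 0
    n_parsed: int = 0
    quarantined: list[dict] = field(default_factory=list)

    def add(self, index: int, reason: str, row: Mapping) -> None:
        self.quarantined.append(
            {"row": int(index), "reason": reason, "data": {k: str(v) for k, v in row.items()}}
        )

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_parsed": self.n_parsed,
            "n_quarantined": len(self.quarantined),
            "quarantined": self.quarantined,
        }


def extract_position(token: object) -> int | None:
    """Pull the amino-acid position out of a position field.

    Accepts plain integers, integer strings, or protein-change tokens like
    ``p.N2875K`` / ``N2875fs`` (first integer run wins). Returns None when no
    integer can be found.
    """
    if token is None or (isinstance(token, float) and pd.isna(token)):
        return None
    if isinstance(token, (int,)) and not isinstance(token, bool):
        return int(token)
    if isinstance(token, float):
        return int(token) if token == int(token) else None
    m = _POSITION_RE.search(str(token))
    return int(m.group(1)) if m else None


def classify_label(
    raw_label: str,
    dialect: str = "tcga",
    lovd_missense: frozenset[str] | set[str] | None = None,
) -> str:
    """Map a raw variant-class label to {missense, truncating, silent, other}.

    TCGA dialect: Missense_Mutation / In_Frame_Del / In_Frame_Ins are
    missense; Nonsense_Mutation / Frame_Shift_Del / Frame_Shift_Ins /
    Splice_Site are truncating; Silent is silent; everything else is other.
    LOVD dialect: the truncating set additionally includes Start_Codon,
    Large_DEL and Stop_Codon; the missense set is configurable because the
    LOVD effect vocabulary for substitutions is not standardised.

    Total function: unknown labels fall through to "other" (counted by the
    caller, never an exception). Comparison is exact on the
    whitespace-trimmed token.
    """
    label = str(raw_label).strip()
    if dialect == "tcga":
        if label in TCGA_MISSENSE_LABELS:
            return MISSENSE
        if label in TCGA_TRUNCATING_LABELS:
            return TRUNCATING
        if label in TCGA_SILENT_LABELS:
            return SILENT
        return OTHER
    if dialect == "lovd":
        missense_set = LOVD_MISSENSE_LABELS if lovd_missense is None else frozenset(lovd_missense)
        if label in LOVD_TRUNCATING_LABELS:
            return TRUNCATING
        if label in missense_set:
            return MISSENSE
        if label in LOVD_SILENT_LABELS:
            return SILENT
        return OTHER
    raise ConfigurationError(f"unknown label dialect: {dialect!r} (expected 'tcga' or 'lovd')")


def _coerce_flag(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return False
    return str(value).strip().lower() in {"1", "true", "yes", "y", "t"}


def read_maf_like(
    path: str | Path,
    dialect: MafDialect | None = None,
    L: int = ATM_LENGTH,
) -> tuple[list[MutationRecord], ReadReport]:
    """Read a MAF-like TSV into MutationRecords, quarantining bad rows.

    Returns ``(records, report)``; row order is preserved. Rows whose
    position cannot be parsed or falls outside ``[1, L]`` go to the report.
    A mandatory column missing from the header raises ConfigurationError.
    """
    dialect = dialect or MafDialect()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    for col in (dialect.case_col, dialect.position_col, dialect.label_col):
        if col not in df.columns:
            raise ConfigurationError(
                f"mandatory column {col!r} missing from {path} (have: {list(df.columns)})"
            )
    report = ReadReport(n_rows=len(df))
    records: list[MutationRecord] = []
    has_change = dialect.protein_change_col and dialect.protein_change_col in df.columns
    for idx, row in df.iterrows():
        pos = extract_position(row[dialect.position_col])
        if pos is None:
            report.add(idx, f"unparsable position {row[dialect.position_col]!r}", row)
            continue
        if not (1 <= pos <= L):
            report.add(idx, f"position {pos} outside [1, {L}]", row)
            continue
        label = str(row[dialect.label_col]).strip()
        if not label or label.lower() == "nan":
            report.add(idx, "empty variant-class label", row)
            continue
        change = str(row[dialect.protein_change_col]) if has_change else ""
        if change.lower() == "nan":
            change = ""
        shallow = (
            _coerce_flag(row[dialect.shallow_deletion_col])
            if dialect.shallow_deletion_col and dialect.shallow_deletion_col in df.columns
            else False
        )
        conc_trunc = (
            _coerce_flag(row[dialect.concurrent_truncating_col])
            if dialect.concurrent_truncating_col
            and dialect.concurrent_truncating_col in df.columns
            else False
        )
        records.append(
            MutationRecord(
                case_id=str(row[dialect.case_col]),
                protein_position=pos,
                raw_label=label,
                protein_change=change,
                concurrent_shallow_deletion=shallow,
                concurrent_truncating=conc_trunc,
            )
        )
    report.n_parsed = len(records)
    if report.quarantined:
        logger.warning("%d/%d rows quarantined reading %s", len(report.quarantined), report.n_rows, path)
    return records, report


def read_variant_list(
    path: str | Path,
    position_col: str = "position",
    label_col: str = "effect",
    L: int = ATM_LENGTH,
) -> tuple[list[MutationRecord], ReadReport]:
    """Read an LOVD-style germline variant list (position/token + effect label).

    Records carry an empty case_id; duplicated rows yield duplicated records
    (deduplication is a later, explicit stage).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    for col in (position_col, label_col):
        if col not in df.columns:
            raise ConfigurationError(f"mandatory column {col!r} missing from {path}")
    report = ReadReport(n_rows=len(df))
    records: list[MutationRecord] = []
    for idx, row in df.iterrows():
        pos = extract_position(row[position_col])
        if pos is None:
            report.add(idx, f"unparsable position {row[position_col]!r}", row)
            continue
        if not (1 <= pos <= L):
            report.add(idx, f"position {pos} outside [1, {L}]", row)
            continue
        token = str(row[position_col])
        records.append(
            MutationRecord(
                case_id="",
                protein_position=pos,
                raw_label=str(row[label_col]).strip(),
                protein_change=token if not token.isdigit() else "",
            )
        )
    report.n_parsed = len(records)
    return records, report


@dataclass
class ClassifiedCatalog:
    """Classified records plus the table of unique protein-level mutations.

    ``unique`` has one row per distinct (protein_change, class) key with
    columns: key, protein_change, position, mclass, n_records,
    concurrent_shallow_deletion, concurrent_truncating, concurrent_any
    (flag-OR over the contributing records, extended by per-case
    cross-referencing against truncating calls when case ids exist).
    """

    L: int
    records: list[MutationRecord]
    classes: list[str]
    unique: pd.DataFrame
    dialect: str = "tcga"
    mapping_log: dict = field(default_factory=dict)

    @property
    def unique_missense(self) -> list[int]:
        return self.unique.loc[self.unique["mclass"] == MISSENSE, "position"].tolist()

    @property
    def unique_truncating(self) -> list[int]:
        return self.unique.loc[self.unique["mclass"] == TRUNCATING, "position"].tolist()

    def unique_positions(self, mclass: str) -> list[int]:
        return self.unique.loc[self.unique["mclass"] == mclass, "position"].tolist()

    def class_counts(self) -> dict[str, int]:
        counts = self.unique["mclass"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in CLASSES}

    def n_unique(self, mclass: str) -> int:
        return int((self.unique["mclass"] == mclass).sum())


def deduplicate_unique(
    records: Sequence[MutationRecord],
    L: int = ATM_LENGTH,
    dialect: str = "tcga",
    lovd_missense: frozenset[str] | None = None,
) -> ClassifiedCatalog:
    """Classify records and collapse them to unique protein-level mutations.

    Uniqueness is keyed on ``(protein_change, class)``; records lacking a
    protein_change token fall back to ``(position, raw_label)`` with a
    logged notice. Concurrent flags are OR-ed over each group, and a
    missense unique is additionally marked ``concurrent_any`` when any of
    its cases also carries a truncating record in the same catalog.
    Idempotent: re-deduplicating the uniques changes nothing.
    """
    classes = [classify_label(r.raw_label, dialect, lovd_missense) for r in records]
    mapping_log: dict[str, dict[str, int]] = {}
    for r, c in zip(records, classes):
        entry = mapping_log.setdefault(r.raw_label, {"class": c, "n": 0})  # type: ignore[dict-item]
        entry["n"] += 1  # type: ignore[index]

    cases_with_truncating = {
        r.case_id for r, c in zip(records, classes) if c == TRUNCATING and r.case_id
    }

    n_fallback = 0
    groups: "OrderedDict[tuple, dict]" = OrderedDict()
    for r, c in zip(records, classes):
        if r.protein_change:
            key = (r.protein_change, c)
        else:
            key = (f"pos{r.protein_position}|{r.raw_label}", c)
            n_fallback += 1
        g = groups.get(key)
        if g is None:
            g = {
                "key": key[0],
                "protein_change": r.protein_change or key[0],
                "position": r.protein_position,
                "mclass": c,
                "n_records": 0,
                "concurrent_shallow_deletion": False,
                "concurrent_truncating": False,
                "case_in_truncating": False,
            }
            groups[key] = g
        g["n_records"] += 1
        g["concurrent_shallow_deletion"] |= r.concurrent_shallow_deletion
        g["concurrent_truncating"] |= r.concurrent_truncating
        g["case_in_truncating"] |= bool(r.case_id) and r.case_id in cases_with_truncating
    if n_fallback:
        logger.info("%d records lacked protein_change; keyed on (position, label)", n_fallback)

    unique = pd.DataFrame(
        list(groups.values()),
        columns=[
            "key",
            "protein_change",
            "position",
            "mclass",
            "n_records",
            "concurrent_shallow_deletion",
            "concurrent_truncating",
            "case_in_truncating",
        ],
    )
    if len(unique):
        unique["concurrent_any"] = (
            unique["concurrent_shallow_deletion"]
            | unique["concurrent_truncating"]
            | unique["case_in_truncating"]
        )
    else:
        unique["concurrent_any"] = pd.Series(dtype=bool)
    return ClassifiedCatalog(
        L=L,
        records=list(records),
        classes=classes,
        unique=unique,
        dialect=dialect,
        mapping_log=mapping_log,
    )


def filter_concurrent_loss(catalog: ClassifiedCatalog) -> ClassifiedCatalog:
    """Restrict the missense uniques to those concurrent with ATM loss.

    Keeps missense uniques whose flag-OR (shallow deletion, explicit
    concurrent-truncating flag, or a truncating record in the same case) is
    true; truncating/silent/other rows pass through unchanged. Raises
    DataError when the catalog carries no flag information at all, because
    the subset is then uncomputable.
    """
    u = catalog.unique
    missense_mask = u["mclass"] == MISSENSE
    has_flag_info = bool(
        u.loc[missense_mask, ["concurrent_shallow_deletion", "concurrent_truncating"]]
        .any()
        .any()
        or any(r.case_id for r in catalog.records)
    )
    if missense_mask.any() and not has_flag_info:
        raise DataError(
            "concurrent-loss subset is uncomputable: no concurrent flags and no "
            "case ids for cross-referencing truncating mutations"
        )
    keep = ~missense_mask | u["concurrent_any"].fillna(False).astype(bool)
    filtered = u.loc[keep].reset_index(drop=True)
    n_before = int(missense_mask.sum())
    n_after = int((filtered["mclass"] == MISSENSE).sum())
    logger.info("concurrent-loss subset: %d of %d missense uniques retained", n_after, n_before)
    return ClassifiedCatalog(
        L=catalog.L,
        records=catalog.records,
        classes=catalog.classes,
        unique=filtered,
        dialect=catalog.dialect,
        mapping_log=dict(catalog.mapping_log),
    )
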