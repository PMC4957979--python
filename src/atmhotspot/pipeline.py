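"""End-to-end orchestration: classify -> density -> enrichment.

A run is fully determined by its RunConfig plus the input files: all
randomness flows from the single run seed through named per-stage
substreams, floats in TSV outputs are printed at 6 significant digits with
stable row order, and the manifest records a SHA-256 checksum per emitted
file, so re-running reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import (
    ATM_LENGTH,
    FIG_OTHERS_LABELS,
    MISSENSE,
    OTHER,
    SILENT,
    TRUNCATING,
    ClassifiedCatalog,
    ConfigurationError,
    DataError,
    MafDialect,
    deduplicate_unique,
    filter_concurrent_loss,
    read_maf_like,
    read_variant_list,
)
from .density import SmootherConfig, density_profile
from .enrichment import DomainSpec, domain_permutation_test, kinase_domain

logger = logging.getLogger(__name__)


def _substream_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the run seed (kept below 2^31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything a run needs beyond the input files themselves."""

    input_path: str
    dialect: str = "tcga"  # 'tcga' (MAF-like) or 'lovd' (variant list)
    out_dir: str = "results"
    L: int = ATM_LENGTH
    classes: tuple[str, ...] = (MISSENSE, TRUNCATING)
    b: float = 80.0
    expected_mode: str = "uniform"
    alpha: float = 0.05
    m_tests: int | None = None
    domains: tuple[tuple[str, int, int], ...] = (
        ("kinase_domain", 2711, 2962),
    )
    n_perm: int = 10_000
    seed: int = 0
    concurrent_subset: bool = False
    maf_columns: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def report_class_fractions(catalog: ClassifiedCatalog, grouping: str = "methods") -> pd.DataFrame:
    """Unique-mutation class fractions under either reporting grouping.

    'methods' reports missense/truncating/silent/other per the computational
    mapping. 'fig1a' mirrors the classification-pie convention in which
    splice-site and stop-codon labels are shown under "Others"; the missense
    fraction is identical under both groupings.
    """
    u = catalog.unique
    if grouping == "methods":
        groups = u["mclass"]
    elif grouping == "fig1a":
        raw_per_unique = u["key"].map(
            {r.protein_change or f"pos{r.protein_position}|{r.raw_label}": r.raw_label
             for r in catalog.records}
        )
        groups = np.where(
            raw_per_unique.isin(FIG_OTHERS_LABELS), "Others", u["mclass"].to_numpy()
        )
        groups = pd.Series(groups, index=u.index)
    else:
        raise ConfigurationError(f"unknown grouping {grouping!r}")
    counts = groups.value_counts()
    total = int(counts.sum())
    out = pd.DataFrame(
        {
            "group": counts.index,
            "count": counts.to_numpy(),
            "fraction": counts.to_numpy() / total if total else 0.0,
        }
    ).sort_values("group", kind="stable").reset_index(drop=True)
    out.attrs["total"] = total
    return out


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        return f"{x:.6g}"
    return str(x)


def write_tsv(df: pd.DataFrame, path: Path) -> None:
    """Deterministic TSV: floats at 6 significant digits, no index."""
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_catalog(config: RunConfig) -> tuple[ClassifiedCatalog, dict]:
    if config.dialect == "tcga":
        dialect = MafDialect(**config.maf_columns) if config.maf_columns else MafDialect()
        records, report = read_maf_like(config.input_path, dialect, L=config.L)
        catalog = deduplicate_unique(records, L=config.L, dialect="tcga")
    elif config.dialect == "lovd":
        records, report = read_variant_list(config.input_path, L=config.L)
        catalog = deduplicate_unique(records, L=config.L, dialect="lovd")
    else:
        raise ConfigurationError(f"unknown dialect {config.dialect!r}")
    return catalog, report.to_dict()


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline and write TSV/JSON outputs plus a manifest.

    Any stage failure aborts with the stage name; a partial-output marker
    file is left in the output directory so downstream consumers can tell a
    truncated run from a complete one.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / "INCOMPLETE"
    marker.write_text("run in progress\n")
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "files": {},
        "stages": {},
    }
    try:
        stage = "classify"
        catalog, read_report = load_catalog(config)
        if config.concurrent_subset:
            catalog = filter_concurrent_loss(catalog)
        frac_methods = report_class_fractions(catalog, "methods")
        frac_fig = report_class_fractions(catalog, "fig1a")
        unique_out = catalog.unique[
            ["protein_change", "position", "mclass",
             "concurrent_shallow_deletion", "concurrent_truncating", "concurrent_any"]
        ].rename(columns={"mclass": "class"})
        write_tsv(unique_out, out_dir / "classified_catalog.tsv")
        class_report = {
            "read": read_report,
            "class_counts": catalog.class_counts(),
            "n_unique": int(len(catalog.unique)),
            "fractions_methods": frac_methods.to_dict(orient="records"),
            "fractions_fig1a": frac_fig.to_dict(orient="records"),
            "label_mapping": catalog.mapping_log,
        }
        (out_dir / "classification_report.json").write_text(
            json.dumps(class_report, indent=2, sort_keys=True) + "\n"
        )
        manifest["stages"][stage] = {"n_unique": int(len(catalog.unique))}

        stage = "density"
        smoother = SmootherConfig(b=config.b, L=config.L)
        manifest["stages"][stage] = {}
        for mclass in config.classes:
            if catalog.n_unique(mclass) == 0:
                logger.info("density for %s skipped: no unique mutations", mclass)
                manifest["stages"][stage][mclass] = {"skipped": "empty class"}
                continue
            profile = density_profile(
                catalog, mclass, config=smoother,
                mode=config.expected_mode, alpha=config.alpha, m_tests=config.m_tests,
            )
            write_tsv(profile.to_frame(), out_dir / f"density_{mclass}.tsv")
            manifest["stages"][stage][mclass] = {
                "n": profile.n,
                "b": smoother.b,
                "expected_mode": config.expected_mode,
                "peak_position": int(np.argmax(profile.y_hat) + 1),
                "peak_fold": float(np.nanmax(profile.fold)),
            }

        stage = "enrichment"
        enrich_rows = []
        manifest["stages"][stage] = {}
        for name, start, end in config.domains:
            domain = DomainSpec(name, start, end)
            for mclass in config.classes:
                if catalog.n_unique(mclass) == 0:
                    continue
                res = domain_permutation_test(
                    catalog, mclass, domain,
                    n_perm=config.n_perm,
                    seed=_substream_seed(config.seed, f"enrich:{name}:{mclass}"),
                )
                enrich_rows.append(res.to_dict())
                (out_dir / f"enrichment_{name}_{mclass}.json").write_text(
                    json.dumps(res.to_dict(), indent=2, sort_keys=True) + "\n"
                )
        if enrich_rows:
            flat = pd.DataFrame(
                [
                    {
                        "domain": r["domain"]["name"],
                        "start": r["domain"]["start"],
                        "end": r["domain"]["end"],
                        "class": r["class"],
                        "n": r["n"],
                        "observed": r["observed"],
                        "expected_mean": r["expected_mean"],
                        "fold": r["fold"],
                        "rate_ratio": r["rate_ratio"],
                        "p_value": r["p_value"],
                    }
                    for r in enrich_rows
                ]
            )
            write_tsv(flat, out_dir / "enrichment.tsv")
        manifest["stages"][stage]["n_tests"] = len(enrich_rows)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(out_dir.iterdir()):
        if f.name in {"manifest.json", "INCOMPLETE"} or f.is_dir():
            continue
        manifest["files"][f.name] = _sha256(f)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    marker.unlink()
    return manifest
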