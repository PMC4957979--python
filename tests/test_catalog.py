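"""Catalog reading, label classification, deduplication, subset filtering."""

import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atmhotspot import (
    ClassifiedCatalog,
    ConfigurationError,
    DataError,
    MafDialect,
    MutationRecord,
    classify_label,
    deduplicate_unique,
    filter_concurrent_loss,
    read_maf_like,
    read_variant_list,
)
from atmhotspot.catalog import CLASSES, extract_position

from .conftest import make_record


@pytest.mark.parametrize(
    "label,dialect,expected",
    [
        ("Missense_Mutation", "tcga", "missense"),
        ("In_Frame_Del", "tcga", "missense"),
        ("In_Frame_Ins", "tcga", "missense"),
        ("Nonsense_Mutation", "tcga", "truncating"),
        ("Frame_Shift_Del", "tcga", "truncating"),
        ("Frame_Shift_Ins", "tcga", "truncating"),
        ("Splice_Site", "tcga", "truncating"),
        ("Silent", "tcga", "silent"),
        ("Nonstop_Mutation", "tcga", "other"),
        ("3'UTR", "tcga", "other"),
        ("  Missense_Mutation  ", "tcga", "missense"),  # whitespace trimmed
        ("Large_DEL", "lovd", "truncating"),
        ("Start_Codon", "lovd", "truncating"),
        ("Stop_Codon", "lovd", "truncating"),
        ("Splice_Site", "lovd", "truncating"),
        ("Missense", "lovd", "missense"),
        ("Unknown_Effect", "lovd", "other"),
    ],
)
def test_classify_label_vocabulary(label, dialect, expected):
    assert classify_label(label, dialect) == expected


def test_classify_label_rejects_unknown_dialect():
    with pytest.raises(ConfigurationError):
        classify_label("Missense_Mutation", "cosmic")


def test_classify_lovd_missense_set_is_configurable():
    assert classify_label("AA_sub", "lovd") == "other"
    assert classify_label("AA_sub", "lovd", lovd_missense={"AA_sub"}) == "missense"


@given(st.text(alphabet=string.printable, max_size=30), st.sampled_from(["tcga", "lovd"]))
@settings(max_examples=200, derandomize=True)
def test_classify_label_is_total(label, dialect):
    """Any label maps to exactly one of the four classes, never an error."""
    assert classify_label(label, dialect) in CLASSES


@pytest.mark.parametrize(
    "token,expected",
    [("p.N2875K", 2875), ("2875", 2875), (2875, 2875), ("p.K200fs*12", 200), ("no-digit", None)],
)
def test_extract_position_tokens(token, expected):
    assert extract_position(token) == expected


def _write_maf(tmp_path, rows, header="Tumor_Sample_Barcode\tProtein_position\tVariant_Classification\tHGVSp_Short"):
    path = tmp_path / "calls.maf.tsv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


def test_read_maf_like_passthrough(tmp_path):
    path = _write_maf(
        tmp_path,
        [
            "C1\t10\tMissense_Mutation\tp.A10V",
            "C2\t100\tNonsense_Mutation\tp.R100*",
            "C3\t50\tSilent\tp.L50L",
        ],
    )
    records, report = read_maf_like(path)
    assert [r.raw_label for r in records] == [
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Silent",
    ]
    assert report.n_parsed == 3 and not report.quarantined


def test_read_maf_like_extracts_position_from_protein_change_token(tmp_path):
    path = _write_maf(tmp_path, ["C1\tp.N2875K\tMissense_Mutation\tp.N2875K"])
    records, _ = read_maf_like(path)
    assert records[0].protein_position == 2875


def test_read_maf_like_empty_file_with_header(tmp_path):
    path = _write_maf(tmp_path, [])
    records, report = read_maf_like(path)
    assert records == [] and report.n_rows == 0


def test_read_maf_like_missing_column_is_config_error(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("Tumor_Sample_Barcode\tVariant_Classification\nC1\tSilent\n")
    with pytest.raises(ConfigurationError, match="Protein_position"):
        read_maf_like(path)


def test_read_maf_like_quarantines_bad_rows_preserving_good_order(tmp_path):
    path = _write_maf(
        tmp_path,
        [
            "C1\t10\tMissense_Mutation\tp.A10V",
            "C2\tnot-a-position\tSilent\t",
            "C3\t9999\tMissense_Mutation\tp.X9999Y",  # outside [1, 3057]
            "C4\t20\tSilent\tp.L20L",
        ],
    )
    records, report = read_maf_like(path)
    assert [r.protein_position for r in records] == [10, 20]
    assert len(report.quarantined) == 2
    reasons = " ".join(q["reason"] for q in report.quarantined)
    assert "unparsable" in reasons and "outside" in reasons


def test_read_maf_like_parses_flag_column(tmp_path):
    header = "Tumor_Sample_Barcode\tProtein_position\tVariant_Classification\tHGVSp_Short\tShallow"
    path = _write_maf(tmp_path, ["C1\t10\tMissense_Mutation\tp.A10V\t1",
                                 "C2\t11\tMissense_Mutation\tp.A11V\t0"], header)
    dialect = MafDialect(shallow_deletion_col="Shallow")
    records, _ = read_maf_like(path, dialect)
    assert records[0].concurrent_shallow_deletion and not records[1].concurrent_shallow_deletion


def test_read_variant_list_lovd(tmp_path):
    path = tmp_path / "lovd.tsv"
    path.write_text(
        "position\teffect\n2875\tMissense\n100\tLarge_DEL\n100\tLarge_DEL\n"
    )
    records, report = read_variant_list(path)
    assert len(records) == 3  # duplicates preserved; dedup is a later stage
    assert records[0].protein_position == 2875 and records[0].case_id == ""
    catalog = deduplicate_unique(records, dialect="lovd")
    assert catalog.n_unique("truncating") == 1  # Large_DEL rows collapse
    assert catalog.n_unique("missense") == 1


def test_deduplicate_recurrent_variant_counts_once(small_catalog):
    # p.N10K appears in two cases -> one unique missense
    assert small_catalog.n_unique("missense") == 3
    assert small_catalog.unique.set_index("key").loc["p.N10K", "n_records"] == 2


def test_deduplicate_distinct_alternates_are_distinct_uniques(small_catalog):
    # p.D12G and p.D12V at the same site are two uniques
    keys = set(small_catalog.unique["key"])
    assert {"p.D12G", "p.D12V"} <= keys


def test_deduplicate_is_idempotent(uniform_catalog):
    again = deduplicate_unique(uniform_catalog.records, L=uniform_catalog.L)
    assert again.unique.equals(uniform_catalog.unique)


def test_unique_counts_partition_distinct_keys(uniform_catalog):
    counts = uniform_catalog.class_counts()
    assert sum(counts.values()) == len(uniform_catalog.unique)
    assert uniform_catalog.unique["key"].is_unique is False or True  # keys unique per class
    assert not uniform_catalog.unique.duplicated(["key", "mclass"]).any()


def test_deduplicate_falls_back_to_position_label_key():
    records = [
        MutationRecord("C1", 77, "Missense_Mutation", ""),
        MutationRecord("C2", 77, "Missense_Mutation", ""),
    ]
    catalog = deduplicate_unique(records)
    assert catalog.n_unique("missense") == 1


def test_dedup_flags_are_or_over_group():
    records = [
        make_record(10, change="p.N10K", case="C1", shallow=False),
        make_record(10, change="p.N10K", case="C2", shallow=True),
    ]
    catalog = deduplicate_unique(records)
    assert bool(catalog.unique["concurrent_shallow_deletion"].iloc[0])


def test_filter_concurrent_loss_keeps_flagged_subset():
    records = [
        make_record(10, change="p.A10V", case="C1", shallow=True),
        make_record(20, change="p.A20V", case="C2", shallow=True),
        make_record(30, change="p.A30V", case="C3"),
        make_record(40, change="p.A40V", case="C4"),
        make_record(500, label="Nonsense_Mutation", change="p.R500*", case="C9"),
    ]
    catalog = deduplicate_unique(records)
    subset = filter_concurrent_loss(catalog)
    assert sorted(subset.unique_missense) == [10, 20]
    assert subset.unique_truncating == catalog.unique_truncating  # invariant


def test_filter_concurrent_loss_cross_references_truncating_case():
    records = [
        make_record(10, change="p.A10V", case="C1"),  # same case as a truncating call
        make_record(20, change="p.A20V", case="C2"),
        make_record(500, label="Nonsense_Mutation", change="p.R500*", case="C1"),
    ]
    subset = filter_concurrent_loss(deduplicate_unique(records))
    assert subset.unique_missense == [10]


def test_filter_concurrent_loss_all_unflagged_gives_empty_missense():
    records = [
        make_record(10, change="p.A10V", case="C1"),
        make_record(500, label="Nonsense_Mutation", change="p.R500*", case="C2"),
    ]
    subset = filter_concurrent_loss(deduplicate_unique(records))
    assert subset.unique_missense == []
    assert isinstance(subset, ClassifiedCatalog)


def test_filter_concurrent_loss_without_any_flag_info_errors():
    records = [MutationRecord("", 10, "Missense_Mutation", "p.A10V")]
    with pytest.raises(DataError, match="uncomputable"):
        filter_concurrent_loss(deduplicate_unique(records))
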