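"""Audit reports and the patient-level binary dataset."""

from collections import Counter

import pytest

from notepheno.annotate import categorize_corpus
from notepheno.context_library import CategoryLabel
from notepheno.errors import ConfigurationError
from notepheno.reports_export import (
    ACUTE_CONFIG,
    EVER_CONFIG,
    ExportConfig,
    aggregate_patients,
    audit_report,
    flags_from_frame,
    merge_datasets,
    phenotype_frame,
    read_dataset,
    write_dataset,
)
from notepheno.search import find_instances
from notepheno.textnorm import compile_pattern


@pytest.fixture
def categorized_db(sim_default):
    cond = sim_default.config.conditions[0]
    pat = compile_pattern(cond.name, list(cond.terms))
    db = find_instances(sim_default.corpus, pat)
    categorize_corpus(db, sim_default.library)
    return db


class TestExportConfig:
    def test_present_categories_exclude_negated(self):
        with pytest.raises(ConfigurationError):
            ExportConfig(present_categories=frozenset({CategoryLabel.NEGATED}))

    def test_fraction_bounds(self):
        with pytest.raises(ConfigurationError):
            ExportConfig(audit_sample_fraction=1.5)


class TestAuditReport:
    def test_full_report_lists_every_instance_once(self, categorized_db):
        report = audit_report(categorized_db, ACUTE_CONFIG)
        assert sorted(report["instance_id"]) == sorted(
            x.instance_id for x in categorized_db.instances
        )

    def test_category_counts_conserved(self, categorized_db):
        report = audit_report(categorized_db, ACUTE_CONFIG)
        by_cat = Counter(report["category"])
        truth = Counter(x.category.value for x in categorized_db.instances)
        assert by_cat == truth
        assert sum(by_cat.values()) == len(categorized_db.instances)

    def test_seeded_sampling_is_reproducible(self, categorized_db):
        cfg = ExportConfig(audit_sample_fraction=0.1, audit_seed=42)
        a = audit_report(categorized_db, cfg)
        b = audit_report(categorized_db, cfg)
        assert a.equals(b)
        assert len(a) == round(0.1 * len(categorized_db.instances))

    def test_different_seed_changes_sample(self, categorized_db):
        a = audit_report(categorized_db, ExportConfig(audit_sample_fraction=0.1, audit_seed=1))
        b = audit_report(categorized_db, ExportConfig(audit_sample_fraction=0.1, audit_seed=2))
        assert set(a["instance_id"]) != set(b["instance_id"])


class TestAggregatePatients:
    def _one_patient(self, category, cfg):
        from notepheno.corpus_io import NoteRecord

        text = {
            CategoryLabel.ACUTE_PRESENT: "admitted with pneumonia",
            CategoryLabel.HISTORICAL_CHRONIC: "history of pneumonia",
            CategoryLabel.NEGATED: "no evidence of pneumonia",
            CategoryLabel.UNDER_EVALUATION: "suspected pneumonia",
            CategoryLabel.DIFFERENT_MEANING: "joint pneumonia performed",
        }[category]
        from notepheno.context_library import starter_library

        note = NoteRecord.build("p1", "n1", text)
        db = find_instances([note], compile_pattern("pneumonia", ["pneumonia"]))
        categorize_corpus(db, starter_library())
        assert db.instances[0].category is category
        (pheno,) = aggregate_patients(db, cfg, ["p1"])
        return pheno.flags["pneumonia"]

    @pytest.mark.parametrize(
        "category, acute_flag, ever_flag",
        [
            (CategoryLabel.ACUTE_PRESENT, 1, 1),
            (CategoryLabel.HISTORICAL_CHRONIC, 0, 1),
            (CategoryLabel.NEGATED, 0, 0),
            (CategoryLabel.UNDER_EVALUATION, 0, 0),
            (CategoryLabel.DIFFERENT_MEANING, 0, 0),
        ],
    )
    def test_category_to_flag_mapping(self, category, acute_flag, ever_flag):
        assert self._one_patient(category, ACUTE_CONFIG) == acute_flag
        assert self._one_patient(category, EVER_CONFIG) == ever_flag

    def test_screened_negatives_get_zero_rows(self, categorized_db, sim_default):
        screened = sim_default.patient_ids
        phenos = aggregate_patients(categorized_db, EVER_CONFIG, screened)
        assert [p.patient_id for p in phenos] == sorted(screened)
        assert any(p.flags["pneumonia"] == 0 for p in phenos)

    def test_support_counts_conserved(self, categorized_db, sim_default):
        phenos = aggregate_patients(categorized_db, EVER_CONFIG, sim_default.patient_ids)
        total = sum(
            n for p in phenos for c in p.support.values() for n in c.values()
        )
        assert total == len(categorized_db.instances)

    def test_enlarging_present_set_never_drops_a_flag(self, categorized_db, sim_default):
        acute = aggregate_patients(categorized_db, ACUTE_CONFIG, sim_default.patient_ids)
        ever = aggregate_patients(categorized_db, EVER_CONFIG, sim_default.patient_ids)
        for a, e in zip(acute, ever):
            assert e.flags["pneumonia"] >= a.flags["pneumonia"]

    def test_uncategorized_instances_block_export(self, sim_default):
        cond = sim_default.config.conditions[0]
        db = find_instances(sim_default.corpus, compile_pattern(cond.name, list(cond.terms)))
        with pytest.raises(ConfigurationError, match="uncategorized"):
            aggregate_patients(db, ACUTE_CONFIG, sim_default.patient_ids)
        # the documented escape hatch: ambiguous -> absent
        cfg = ExportConfig(uncategorized_as_absent=True)
        phenos = aggregate_patients(db, cfg, sim_default.patient_ids)
        assert all(p.flags[cond.name] == 0 for p in phenos)


class TestDatasets:
    def _phenos(self, categorized_db, sim_default):
        return aggregate_patients(categorized_db, EVER_CONFIG, sim_default.patient_ids)

    def test_written_dataset_shape_and_values(self, categorized_db, sim_default, tmp_path):
        phenos = self._phenos(categorized_db, sim_default)
        path = tmp_path / "flags.csv"
        df = write_dataset(phenos, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "patient_id,pneumonia"
        assert len(lines) == len(phenos) + 1
        assert set(df["pneumonia"]) <= {0, 1}

    def test_write_read_write_is_byte_identical(self, categorized_db, sim_default, tmp_path):
        phenos = self._phenos(categorized_db, sim_default)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_dataset(phenos, a)
        read_dataset(a).to_csv(b, index=False, lineterminator="\n")
        assert a.read_bytes() == b.read_bytes()

    def test_merge_is_column_union_without_row_duplication(self, sim_default):
        dbs = []
        for cond in sim_default.config.conditions:
            db = find_instances(
                sim_default.corpus, compile_pattern(cond.name, list(cond.terms))
            )
            categorize_corpus(db, sim_default.library)
            dbs.append(db)
        separate = [
            phenotype_frame(aggregate_patients(db, EVER_CONFIG, sim_default.patient_ids))
            for db in dbs
        ]
        merged = merge_datasets(*separate)
        joint = phenotype_frame(
            aggregate_patients(dbs, EVER_CONFIG, sim_default.patient_ids)
        )
        assert merged.equals(joint)
        assert len(merged) == len(sim_default.patient_ids)

    def test_flags_from_frame_round_trip(self, categorized_db, sim_default):
        phenos = self._phenos(categorized_db, sim_default)
        df = phenotype_frame(phenos)
        flags = flags_from_frame(df, "pneumonia")
        assert flags == {p.patient_id: p.flags["pneumonia"] for p in phenos}
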