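"""Auto-categorization and the expanding-context review workflow."""

import copy
from collections import Counter

import pytest

from notepheno.annotate import (
    ReviewGroup,
    ScriptedDecisions,
    apply_assignment,
    categorize_corpus,
    load_transcript,
    review_groups,
    review_session,
    save_transcript,
)
from notepheno.context_library import CategoryLabel, RuleLibrary
from notepheno.search import find_instances
from notepheno.synthgen import SimConfig, generate
from notepheno.textnorm import compile_pattern


def _search_all(sim):
    dbs = []
    for cond in sim.config.conditions:
        pat = compile_pattern(cond.name, list(cond.terms))
        dbs.append(find_instances(sim.corpus, pat))
    return dbs


class TestCategorize:
    def test_complete_library_leaves_nothing_uncategorized(self):
        """With the generator's own cue inventory, every instance resolves
        and every label equals the embedded ground-truth category."""
        sim = generate(SimConfig(n_patients=120, bloat_factor=0.0, seed=5))
        truth_counts = Counter(
            (t["note_id"], t["condition"], t["category"]) for t in sim.truth
        )
        seen = Counter()
        for db in _search_all(sim):
            _, uncategorized = categorize_corpus(db, sim.library)
            assert uncategorized == []
            for x in db.instances:
                seen[(x.note_id, x.condition_name, x.category.value)] += 1
        assert seen == truth_counts

    def test_empty_library_leaves_everything_uncategorized(self, sim_default):
        db = _search_all(sim_default)[0]
        _, uncategorized = categorize_corpus(db, RuleLibrary())
        assert len(uncategorized) == len(db.instances) > 0

    def test_idempotent(self, sim_default, starter_lib):
        db = _search_all(sim_default)[0]
        categorize_corpus(db, starter_lib)
        snapshot = copy.deepcopy(db.instances)
        categorize_corpus(db, starter_lib)
        assert db.instances == snapshot


class TestReviewGroups:
    def test_shared_windows_collapse_largest_first(self):
        """Five instances, three sharing one 3-token window: the shared
        group of three is listed first and one decision covers it."""
        from notepheno.corpus_io import NoteRecord

        texts = {
            "n1": "smear rules out pna today repeat pending",
            "n2": "culture rules out pna today repeat negative",
            "n3": "imaging rules out pna today repeat done",
            "n4": "admitted for pna treatment started",
            "n5": "recovering from pna slowly improving",
        }
        corpus = [NoteRecord.build("p1", nid, t) for nid, t in texts.items()]
        db = find_instances(corpus, compile_pattern("pneumonia", ["pna"]))
        groups = review_groups(db.instances, k=1)
        assert groups[0].size == 3
        assert groups[0].context_key == ("out", "<term>", "today")
        sizes = [g.size for g in groups]
        assert sizes == sorted(sizes, reverse=True)
        assert sum(sizes) == len(db.instances)  # a partition

    def test_members_share_identical_window(self, small_db):
        groups = review_groups(small_db.instances, k=2)
        by_id = {x.instance_id: x for x in small_db.instances}
        for g in groups:
            keys = {
                tuple(by_id[i].left_context[-2:])
                + ("<term>",)
                + tuple(by_id[i].right_context[:2])
                for i in g.member_instance_ids
            }
            assert keys == {g.context_key}

    def test_empty_uncategorized_set(self):
        assert review_groups([], k=3) == []

    def test_oversized_k_saturates(self, small_db):
        wide = review_groups(small_db.instances, k=50)
        wider = review_groups(small_db.instances, k=80)
        assert {g.context_key for g in wide} == {g.context_key for g in wider}


class TestApplyAssignment:
    def test_group_assignment_shrinks_pending_and_grows_library(self, small_db):
        lib = RuleLibrary()
        before = len(small_db.uncategorized_ids())
        group = review_groups(small_db.instances, k=3)[0]
        _, _, rule = apply_assignment(small_db, lib, group, CategoryLabel.NEGATED)
        assert len(small_db.uncategorized_ids()) == before - group.size
        assert len(lib) == 1
        assert rule.category is CategoryLabel.NEGATED

    def test_repeat_assignment_is_noop(self, small_db):
        lib = RuleLibrary()
        group = review_groups(small_db.instances, k=3)[0]
        apply_assignment(small_db, lib, group, CategoryLabel.NEGATED)
        apply_assignment(small_db, lib, group, CategoryLabel.NEGATED)
        assert len(lib) == 1
        assert [p["action"] for p in lib.provenance] == ["add", "duplicate-noop"]

    def test_uncategorized_cannot_be_assigned(self, small_db):
        group = review_groups(small_db.instances, k=3)[0]
        with pytest.raises(ValueError):
            apply_assignment(small_db, RuleLibrary(), group, CategoryLabel.UNCATEGORIZED)

    def test_promoted_rule_does_not_relabel_other_groups(self):
        """Library growth is monotone: new rules categorize their own
        group's instances without touching previously categorized ones."""
        sim = generate(SimConfig(n_patients=80, seed=9))
        db = _search_all(sim)[0]
        lib = RuleLibrary()
        groups = review_groups(db.instances, k=3)
        truth = {
            g.context_key: CategoryLabel.NEGATED if i % 2 else CategoryLabel.ACUTE_PRESENT
            for i, g in enumerate(groups)
        }
        assigned: dict[str, CategoryLabel] = {}
        while True:
            pending = [x for x in db.instances if x.category is CategoryLabel.UNCATEGORIZED]
            if not pending:
                break
            group = review_groups(pending, k=3)[0]
            apply_assignment(db, lib, group, truth[group.context_key])
            categorize_corpus(db, lib)
            for x in db.instances:
                if x.category is not CategoryLabel.UNCATEGORIZED:
                    if x.instance_id in assigned:
                        assert x.category is assigned[x.instance_id]
                    else:
                        assigned[x.instance_id] = x.category


def _full_decision_table(db, k_schedule):
    """Scripted reviewer answering NEGATED for every group it is shown."""

    def decide(group, k):
        return (CategoryLabel.NEGATED, "project")

    return decide


class TestReviewSession:
    def test_scripted_session_resolves_everything(self):
        sim = generate(SimConfig(n_patients=60, seed=3))
        db = _search_all(sim)[0]
        lib = RuleLibrary()
        report = review_session(db, lib, _full_decision_table(db, None))
        assert report.fully_resolved
        assert db.uncategorized_ids() == []
        assert report.n_assigned > 0

    def test_uncategorized_count_monotonically_decreases(self):
        sim = generate(SimConfig(n_patients=60, seed=4))
        db = _search_all(sim)[1]
        lib = RuleLibrary()
        counts = []

        def decide(group, k):
            counts.append(len(db.uncategorized_ids()))
            return (CategoryLabel.UNDER_EVALUATION, "general")

        review_session(db, lib, decide)
        assert counts == sorted(counts, reverse=True)

    def test_abstaining_source_returns_unresolved_report(self, small_db):
        report = review_session(small_db, RuleLibrary(), lambda g, k: None)
        assert not report.fully_resolved
        assert set(report.unresolved_ids) == set(small_db.uncategorized_ids())

    def test_transcript_replay_reproduces_session(self, tmp_path):
        sim = generate(SimConfig(n_patients=60, seed=6))
        [db_a] = _search_all(sim)[:1]
        lib_a = RuleLibrary()

        def reviewer(group, k):
            cats = (CategoryLabel.NEGATED, CategoryLabel.ACUTE_PRESENT,
                    CategoryLabel.UNDER_EVALUATION)
            return (cats[len(group.context_key) % 3], "project")

        report = review_session(db_a, lib_a, reviewer)
        path = tmp_path / "transcript.jsonl"
        save_transcript(report.transcript, path)

        [db_b] = _search_all(sim)[:1]
        lib_b = RuleLibrary()
        replay = review_session(db_b, lib_b, load_transcript(path))
        assert [x.category for x in db_b.instances] == [x.category for x in db_a.instances]
        assert [r.cue for r in lib_b.rules] == [r.cue for r in lib_a.rules]
        assert replay.fully_resolved == report.fully_resolved

    def test_k_schedule_must_increase(self, small_db):
        with pytest.raises(ValueError):
            review_session(small_db, RuleLibrary(), lambda g, k: None, k_schedule=(5, 3))
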