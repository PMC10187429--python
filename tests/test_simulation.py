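"""Mixed/unknown simulation generators, response classification, accuracy."""

import numpy as np
import pytest

from cellprompt import fixtures
from cellprompt.annotate import annotate_rows
from cellprompt.errors import SimulationError
from cellprompt.evaluation import reproducibility
from cellprompt.marker_io import MarkerGeneSet
from cellprompt.prompts import PromptOptions
from cellprompt.simulation import (
    MixedSimSpec,
    UnknownSimSpec,
    classify_response,
    collect_negative_control_labels,
    compute_sim_accuracy,
    simulate_mixed,
    simulate_unknown,
)


class TestSimulateMixed:
    def test_same_seed_gives_byte_identical_batches(self, breast_markers):
        spec = MixedSimSpec(seed=11)
        a = simulate_mixed(spec, breast_markers)
        b = simulate_mixed(spec, breast_markers)
        assert a.to_csv() == b.to_csv()

    def test_rep_composition_and_distinct_parents(self, breast_markers):
        spec = MixedSimSpec(n_mixed=4, n_single=6, n_reps=3, seed=5)
        batch = simulate_mixed(spec, breast_markers)
        for rep in range(1, 4):
            rep_qs = [q for q in batch.queries if q.rep_index == rep]
            kinds = [batch.truth[q.query_id].kind for q in rep_qs]
            assert kinds.count("mixed") == 4
            assert kinds.count("single") == 6
        for qid, t in batch.truth.items():
            if t.kind == "mixed":
                a, b = t.detail.split(",")
                assert a != b

    def test_two_type_set_mixes_the_dedup_union(self):
        markers = MarkerGeneSet(entries={"A": ["G1", "G2", "G3"], "B": ["G3", "G4"]})
        batch = simulate_mixed(MixedSimSpec(n_mixed=1, n_single=2, seed=0), markers)
        mixed_rows = {
            q.row for q in batch.queries if batch.truth[q.query_id].kind == "mixed"
        }
        assert mixed_rows <= {"G1,G2,G3,G4", "G3,G4,G1,G2"}

    def test_too_few_source_types_rejected(self):
        markers = MarkerGeneSet(entries={"A": ["G1"], "B": ["G2"]})
        with pytest.raises(SimulationError):
            simulate_mixed(MixedSimSpec(n_single=3), markers)

    def test_parent_sampling_is_roughly_uniform(self, breast_markers):
        # 12 types, 5 mixed/rep, 200 reps -> 2000 parent draws, expected ~167
        # per type; allow 5 standard deviations of binomial noise.
        spec = MixedSimSpec(n_mixed=5, n_single=2, n_reps=200, seed=19)
        batch = simulate_mixed(spec, breast_markers)
        counts = {name: 0 for name in breast_markers.entries}
        for t in batch.truth.values():
            if t.kind == "mixed":
                for parent in t.detail.split(","):
                    counts[parent] += 1
        n_draws = 2 * 5 * 200
        p = 2 / len(breast_markers.entries)
        expected = n_draws * p / 2
        sd = np.sqrt(n_draws * (1 / 12) * (11 / 12))
        for name, c in counts.items():
            assert abs(c - expected) < 5 * sd, name


class TestSimulateUnknown:
    def test_same_seed_gives_identical_batches(self, breast_markers):
        universe = fixtures.synthetic_gene_universe(seed=2)
        spec = UnknownSimSpec(seed=4)
        a = simulate_unknown(spec, universe, breast_markers)
        b = simulate_unknown(spec, universe, breast_markers)
        assert a.to_csv() == b.to_csv()

    def test_tiny_universe_rows_are_permutations_of_it(self, breast_markers):
        universe = [f"U{i}" for i in range(10)]
        spec = UnknownSimSpec(n_unknown=2, genes_per_unknown=10, n_known=2,
                              n_reps=1, seed=0)
        batch = simulate_unknown(spec, universe, breast_markers)
        for q in batch.queries:
            if batch.truth[q.query_id].kind == "unknown":
                assert sorted(q.row.split(",")) == sorted(universe)

    def test_universe_too_small_rejected(self, breast_markers):
        with pytest.raises(SimulationError):
            simulate_unknown(
                UnknownSimSpec(genes_per_unknown=10), ["G1"], breast_markers
            )

    def test_disjoint_universe_rows_never_equal_marker_lists(self, breast_markers):
        universe = fixtures.synthetic_gene_universe(seed=2)
        batch = simulate_unknown(UnknownSimSpec(seed=4), universe, breast_markers)
        marker_rows = {",".join(g) for g in breast_markers.entries.values()}
        for q in batch.queries:
            if batch.truth[q.query_id].kind == "unknown":
                assert q.row not in marker_rows


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "label,mode,positive",
        [
            ("mixture of T cells and B cells", "mixed_test", True),
            ("Mixed population", "mixed_test", True),
            ("T cells / B cells", "mixed_test", True),
            ("T cells", "mixed_test", False),
            ("unknown cell type", "unknown_test", True),
            ("novel cell population", "unknown_test", True),
            ("fibroblast", "unknown_test", False),
        ],
    )
    def test_keyword_rules(self, label, mode, positive):
        cls = classify_response(label, mode)
        assert cls.positive is positive
        if not positive:
            assert cls.label == label

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            classify_response("T cells", "other_test")


class TestComputeSimAccuracy:
    def test_all_correct_gives_one(self, breast_markers):
        batch = simulate_mixed(MixedSimSpec(n_reps=1, seed=0), breast_markers)
        labels = {
            q.query_id: (
                "mixture of both" if batch.truth[q.query_id].kind == "mixed"
                else batch.truth[q.query_id].detail
            )
            for q in batch.queries
        }
        result = compute_sim_accuracy(batch, labels, "mixed_test")
        assert result.mean_accuracy == result.pooled_accuracy == 1.0

    def test_eighteen_of_twenty_gives_point_nine(self, breast_markers):
        batch = simulate_mixed(MixedSimSpec(n_reps=1, seed=0), breast_markers)
        labels = {}
        wrong = 0
        for q in batch.queries:
            t = batch.truth[q.query_id]
            correct_label = "a mixture" if t.kind == "mixed" else t.detail
            if t.kind == "mixed" and wrong < 2:
                labels[q.query_id] = "fibroblast"  # miss two mixtures
                wrong += 1
            else:
                labels[q.query_id] = correct_label
        result = compute_sim_accuracy(batch, labels, "mixed_test")
        assert result.per_rep[0].accuracy == pytest.approx(0.9)

    def test_missing_labels_listed(self, breast_markers):
        batch = simulate_mixed(MixedSimSpec(n_reps=1, seed=0), breast_markers)
        with pytest.raises(SimulationError, match="missing"):
            compute_sim_accuracy(batch, {}, "mixed_test")

    def test_parent_only_answers_counted_incorrect_but_reported(self, breast_markers):
        batch = simulate_mixed(MixedSimSpec(n_reps=1, seed=0), breast_markers)
        labels = {}
        target = None
        for q in batch.queries:
            t = batch.truth[q.query_id]
            if t.kind == "mixed" and target is None:
                target = q.query_id
                labels[q.query_id] = t.detail.split(",")[0]  # one parent only
            elif t.kind == "mixed":
                labels[q.query_id] = "a mixture"
            else:
                labels[q.query_id] = t.detail
        result = compute_sim_accuracy(batch, labels, "mixed_test")
        assert result.parent_only_ids == [target]
        assert result.pooled_accuracy == pytest.approx(19 / 20)


def _run_pipeline(batch, backend, context, options):
    return annotate_rows(
        [(q.query_id, q.row) for q in batch.queries], context, backend, options
    )


class TestClosedLoopWithOracle:
    def test_mock_backend_achieves_perfect_mixed_accuracy(
        self, breast_markers, mock_backend, context
    ):
        batch = simulate_mixed(MixedSimSpec(seed=23), breast_markers)
        labels = _run_pipeline(
            batch, mock_backend, context, PromptOptions(allow_mixture=True)
        )
        assert compute_sim_accuracy(batch, labels, "mixed_test").mean_accuracy == 1.0

    def test_mock_backend_achieves_perfect_unknown_accuracy(
        self, breast_markers, mock_backend, context
    ):
        universe = fixtures.synthetic_gene_universe(seed=23)
        batch = simulate_unknown(UnknownSimSpec(seed=23), universe, breast_markers)
        labels = _run_pipeline(
            batch, mock_backend, context, PromptOptions(allow_unknown=True)
        )
        assert compute_sim_accuracy(batch, labels, "unknown_test").mean_accuracy == 1.0


class TestCollectNegativeControls:
    def test_groups_across_studies_and_reps(self, breast_markers, mock_backend, context):
        mixed = simulate_mixed(MixedSimSpec(seed=31), breast_markers)
        universe = fixtures.synthetic_gene_universe(seed=31)
        unknown = simulate_unknown(UnknownSimSpec(seed=32), universe, breast_markers)
        labels = {
            **_run_pipeline(mixed, mock_backend, context, PromptOptions(allow_mixture=True)),
            **_run_pipeline(unknown, mock_backend, context, PromptOptions(allow_unknown=True)),
        }
        grouped = collect_negative_control_labels([mixed, unknown], labels)
        n_controls = sum(
            1 for b in (mixed, unknown) for q in b.queries
            if b.truth[q.query_id].kind == "single"
        )
        assert sum(len(v) for v in grouped.values()) == n_controls
        # deterministic backend -> constant labels -> reproducibility 1.0
        report = reproducibility(grouped)
        assert report.mean_reproducibility == 1.0

    def test_never_sampled_type_absent(self, breast_markers):
        batch = simulate_mixed(
            MixedSimSpec(n_mixed=1, n_single=1, n_reps=1, seed=0), breast_markers
        )
        labels = {q.query_id: "x" for q in batch.queries}
        grouped = collect_negative_control_labels([batch], labels)
        assert len(grouped) == 1
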