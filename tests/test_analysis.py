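"""Stratified comparisons and full-study orchestration."""

import yaml
import pytest

from tfoverlap.analysis import (
    PropertySpec,
    analyze_categorical,
    analyze_numeric,
    bound_tf_counts,
    results_frame,
    run_full_study,
)
from tfoverlap.overlap import op_for_gene_set, op_for_tf_set, stratify_top_bottom
from tfoverlap.redundancy import score_all_redundancy
from tfoverlap.simulate import (
    WorldParams,
    default_study_config,
    generate_world,
    world_maps,
    write_world,
)


@pytest.fixture(scope="module")
def masked_world_maps(default_world):
    return world_maps(default_world)


class TestAnalyzeNumeric:
    def test_row_per_x_and_floor_sizes(self, masked_world_maps, default_world):
        binding, knockout, universe = masked_world_maps
        genes = sorted(universe.genes)[:20]
        scores = {g: float(i) for i, g in enumerate(genes)}
        spec = PropertySpec(name="toy", level="gene", mode="numeric_top_bottom",
                            x_grid=(10.0, 20.0))
        res = analyze_numeric(spec, scores, binding, knockout, universe)
        assert len(res.rows) == 2
        # floor(20*0.10)=2 and floor(20*0.20)=4 entities per stratum
        assert [r.group1.n_entities for r in res.rows] == [2, 4]
        assert [r.group2.n_entities for r in res.rows] == [2, 4]

    def test_masked_world_depresses_high_fr_op_at_every_x(self, default_world, masked_world_maps):
        """With strong masking, the top-FR stratum's OP sits below the
        bottom-FR stratum's OP across the whole X grid."""
        binding, knockout, universe = masked_world_maps
        red = score_all_redundancy(default_world.annotation_catalog, universe.tfs)
        spec = PropertySpec(name="fr", level="tf", mode="numeric_top_bottom",
                            expected_direction="first_group_higher")
        res = analyze_numeric(spec, dict(red.fr_by_tf), binding, knockout, universe)
        for row in res.rows:
            assert row.group2.op < row.group1.op  # top (high FR) < bottom (low FR)
            assert row.test.p_value < 0.001

    def test_constant_scores_rejected(self, masked_world_maps):
        binding, knockout, universe = masked_world_maps
        scores = {g: 1.0 for g in list(universe.genes)[:50]}
        spec = PropertySpec(name="flat", level="gene", mode="numeric_top_bottom")
        with pytest.raises(ValueError, match="identical"):
            analyze_numeric(spec, scores, binding, knockout, universe)

    def test_out_of_universe_entities_are_logged(self, masked_world_maps):
        binding, knockout, universe = masked_world_maps
        genes = sorted(universe.genes)[:20]
        scores = {g: float(i) for i, g in enumerate(genes)}
        scores["NOT_A_GENE"] = 5.0
        spec = PropertySpec(name="toy", level="gene", mode="numeric_top_bottom",
                            x_grid=(50.0,))
        res = analyze_numeric(spec, scores, binding, knockout, universe)
        assert ("NOT_A_GENE", "outside universe") in res.exclusions


class TestAnalyzeCategorical:
    def test_reduced_effect_class_is_detected(self, default_world, masked_world_maps):
        """NFR-containing genes carry a <1 effect multiplier in the
        generative model; the split recovers a lower OP, significantly."""
        binding, knockout, universe = masked_world_maps
        spec = PropertySpec(name="nfr", level="gene", mode="categorical_two_lists",
                            expected_direction="first_group_lower")
        res = analyze_categorical(
            spec,
            default_world.class_lists["nfr_containing"],
            default_world.class_lists["nfr_less"],
            binding, knockout, universe,
        )
        row = res.rows[0]
        assert row.group1.op < row.group2.op
        assert row.test.p_value < 0.001

    def test_same_list_both_sides_is_degenerate(self, masked_world_maps):
        binding, knockout, universe = masked_world_maps
        genes = frozenset(sorted(universe.genes)[:200])
        spec = PropertySpec(name="same", level="gene", mode="categorical_two_lists")
        res = analyze_categorical(spec, genes, genes, binding, knockout, universe)
        assert res.rows[0].test.z == 0.0
        assert res.rows[0].test.p_value == 0.5

    def test_vs_rest_with_full_universe_errors(self, masked_world_maps):
        binding, knockout, universe = masked_world_maps
        spec = PropertySpec(name="all", level="gene", mode="categorical_vs_rest")
        with pytest.raises(ValueError, match="complement"):
            analyze_categorical(spec, universe.gene_set, "rest", binding, knockout, universe)


@pytest.fixture(scope="module")
def world_dir(tmp_path_factory, default_world):
    d = tmp_path_factory.mktemp("world")
    write_world(default_world, d)
    return d


class TestRunFullStudy:
    def test_file_run_matches_in_memory_analysis(self, world_dir, default_world):
        config = yaml.safe_load((world_dir / "study.yaml").read_text())
        res = run_full_study(config, world_dir)
        binding, knockout, universe = world_maps(default_world)
        in_mem = op_for_tf_set(universe.tfs, binding, knockout)
        assert (res.overall.numerator, res.overall.denominator) == (
            in_mem.numerator, in_mem.denominator)

    def test_every_injected_direction_recovered_at_x50(self, world_dir):
        config = yaml.safe_load((world_dir / "study.yaml").read_text())
        res = run_full_study(config, world_dir)
        assert len(res.analyses) == len(config["properties"])
        for a in res.analyses:
            row = a.rows[-1]  # X=50 for numeric, the single split otherwise
            diff = row.group1.op - row.group2.op
            if a.spec.expected_direction == "first_group_lower":
                assert diff < 0, a.spec.name
            else:
                assert diff > 0, a.spec.name

    def test_gene_level_never_uses_tf_pooling(self, world_dir):
        """Level correctness via the conservation identity: a gene-level
        stratum's denominator is a sum of |T_B(g)|, so pooling the two
        disjoint strata never exceeds the total pair count."""
        config = yaml.safe_load((world_dir / "study.yaml").read_text())
        res = run_full_study(config, world_dir)
        total = res.overall.denominator
        for a in res.analyses:
            for row in a.rows:
                assert row.group1.denominator + row.group2.denominator <= total

    def test_results_tsv_is_deterministic(self, world_dir, tmp_path):
        config = yaml.safe_load((world_dir / "study.yaml").read_text())
        frames = [results_frame(run_full_study(config, world_dir).analyses) for _ in range(2)]
        a, b = (f.to_csv(sep="\t", index=False) for f in frames)
        assert a == b

    def test_missing_property_file_names_the_property(self, world_dir):
        config = yaml.safe_load((world_dir / "study.yaml").read_text())
        config["properties"] = [dict(config["properties"][1], scores="absent.tsv")]
        with pytest.raises(RuntimeError, match="expression"):
            run_full_study(config, world_dir)


def test_bound_tf_counts_match_map_degree(masked_world_maps):
    binding, _, universe = masked_world_maps
    counts = bound_tf_counts(binding, universe)
    for g in list(universe.genes)[:100]:
        assert counts[g] == len(binding.regulators_of(g))
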