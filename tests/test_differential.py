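"""Differential testing, score correlation, DEG intersection and ORA."""

import numpy as np
import pandas as pd
import pytest

from broadres import (
    GeneSetLibrary,
    OmicsMatrix,
    ValidationError,
    correlate_with_score,
    intersect_degs,
    joint_ora,
    ora_enrichment,
    two_class_differential,
)
from broadres.datatypes import GroupAssignment

from _oracles import fisher_p_oracle, pearson_r_oracle, welch_p_oracle
from test_cohorts import scores_from_series


def omics(data: dict[str, list], lines: list[str]) -> OmicsMatrix:
    return OmicsMatrix(values=pd.DataFrame(data, index=lines).T)


def make_groups(res, sen):
    return GroupAssignment(
        strategy="decile", resistant=frozenset(res), sensitive=frozenset(sen)
    )


class TestTwoClassDifferential:
    def test_identical_group_values_are_null(self):
        lines = ["R1", "R2", "R3", "S1", "S2", "S3"]
        mat = omics({"g": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]}, lines)
        out = two_class_differential(mat, make_groups(lines[:3], lines[3:]))
        assert out.iloc[0].effect_size == pytest.approx(0.0)
        assert out.iloc[0].p_value == pytest.approx(1.0)

    def test_constant_equal_feature_gets_p_one(self):
        lines = ["R1", "R2", "S1", "S2"]
        mat = omics({"g": [5.0, 5.0, 5.0, 5.0]}, lines)
        out = two_class_differential(mat, make_groups(lines[:2], lines[2:]))
        assert out.iloc[0].p_value == 1.0

    def test_label_swap_negates_effects_and_preserves_p(self, mini_bundle, mini_groups):
        fwd = two_class_differential(mini_bundle.expression, mini_groups)
        rev = two_class_differential(
            mini_bundle.expression,
            make_groups(mini_groups.sensitive, mini_groups.resistant),
        )
        np.testing.assert_allclose(
            fwd.effect_size.to_numpy(), -rev.effect_size.to_numpy(), atol=1e-12
        )
        np.testing.assert_allclose(
            fwd.p_value.to_numpy(), rev.p_value.to_numpy(), rtol=1e-12
        )

    def test_matches_reference_welch_computation(self):
        rng = np.random.default_rng(5)
        lines = [f"R{i}" for i in range(6)] + [f"S{i}" for i in range(8)]
        vals = {f"g{j}": rng.normal(size=14).tolist() for j in range(5)}
        mat = omics(vals, lines)
        out = two_class_differential(mat, make_groups(lines[:6], lines[6:])).set_index("feature")
        for gene, row in vals.items():
            expected = welch_p_oracle(row[:6], row[6:])
            assert out.loc[gene, "p_value"] == pytest.approx(expected, abs=1e-9)

    def test_direction_matches_effect_sign(self, mini_bundle, mini_groups):
        out = two_class_differential(mini_bundle.expression, mini_groups)
        up = out.direction == "up_in_resistant"
        assert (out.effect_size[up] > 0).all()
        assert (out.effect_size[~up] <= 0).all()

    def test_too_small_groups_rejected(self):
        lines = ["R1", "S1", "S2"]
        mat = omics({"g": [1.0, 2.0, 3.0]}, lines)
        with pytest.raises(ValidationError):
            two_class_differential(mat, make_groups(lines[:1], lines[1:]))


class TestCorrelateWithScore:
    def test_self_and_negated_feature_retained(self):
        rng = np.random.default_rng(2)
        lines = [f"L{i}" for i in range(30)]
        comp = pd.Series(rng.normal(size=30), index=lines)
        mat = omics(
            {
                "same": comp.tolist(),
                "neg": (-comp).tolist(),
                "flat": [1.0] * 30,
            },
            lines,
        )
        out = correlate_with_score(mat, scores_from_series(comp)).set_index("feature")
        assert out.loc["same", "pearson_r"] == pytest.approx(1.0)
        assert out.loc["neg", "pearson_r"] == pytest.approx(-1.0)
        assert bool(out.loc["same", "retained"]) and bool(out.loc["neg", "retained"])
        assert out.loc["flat", "excluded_reason"] == "zero variance"
        assert not bool(out.loc["flat", "retained"])

    def test_r_matches_longhand_computation(self, mini_bundle, mini_scores):
        out = correlate_with_score(mini_bundle.expression, mini_scores).set_index("feature")
        comp = mini_scores.composite.dropna()
        shared = [l for l in mini_bundle.expression.values.columns if l in comp.index]
        y = comp.reindex(shared)
        for gene in list(out.index[:8]):
            expected = pearson_r_oracle(
                mini_bundle.expression.values.loc[gene, shared], y
            )
            assert out.loc[gene, "pearson_r"] == pytest.approx(expected, abs=1e-10)


def deg_frame(entries: dict[str, tuple[float, str]]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": list(entries),
            "effect_size": [1.0 if d == "up_in_resistant" else -1.0 for _, d in entries.values()],
            "p_value": [p for p, _ in entries.values()],
            "q_value": [p for p, _ in entries.values()],
            "direction": [d for _, d in entries.values()],
        }
    )


class TestIntersectDegs:
    def test_plain_set_intersection(self):
        up = "up_in_resistant"
        r1 = deg_frame({"a": (0.01, up), "b": (0.01, up), "c": (0.01, up), "x": (0.9, up)})
        r2 = deg_frame({"b": (0.02, up), "c": (0.02, up), "d": (0.02, up)})
        r3 = deg_frame({"c": (0.03, up), "b": (0.03, up)})
        got_up, got_down = intersect_degs([r1, r2, r3])
        assert got_up == frozenset({"b", "c"}) and got_down == frozenset()

    def test_inconsistent_direction_excluded(self):
        r1 = deg_frame({"g": (0.01, "up_in_resistant")})
        r2 = deg_frame({"g": (0.01, "down_in_resistant")})
        up, down = intersect_degs([r1, r2], require_consistent_direction=True)
        assert not up and not down
        up, down = intersect_degs([r1, r2], require_consistent_direction=False)
        assert up == frozenset({"g"})

    def test_invariant_to_result_order(self, mini_bundle, mini_groups, mini_scores):
        from broadres import balance_lineages, refine_by_clustering

        degs = [
            two_class_differential(mini_bundle.expression, mini_groups),
            two_class_differential(
                mini_bundle.expression,
                refine_by_clustering(mini_bundle.expression, mini_scores, mini_groups),
            ),
        ]
        fwd = intersect_degs(degs)
        rev = intersect_degs(degs[::-1])
        assert fwd == rev

    def test_single_result_rejected(self):
        with pytest.raises(ValidationError):
            intersect_degs([deg_frame({"a": (0.01, "up_in_resistant")})])


class TestORA:
    def test_exact_set_match_ranks_first(self):
        universe = {f"g{i}" for i in range(100)}
        lib = GeneSetLibrary(
            sets={
                "hit": frozenset({"g1", "g2", "g3"}),
                "other": frozenset({"g50", "g51", "g52", "g53"}),
            }
        )
        out = ora_enrichment({"g1", "g2", "g3"}, lib, universe)
        assert out.iloc[0].set_name == "hit"
        assert out.iloc[0].overlap_size == 3

    def test_disjoint_query_is_null(self):
        universe = {f"g{i}" for i in range(50)}
        lib = GeneSetLibrary(sets={"s": frozenset({"g40", "g41"})})
        out = ora_enrichment({"g1", "g2"}, lib, universe)
        assert (out.p_value >= 0.5).all()

    def test_empty_query_rejected(self):
        lib = GeneSetLibrary(sets={"s": frozenset({"a"})})
        with pytest.raises(ValidationError):
            ora_enrichment(set(), lib, {"a", "b"})

    def test_p_matches_exhaustive_oracle_small_universe(self):
        universe = {f"g{i}" for i in range(20)}
        rng = np.random.default_rng(9)
        for _ in range(20):
            set_size = int(rng.integers(1, 15))
            query_size = int(rng.integers(1, 15))
            members = set(rng.choice(sorted(universe), size=set_size, replace=False))
            query = set(rng.choice(sorted(universe), size=query_size, replace=False))
            lib = GeneSetLibrary(sets={"s": frozenset(members)})
            out = ora_enrichment(query, lib, universe)
            expected = fisher_p_oracle(
                len(query & members), query_size, set_size, 20, "greater"
            )
            assert out.iloc[0].p_value == pytest.approx(expected, abs=1e-10)


class TestJointORA:
    def test_reduces_to_ora_without_metabolites(self):
        universe = {f"g{i}" for i in range(30)}
        lib = GeneSetLibrary(sets={"s": frozenset({"g1", "g2", "g3"})})
        query = {"g1", "g2", "g9"}
        joint = joint_ora(query, set(), lib, universe)
        plain = ora_enrichment(query, lib, universe)
        pd.testing.assert_frame_equal(joint, plain)

    def test_metabolite_only_pathway_detected(self):
        universe = {f"g{i}" for i in range(50)} | {f"m{i}" for i in range(50)}
        lib = GeneSetLibrary(sets={"metab": frozenset({"m1", "m2", "m3"})})
        out = joint_ora(set(), {"m1", "m2", "m3"}, lib, universe)
        assert out.iloc[0].p_value < 1e-4

    def test_planted_joint_pathway_ranks_first(self, mini_bundle):
        truth = mini_bundle.truth
        universe = set(mini_bundle.expression.values.index) | set(
            mini_bundle.metabolites.values.index
        )
        out = joint_ora(
            set(truth.true_signature_up),
            set(truth.shifted_metabolites),
            mini_bundle.pathways,
            universe,
        )
        # the mixed-member planted pathway must beat every random pathway
        mixed = out[out.set_name == "JOINT_METABOLIC_PATHWAY"].iloc[0]
        random_best = out[out.set_name.str.startswith("PW_")].p_value.min()
        assert mixed.p_value < random_best
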