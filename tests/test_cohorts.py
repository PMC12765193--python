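"""Group-selection strategies and the metadata covariate screen."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from broadres import (
    CellLinePanel,
    OmicsMatrix,
    ValidationError,
    balance_lineages,
    covariate_screen,
    refine_by_clustering,
    select_decile_groups,
    simulate_panel,
    compute_scores,
)
from broadres.datatypes import SensitivityScoreTable

from conftest import mini_config


def scores_from_series(comp: pd.Series) -> SensitivityScoreTable:
    table = pd.DataFrame(
        {"composite": comp, "global_median": comp, "n_classes_used": 2}
    )
    table.index.name = "line_id"
    return SensitivityScoreTable(
        table=table, class_medians=pd.DataFrame(index=comp.index), n_classes=2
    )


class TestDecileGroups:
    def test_910_lines_gives_91_per_group(self):
        comp = pd.Series(
            np.linspace(-3, 0, 910), index=[f"L{i:04d}" for i in range(910)]
        )
        groups = select_decile_groups(scores_from_series(comp))
        assert len(groups.resistant) == len(groups.sensitive) == 91
        assert not groups.resistant & groups.sensitive

    def test_100_lines_disjoint_deciles(self):
        rng = np.random.default_rng(0)
        comp = pd.Series(rng.normal(size=100), index=[f"L{i}" for i in range(100)])
        groups = select_decile_groups(scores_from_series(comp))
        assert len(groups.resistant) == len(groups.sensitive) == 10
        assert not groups.resistant & groups.sensitive
        # resistant = least negative LFC
        assert min(comp[l] for l in groups.resistant) > max(
            comp[l] for l in groups.sensitive
        )

    def test_degenerate_ties_resolved_deterministically(self):
        comp = pd.Series(0.0, index=[f"L{i:02d}" for i in range(30)])
        a = select_decile_groups(scores_from_series(comp))
        b = select_decile_groups(scores_from_series(comp.sample(frac=1, random_state=1)))
        assert a.resistant == b.resistant and a.sensitive == b.sensitive
        assert len(a.resistant) == 3 and not a.resistant & a.sensitive

    def test_zero_k_rejected(self):
        comp = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(ValidationError):
            select_decile_groups(scores_from_series(comp), fraction=0.10)

    @pytest.mark.parametrize("fraction", [0.0, 0.6, -0.1])
    def test_fraction_bounds(self, fraction):
        comp = pd.Series(np.arange(100.0), index=[f"L{i}" for i in range(100)])
        with pytest.raises(ValidationError):
            select_decile_groups(scores_from_series(comp), fraction=fraction)


class TestClusterRefinement:
    def _blob_fixture(self, seed, n_per=15, n_genes=80, sep=6.0):
        rng = np.random.default_rng(seed)
        lines = [f"R{i}" for i in range(n_per)] + [f"S{i}" for i in range(n_per)]
        X = rng.normal(size=(n_genes, 2 * n_per))
        X[:, :n_per] += sep  # resistant blob shifted on every gene
        expr = OmicsMatrix(
            values=pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)], columns=lines)
        )
        comp = pd.Series(
            np.r_[rng.normal(0, 0.1, n_per), rng.normal(-3, 0.1, n_per)], index=lines
        )
        scores = scores_from_series(comp)
        groups = select_decile_groups(scores, fraction=0.5)
        return expr, scores, groups

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_planted_blobs_exactly(self, seed):
        expr, scores, groups = self._blob_fixture(seed)
        refined = refine_by_clustering(expr, scores, groups, n_features=50)
        assert refined.resistant == groups.resistant
        assert refined.sensitive == groups.sensitive

    def test_n_features_above_gene_count_warns_and_uses_all(self):
        expr, scores, groups = self._blob_fixture(0, n_genes=30)
        with pytest.warns(UserWarning, match="using all"):
            refined = refine_by_clustering(expr, scores, groups, n_features=500)
        assert refined.members <= groups.members

    def test_refined_groups_are_subsets(self, mini_bundle, mini_scores, mini_groups):
        refined = refine_by_clustering(
            mini_bundle.expression, mini_scores, mini_groups
        )
        assert refined.resistant <= mini_groups.resistant
        assert refined.sensitive <= mini_groups.sensitive
        assert refined.strategy == "cluster_refined"


class TestLineageBalance:
    def _panel(self, lineages: dict) -> CellLinePanel:
        return CellLinePanel(
            line_ids=list(lineages), lineage=lineages, metadata=None
        )

    def test_only_shared_lineages_used_and_min_rule(self):
        # resistant decile lineages {A: 2, B: 5}; sensitive {B: 3, C: 2}
        comp = {}
        lineages = {}
        for i in range(2):
            comp[f"rA{i}"] = 10.0 + i; lineages[f"rA{i}"] = "A"
        for i in range(5):
            comp[f"rB{i}"] = 20.0 + i; lineages[f"rB{i}"] = "B"
        for i in range(3):
            comp[f"sB{i}"] = -20.0 - i; lineages[f"sB{i}"] = "B"
        for i in range(2):
            comp[f"sC{i}"] = -10.0 - i; lineages[f"sC{i}"] = "C"
        for i in range(48):  # bulk keeps the deciles at the planted extremes
            comp[f"m{i:02d}"] = 0.0 + i * 0.01; lineages[f"m{i:02d}"] = "D"
        comp = pd.Series(comp)
        scores = scores_from_series(comp)
        groups = balance_lineages(scores, self._panel(lineages), fraction=6 / 60)
        # only lineage B is shared: min(5 resistant, 1 sensitive-decile B...)
        got_lineages = {lineages[l] for l in groups.members}
        assert got_lineages == {"B"}
        assert len(groups.resistant) == len(groups.sensitive)
        # resistant side takes the highest-score B lines
        assert all(l.startswith("rB") for l in groups.resistant)

    def test_no_shared_lineage_rejected(self):
        comp = pd.Series(
            {"r1": 5.0, "r2": 4.0, "s1": -5.0, "s2": -4.0}
        )
        lineages = {"r1": "A", "r2": "A", "s1": "B", "s2": "B"}
        with pytest.raises(ValidationError, match="lineage"):
            balance_lineages(
                scores_from_series(comp), self._panel(lineages), fraction=0.5
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_lineage_multisets_identical_on_random_fixtures(self, seed):
        bundle = simulate_panel(mini_config(seed=seed, n_lines=80))
        scores = compute_scores(bundle.drug_response)
        groups = balance_lineages(scores, bundle.panel)
        res = Counter(bundle.panel.lineage[l] for l in groups.resistant)
        sen = Counter(bundle.panel.lineage[l] for l in groups.sensitive)
        assert res == sen
        assert len(groups.resistant) == len(groups.sensitive)


class TestCovariateScreen:
    def test_constant_feature_skipped(self, mini_scores):
        lines = list(mini_scores.table.index)
        meta = pd.DataFrame({"const": ["x"] * len(lines)}, index=lines)
        panel = CellLinePanel(line_ids=lines, lineage={}, metadata=meta)
        out = covariate_screen(panel, mini_scores)
        row = out[out.feature == "const"].iloc[0]
        assert row.test == "skipped" and row.skip_reason == "constant"

    def test_self_association_ranks_first(self, mini_scores):
        lines = list(mini_scores.table.index)
        rng = np.random.default_rng(1)
        meta = pd.DataFrame(
            {
                "self": mini_scores.composite.reindex(lines),
                "noise": rng.normal(size=len(lines)),
            },
            index=lines,
        )
        panel = CellLinePanel(line_ids=lines, lineage={}, metadata=meta)
        out = covariate_screen(panel, mini_scores)
        assert out.iloc[0].feature == "self"
        assert out.iloc[0].p_value < 1e-20

    def test_null_features_calibrated(self, mini_scores):
        """Independent random covariates: ~5% nominal positives."""
        lines = list(mini_scores.table.index)
        rng = np.random.default_rng(7)
        meta = pd.DataFrame(
            {f"f{i:03d}": rng.normal(size=len(lines)) for i in range(200)},
            index=lines,
        )
        panel = CellLinePanel(line_ids=lines, lineage={}, metadata=meta)
        out = covariate_screen(panel, mini_scores)
        rate = float((out.p_value < 0.05).mean())
        ci = 2.576 * np.sqrt(0.05 * 0.95 / 200)
        assert abs(rate - 0.05) <= ci + 1 / 200
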