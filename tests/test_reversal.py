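"""Reversal screening, overlap validation, MoA enrichment and target tallies."""

import numpy as np
import pytest

from broadres import (
    SignatureLibrary,
    ValidationError,
    moa_enrichment,
    overlap_validation,
    reversal_screen,
    target_tally,
)

from _oracles import fisher_p_oracle


def random_library(rng, n_perts=50, n_genes=500, sig=20, moa_classes=None):
    genes = [f"g{i}" for i in range(n_genes)]
    signatures, moa = {}, {}
    labels = moa_classes or ["A", "B", "C", "D", "E"]
    for i in range(n_perts):
        picked = rng.choice(genes, size=2 * sig, replace=False)
        signatures[f"p{i:03d}"] = (frozenset(picked[:sig]), frozenset(picked[sig:]))
        moa[f"p{i:03d}"] = labels[i % len(labels)]
    return SignatureLibrary(signatures=signatures, moa=moa)


class TestReversalScreen:
    def test_planted_reverser_ranks_first(self, mini_bundle):
        truth = mini_bundle.truth
        out = reversal_screen(
            set(truth.true_signature_up),
            set(truth.true_signature_down),
            mini_bundle.signatures,
        )
        assert out.iloc[0].perturbagen_id in truth.true_reverser_ids
        assert out.iloc[0]["rank"] == 1
        assert out.iloc[0].q_value < 0.05

    def test_disjoint_perturbagen_scores_zero(self):
        rng = np.random.default_rng(0)
        lib = random_library(rng)
        # query drawn from genes outside every signature
        covered = lib.gene_space()
        universe = set(covered) | {f"x{i}" for i in range(50)}
        out = reversal_screen({f"x{i}" for i in range(20)}, set(), lib, universe)
        assert (out.combined_score == 0).all()

    def test_invariant_to_library_ordering(self, mini_bundle):
        truth = mini_bundle.truth
        sig = mini_bundle.signatures
        shuffled = SignatureLibrary(
            signatures=dict(sorted(sig.signatures.items(), reverse=True)),
            moa=sig.moa,
            targets=sig.targets,
        )
        a = reversal_screen(set(truth.true_signature_up), set(), sig)
        b = reversal_screen(set(truth.true_signature_up), set(), shuffled)
        assert list(a.perturbagen_id) == list(b.perturbagen_id)

    def test_swapping_queries_and_signatures_preserves_ranks(self, mini_bundle):
        truth = mini_bundle.truth
        sig = mini_bundle.signatures
        swapped = SignatureLibrary(
            signatures={p: (d, u) for p, (u, d) in sig.signatures.items()},
            moa=sig.moa,
        )
        fwd = reversal_screen(
            set(truth.true_signature_up), set(truth.true_signature_down), sig
        )
        rev = reversal_screen(
            set(truth.true_signature_down), set(truth.true_signature_up), swapped
        )
        assert list(fwd.perturbagen_id) == list(rev.perturbagen_id)
        np.testing.assert_allclose(
            fwd.combined_score.to_numpy(), rev.combined_score.to_numpy(), rtol=1e-12
        )

    def test_score_nonincreasing_as_overlap_shrinks(self):
        genes = [f"g{i}" for i in range(200)]
        sig_down = frozenset(genes[:30])
        lib = SignatureLibrary(signatures={"p": (frozenset(genes[100:120]), sig_down)})
        universe = set(genes)
        prev = np.inf
        for n_overlap in (20, 10, 5, 1):
            query = set(genes[:n_overlap]) | set(genes[150:170])
            score = reversal_screen(query, set(), lib, universe).iloc[0].combined_score
            assert score <= prev + 1e-12
            prev = score

    def test_overlapping_queries_rejected(self, mini_bundle):
        with pytest.raises(ValidationError):
            reversal_screen({"a"}, {"a"}, mini_bundle.signatures)


class TestOverlapValidation:
    def test_cross_product_example(self):
        odds, _ = overlap_validation(
            {f"a{i}" for i in range(5)} | {f"c{i}" for i in range(5)},
            {f"a{i}" for i in range(5)} | {f"b{i}" for i in range(5)},
            100,
        )
        assert odds == pytest.approx(17.0)

    def test_zero_overlap_small_sets(self):
        odds, p = overlap_validation({"a", "b"}, {"c", "d"}, 1000)
        assert odds == 0.0
        assert p > 0.9

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(ValidationError):
            overlap_validation({"a", "b"}, {"c"}, 2)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        pool = [f"g{i}" for i in range(25)]
        for _ in range(20):
            a = set(rng.choice(pool, size=int(rng.integers(1, 12)), replace=False))
            b = set(rng.choice(pool, size=int(rng.integers(1, 12)), replace=False))
            _, p = overlap_validation(a, b, 25)
            expected = fisher_p_oracle(len(a & b), len(a), len(b), 25, "two_sided")
            assert p == pytest.approx(expected, abs=1e-10)


class TestMoaEnrichment:
    def test_pure_class_hits_rank_first(self):
        rng = np.random.default_rng(1)
        lib = random_library(rng, n_perts=60)
        hits = {p for p, label in lib.moa.items() if label == "B"}
        out = moa_enrichment(hits, lib)
        assert out.iloc[0].set_name == "B"
        assert out.iloc[0].q_value < 0.05

    def test_p_matches_oracle_on_small_universe(self):
        rng = np.random.default_rng(2)
        lib = random_library(rng, n_perts=20, moa_classes=["A", "B"])
        hits = set(list(lib.signatures)[:6])
        out = moa_enrichment(hits, lib).set_index("set_name")
        for label in ("A", "B"):
            members = {p for p, l in lib.moa.items() if l == label}
            expected = fisher_p_oracle(len(hits & members), 6, len(members), 20, "greater")
            assert out.loc[label, "p_value"] == pytest.approx(expected, abs=1e-10)

    def test_no_moa_annotations_rejected(self):
        lib = SignatureLibrary(signatures={"p": (frozenset({"a"}), frozenset())})
        with pytest.raises(ValidationError):
            moa_enrichment({"p"}, lib)


class TestTargetTally:
    def test_counts_hit_compounds_per_gene(self):
        lib = SignatureLibrary(
            signatures={
                "p1": (frozenset({"a"}), frozenset()),
                "p2": (frozenset({"b"}), frozenset()),
                "p3": (frozenset({"c"}), frozenset()),
            },
            targets={
                "p1": frozenset({"G", "H"}),
                "p2": frozenset({"G"}),
                "p3": frozenset({"H"}),
            },
        )
        out = target_tally({"p1", "p2"}, lib)
        assert list(out.itertuples(index=False, name=None)) == [("G", 2), ("H", 1)]

    def test_empty_hits_empty_tally(self):
        lib = SignatureLibrary(
            signatures={"p1": (frozenset({"a"}), frozenset())},
            targets={"p1": frozenset({"G"})},
        )
        assert len(target_tally(set(), lib)) == 0

    def test_counts_match_brute_force(self, mini_bundle):
        lib = mini_bundle.signatures
        hits = set(list(lib.signatures)[:15])
        out = target_tally(hits, lib).set_index("gene")["n_compounds"]
        for gene in out.index:
            expected = sum(1 for p in hits if gene in lib.targets.get(p, ()))
            assert out[gene] == expected
        assert (out <= len(hits)).all()
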