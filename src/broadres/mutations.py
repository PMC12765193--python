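"""Mutation skew, per-sample pathway burden, pathway impact and set coverage.

Gene-level analysis: the *skew score* of a gene is the difference in the
percentage of mutated lines between the resistant and sensitive groups
(percentage points, in [-100, 100]); the top-k genes per direction feed
downstream enrichment.

Pathway-level analysis: each line's mutated gene set is tested for
over-representation in every pathway (one-sided Fisher over a fixed gene
universe), stored as -log10 p.  Per group and pathway,

    impact = (fraction of lines with p < alpha) * (mean -log10 p),

with the mean taken over *all* group lines, and the pathway *group skew* is
impact(resistant) - impact(sensitive).  Fractions (0.5, not 50) are used
inside the product so magnitudes are comparable across alpha choices;
reported tables carry both scales.

Set coverage: for a candidate convergent gene set, the percent of group
lines with at least one mutation in the set, and the exclusivity — the
fraction of covered lines carrying exactly one mutated set gene.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import GeneSetLibrary, GroupAssignment, MutationMatrix
from .errors import ValidationError
from .stats import fisher_overlap

__all__ = [
    "mutation_skew",
    "sample_pathway_burden",
    "pathway_impact",
    "set_coverage",
    "SkewResult",
    "PathwayBurdenResult",
    "CoverageResult",
]


class SkewResult:
    """Full per-gene skew table plus top-k lists per direction."""

    def __init__(self, table: pd.DataFrame, top_resistant: list[str], top_sensitive: list[str]):
        self.table = table
        self.top_resistant = top_resistant
        self.top_sensitive = top_sensitive

    def skew_of(self, gene: str) -> float:
        return float(self.table.set_index("gene").loc[gene, "skew"])


def mutation_skew(
    mut: MutationMatrix, groups: GroupAssignment, top_k: int = 50
) -> SkewResult:
    """Per-gene mutation-frequency skew between the two groups."""
    cols = set(mut.indicator.columns)
    res = sorted(groups.resistant & cols)
    sen = sorted(groups.sensitive & cols)
    if not res or not sen:
        raise ValidationError("groups have no members in the mutation matrix")
    missing = groups.members - cols
    if missing:
        warnings.warn(
            f"{len(missing)} group line(s) absent from mutation matrix",
            stacklevel=2,
        )
    pct_res = 100.0 * mut.indicator[res].mean(axis=1)
    pct_sen = 100.0 * mut.indicator[sen].mean(axis=1)
    table = pd.DataFrame(
        {
            "gene": mut.indicator.index,
            "pct_mutated_resistant": pct_res.to_numpy(),
            "pct_mutated_sensitive": pct_sen.to_numpy(),
        }
    )
    table["skew"] = table["pct_mutated_resistant"] - table["pct_mutated_sensitive"]
    # deterministic: |skew| descending, gene name ascending on ties
    by_res = table.sort_values(["skew", "gene"], ascending=[False, True], kind="stable")
    by_sen = table.sort_values(["skew", "gene"], ascending=[True, True], kind="stable")
    top_resistant = list(by_res.loc[by_res["skew"] > 0, "gene"][:top_k])
    top_sensitive = list(by_sen.loc[by_sen["skew"] < 0, "gene"][:top_k])
    return SkewResult(table=table, top_resistant=top_resistant, top_sensitive=top_sensitive)


def sample_pathway_burden(
    mut: MutationMatrix,
    library: GeneSetLibrary,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Pathway x line matrix of per-sample -log10 enrichment p-values.

    Each line's mutated gene set is tested against each pathway with a
    one-sided Fisher test over the universe (all genes in the matrix by
    default).  Lines with zero mutations score 0 everywhere (p = 1).
    """
    genes = set(mut.indicator.index)
    universe = set(universe) if universe is not None else genes
    stray = (library.all_members() & genes) - universe
    if stray:
        raise ValidationError(
            f"universe misses library genes present in matrix: {sorted(stray)[:5]}"
        )
    n = len(universe)
    pathways = sorted(library.sets)
    path_members = {p: library.sets[p] & universe for p in pathways}
    out = np.zeros((len(pathways), mut.indicator.shape[1]))
    ind = mut.indicator
    for j, line in enumerate(ind.columns):
        mutated = set(ind.index[ind[line].to_numpy() == 1]) & universe
        a = len(mutated)
        if a == 0:
            continue
        for i, pw in enumerate(pathways):
            members = path_members[pw]
            if not members:
                continue
            k = len(mutated & members)
            _, p = fisher_overlap(k, a, len(members), n, sidedness="greater")
            out[i, j] = -np.log10(max(p, np.finfo(float).tiny))
    return pd.DataFrame(out, index=pathways, columns=ind.columns)


class PathwayBurdenResult:
    """Group-level impact table and pathway skew from per-sample burden."""

    def __init__(self, per_sample_neglogp: pd.DataFrame, impact_table: pd.DataFrame):
        self.per_sample_neglogp = per_sample_neglogp
        self.impact_table = impact_table

    @property
    def group_skew(self) -> pd.Series:
        return self.impact_table.set_index("pathway")["group_skew"]


def pathway_impact(
    burden: pd.DataFrame,
    groups: GroupAssignment,
    alpha: float = 0.05,
) -> PathwayBurdenResult:
    """Group-level pathway impact and skew from a per-sample burden matrix."""
    cols = set(burden.columns)
    res = sorted(groups.resistant & cols)
    sen = sorted(groups.sensitive & cols)
    if not res or not sen:
        raise ValidationError("empty group after intersecting with burden matrix")
    threshold = -np.log10(alpha)
    rows = []
    for pw in burden.index:
        row = {"pathway": pw}
        for label, members in (("resistant", res), ("sensitive", sen)):
            vals = burden.loc[pw, members].to_numpy(dtype=float)
            frac = float((vals > threshold).mean())
            mean_nlp = float(vals.mean())
            row[f"frac_enriched_{label}"] = frac
            row[f"pct_enriched_{label}"] = 100.0 * frac
            row[f"mean_neglogp_{label}"] = mean_nlp
            row[f"impact_{label}"] = frac * mean_nlp
        row["group_skew"] = row["impact_resistant"] - row["impact_sensitive"]
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        "group_skew", ascending=False, kind="stable"
    ).reset_index(drop=True)
    return PathwayBurdenResult(per_sample_neglogp=burden, impact_table=table)


class CoverageResult:
    """Coverage and mutual-exclusivity of a gene set within one group."""

    def __init__(self, gene_set, per_gene_pct, coverage_pct, exclusivity, n_lines):
        self.gene_set = frozenset(gene_set)
        self.per_gene_pct = per_gene_pct
        self.coverage_pct = coverage_pct
        self.exclusivity = exclusivity
        self.n_lines = n_lines


def set_coverage(
    mut: MutationMatrix, gene_set: set[str], group: set[str]
) -> CoverageResult:
    """Fraction of group lines hit by the set, and how exclusively."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValidationError("empty gene set")
    present = sorted(gene_set & set(mut.indicator.index))
    if not present:
        raise ValidationError("gene set entirely absent from mutation matrix")
    lines = sorted(set(group) & set(mut.indicator.columns))
    if not lines:
        raise ValidationError("group has no members in the mutation matrix")
    sub = mut.indicator.loc[present, lines]
    hits_per_line = sub.sum(axis=0)
    covered = hits_per_line > 0
    coverage_pct = 100.0 * float(covered.mean())
    exclusivity = (
        float((hits_per_line[covered] == 1).mean()) if covered.any() else float("nan")
    )
    per_gene_pct = (100.0 * sub.mean(axis=1)).to_dict()
    return CoverageResult(
        gene_set=present,
        per_gene_pct=per_gene_pct,
        coverage_pct=coverage_pct,
        exclusivity=exclusivity,
        n_lines=len(lines),
    )
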