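"""Resistant / sensitive cohort selection and the metadata covariate screen.

Three complementary strategies define the comparison groups:

* **decile** — top and bottom deciles of the composite sensitivity score
  (resistant = least negative LFC, i.e. least killing);
* **cluster_refined** — within the decile groups, supervised feature
  selection (correlation prefilter, then two-group ANOVA F ranking)
  followed by Ward hierarchical clustering; the largest phenotype-pure
  clusters become the refined groups, trimming lines whose transcriptomes
  do not segregate with their phenotype;
* **lineage_balanced** — restrict to lineages present in both decile
  groups and take equal numbers per lineage, chosen by most extreme score,
  so the two groups have identical lineage multisets.

The covariate screen tests each panel metadata feature against the
composite score (one-way ANOVA for categorical features, a simple
regression slope test for numeric ones) with BH adjustment across all
tested features.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.feature_selection import f_classif

from .datatypes import (
    CellLinePanel,
    GroupAssignment,
    OmicsMatrix,
    SensitivityScoreTable,
)
from .errors import ValidationError
from .stats import bh_adjust

__all__ = [
    "select_decile_groups",
    "refine_by_clustering",
    "balance_lineages",
    "covariate_screen",
]


def select_decile_groups(
    scores: SensitivityScoreTable, fraction: float = 0.10
) -> GroupAssignment:
    """Top/bottom score fraction as resistant/sensitive groups.

    ``k = floor(fraction * n)`` over lines with a defined composite score.
    Ties are broken lexicographically by line id, so the assignment is
    deterministic even on degenerate score vectors.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValidationError(f"fraction must be in (0, 0.5], got {fraction}")
    comp = scores.composite.dropna()
    n = len(comp)
    k = int(np.floor(fraction * n))
    if k == 0:
        raise ValidationError(f"fraction {fraction} of {n} lines gives empty groups")
    ordered = sorted(comp.index, key=lambda l: (comp[l], l))
    sensitive = frozenset(ordered[:k])
    resistant = frozenset(ordered[-k:])
    return GroupAssignment(
        strategy="decile",
        resistant=resistant,
        sensitive=sensitive,
        provenance={"fraction": fraction, "n_scored": n, "k": k},
    )


def _linkage_clusters(link: np.ndarray, n_leaves: int) -> list[list[int]]:
    """Leaf index sets of every internal node of a scipy linkage matrix."""
    members: dict[int, list[int]] = {i: [i] for i in range(n_leaves)}
    out = []
    for step, (a, b, _, _) in enumerate(link):
        merged = members[int(a)] + members[int(b)]
        members[n_leaves + step] = merged
        out.append(merged)
    return out


def refine_by_clustering(
    expr: OmicsMatrix,
    scores: SensitivityScoreTable,
    groups: GroupAssignment,
    n_features: int = 250,
    r_threshold: float = 0.15,
    min_cluster_size: int = 3,
) -> GroupAssignment:
    """Trim decile groups to their largest phenotype-pure expression clusters.

    Steps: (1) Pearson |r| prefilter of genes against the composite score
    over the group members, (2) two-group ANOVA F ranking, keep the top
    ``n_features``, (3) per-gene z-scoring, (4) Ward/Euclidean hierarchical
    clustering of the members, (5) scan every dendrogram node and return,
    per phenotype, the largest cluster whose members all share that
    phenotype (ties broken by lower within-cluster variance).
    """
    members = sorted(groups.members & set(expr.values.columns))
    missing = groups.members - set(members)
    if missing:
        raise ValidationError(
            f"expression matrix lacks group members: {sorted(missing)[:5]}"
        )
    X = expr.values[members]  # genes x members
    y = np.array([1 if l in groups.resistant else 0 for l in members])
    comp = scores.composite.reindex(members).to_numpy()

    # (1) correlation prefilter vs composite score
    Xa = X.to_numpy()
    xc = Xa - Xa.mean(axis=1, keepdims=True)
    cc = comp - comp.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (cc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc @ cc / denom, 0.0)
    keep = np.abs(r) > r_threshold
    if keep.sum() == 0:
        warnings.warn("correlation prefilter removed all genes; skipping it", stacklevel=2)
        keep = np.ones(len(r), dtype=bool)
    Xk = Xa[keep]
    kept_genes = X.index[keep]

    # (2) ANOVA F ranking on the two phenotype groups
    with np.errstate(invalid="ignore", divide="ignore"):
        F, _ = f_classif(Xk.T, y)
    F = np.nan_to_num(F, nan=0.0)
    if len(kept_genes) < n_features:
        warnings.warn(
            f"only {len(kept_genes)} genes available (< n_features={n_features}); using all",
            stacklevel=2,
        )
        top = np.argsort(-F, kind="stable")
    else:
        top = np.argsort(-F, kind="stable")[:n_features]
    Xt = Xk[top]

    # (3) z-score each gene across members
    mu = Xt.mean(axis=1, keepdims=True)
    sd = Xt.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (Xt - mu) / sd

    # (4) Ward clustering of members
    link = hierarchy.linkage(Z.T, method="ward", metric="euclidean")

    # (5) largest phenotype-pure cluster per phenotype
    best: dict[int, tuple[int, float, list[int]]] = {}
    for node in _linkage_clusters(link, len(members)):
        labels = y[node]
        if len(node) < min_cluster_size or labels.min() != labels.max():
            continue
        phen = int(labels[0])
        var = float(Z[:, node].var())
        size = len(node)
        cur = best.get(phen)
        if cur is None or size > cur[0] or (size == cur[0] and var < cur[1]):
            best[phen] = (size, var, node)
    if 0 not in best or 1 not in best:
        raise ValidationError(
            f"no phenotype-pure cluster of size >= {min_cluster_size} for "
            "both phenotypes; groups may not separate transcriptionally"
        )
    resistant = frozenset(members[i] for i in best[1][2])
    sensitive = frozenset(members[i] for i in best[0][2])
    return GroupAssignment(
        strategy="cluster_refined",
        resistant=resistant,
        sensitive=sensitive,
        provenance={
            "n_features": int(min(n_features, len(kept_genes))),
            "r_threshold": r_threshold,
            "parent_strategy": groups.strategy,
        },
    )


def balance_lineages(
    scores: SensitivityScoreTable,
    panel: CellLinePanel,
    fraction: float = 0.10,
) -> GroupAssignment:
    """Lineage-balanced groups with identical lineage multisets.

    Start from the decile groups, keep only lineages present on both
    sides, and per shared lineage take ``m = min(count_resistant,
    count_sensitive)`` lines per side, chosen by most extreme composite
    score (highest for resistant, lowest for sensitive).
    """
    decile = select_decile_groups(scores, fraction)
    lineage = panel.lineage
    missing = [l for l in decile.members if l not in lineage]
    if missing:
        raise ValidationError(f"lines without lineage label: {missing[:5]}")
    res_by_lin: dict[str, list[str]] = {}
    sen_by_lin: dict[str, list[str]] = {}
    for l in decile.resistant:
        res_by_lin.setdefault(lineage[l], []).append(l)
    for l in decile.sensitive:
        sen_by_lin.setdefault(lineage[l], []).append(l)
    shared = sorted(set(res_by_lin) & set(sen_by_lin))
    if not shared:
        raise ValidationError("no lineage present in both decile groups")
    comp = scores.composite
    resistant: set[str] = set()
    sensitive: set[str] = set()
    for lin in shared:
        m = min(len(res_by_lin[lin]), len(sen_by_lin[lin]))
        res_sorted = sorted(res_by_lin[lin], key=lambda l: (-comp[l], l))
        sen_sorted = sorted(sen_by_lin[lin], key=lambda l: (comp[l], l))
        resistant.update(res_sorted[:m])
        sensitive.update(sen_sorted[:m])
    return GroupAssignment(
        strategy="lineage_balanced",
        resistant=frozenset(resistant),
        sensitive=frozenset(sensitive),
        provenance={"fraction": fraction, "shared_lineages": shared},
    )


def covariate_screen(
    panel: CellLinePanel, scores: SensitivityScoreTable
) -> pd.DataFrame:
    """Univariate association of every metadata feature with the composite.

    Categorical features: one-way ANOVA of the score across levels.
    Numeric features: two-sided test of the simple-regression slope.
    Constant or singleton features are skipped with a recorded reason;
    q-values are BH over all *tested* features.
    """
    if panel.metadata is None or panel.metadata.shape[1] == 0:
        raise ValidationError("panel has no metadata to screen")
    comp = scores.composite.dropna()
    meta = panel.metadata.reindex(comp.index)
    rows = []
    for feature in meta.columns:
        col = meta[feature].dropna()
        s = comp.reindex(col.index)
        if len(col) < 3:
            rows.append((feature, "skipped", np.nan, "too few observations", np.nan))
            continue
        if pd.api.types.is_numeric_dtype(col):
            if float(np.var(col.to_numpy(dtype=float))) == 0.0:
                rows.append((feature, "skipped", np.nan, "constant", np.nan))
                continue
            res = sps.linregress(col.to_numpy(dtype=float), s.to_numpy())
            rows.append((feature, "regression", float(res.pvalue), "", float(res.slope)))
        else:
            levels = [s[col == lv].to_numpy() for lv in col.unique()]
            levels = [g for g in levels if len(g) >= 2]
            if len(levels) < 2:
                rows.append((feature, "skipped", np.nan, "constant", np.nan))
                continue
            stat, p = sps.f_oneway(*levels)
            rows.append((feature, "anova", float(p), "", float(len(levels))))
    out = pd.DataFrame(
        rows, columns=["feature", "test", "p_value", "skip_reason", "slope_or_levels"]
    )
    tested = out["test"] != "skipped"
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = bh_adjust(out.loc[tested, "p_value"].to_numpy())
    out["q_value"] = q
    return out.sort_values("p_value", na_position="last").reset_index(drop=True)
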