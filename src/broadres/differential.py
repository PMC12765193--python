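"""Two-class differential analysis, score correlation, DEG intersection, ORA.

Differential testing is a per-feature Welch (unequal-variance) t-test on the
matrix scale (log2(TPM+1) for expression, normalized abundance for
metabolites); the effect size is the plain mean difference
resistant - sensitive, interpreted as a log2 fold difference for
expression.  Robust resistance markers are features that are nominally
significant with a consistent direction in *every* grouping strategy and
additionally correlate with the composite sensitivity score
(|r| > 0.15, q < 0.05 by default).

Over-representation analysis is a one-sided Fisher test per library set
against an explicit background universe, BH-adjusted across the library;
the joint variant simply pools genes and metabolites into one mixed query
and universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    GeneSetLibrary,
    GroupAssignment,
    OmicsMatrix,
    SensitivityScoreTable,
)
from .errors import ValidationError
from .stats import bh_adjust, fisher_overlap

__all__ = [
    "two_class_differential",
    "correlate_with_score",
    "intersect_degs",
    "ora_enrichment",
    "joint_ora",
]


def two_class_differential(
    omics: OmicsMatrix, groups: GroupAssignment
) -> pd.DataFrame:
    """Welch t-test per feature between resistant and sensitive lines.

    Returns a DataFrame with columns ``feature``, ``effect_size`` (mean
    resistant - mean sensitive), ``p_value``, ``q_value`` (BH across
    features) and ``direction``.  Features constant and equal across both
    groups get p = 1 rather than an error.
    """
    cols = set(omics.values.columns)
    res = sorted(groups.resistant & cols)
    sen = sorted(groups.sensitive & cols)
    if len(res) < 2 or len(sen) < 2:
        raise ValidationError("need >= 2 observed members per group")
    A = omics.values[res].to_numpy()
    B = omics.values[sen].to_numpy()
    effect = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = sps.ttest_ind(A, B, axis=1, equal_var=False)
    degenerate = np.isnan(p)
    if degenerate.any():
        # both groups constant: p=1 when the means agree, else overwhelming
        p = p.copy()
        p[degenerate & (effect == 0)] = 1.0
        p[degenerate & (effect != 0)] = 0.0
    q = bh_adjust(p)
    direction = np.where(effect > 0, "up_in_resistant", "down_in_resistant")
    return pd.DataFrame(
        {
            "feature": omics.values.index,
            "effect_size": effect,
            "p_value": p,
            "q_value": q,
            "direction": direction,
        }
    )


def correlate_with_score(
    omics: OmicsMatrix,
    scores: SensitivityScoreTable,
    r_threshold: float = 0.15,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of every feature with the composite score.

    Features are ``retained`` when |r| exceeds ``r_threshold`` AND the BH
    q-value is below ``q_threshold``.  Zero-variance features are excluded
    with a reason rather than given an undefined r.
    """
    comp = scores.composite.dropna()
    shared = [l for l in omics.values.columns if l in comp.index]
    if len(shared) < 3:
        raise ValidationError("need >= 3 lines with both expression and score")
    X = omics.values[shared].to_numpy()
    y = comp.reindex(shared).to_numpy()
    n = len(shared)
    xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    ok = sx > 0
    r = np.full(X.shape[0], np.nan)
    r[ok] = (xc[ok] @ yc) / (sx[ok] * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * sps.t.sf(np.abs(t), df=n - 2))
    out = pd.DataFrame(
        {
            "feature": omics.values.index,
            "pearson_r": r,
            "p_value": np.where(ok, p, np.nan),
            "excluded_reason": np.where(ok, "", "zero variance"),
        }
    )
    q = np.full(len(out), np.nan)
    q[ok] = bh_adjust(out.loc[ok, "p_value"].to_numpy())
    out["q_value"] = q
    out["retained"] = ok & (np.abs(r) > r_threshold) & (q < q_threshold)
    return out


def intersect_degs(
    results: list[pd.DataFrame],
    p_threshold: float = 0.05,
    require_consistent_direction: bool = True,
    restrict_to: set[str] | None = None,
) -> tuple[frozenset[str], frozenset[str]]:
    """Features significant in every grouping strategy, split by direction.

    Returns ``(up, down)`` feature sets: significant at ``p <
    p_threshold`` in every result and, when
    ``require_consistent_direction``, with the same direction throughout.
    ``restrict_to`` optionally pre-restricts the candidate features (e.g.
    to correlation-filter survivors).  Order of the input results is
    irrelevant.
    """
    if len(results) < 2:
        raise ValidationError("intersection needs >= 2 differential results")
    sig_sets, dir_maps = [], []
    for res in results:
        sig = res[res["p_value"] < p_threshold]
        sig_sets.append(set(sig["feature"]))
        dir_maps.append(dict(zip(sig["feature"], sig["direction"])))
    common = set.intersection(*sig_sets)
    if restrict_to is not None:
        common &= set(restrict_to)
    up, down = set(), set()
    for feat in common:
        dirs = {d[feat] for d in dir_maps}
        if require_consistent_direction and len(dirs) > 1:
            continue
        # without the consistency requirement, the first result's call wins
        call = dir_maps[0][feat] if len(dirs) > 1 else dirs.pop()
        (up if call == "up_in_resistant" else down).add(feat)
    return frozenset(up), frozenset(down)


def ora_enrichment(
    query: set[str],
    library: GeneSetLibrary,
    universe: set[str],
) -> pd.DataFrame:
    """One-sided Fisher over-representation of ``query`` in each library set.

    Library sets are intersected with the universe; the query must be a
    subset of the universe.  Columns follow the enrichment-result contract:
    set_name, overlap_size, query_size, set_size, universe_size,
    odds_ratio, p_value, q_value.
    """
    universe = set(universe)
    query = set(query)
    if not query:
        raise ValidationError("empty query set")
    if not query <= universe:
        stray = sorted(query - universe)[:5]
        raise ValidationError(f"query members outside universe: {stray}")
    n = len(universe)
    rows = []
    for name in sorted(library.sets):
        members = library.sets[name] & universe
        if not members:
            continue
        k = len(query & members)
        odds, p = fisher_overlap(k, len(query), len(members), n, sidedness="greater")
        rows.append((name, k, len(query), len(members), n, odds, p))
    out = pd.DataFrame(
        rows,
        columns=[
            "set_name", "overlap_size", "query_size", "set_size",
            "universe_size", "odds_ratio", "p_value",
        ],
    )
    out["q_value"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out.sort_values(["p_value", "set_name"]).reset_index(drop=True)


def joint_ora(
    genes: set[str],
    metabolites: set[str],
    library: GeneSetLibrary,
    universe: set[str],
) -> pd.DataFrame:
    """Joint gene + metabolite over-representation against mixed-member sets.

    The query is the plain union of the two feature sets; reduces exactly
    to :func:`ora_enrichment` when the metabolite set is empty.
    """
    return ora_enrichment(set(genes) | set(metabolites), library, universe)
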