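"""Composite class-weighted drug-sensitivity scoring and rank diagnostics.

A cell line's *composite sensitivity score* is the unweighted mean of its
per-mechanism-class median log2 fold changes: every drug class carries the
same weight regardless of how many compounds it contains, so classes that
are over-represented in the screen (e.g. kinase inhibitors vs epigenetic
modulators) cannot dominate the score the way they dominate a global
median.  Lower (more negative) scores mean broadly sensitive lines; scores
near zero mean broad resistance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import DrugResponseMatrix, GroupAssignment, SensitivityScoreTable
from .errors import ValidationError

__all__ = ["compute_scores", "rank_stability", "compound_activity_contrast", "RankStability"]


def compute_scores(
    drm: DrugResponseMatrix, allow_partial_classes: bool = False
) -> SensitivityScoreTable:
    """Per-line composite (class-weighted) and global-median sensitivity.

    ``class_medians[line, cls]`` is the median observed LFC for the line
    over the compounds of that class; the composite is the arithmetic mean
    of the class medians.  By default a line missing *all* observations in
    some class is excluded from the composite (NaN, listed in
    ``excluded``); with ``allow_partial_classes`` the mean runs over the
    classes the line does cover.
    """
    classes = drm.classes
    if len(classes) < 2:
        raise ValidationError("composite scoring needs >= 2 mechanism classes")
    values = drm.values
    cls_of = pd.Series(
        [drm.moa_class[c] for c in values.index], index=values.index
    )
    # line x class matrix of per-class medians over observed compounds
    class_medians = values.groupby(cls_of).median().T
    class_medians = class_medians.reindex(columns=classes)

    n_used = class_medians.notna().sum(axis=1)
    if allow_partial_classes:
        composite = class_medians.mean(axis=1, skipna=True)
        excluded = list(class_medians.index[n_used == 0])
    else:
        composite = class_medians.mean(axis=1, skipna=False)
        excluded = list(class_medians.index[composite.isna()])
        if excluded:
            warnings.warn(
                f"{len(excluded)} line(s) lack observations in some class "
                "and are excluded from the composite score",
                stacklevel=2,
            )
    global_median = values.median(axis=0, skipna=True)

    table = pd.DataFrame(
        {
            "composite": composite,
            "global_median": global_median,
            "n_classes_used": n_used.astype(int),
        }
    )
    table.index.name = "line_id"
    return SensitivityScoreTable(
        table=table,
        class_medians=class_medians,
        n_classes=len(classes),
        excluded=excluded,
    )


class RankStability:
    """Cross-class rank diagnostic for the composite score.

    ``per_class_ranks``: line x class ranks by class median (1 = most
    sensitive, i.e. most negative LFC; ties get average ranks).
    ``rank_spread``: per-line sample SD of its ranks across classes.
    ``class_concordance``: Spearman correlation between each class ranking
    and the composite ranking.
    """

    def __init__(self, per_class_ranks: pd.DataFrame, rank_spread: pd.Series,
                 class_concordance: pd.Series):
        self.per_class_ranks = per_class_ranks
        self.rank_spread = rank_spread
        self.class_concordance = class_concordance


def rank_stability(drm: DrugResponseMatrix, scores: SensitivityScoreTable) -> RankStability:
    """Quantify how stable a line's sensitivity ranking is across classes."""
    cm = scores.class_medians
    if cm.shape[1] < 2:
        raise ValidationError("rank stability needs >= 2 mechanism classes")
    ranks = cm.rank(axis=0, method="average", ascending=True)
    spread = ranks.std(axis=1, ddof=1)
    composite_rank = scores.composite.rank(method="average", ascending=True)
    concordance = {}
    for cls in cm.columns:
        joint = pd.concat([ranks[cls], composite_rank], axis=1).dropna()
        if len(joint) < 2:
            concordance[cls] = np.nan
            continue
        rho, _ = sps.spearmanr(joint.iloc[:, 0], joint.iloc[:, 1])
        concordance[cls] = float(rho)
    return RankStability(
        per_class_ranks=ranks,
        rank_spread=spread,
        class_concordance=pd.Series(concordance),
    )


def compound_activity_contrast(
    drm: DrugResponseMatrix,
    groups: GroupAssignment,
    compounds: list[str],
) -> pd.DataFrame:
    """Per-compound median LFC in sensitive vs resistant lines.

    ``delta = median(resistant) - median(sensitive)``; a positive delta
    means the compound kills sensitive lines harder.  Compounds absent from
    the matrix are listed with null medians and a warning.
    """
    sens = sorted(groups.sensitive & set(drm.values.columns))
    res = sorted(groups.resistant & set(drm.values.columns))
    if not sens or not res:
        raise ValidationError("groups have no members in the drug matrix")
    rows = []
    for compound in compounds:
        if compound not in drm.values.index:
            warnings.warn(f"compound {compound!r} absent from matrix", stacklevel=2)
            rows.append((compound, np.nan, np.nan, np.nan))
            continue
        ms = drm.values.loc[compound, sens].median(skipna=True)
        mr = drm.values.loc[compound, res].median(skipna=True)
        rows.append((compound, float(ms), float(mr), float(mr - ms)))
    return pd.DataFrame(
        rows, columns=["compound", "median_sensitive", "median_resistant", "delta"]
    )
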