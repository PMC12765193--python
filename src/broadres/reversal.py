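"""Signature-reversal perturbagen screening and its companion statistics.

A perturbagen *reverses* a resistance signature when its down-signature
overlaps the genes up in resistant lines and its up-signature overlaps the
genes down in resistant lines.  Each arm is scored with a one-sided Fisher
test over the library-covered gene universe and combined as

    combined_score = -log10(p_up_down) + -log10(p_down_up),

omitting (not penalizing) a term whose query set is empty — repression of
over-expressed genes is the primary axis.  Perturbagens are ranked by
combined score; the top-k become the hit list fed into mechanism-of-action
enrichment and drug-target tallies.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import GeneSetLibrary, SignatureLibrary
from .errors import ValidationError
from .stats import bh_adjust, fisher_overlap

__all__ = ["reversal_screen", "overlap_validation", "moa_enrichment", "target_tally"]


def reversal_screen(
    up_resistant: set[str],
    down_resistant: set[str],
    library: SignatureLibrary,
    universe: set[str] | None = None,
    top_k: int = 100,
) -> pd.DataFrame:
    """Rank library perturbagens by predicted reversal of the signature.

    ``universe`` defaults to the library's own gene space (LINCS-style
    libraries measure a restricted gene set); query genes outside it are
    dropped before testing.  Returns one row per perturbagen with the two
    arm p-values, the combined score, the rank (1 = best, deterministic tie
    break by perturbagen id), a BH q-value over the primary (repression)
    arm, and an ``is_hit`` flag for the top-k.
    """
    up_resistant = set(up_resistant)
    down_resistant = set(down_resistant)
    if up_resistant & down_resistant:
        raise ValidationError("up and down resistance signatures overlap")
    if universe is None:
        universe = set(library.gene_space())
    else:
        universe = set(universe)
    up_q = up_resistant & universe
    down_q = down_resistant & universe
    n = len(universe)
    rows = []
    for pert in sorted(library.signatures):
        sig_up, sig_down = library.signatures[pert]
        sig_up = sig_up & universe
        sig_down = sig_down & universe
        if not sig_up and not sig_down:
            warnings.warn(f"perturbagen {pert!r} has empty signatures; excluded", stacklevel=2)
            continue
        p_ud = p_du = np.nan
        score = 0.0
        if up_q and sig_down:
            k = len(up_q & sig_down)
            _, p_ud = fisher_overlap(k, len(up_q), len(sig_down), n, "greater")
            score += -np.log10(max(p_ud, np.finfo(float).tiny))
        if down_q and sig_up:
            k = len(down_q & sig_up)
            _, p_du = fisher_overlap(k, len(down_q), len(sig_up), n, "greater")
            score += -np.log10(max(p_du, np.finfo(float).tiny))
        rows.append((pert, p_ud, p_du, score))
    if not rows:
        raise ValidationError("no perturbagen with a usable signature")
    out = pd.DataFrame(rows, columns=["perturbagen_id", "p_up_down", "p_down_up", "combined_score"])
    out = out.sort_values(
        ["combined_score", "perturbagen_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    # BH over the repression arm (fall back to the restoration arm when the
    # up query is empty and that arm was never tested)
    primary = out["p_up_down"].where(out["p_up_down"].notna(), out["p_down_up"])
    tested = primary.notna()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = bh_adjust(primary[tested].to_numpy())
    out["q_value"] = q
    out["is_hit"] = out["rank"] <= top_k
    return out


def overlap_validation(
    up_resistant: set[str],
    down_after_treatment: set[str],
    universe_size: int,
) -> tuple[float, float]:
    """Two-sided Fisher test of resistance-up vs treatment-down overlap.

    Mirrors the validation contrast of resistance markers against a
    perturbation experiment over a fixed expressed-gene universe.
    """
    a = set(up_resistant)
    b = set(down_after_treatment)
    k = len(a & b)
    if universe_size < len(a | b):
        raise ValidationError(
            f"universe ({universe_size}) smaller than the union ({len(a | b)})"
        )
    return fisher_overlap(k, len(a), len(b), universe_size, sidedness="two_sided")


def moa_enrichment(hits: set[str], library: SignatureLibrary) -> pd.DataFrame:
    """Over-representation of mechanism-of-action classes among hits.

    Each MoA label is treated as a set of perturbagens and tested against
    the hit list over the whole perturbagen universe.  Perturbagens without
    an annotation stay in the universe but belong to no class.
    """
    if library.moa is None:
        raise ValidationError("signature library carries no MoA annotations")
    universe = set(library.signatures)
    hits = set(hits) & universe
    if not hits:
        raise ValidationError("no hits present in the library")
    unannotated = [p for p in universe if p not in library.moa]
    if unannotated:
        warnings.warn(
            f"{len(unannotated)} perturbagen(s) lack MoA annotation", stacklevel=2
        )
    sets: dict[str, set[str]] = {}
    for pert, label in library.moa.items():
        if pert in universe:
            sets.setdefault(label, set()).add(pert)
    n = len(universe)
    rows = []
    for label in sorted(sets):
        members = sets[label]
        k = len(hits & members)
        odds, p = fisher_overlap(k, len(hits), len(members), n, "greater")
        rows.append((label, k, len(hits), len(members), n, odds, p))
    out = pd.DataFrame(
        rows,
        columns=[
            "set_name", "overlap_size", "query_size", "set_size",
            "universe_size", "odds_ratio", "p_value",
        ],
    )
    out["q_value"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out.sort_values(["p_value", "set_name"]).reset_index(drop=True)


def target_tally(hits: set[str], library: SignatureLibrary) -> pd.DataFrame:
    """Count hit compounds per annotated target gene.

    Sorted by count descending, gene name ascending on ties; empty hit
    sets give an empty tally.
    """
    if library.targets is None:
        raise ValidationError("signature library carries no target annotations")
    counts: dict[str, int] = {}
    for pert in set(hits):
        for gene in library.targets.get(pert, ()):  # un-annotated hits contribute nothing
            counts[gene] = counts.get(gene, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["gene", "n_compounds"])
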