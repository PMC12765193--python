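"""Domain containers for panel, drug-response, omics, mutation and set data.

All matrix-like types wrap a :class:`pandas.DataFrame` with features in rows
and cell lines in columns; set-like types wrap plain dict/frozenset
structures.  Validation happens at construction so downstream stages can
assume the invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CellLinePanel",
    "DrugResponseMatrix",
    "OmicsMatrix",
    "MutationMatrix",
    "GeneSetLibrary",
    "SignatureLibrary",
    "SensitivityScoreTable",
    "GroupAssignment",
]


def _check_unique_nonempty(ids, what: str) -> None:
    if len(ids) == 0:
        raise ValidationError(f"{what}: must be nonempty")
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if list(ids).count(x) > 1})[:5]
        raise ValidationError(f"{what}: duplicate identifiers {dupes}")


@dataclass
class CellLinePanel:
    """Cell-line identifiers with lineage labels and optional metadata.

    ``metadata`` is a DataFrame indexed by line id (one row per line, one
    column per covariate); categorical covariates are object/category
    columns, numeric covariates numeric columns.
    """

    line_ids: list[str]
    lineage: dict[str, str]
    metadata: pd.DataFrame | None = None

    def __post_init__(self):
        _check_unique_nonempty(self.line_ids, "CellLinePanel.line_ids")
        ids = set(self.line_ids)
        stray = set(self.lineage) - ids
        if stray:
            raise ValidationError(f"lineage keys not in panel: {sorted(stray)[:5]}")
        if self.metadata is not None:
            stray = set(self.metadata.index) - ids
            if stray:
                raise ValidationError(
                    f"metadata rows not in panel: {sorted(stray)[:5]}"
                )


@dataclass
class DrugResponseMatrix:
    """Compound x line viability log2 fold changes with MoA class labels.

    Negative values mean killing.  Missing entries (NaN) are permitted and
    skipped by all medians.  Every compound must carry exactly one
    mechanism-of-action class.
    """

    values: pd.DataFrame
    moa_class: dict[str, str]

    def __post_init__(self):
        _check_unique_nonempty(list(self.values.index), "compound ids")
        _check_unique_nonempty(list(self.values.columns), "line ids")
        missing = [c for c in self.values.index if c not in self.moa_class]
        if missing:
            raise ValidationError(
                f"compounds without a mechanism class: {missing[:5]}"
            )

    @property
    def classes(self) -> list[str]:
        return sorted({self.moa_class[c] for c in self.values.index})

    def compounds_in_class(self, cls: str) -> list[str]:
        return [c for c in self.values.index if self.moa_class[c] == cls]


@dataclass
class OmicsMatrix:
    """Feature x line continuous abundances (expression or metabolites).

    Expression is on the log2(TPM+1) scale; metabolite abundances are
    normalized intensities.  Values must be finite: dense omics matrices with
    holes are rejected rather than imputed.
    """

    values: pd.DataFrame
    feature_kind: str = "gene"  # or "metabolite"

    def __post_init__(self):
        _check_unique_nonempty(list(self.values.index), "feature ids")
        _check_unique_nonempty(list(self.values.columns), "line ids")
        if self.feature_kind not in ("gene", "metabolite"):
            raise ValidationError(f"unknown feature_kind {self.feature_kind!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                "omics matrix contains non-finite values, e.g. at "
                f"feature {self.values.index[bad[0]]!r}, "
                f"line {self.values.columns[bad[1]]!r}"
            )


@dataclass
class MutationMatrix:
    """Gene x line binary indicator (1 = any mutation called)."""

    indicator: pd.DataFrame

    def __post_init__(self):
        _check_unique_nonempty(list(self.indicator.index), "gene ids")
        _check_unique_nonempty(list(self.indicator.columns), "line ids")
        arr = self.indicator.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("mutation matrix entries must be 0 or 1")
        self.indicator = self.indicator.astype(int)


@dataclass
class GeneSetLibrary:
    """Named feature sets with an optional explicit background universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self):
        clean = {}
        for name, members in self.sets.items():
            members = frozenset(str(m).strip() for m in members)
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            clean[name] = members
        self.sets = clean
        if self.universe is not None:
            self.universe = frozenset(str(m).strip() for m in self.universe)

    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


@dataclass
class SignatureLibrary:
    """Perturbagen -> (up, down) transcriptional signatures.

    A local stand-in for LINCS-style signature libraries, with optional
    mechanism-of-action labels and drug-target maps.
    """

    signatures: dict[str, tuple[frozenset[str], frozenset[str]]]
    moa: dict[str, str] | None = None
    targets: dict[str, frozenset[str]] | None = None

    def __post_init__(self):
        clean = {}
        for pert, (up, down) in self.signatures.items():
            up, down = frozenset(up), frozenset(down)
            if up & down:
                raise ValidationError(
                    f"perturbagen {pert!r}: up and down signatures overlap"
                )
            clean[pert] = (up, down)
        self.signatures = clean

    def gene_space(self) -> frozenset[str]:
        out: set[str] = set()
        for up, down in self.signatures.values():
            out |= up | down
        return frozenset(out)


@dataclass
class SensitivityScoreTable:
    """Per-line composite (class-weighted) and global-median sensitivity.

    ``table`` has one row per line with columns ``composite``,
    ``global_median`` and ``n_classes_used``; ``class_medians`` is a
    line x class DataFrame of per-class median LFCs (NaN when a line has no
    observed compound in a class).  Lines excluded from the composite (a
    whole class unobserved, under the strict default) are listed in
    ``excluded`` and carry a NaN composite.
    """

    table: pd.DataFrame
    class_medians: pd.DataFrame
    n_classes: int
    excluded: list[str] = field(default_factory=list)

    @property
    def composite(self) -> pd.Series:
        return self.table["composite"]

    @property
    def global_median(self) -> pd.Series:
        return self.table["global_median"]


@dataclass
class GroupAssignment:
    """Disjoint resistant / sensitive line sets under one strategy."""

    strategy: str
    resistant: frozenset[str]
    sensitive: frozenset[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.resistant = frozenset(self.resistant)
        self.sensitive = frozenset(self.sensitive)
        if self.resistant & self.sensitive:
            raise ValidationError("resistant and sensitive groups overlap")
        if not self.resistant or not self.sensitive:
            raise ValidationError("both groups must be nonempty")

    @property
    def members(self) -> frozenset[str]:
        return self.resistant | self.sensitive

    def label_of(self, line_id: str) -> str:
        if line_id in self.resistant:
            return "resistant"
        if line_id in self.sensitive:
            return "sensitive"
        return "unassigned"
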