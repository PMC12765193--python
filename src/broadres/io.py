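"""Readers and writers for the package's plain-text interchange formats.

* Delimited matrices: TSV, features in rows, header row of line ids, first
  column of feature ids.  ``NA`` cells are allowed only in drug-response
  files (PRISM-style sparsity); omics matrices must be dense and mutation
  matrices strictly 0/1.  No quoting is supported — identifiers must not
  contain tabs.
* Gene sets: standard GMT (name, description, tab-separated members).
* Signature libraries: a pair of GMT files (up / down signatures) plus
  optional MoA and target TSV maps.
* Edge tables: TSV with columns ``source``, ``target``, ``edge_type``.

Identifiers are case-sensitive; the single normalization applied at
ingestion is whitespace trimming.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CellLinePanel,
    DrugResponseMatrix,
    GeneSetLibrary,
    GroupAssignment,
    MutationMatrix,
    OmicsMatrix,
    SignatureLibrary,
)
from .errors import FormatError, ValidationError

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_moa_map",
    "write_moa_map",
    "read_drug_response",
    "read_gmt",
    "write_gmt",
    "read_signature_library",
    "write_signature_library",
    "read_edge_table",
    "write_edge_table",
    "read_panel",
    "write_panel",
    "read_groups",
    "write_groups",
    "FLOAT_FORMAT",
]

# 12 significant digits: round-trips float matrices well below 1e-9.
FLOAT_FORMAT = "%.12g"


def _read_cells(path: str | Path) -> list[list[str]]:
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if line == "" and lineno > 1:
                continue
            rows.append([c.strip() for c in line.split("\t")])
    if not rows:
        raise FormatError(f"{path}: empty file")
    width = len(rows[0])
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged row at line {i} "
                f"({len(row)} fields, expected {width})"
            )
    return rows


def read_matrix(path: str | Path, kind: str = "omics", feature_kind: str = "gene"):
    """Read a feature x line TSV into a typed matrix.

    ``kind`` selects the container and validation regime: ``"omics"``
    (dense finite floats), ``"drug"`` (floats, ``NA`` allowed — pair with a
    MoA map via :func:`read_moa_map` to build a DrugResponseMatrix), or
    ``"mutation"`` (strict 0/1).
    """
    if kind not in ("omics", "drug", "mutation"):
        raise ValidationError(f"unknown matrix kind {kind!r}")
    rows = _read_cells(path)
    header = rows[0]
    if len(header) < 2 or len(rows) < 2:
        raise FormatError(f"{path}: matrix needs a header row and >=1 feature row")
    line_ids = header[1:]
    feature_ids = [r[0] for r in rows[1:]]
    if len(set(feature_ids)) != len(feature_ids):
        dupes = sorted({f for f in feature_ids if feature_ids.count(f) > 1})[:5]
        raise ValidationError(f"{path}: duplicate feature ids {dupes}")

    data = np.empty((len(feature_ids), len(line_ids)), dtype=float)
    for i, row in enumerate(rows[1:]):
        for j, cell in enumerate(row[1:]):
            if cell == "NA":
                if kind != "drug":
                    raise ValidationError(
                        f"{path}: 'NA' at feature {feature_ids[i]!r}, "
                        f"line {line_ids[j]!r} — only drug-response "
                        "matrices may contain missing entries"
                    )
                data[i, j] = np.nan
                continue
            try:
                data[i, j] = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: cannot parse {cell!r} at feature "
                    f"{feature_ids[i]!r}, line {line_ids[j]!r}"
                ) from exc

    df = pd.DataFrame(data, index=feature_ids, columns=line_ids)
    if kind == "omics":
        return OmicsMatrix(values=df, feature_kind=feature_kind)
    if kind == "mutation":
        return MutationMatrix(indicator=df)
    return df  # drug: caller attaches the MoA map


def write_matrix(matrix, path: str | Path) -> None:
    """Write a matrix container (or raw feature x line DataFrame) as TSV."""
    if isinstance(matrix, OmicsMatrix):
        df = matrix.values
    elif isinstance(matrix, MutationMatrix):
        df = matrix.indicator
    elif isinstance(matrix, DrugResponseMatrix):
        df = matrix.values
    else:
        df = matrix
    df = df.copy()
    df.index.name = "feature"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep="NA")


def read_moa_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (compound, mechanism class) into a dict."""
    rows = _read_cells(path)
    if rows[0][:2] != ["compound", "moa_class"]:
        raise FormatError(f"{path}: expected header 'compound\\tmoa_class'")
    return {r[0]: r[1] for r in rows[1:]}


def write_moa_map(moa: dict[str, str], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("compound\tmoa_class\n")
        for compound in sorted(moa):
            fh.write(f"{compound}\t{moa[compound]}\n")


def read_drug_response(values_path: str | Path, moa_path: str | Path) -> DrugResponseMatrix:
    values = read_matrix(values_path, kind="drug")
    return DrugResponseMatrix(values=values, moa_class=read_moa_map(moa_path))


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Read a GMT file (name, description, members) into a set library."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = [c.strip() for c in line.split("\t")]
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    "expected name, description and >=1 member"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}: duplicate set name {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {name!r} empty")
            sets[name] = members
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetLibrary(sets=sets)


def write_gmt(library: GeneSetLibrary, path: str | Path, description: str = "na") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name in sorted(library.sets):
            members = "\t".join(sorted(library.sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_signature_library(
    up_path: str | Path,
    down_path: str | Path,
    moa_path: str | Path | None = None,
    targets_path: str | Path | None = None,
) -> SignatureLibrary:
    """Assemble a signature library from paired up/down GMTs.

    A perturbagen may appear in only one of the two files; the missing arm
    is then the empty set.
    """
    up = read_gmt(up_path).sets
    down = read_gmt(down_path).sets
    perts = sorted(set(up) | set(down))
    signatures = {
        p: (up.get(p, frozenset()), down.get(p, frozenset())) for p in perts
    }
    moa = None
    if moa_path is not None:
        rows = _read_cells(moa_path)
        if rows[0][:2] != ["perturbagen", "moa"]:
            raise FormatError(f"{moa_path}: expected header 'perturbagen\\tmoa'")
        moa = {r[0]: r[1] for r in rows[1:]}
    targets = None
    if targets_path is not None:
        rows = _read_cells(targets_path)
        if rows[0][:2] != ["perturbagen", "target"]:
            raise FormatError(
                f"{targets_path}: expected header 'perturbagen\\ttarget'"
            )
        targets = {}
        for r in rows[1:]:
            targets.setdefault(r[0], set()).add(r[1])
        targets = {p: frozenset(t) for p, t in targets.items()}
    return SignatureLibrary(signatures=signatures, moa=moa, targets=targets)


def write_signature_library(
    library: SignatureLibrary,
    up_path: str | Path,
    down_path: str | Path,
    moa_path: str | Path | None = None,
    targets_path: str | Path | None = None,
) -> None:
    up_sets = {p: s[0] for p, s in library.signatures.items() if s[0]}
    down_sets = {p: s[1] for p, s in library.signatures.items() if s[1]}
    write_gmt(GeneSetLibrary(sets=up_sets), up_path)
    write_gmt(GeneSetLibrary(sets=down_sets), down_path)
    if moa_path is not None and library.moa is not None:
        with open(moa_path, "wt", encoding="utf-8") as fh:
            fh.write("perturbagen\tmoa\n")
            for pert in sorted(library.moa):
                fh.write(f"{pert}\t{library.moa[pert]}\n")
    if targets_path is not None and library.targets is not None:
        with open(targets_path, "wt", encoding="utf-8") as fh:
            fh.write("perturbagen\ttarget\n")
            for pert in sorted(library.targets):
                for gene in sorted(library.targets[pert]):
                    fh.write(f"{pert}\t{gene}\n")


EDGE_TYPES = ("ppi", "tf_target", "drug_gene")


def read_edge_table(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read an edge TSV; returns (edges, per-row error report).

    Malformed rows are reported, not fatal, so a partially dirty table still
    yields a network.
    """
    rows = _read_cells(path)
    if rows[0][:3] != ["source", "target", "edge_type"]:
        raise FormatError(f"{path}: expected header 'source\\ttarget\\tedge_type'")
    good, errors = [], []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) < 3 or not row[0] or not row[1]:
            errors.append(f"line {i}: missing source/target")
            continue
        if row[2] not in EDGE_TYPES:
            errors.append(f"line {i}: unknown edge_type {row[2]!r}")
            continue
        good.append(row[:3])
    return pd.DataFrame(good, columns=["source", "target", "edge_type"]), errors


def write_edge_table(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> CellLinePanel:
    """Read panel metadata TSV (line_id, lineage, then covariate columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str})
    if "line_id" not in df.columns or "lineage" not in df.columns:
        raise FormatError(f"{path}: needs 'line_id' and 'lineage' columns")
    df = df.set_index("line_id")
    meta = df.drop(columns=["lineage"])
    return CellLinePanel(
        line_ids=list(df.index),
        lineage=df["lineage"].to_dict(),
        metadata=meta if meta.shape[1] else None,
    )


def write_panel(panel: CellLinePanel, path: str | Path) -> None:
    df = pd.DataFrame(index=pd.Index(panel.line_ids, name="line_id"))
    df["lineage"] = [panel.lineage.get(i, "") for i in panel.line_ids]
    if panel.metadata is not None:
        df = df.join(panel.metadata)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_groups(path: str | Path) -> GroupAssignment:
    with open(path, "rt", encoding="utf-8") as fh:
        payload = json.load(fh)
    return GroupAssignment(
        strategy=payload["strategy"],
        resistant=frozenset(payload["resistant"]),
        sensitive=frozenset(payload["sensitive"]),
        provenance=payload.get("provenance", {}),
    )


def write_groups(groups: GroupAssignment, path: str | Path) -> None:
    payload = {
        "strategy": groups.strategy,
        "resistant": sorted(groups.resistant),
        "sensitive": sorted(groups.sensitive),
        "provenance": groups.provenance,
    }
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
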