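"""Synthetic multi-omic cell-line panel with planted ground truth.

The generator emulates the statistical structure of a pharmacogenomic
screen of cancer cell lines:

* a latent *resistance axis* ``z`` (standard normal per line) that shifts
  viability log2 fold changes toward 0 (less killing) for resistant lines;
* compounds grouped into deliberately **unequal** mechanism-of-action
  classes (one class ~10x another), so class-weighted and global-median
  scoring genuinely disagree;
* a planted resistance expression program: an up-regulated gene set and a
  smaller down-regulated set, shifted in the truly resistant decile
  (resistance programs in screens are dominated by up-regulation, so the
  down program is a quarter the size of the up program);
* a convergent, mutually exclusive mutation set: each selected resistant
  line carries **exactly one** mutation from the set, and the set's genes
  receive no background mutations anywhere, so coverage and exclusivity are
  exact by construction;
* planted metabolite shifts in resistant lines;
* a perturbagen signature library containing one true *reverser* whose
  down-signature overlaps the planted up program;
* a small regulator/drug edge table wiring a hub regulator to the planted
  program, for network assembly.

All randomness flows from a single :func:`numpy.random.default_rng` stream
in documented order, so a config + seed pair is fully reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CellLinePanel,
    DrugResponseMatrix,
    GeneSetLibrary,
    MutationMatrix,
    OmicsMatrix,
    SignatureLibrary,
)
from .errors import ValidationError
from . import io as bio

__all__ = ["SimulationConfig", "GroundTruth", "SimulatedPanel", "simulate_panel", "write_fixture"]


def _default_classes() -> dict[str, int]:
    # Deliberately unequal: kinase inhibitors 10x epigenetic modulators.
    return {
        "kinase_inhibitor": 120,
        "dna_damaging": 60,
        "unique_moa": 78,
        "proteasome_inhibitor": 30,
        "epigenetic_modulator": 12,
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic panel; defaults are the study conditions."""

    n_lines: int = 200
    n_lineages: int = 3
    classes: dict[str, int] = field(default_factory=_default_classes)
    resistance_effect: float = 1.0     # LFC shift per unit latent resistance
    n_genes: int = 2000
    n_signature_genes: int = 50        # planted resistance-up program
    signature_effect: float = 2.0      # log2-scale expression shift
    n_metabolites: int = 200
    n_shifted_metabolites: int = 20
    metabolite_effect: float = 1.0
    convergent_set_size: int = 6
    convergent_coverage: float = 0.44  # fraction of resistant lines covered
    background_mutation_rate: float = 0.01
    n_perturbagens: int = 200
    reverser_overlap_fraction: float = 0.5
    noise_sd: float = 0.5
    missing_rate: float = 0.02         # PRISM-style sparsity in drug LFCs
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_lines": self.n_lines,
            "n_lineages": self.n_lineages,
            "n_genes": self.n_genes,
            "n_signature_genes": self.n_signature_genes,
            "n_metabolites": self.n_metabolites,
            "convergent_set_size": self.convergent_set_size,
            "n_perturbagens": self.n_perturbagens,
        }
        for name, v in counts.items():
            if int(v) < 1:
                raise ValidationError(f"{name} must be >= 1, got {v}")
        for name, v in (
            ("convergent_coverage", self.convergent_coverage),
            ("reverser_overlap_fraction", self.reverser_overlap_fraction),
            ("background_mutation_rate", self.background_mutation_rate),
            ("missing_rate", self.missing_rate),
        ):
            if not 0.0 <= float(v) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if len(self.classes) < 2:
            raise ValidationError("need >= 2 mechanism classes")
        if any(int(c) < 1 for c in self.classes.values()):
            raise ValidationError("every class needs >= 1 compound")
        n_down = max(1, self.n_signature_genes // 4)
        if self.convergent_set_size + self.n_signature_genes + n_down > self.n_genes:
            raise ValidationError(
                "planted gene programs do not fit into n_genes"
            )


@dataclass
class GroundTruth:
    """Planted quantities recorded alongside the generated panel."""

    latent_resistance: dict[str, float]
    true_signature_up: frozenset[str]
    true_signature_down: frozenset[str]
    convergent_genes: frozenset[str]
    true_reverser_ids: frozenset[str]
    true_resistant: frozenset[str]
    true_sensitive: frozenset[str]
    shifted_metabolites: frozenset[str]
    hub_regulator: str

    def __post_init__(self):
        if self.true_resistant & self.true_sensitive:
            raise ValidationError("true resistant/sensitive sets overlap")


@dataclass
class SimulatedPanel:
    """Bundle returned by :func:`simulate_panel`."""

    panel: CellLinePanel
    drug_response: DrugResponseMatrix
    expression: OmicsMatrix
    metabolites: OmicsMatrix
    mutations: MutationMatrix
    pathways: GeneSetLibrary
    signatures: SignatureLibrary
    edges: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def simulate_panel(config: SimulationConfig) -> SimulatedPanel:
    """Generate the full synthetic panel for one config (deterministic per seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_lines

    # 1) lines and lineages
    width = max(4, len(str(n)))
    line_ids = [f"CL{i:0{width}d}" for i in range(1, n + 1)]
    lineage_labels = [f"LIN{i:02d}" for i in range(1, config.n_lineages + 1)]
    lineage = dict(zip(line_ids, rng.choice(lineage_labels, size=n)))

    # 2) latent resistance axis and true extreme deciles
    z = rng.standard_normal(n)
    latent = dict(zip(line_ids, z.tolist()))
    k = max(1, int(np.floor(0.10 * n)))
    order = np.argsort(z, kind="stable")
    true_sensitive = frozenset(line_ids[i] for i in order[:k])
    true_resistant = frozenset(line_ids[i] for i in order[-k:])

    # 3) drug response: base effect per compound (left-shifted so most kill)
    compounds, moa_class = [], {}
    prefix = {c: c[:3].upper() for c in config.classes}
    for cls in sorted(config.classes):
        for j in range(1, int(config.classes[cls]) + 1):
            cid = f"{prefix[cls]}_{j:03d}"
            compounds.append(cid)
            moa_class[cid] = cls
    m = len(compounds)
    base = rng.normal(-1.5, 0.5, size=m)
    lfc = (
        base[:, None]
        + config.resistance_effect * z[None, :]
        + rng.normal(0.0, config.noise_sd, size=(m, n))
    )
    if config.missing_rate > 0:
        mask = rng.random(size=(m, n)) < config.missing_rate
        lfc = np.where(mask, np.nan, lfc)
    drug = DrugResponseMatrix(
        values=pd.DataFrame(lfc, index=compounds, columns=line_ids),
        moa_class=moa_class,
    )

    # 4) expression: baseline + small lineage offsets + planted program
    gene_ids = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    n_down = max(1, config.n_signature_genes // 4)
    planted = rng.choice(
        config.n_genes,
        size=config.n_signature_genes + n_down + config.convergent_set_size,
        replace=False,
    )
    up_idx = planted[: config.n_signature_genes]
    down_idx = planted[config.n_signature_genes : config.n_signature_genes + n_down]
    conv_idx = planted[config.n_signature_genes + n_down :]
    sig_up = frozenset(gene_ids[i] for i in up_idx)
    sig_down = frozenset(gene_ids[i] for i in down_idx)
    convergent = frozenset(gene_ids[i] for i in conv_idx)

    baseline = rng.normal(6.0, 1.0, size=config.n_genes)
    lineage_offset = rng.normal(0.0, 0.3, size=(config.n_genes, config.n_lineages))
    lin_index = np.array([lineage_labels.index(lineage[l]) for l in line_ids])
    expr = (
        baseline[:, None]
        + lineage_offset[:, lin_index]
        + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
    )
    res_mask = np.array([l in true_resistant for l in line_ids])
    expr[np.ix_(up_idx, res_mask)] += config.signature_effect
    expr[np.ix_(down_idx, res_mask)] -= config.signature_effect
    expression = OmicsMatrix(
        values=pd.DataFrame(expr, index=gene_ids, columns=line_ids),
        feature_kind="gene",
    )

    # 5) metabolites: normalized abundances with a planted shift
    met_ids = [f"M{i:04d}" for i in range(1, config.n_metabolites + 1)]
    n_shift = min(config.n_shifted_metabolites, config.n_metabolites)
    shift_idx = rng.choice(config.n_metabolites, size=n_shift, replace=False)
    met = rng.normal(0.0, 1.0, size=(config.n_metabolites, n)) * config.noise_sd
    met[np.ix_(shift_idx, res_mask)] += config.metabolite_effect
    shifted_mets = frozenset(met_ids[i] for i in shift_idx)
    metabolites = OmicsMatrix(
        values=pd.DataFrame(met, index=met_ids, columns=line_ids),
        feature_kind="metabolite",
    )

    # 6) mutations: background everywhere except the convergent set, which
    #    is mutated only through the planted, mutually exclusive assignment
    mut = (rng.random(size=(config.n_genes, n)) < config.background_mutation_rate)
    mut = mut.astype(int)
    mut[conv_idx, :] = 0
    res_sorted = sorted(true_resistant)
    target = int(round(config.convergent_coverage * len(res_sorted)))
    if target > 0:
        chosen = rng.choice(len(res_sorted), size=target, replace=False)
        gene_cycle = rng.permutation(conv_idx)
        col_of = {l: j for j, l in enumerate(line_ids)}
        for t, li in enumerate(chosen):
            gi = gene_cycle[t % len(gene_cycle)]
            mut[gi, col_of[res_sorted[li]]] = 1
    mutations = MutationMatrix(
        indicator=pd.DataFrame(mut, index=gene_ids, columns=line_ids)
    )

    # 7) pathway library: planted programs + random background pathways
    sets: dict[str, frozenset[str]] = {
        "RESISTANCE_UP_PROGRAM": sig_up,
        "RESISTANCE_DOWN_PROGRAM": sig_down,
        "CONVERGENT_STRESS_SET": convergent,
    }
    joint_genes = rng.choice(sorted(sig_up), size=min(10, len(sig_up)), replace=False)
    joint_mets = rng.choice(sorted(shifted_mets), size=min(10, len(shifted_mets)), replace=False)
    sets["JOINT_METABOLIC_PATHWAY"] = frozenset(joint_genes) | frozenset(joint_mets)
    for p in range(1, 21):
        members = rng.choice(config.n_genes, size=min(30, config.n_genes), replace=False)
        sets[f"PW_{p:03d}"] = frozenset(gene_ids[i] for i in members)
    pathways = GeneSetLibrary(sets=sets, universe=frozenset(gene_ids))

    # 8) perturbagen signature library with one planted reverser
    pert_ids = [f"PERT_{i:03d}" for i in range(1, config.n_perturbagens + 1)]
    reverser = pert_ids[int(rng.integers(config.n_perturbagens))]
    # signature arm size scales down with small gene spaces so up/down/filler fit
    sig_size = max(5, min(50, config.n_genes // 5))
    moa_labels = [
        "glucocorticoid_agonist", "jak_inhibitor", "hdac_inhibitor",
        "mek_inhibitor", "egfr_inhibitor", "ppar_agonist",
        "tubulin_binder", "atpase_inhibitor",
    ]
    signatures, moa, targets = {}, {}, {}
    up_sorted = sorted(sig_up)
    down_sorted = sorted(sig_down)
    for pert in pert_ids:
        if pert == reverser:
            n_rev = int(round(config.reverser_overlap_fraction * len(up_sorted)))
            down_core = list(
                np.array(up_sorted)[
                    rng.choice(len(up_sorted), size=n_rev, replace=False)
                ]
            )
            n_up_core = int(round(config.reverser_overlap_fraction * len(down_sorted)))
            up_core = list(
                np.array(down_sorted)[
                    rng.choice(len(down_sorted), size=n_up_core, replace=False)
                ]
            )
            # filler must not add planted genes beyond the chosen cores,
            # so the reverser's planted overlap is exactly the target
            forbidden = (sig_up | sig_down) - set(down_core) - set(up_core)
        else:
            down_core, up_core = [], []
            forbidden = set()
        pool = rng.choice(
            config.n_genes, size=min(4 * sig_size, config.n_genes), replace=False
        )
        pool = [gene_ids[i] for i in pool]
        up_set = set(up_core)
        down_set = set(down_core)
        for g in pool:
            if g in up_set or g in down_set or g in forbidden:
                continue
            if len(up_set) < sig_size:
                up_set.add(g)
            elif len(down_set) < sig_size:
                down_set.add(g)
            else:
                break
        signatures[pert] = (frozenset(up_set), frozenset(down_set))
        moa[pert] = moa_labels[int(rng.integers(len(moa_labels)))]
        n_targets = int(rng.integers(1, 4))
        tgt = rng.choice(config.n_genes, size=n_targets, replace=False)
        targets[pert] = frozenset(gene_ids[i] for i in tgt)
    library = SignatureLibrary(signatures=signatures, moa=moa, targets=targets)

    # 9) edge table: hub regulator -> planted program; convergent genes and
    #    a few drug-gene edges hang off the same hub neighborhood
    hub = "TF_HUB1"
    edge_rows: list[tuple[str, str, str]] = []
    for g in sorted(sig_up):
        edge_rows.append((hub, g, "tf_target"))
    for g in sorted(convergent):
        edge_rows.append((g, hub, "ppi"))
    sig_list = sorted(sig_up | sig_down)
    for _ in range(30):
        a, b = rng.choice(len(sig_list), size=2, replace=False)
        edge_rows.append((sig_list[a], sig_list[b], "ppi"))
    for pert in sorted(pert_ids)[:20] + [reverser]:
        for g in sorted(targets[pert]):
            edge_rows.append((pert, g, "drug_gene"))
    edges = pd.DataFrame(edge_rows, columns=["source", "target", "edge_type"])
    edges = edges.drop_duplicates(ignore_index=True)

    # 10) panel metadata: null covariates plus one true association
    meta = pd.DataFrame(index=pd.Index(line_ids, name="line_id"))
    meta["growth_pattern"] = rng.choice(
        ["adherent", "suspension", "mixed"], size=n
    )
    meta["collection_site"] = rng.choice(
        [f"site_{i}" for i in range(1, 6)], size=n
    )
    meta["media"] = rng.choice(["RPMI", "DMEM", "EMEM"], size=n)
    meta["age"] = rng.integers(18, 90, size=n).astype(float)
    meta["stress_marker_score"] = 0.5 * z + rng.normal(0.0, 0.5, size=n)
    panel = CellLinePanel(line_ids=line_ids, lineage=lineage, metadata=meta)

    truth = GroundTruth(
        latent_resistance=latent,
        true_signature_up=sig_up,
        true_signature_down=sig_down,
        convergent_genes=convergent,
        true_reverser_ids=frozenset({reverser}),
        true_resistant=true_resistant,
        true_sensitive=true_sensitive,
        shifted_metabolites=shifted_mets,
        hub_regulator=hub,
    )
    return SimulatedPanel(
        panel=panel,
        drug_response=drug,
        expression=expression,
        metabolites=metabolites,
        mutations=mutations,
        pathways=pathways,
        signatures=library,
        edges=edges,
        truth=truth,
        config=config,
    )


def write_fixture(bundle: SimulatedPanel, out_dir: str | Path, force: bool = False) -> Path:
    """Write the bundle to ``out_dir`` in the interchange formats.

    Returns the path of the JSON manifest.  Refuses to write into an
    existing non-empty directory unless ``force`` is set.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ValidationError(
            f"{out}: directory not empty (pass force=True to overwrite)"
        )
    out.mkdir(parents=True, exist_ok=True)

    bio.write_panel(bundle.panel, out / "panel.tsv")
    bio.write_matrix(bundle.drug_response, out / "drug_response.tsv")
    bio.write_moa_map(bundle.drug_response.moa_class, out / "moa.tsv")
    bio.write_matrix(bundle.expression, out / "expression.tsv")
    bio.write_matrix(bundle.metabolites, out / "metabolites.tsv")
    bio.write_matrix(bundle.mutations, out / "mutations.tsv")
    bio.write_gmt(bundle.pathways, out / "pathways.gmt")
    bio.write_signature_library(
        bundle.signatures,
        out / "signatures_up.gmt",
        out / "signatures_down.gmt",
        out / "signature_moa.tsv",
        out / "signature_targets.tsv",
    )
    bio.write_edge_table(bundle.edges, out / "edges.tsv")

    truth = bundle.truth
    truth_payload = {
        "latent_resistance": {k: truth.latent_resistance[k] for k in sorted(truth.latent_resistance)},
        "true_signature_up": sorted(truth.true_signature_up),
        "true_signature_down": sorted(truth.true_signature_down),
        "convergent_genes": sorted(truth.convergent_genes),
        "true_reverser_ids": sorted(truth.true_reverser_ids),
        "true_resistant": sorted(truth.true_resistant),
        "true_sensitive": sorted(truth.true_sensitive),
        "shifted_metabolites": sorted(truth.shifted_metabolites),
        "hub_regulator": truth.hub_regulator,
    }
    with open(out / "ground_truth.json", "wt", encoding="utf-8") as fh:
        json.dump(truth_payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {
        "config": dataclasses.asdict(bundle.config),
        "files": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        "n_lines": len(bundle.panel.line_ids),
        "n_compounds": int(bundle.drug_response.values.shape[0]),
        "n_genes": int(bundle.expression.values.shape[0]),
        "n_metabolites": int(bundle.metabolites.values.shape[0]),
        "n_perturbagens": len(bundle.signatures.signatures),
        "n_planted_up_genes": len(truth.true_signature_up),
        "n_planted_down_genes": len(truth.true_signature_down),
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path
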