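"""End-to-end workflow: simulate/load -> score -> groups x3 -> differential ->
enrichment -> mutation statistics -> reversal screen -> network.

A run is driven by a single :class:`RunConfig` (YAML- or JSON-serializable)
and produces a directory of TSV/JSON outputs plus a run manifest recording
versions, parameters and per-stage outputs with row counts.  Every stage is
a pure function of its declared inputs and the seed, so a rerun with the
same config produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as bio
from .cohorts import balance_lineages, covariate_screen, refine_by_clustering, select_decile_groups
from .differential import correlate_with_score, intersect_degs, joint_ora, ora_enrichment, two_class_differential
from .errors import BroadresError, ConfigError
from .mutations import mutation_skew, pathway_impact, sample_pathway_burden, set_coverage
from .network import build_network, degree_table, ego_subnetwork
from .reversal import moa_enrichment, reversal_screen, target_tally
from .sensitivity import compute_scores
from .simulate import SimulationConfig, simulate_panel, write_fixture

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    out_dir: str
    seed: int = 0
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    input_dir: str | None = None      # fixture directory when simulate=False
    fraction: float = 0.10
    n_features: int = 250
    r_threshold: float = 0.15
    q_threshold: float = 0.05
    p_threshold: float = 0.05
    alpha: float = 0.05
    top_k_skew: int = 50
    top_k_reversal: int = 100
    convergent_candidates: int = 6
    hub: str | None = None            # ego-network center; highest-degree node if None
    radius: int = 1
    force: bool = False

    def validate(self) -> None:
        if not 0.0 < self.fraction <= 0.5:
            raise ConfigError(f"fraction must be in (0, 0.5], got {self.fraction}")
        for name in ("q_threshold", "p_threshold", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.r_threshold < 0 or self.r_threshold >= 1:
            raise ConfigError(f"r_threshold must be in [0, 1), got {self.r_threshold}")
        for name in ("n_features", "top_k_skew", "top_k_reversal", "convergent_candidates"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.radius < 0:
            raise ConfigError("radius must be >= 0")
        if not self.simulate and not self.input_dir:
            raise ConfigError("input_dir required when simulate is disabled")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in payload:
            raise ConfigError("config must set out_dir")
        return cls(**payload)

    def to_file(self, path: str | Path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format=bio.FLOAT_FORMAT)
    return len(df)


def _write_genes(genes: frozenset[str], path: Path) -> int:
    with open(path, "wt", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
    return len(genes)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "versions": {
            "broadres": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        # out_dir is where the manifest lives; omitting it keeps manifests
        # byte-comparable across output locations
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"
        },
        "stages": {},
    }

    def record(stage: str, **outputs):
        manifest["stages"][stage] = outputs

    stage = "simulate"
    try:
        if config.simulate:
            sim_cfg = SimulationConfig(seed=config.seed, **config.sim_overrides)
            bundle = simulate_panel(sim_cfg)
            fixture_dir = out / "fixture"
            write_fixture(bundle, fixture_dir, force=config.force)
            record(stage, fixture_dir="fixture", n_lines=len(bundle.panel.line_ids))
            panel = bundle.panel
            drm = bundle.drug_response
            expression = bundle.expression
            metabolites = bundle.metabolites
            mutations = bundle.mutations
            pathways = bundle.pathways
            signatures = bundle.signatures
            edges, edge_errors = bundle.edges, []
        else:
            src = Path(config.input_dir)
            panel = bio.read_panel(src / "panel.tsv")
            drm = bio.read_drug_response(src / "drug_response.tsv", src / "moa.tsv")
            expression = bio.read_matrix(src / "expression.tsv", kind="omics")
            metabolites = bio.read_matrix(
                src / "metabolites.tsv", kind="omics", feature_kind="metabolite"
            )
            mutations = bio.read_matrix(src / "mutations.tsv", kind="mutation")
            pathways = bio.read_gmt(src / "pathways.gmt")
            signatures = bio.read_signature_library(
                src / "signatures_up.gmt",
                src / "signatures_down.gmt",
                src / "signature_moa.tsv" if (src / "signature_moa.tsv").exists() else None,
                src / "signature_targets.tsv" if (src / "signature_targets.tsv").exists() else None,
            )
            edges_path = src / "edges.tsv"
            if edges_path.exists():
                edges, edge_errors = bio.read_edge_table(edges_path)
            else:
                edges, edge_errors = pd.DataFrame(columns=["source", "target", "edge_type"]), []
            record("load", input_dir=str(src), n_lines=len(panel.line_ids))

        stage = "score"
        scores = compute_scores(drm)
        table = scores.table.reset_index()
        n = _write_tsv(table, out / "scores.tsv")
        record(stage, path="scores.tsv", rows=n)

        stage = "covariates"
        if panel.metadata is not None and panel.metadata.shape[1] > 0:
            screen = covariate_screen(panel, scores)
            n = _write_tsv(screen, out / "covariate_screen.tsv")
            n_sig = int((screen["q_value"] < config.q_threshold).sum())
            record(stage, path="covariate_screen.tsv", rows=n,
                   n_significant=n_sig)

        stage = "groups"
        decile = select_decile_groups(scores, config.fraction)
        refined = refine_by_clustering(
            expression, scores, decile,
            n_features=config.n_features, r_threshold=config.r_threshold,
        )
        balanced = balance_lineages(scores, panel, config.fraction)
        all_groups = {"decile": decile, "cluster_refined": refined, "lineage_balanced": balanced}
        sizes = {}
        for name, grp in all_groups.items():
            bio.write_groups(grp, out / f"groups_{name}.json")
            sizes[name] = {"resistant": len(grp.resistant), "sensitive": len(grp.sensitive)}
        record(stage, sizes=sizes)

        stage = "differential"
        deg_results = []
        for name, grp in all_groups.items():
            deg = two_class_differential(expression, grp)
            _write_tsv(deg, out / f"deg_{name}.tsv")
            deg_results.append(deg)
        corr = correlate_with_score(
            expression, scores, config.r_threshold, config.q_threshold
        )
        _write_tsv(corr, out / "correlation.tsv")
        retained = set(corr.loc[corr["retained"], "feature"])
        up, down = intersect_degs(
            deg_results, p_threshold=config.p_threshold,
            require_consistent_direction=True, restrict_to=retained,
        )
        _write_genes(up, out / "intersect_up.txt")
        _write_genes(down, out / "intersect_down.txt")
        met_deg = two_class_differential(metabolites, decile)
        _write_tsv(met_deg, out / "deg_metabolites.tsv")
        record(stage, n_up=len(up), n_down=len(down),
               n_metabolite_hits=int((met_deg["p_value"] < config.p_threshold).sum()))

        stage = "enrichment"
        universe = set(expression.values.index)
        if up:
            enr_up = ora_enrichment(up, pathways, universe)
            _write_tsv(enr_up, out / "enrichment_up.tsv")
        if down:
            enr_down = ora_enrichment(down, pathways, universe)
            _write_tsv(enr_down, out / "enrichment_down.tsv")
        met_hits = set(met_deg.loc[met_deg["p_value"] < config.p_threshold, "feature"])
        if up or met_hits:
            joint_universe = universe | set(metabolites.values.index)
            enr_joint = joint_ora(up, met_hits, pathways, joint_universe)
            _write_tsv(enr_joint, out / "enrichment_joint.tsv")
        record(stage, n_up_query=len(up), n_metabolites_joint=len(met_hits))

        stage = "mutations"
        skew = mutation_skew(mutations, decile, top_k=config.top_k_skew)
        _write_tsv(skew.table, out / "mutation_skew.tsv")
        mut_universe = set(mutations.indicator.index)
        burden = sample_pathway_burden(mutations, pathways, mut_universe)
        burden_out = burden.copy()
        burden_out.index.name = "pathway"
        burden_out.to_csv(out / "pathway_burden.tsv", sep="\t", float_format=bio.FLOAT_FORMAT)
        impact = pathway_impact(burden, decile, alpha=config.alpha)
        _write_tsv(impact.impact_table, out / "pathway_impact.tsv")
        candidates = skew.top_resistant[: config.convergent_candidates]
        coverage = set_coverage(mutations, set(candidates), decile.resistant)
        cov_payload = {
            "candidate_genes": sorted(candidates),
            "coverage_pct": coverage.coverage_pct,
            "exclusivity": coverage.exclusivity,
            "per_gene_pct": {g: coverage.per_gene_pct[g] for g in sorted(coverage.per_gene_pct)},
            "n_lines": coverage.n_lines,
        }
        with open(out / "convergent_coverage.json", "wt", encoding="utf-8") as fh:
            json.dump(cov_payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        record(stage, n_genes=len(skew.table), coverage_pct=coverage.coverage_pct)

        stage = "reversal"
        if up or down:
            screen = reversal_screen(
                up, down, signatures, top_k=config.top_k_reversal
            )
            _write_tsv(screen, out / "reversal.tsv")
            hits = set(screen.loc[screen["is_hit"], "perturbagen_id"])
            if signatures.moa is not None:
                moa = moa_enrichment(hits, signatures)
                _write_tsv(moa, out / "moa_enrichment.tsv")
            if signatures.targets is not None:
                tally = target_tally(hits, signatures)
                _write_tsv(tally, out / "target_tally.tsv")
            record(stage, n_hits=len(hits),
                   top_perturbagen=str(screen.iloc[0]["perturbagen_id"]))
        else:
            record(stage, skipped="empty resistance signature")

        stage = "network"
        if len(edges):
            drug_targets = None
            net = build_network(
                edges, deg_up=up, deg_down=down, skew=skew,
                drug_targets=drug_targets, row_errors=edge_errors,
            )
            net_dir = out / "network"
            net.write(net_dir)
            degrees = degree_table(net)
            _write_tsv(degrees, net_dir / "degrees.tsv")
            hub = config.hub or str(degrees.iloc[0]["node"])
            ego = ego_subnetwork(net, hub, radius=config.radius)
            ego.write(net_dir / "ego")
            record(stage, n_nodes=net.graph.number_of_nodes(),
                   n_edges=net.graph.number_of_edges(), hub=hub)
        else:
            record(stage, skipped="no edge table")
    except BroadresError as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "run_manifest.json"
    with open(manifest_path, "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
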