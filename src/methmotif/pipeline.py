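"""End-to-end orchestration: screens -> regions -> scan -> enrichment -> network.

One :class:`PipelineConfig` describes a full run over synthetic or on-disk
inputs: which screens to run (differential methylation between the two
clinical groups; univariate Cox survival within optional subtype strata),
which foreground CpG categories to test for motif enrichment, the
thresholds at every stage, clustering, and the TF subnetwork export. The
presence matrix is computed once over the union of all overlap-filtered
regions and reused across analyses. A manifest records seed, thresholds
and entity counts at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster as cluster_mod
from . import dataio, diffassoc, enrich, network, regions as regions_mod, survcox
from .motifscan import ScanParams, build_presence_matrix, motif_thresholds, thresholds_table
from .synthdata import SimulationConfig, simulate_all


@dataclass
class AnalysisSpec:
    """One enrichment analysis: a foreground definition within a stratum."""

    foreground: str                  # protective | hazardous | pro+haz | hyper | hypo | cluster_<i>
    stratum: tuple | None = None     # (clinical column, label) for survival screens
    label: str | None = None

    def name(self) -> str:
        if self.label:
            return self.label
        stratum = "all" if self.stratum is None else f"{self.stratum[0]}={self.stratum[1]}"
        return f"{stratum}:{self.foreground}"


def default_analyses() -> list:
    return [
        AnalysisSpec("pro+haz"),
        AnalysisSpec("protective"),
        AnalysisSpec("hazardous"),
        AnalysisSpec("hyper"),
        AnalysisSpec("hypo"),
    ]


@dataclass
class PipelineConfig:
    simulate: SimulationConfig | None = None
    beta_path: str | None = None
    annotation_path: str | None = None
    clinical_path: str | None = None
    genome_path: str | None = None
    motifs_path: str | None = None
    motifs_format: str = "meme"
    tf_edges_path: str | None = None
    analyses: list = field(default_factory=default_analyses)
    group_column: str = "ER"
    diffmeth_alpha: float = 0.05
    diffmeth_method: str = "student_t"
    survival_p: float = 0.02
    scan_params: ScanParams = field(default_factory=ScanParams)
    background_choice: str = "rest"      # rest | nonsignificant
    enrichment_alpha: float = 0.01       # TF-level significance for the network
    k_clusters: int = 5
    cluster_kmax: int = 10
    cluster_restarts: int = 10
    run_clustering: bool = True
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("diffmeth_alpha", "survival_p", "enrichment_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0,1)")
        valid = {"protective", "hazardous", "pro+haz", "hyper", "hypo"}
        for a in self.analyses:
            if a.foreground not in valid and not a.foreground.startswith("cluster_"):
                raise ValueError(f"invalid foreground {a.foreground!r}")


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        ds = simulate_all(config.simulate)
        return ds.genome, ds.annotation, ds.beta, ds.clinical, ds.pwms, ds.tf_edges
    genome = dataio.read_genome_fasta(config.genome_path)
    beta, annotation, clinical = dataio.load_methylation_dataset(
        config.beta_path, config.annotation_path, config.clinical_path
    )
    pwms = dataio.read_pwms(config.motifs_path, config.motifs_format)
    edges = dataio.read_tsv(config.tf_edges_path) if config.tf_edges_path else pd.DataFrame(columns=["tf1", "tf2"])
    return genome, annotation, beta, clinical, pwms, edges


_SURVIVAL_FG = {"protective", "hazardous", "pro+haz"}


def _screen_key(spec: AnalysisSpec, config: PipelineConfig):
    if spec.foreground in _SURVIVAL_FG:
        return ("survival", spec.stratum)
    if spec.foreground in {"hyper", "hypo"}:
        return ("diffmeth", None)
    return ("cluster", None)


def _fg_mask(kept: pd.DataFrame, foreground: str) -> pd.Series:
    if foreground == "pro+haz":
        return kept["category"].isin(["protective", "hazardous"])
    return kept["category"] == foreground


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured analyses; returns the in-memory result bundle.

    The bundle holds screens, filtered region tables, the presence matrix,
    per-analysis enrichment, clustering, the TF subnetwork and the manifest.
    If ``config.out_dir`` is set, everything is also serialized there.
    """
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            "diffmeth_alpha": config.diffmeth_alpha,
            "survival_p": config.survival_p,
            "scan_p": config.scan_params.p_threshold,
            "enrichment_alpha": config.enrichment_alpha,
        },
        "stages": {},
        "notes": [],
    }
    genome, annotation, beta, clinical, pwms, tf_edges = _load_inputs(config)
    tf_names = {p.motif_id: p.tf_name for p in pwms}
    manifest["stages"]["inputs"] = {
        "n_cpgs": len(beta), "n_samples": beta.shape[1], "n_motifs": len(pwms),
        "n_tf_edges": len(tf_edges),
    }

    # --- screens (shared across analyses that use the same one) -------------
    screens: dict = {}
    for spec in config.analyses:
        key = _screen_key(spec, config)
        if key in screens:
            continue
        kind = key[0]
        if kind == "survival":
            res = survcox.screen_survival_cpgs(
                beta, clinical, stratum=spec.stratum, p_cut=config.survival_p
            )
            scored = res[res["converged"] == True].rename(columns={"wald_p": "p_value"})  # noqa: E712
            scored = scored[["cpg_id", "p_value", "category"]]
        elif kind == "diffmeth":
            groups = dict(zip(clinical["sample_id"], clinical[config.group_column]))
            res = diffassoc.diff_methylation(
                beta, groups, method=config.diffmeth_method, alpha=config.diffmeth_alpha
            )
            scored = res[res["tested"]].rename(columns={"adjusted_p": "p_value"})
            scored = scored[["cpg_id", "p_value", "direction"]].rename(columns={"direction": "category"})
        else:  # cluster foregrounds: membership sets, no per-CpG p; constant score
            result = cluster_mod.kmeans_beta(
                beta, config.k_clusters, restarts=config.cluster_restarts, seed=config.seed
            )
            scored = pd.DataFrame(
                {
                    "cpg_id": result.assignments.index,
                    "p_value": 0.5,
                    "category": [f"cluster_{c}" for c in result.assignments],
                }
            )
            res = scored
        screens[key] = {"raw": res, "scored": scored}
        manifest["stages"][f"screen:{kind}:{spec.stratum}"] = {
            "n_tested": len(scored),
            "n_by_category": scored["category"].value_counts().to_dict(),
        }

    # --- regions + overlap filtering per screen -----------------------------
    for key, screen in screens.items():
        made = regions_mod.make_regions(screen["scored"], annotation, genome)
        kept = regions_mod.filter_overlapping_regions(made)
        screen["regions"] = kept
        manifest["stages"][f"regions:{key[0]}:{key[1]}"] = {
            "n_selected": len(screen["scored"]),
            "n_regions": len(made),
            "n_after_overlap_filter": len(kept),
        }

    # --- presence matrix over the union of filtered regions -----------------
    union_rows = pd.concat([s["regions"] for s in screens.values()], ignore_index=True)
    union_rows = union_rows.drop_duplicates(subset="cpg_id")
    seqs = regions_mod.extract_region_sequences(union_rows, genome)
    presence = build_presence_matrix(seqs, pwms, config.scan_params)
    _, thresholds = motif_thresholds(pwms, config.scan_params, region_sequences=seqs.values)
    manifest["stages"]["scan"] = {
        "n_regions_scanned": len(presence),
        "n_motifs": len(pwms),
        "n_unattainable_motifs": int(sum(not t.attainable for t in thresholds.values())),
    }

    # --- enrichment per analysis --------------------------------------------
    enrichment_tables = []
    for spec in config.analyses:
        key = _screen_key(spec, config)
        kept = screens[key]["regions"]
        fg_ids = kept.loc[_fg_mask(kept, spec.foreground), "cpg_id"]
        if config.background_choice == "rest":
            bg_ids = kept.loc[~kept["cpg_id"].isin(fg_ids), "cpg_id"]
        elif config.background_choice == "nonsignificant":
            bg_ids = kept.loc[kept["category"] == "none", "cpg_id"]
        else:
            raise ValueError(f"unknown background_choice {config.background_choice!r}")
        if len(fg_ids) == 0 or len(bg_ids) == 0:
            manifest["notes"].append(
                f"analysis {spec.name()}: empty foreground or background, enrichment skipped"
            )
            continue
        table = enrich.motif_enrichment(
            presence, fg_ids, bg_ids, tf_names=tf_names, analysis=spec.name()
        )
        table.insert(0, "foreground", spec.foreground)
        enrichment_tables.append(table)
        manifest["stages"][f"enrichment:{spec.name()}"] = {
            "n_foreground": len(fg_ids),
            "n_background": len(bg_ids),
            "n_enriched_sig": int(((table["adjusted_p"] < config.enrichment_alpha)
                                   & (table["relative_enrichment"] > 1)).sum()),
        }
    enrichment = (
        pd.concat(enrichment_tables, ignore_index=True)
        if enrichment_tables
        else pd.DataFrame()
    )

    # --- clustering ----------------------------------------------------------
    cluster_result = None
    wcss = None
    if config.run_clustering:
        cluster_result = cluster_mod.kmeans_beta(
            beta, config.k_clusters, restarts=config.cluster_restarts, seed=config.seed
        )
        wcss = cluster_mod.wcss_curve(
            beta, k_max=config.cluster_kmax, restarts=config.cluster_restarts, seed=config.seed
        )
        manifest["stages"]["clustering"] = {
            "k": config.k_clusters,
            "wcss_total": cluster_result.wcss_total,
        }

    # --- TF subnetwork from survival enrichment ------------------------------
    tf_graph = None
    tf_table = None
    if not enrichment.empty:
        surv = enrichment[enrichment["foreground"].isin(["protective", "hazardous"])].copy()
        if not surv.empty:
            surv["analysis"] = surv["foreground"]
            tf_table = network.aggregate_tf_pvalues(surv, alpha=config.enrichment_alpha)
            tf_graph = network.build_subnetwork(tf_table, tf_edges)
            manifest["stages"]["network"] = {
                "n_significant_tfs": len(tf_table),
                "n_nodes": tf_graph.number_of_nodes(),
                "n_edges": tf_graph.number_of_edges(),
            }

    bundle = {
        "screens": screens,
        "presence": presence,
        "thresholds": thresholds_table(thresholds),
        "enrichment": enrichment,
        "cluster": cluster_result,
        "wcss_curve": wcss,
        "tf_table": tf_table,
        "network": tf_graph,
        "manifest": manifest,
    }
    if config.out_dir:
        _write_bundle(bundle, config.out_dir)
    return bundle


def _write_bundle(bundle: dict, out_dir: str) -> None:
    outputs: dict = {"manifest": bundle["manifest"]}
    for key, screen in bundle["screens"].items():
        tag = f"{key[0]}" + ("" if key[1] is None else f"_{key[1][0]}_{key[1][1]}")
        outputs[f"screen_{tag}"] = screen["raw"]
        outputs[f"regions_{tag}"] = screen["regions"]
    outputs["presence"] = bundle["presence"].astype(int).rename_axis("region_id").reset_index()
    outputs["motif_thresholds"] = bundle["thresholds"]
    if not bundle["enrichment"].empty:
        outputs["enrichment"] = bundle["enrichment"]
    if bundle["cluster"] is not None:
        outputs["cluster_assignments"] = cluster_mod.cluster_assignments_table(bundle["cluster"])
        outputs["wcss_curve"] = pd.DataFrame(bundle["wcss_curve"], columns=["k", "wcss_total"])
    if bundle["network"] is not None:
        outputs["tf_network"] = bundle["network"]
        nodes, edges = network.network_tables(bundle["network"])
        outputs["tf_network_nodes"] = nodes
        outputs["tf_network_edges"] = edges
        outputs["tf_table"] = bundle["tf_table"]
    dataio.write_outputs(outputs, out_dir)
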