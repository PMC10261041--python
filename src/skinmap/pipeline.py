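"""End-to-end orchestration: synthetic generation through the analysis
stages, with a reproducible run manifest.

Stage order: simulate -> QC/normalize/cluster -> composition/module
scores -> signature/deconvolution/domains -> adjacency + grid stats ->
ligand-receptor differential network -> enrichment.  Every stage writes
its artifacts under the output directory and records a content hash in
the manifest, so identical configs reproduce identical bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrich, io, lr_interactome, sc_core, spatial_deconv, spatial_stats
from .synthgen import SimConfig, default_config, lr_benchmark_config, simulate_cells, simulate_pixels, simulate_spots


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with field-standard defaults."""

    min_transcripts: int = 500
    min_genes: int = 100
    max_mito_frac: float = 0.10
    mito_prefix: str = "MT-"
    n_hvg: int = 1000
    n_pcs: int = 20
    resolution: float = 0.5
    panel_markers_per_type: int = 50
    k_domains: int = 6
    adjacency_rule: str = "threshold"
    adjacency_tau: float = 0.1
    grid_um: float = 10.0
    min_genes_per_grid: int = 30
    lr_min_expressed_frac: float = 0.10
    lr_n_perm: int = 1000
    lr_p_cutoff: float = 0.05
    specificity_cutoff: float = 0.70
    seed: int = 0
    outdir: str = "skinmap_run"
    sim: SimConfig | None = None

    def to_dict(self) -> dict:
        # analysis thresholds only; the simulation config is programmatic
        d = dataclasses.asdict(self)
        d.pop("sim", None)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("sim", None)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run the full synthetic-data pipeline; returns the manifest dict."""
    cfg = config or PipelineConfig()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": cfg.seed, "outputs": {}, "warnings": []}

    def record(stage: str, **info):
        manifest["stages"].append({"stage": stage, **info})

    def save(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest["outputs"][name] = _sha256(path)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- synthgen -------------------------------------------------
        sim = cfg.sim
        lr_db = None
        if sim is None:
            sim, lr_db = lr_benchmark_config(seed=cfg.seed)
        cells, truth = simulate_cells(sim)
        spots, spot_truth = simulate_spots(sim)
        pixels, _ = simulate_pixels(sim)
        if lr_db is None:
            from .synthgen import null_lr_database

            lr_db = null_lr_database(sim, n_pairs=200)
        io.write_10x_mtx(cells, outdir / "sc_counts")
        save("cell_meta.csv", lambda p: io.write_cell_meta(cells, p))
        save("tissue_positions.csv", lambda p: io.write_tissue_positions(spots, p))
        save("pixels.csv", lambda p: io.write_pixel_table(pixels, p))
        save("truth.json", lambda p: io.write_truth_json(truth, p))
        record("simulate", n_cells=cells.n_obs, n_genes=cells.n_vars,
               n_spots=spots.n_obs, n_pixels=len(pixels))

        # --- sc_core --------------------------------------------------
        filtered, qc_report = sc_core.qc_filter(
            cells,
            min_transcripts=cfg.min_transcripts,
            min_genes=cfg.min_genes,
            max_mito_frac=cfg.max_mito_frac,
            mito_prefix=cfg.mito_prefix,
        )
        save("qc_report.csv", lambda p: qc_report.to_csv(p))
        nm = sc_core.normalize_cp10k_log(filtered)
        hvg = sc_core.select_variable_genes(nm, n_top=min(cfg.n_hvg, nm.n_vars))
        clusters = sc_core.cluster_cells(
            nm, hvg, n_pcs=cfg.n_pcs, resolution=cfg.resolution,
            seed=_subseed(cfg.seed, 1),
        )
        save("clusters.csv", lambda p: clusters.to_csv(p))
        comp_tbl = sc_core.composition_table(clusters, nm.obs["condition"])
        save("composition.csv", lambda p: comp_tbl.to_csv(p))
        scores = {
            name: sc_core.module_score(nm, genes, seed=_subseed(cfg.seed, 2))
            for name, genes in truth.program_gene_sets.items()
        }
        score_df = pd.DataFrame(scores, index=nm.obs_names)
        save("module_scores.csv", lambda p: score_df.to_csv(p))
        record("sc_core", cells_in=cells.n_obs, cells_out=filtered.n_obs,
               n_clusters=int(clusters.nunique()))

        # --- spatial_deconv -------------------------------------------
        truth_types = truth.cell_type_of_cell.loc[nm.obs_names]
        panel = spatial_deconv.marker_hvg_panel(
            nm, truth_types, n_markers=cfg.panel_markers_per_type, hvg=hvg
        )
        sig = spatial_deconv.build_signature_matrix(nm, truth_types, panel)
        fractions, resid = spatial_deconv.deconvolve_spots(spots, sig)
        save("spot_composition.csv", lambda p: fractions.to_csv(p))
        k = min(cfg.k_domains, len(fractions.dropna()))
        domains, domain_means = spatial_deconv.cluster_domains(
            fractions, k=k, seed=_subseed(cfg.seed, 3)
        )
        annot = spatial_deconv.annotate_domains(domains, fractions)
        save("domains.csv", lambda p: domains.to_csv(p))
        save("domain_annotations.csv", lambda p: annot.to_csv(p))
        # scatter-pie export: per-spot fraction JSON keyed by barcode
        save(
            "scatter_pie.json",
            lambda p: p.write_text(
                json.dumps(
                    {
                        sid: {t: (None if pd.isna(v) else round(float(v), 6))
                              for t, v in row.items()}
                        for sid, row in fractions.iterrows()
                    }
                )
            ),
        )
        record("spatial_deconv", n_spots=spots.n_obs, panel_size=len(panel),
               k_domains=k)

        # --- spatial_stats --------------------------------------------
        coords = spots.obs[["array_row", "array_col"]]
        adj = spatial_stats.adjacency_counts(
            fractions, coords, sim.lattice, rule=cfg.adjacency_rule,
            tau=cfg.adjacency_tau,
        )
        save("adjacency.csv", lambda p: adj.to_csv(p))
        grid = spatial_stats.bin_pixels_to_grid(
            pixels, grid_um=cfg.grid_um, min_genes_per_grid=cfg.min_genes_per_grid
        )
        save("grid_matrix.csv", lambda p: grid.to_csv(p))
        record("spatial_stats", n_edges=int(adj.to_numpy().sum()),
               n_grids=grid.shape[1] if not grid.empty else 0)

        # --- lr_interactome -------------------------------------------
        sub_labels = truth.subcluster_of_cell.loc[nm.obs_names]
        ns_tbl, pp_tbl, spec = lr_interactome.run_condition_specific(
            nm, sub_labels, nm.obs["condition"], lr_db,
            cutoff=cfg.specificity_cutoff,
            min_expressed_frac=cfg.lr_min_expressed_frac,
            n_perm=cfg.lr_n_perm, seed=_subseed(cfg.seed, 4),
            alpha=cfg.lr_p_cutoff,
        )
        sub_to_type = {s: s.rsplit("_", 1)[0] for s in sub_labels.unique()}
        ns_merged = lr_interactome.merge_to_celltype_pairs(ns_tbl, sub_to_type)
        pp_merged = lr_interactome.merge_to_celltype_pairs(pp_tbl, sub_to_type)
        diff, pair_counts = lr_interactome.differential_network(pp_merged, ns_merged)
        save("lr_differential.csv", lambda p: diff.to_csv(p, index=False))
        save("lr_pair_counts.csv", lambda p: pair_counts.to_csv(p))
        record("lr_interactome", n_ns=len(ns_merged), n_pp=len(pp_merged),
               n_differential=len(diff))

        # --- enrich ---------------------------------------------------
        universe = enrich.detected_universe(nm)
        pp_mask = (nm.obs["condition"] == "PP").to_numpy()
        ns_mask = (nm.obs["condition"] == "NS").to_numpy()
        de = sc_core.wilcoxon_de(nm, pp_mask, ns_mask)
        query = list(de.index[(de["fdr"] < 0.05) & (de["log_fc"] > 0)])
        enr = enrich.hypergeometric_enrichment(
            query, truth.program_gene_sets, universe
        )
        save("enrichment.csv", lambda p: enr.to_csv(p))
        kc_mask = truth_types.str.startswith("KC").to_numpy()
        if kc_mask.any():
            corr = enrich.regulator_score_correlation(
                nm[kc_mask], truth.program_gene_sets,
                truth.pseudotime_true, seed=_subseed(cfg.seed, 5),
            )
            save("pseudotime_correlation.csv", lambda p: corr.to_csv(p))
        record("enrich", n_query=len(query), n_regulators=len(enr))

        manifest["warnings"] = [str(w.message) for w in caught]

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
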