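"""End-to-end orchestration: simulate/ingest -> normalize -> DE -> cluster ->
qPCR -> score -> ratio, with a JSON manifest tying every output file to the
configuration, seed and input digests.

Stages communicate only via files in the output directory, so any stage can
be rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

import cd8mir
from cd8mir import cluster as cl
from cd8mir import de as de_mod
from cd8mir import microarray as ma
from cd8mir import phenotype as ph
from cd8mir import qpcr as qp
from cd8mir import ratio as rt
from cd8mir import simulate as sim
from cd8mir.io_core import (
    Cd8mirError,
    SchemaError,
    default_panel,
    load_config,
    logger,
    write_expression_table,
    write_noise_stats,
    write_sample_metadata,
)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, outputs: list[Path], skipped: bool = False) -> dict:
    return {
        "name": name,
        "skipped": skipped,
        "outputs": {str(p): _digest(p) for p in outputs},
    }


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise SchemaError("config must be a mapping")
    known = {"microarray", "qpcr", "phenotype", "seed"}
    unknown = set(cfg) - known
    if unknown:
        raise SchemaError(f"unknown config blocks: {sorted(unknown)}")
    for block in ("microarray", "qpcr", "phenotype"):
        if block in cfg and not isinstance(cfg[block], dict):
            raise SchemaError(f"config block '{block}' must be a mapping")


def run_pipeline(config: dict | str | Path, out_dir: str | Path, seed: int = 0) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    validate_config(config)
    seed = int(config.get("seed", seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    manifest_path = out / "manifest.json"

    def flush(status: str) -> dict:
        manifest = {
            "tool": "cd8mir",
            "version": cd8mir.__version__,
            "status": status,
            "seed": seed,
            "config": config,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "stages": stages,
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    try:
        # ------------------------------------------------------ microarray arm
        ma_cfg = config.get("microarray", {})
        sim_cfg = sim.MicroarraySimConfig(seed=seed, **ma_cfg.get("simulate", {}))
        raw, noise, meta, truth = sim.simulate_microarray(sim_cfg)
        raw_p = out / "raw_intensities.tsv"
        noise_p = out / "noise_stats.tsv"
        meta_p = out / "samples.csv"
        truth_p = out / "microarray_truth.json"
        write_expression_table(raw, raw_p)
        write_noise_stats(noise, noise_p)
        write_sample_metadata(meta, meta_p)
        truth_p.write_text(json.dumps(truth.to_dict(), indent=2))
        stages.append(_stage("simulate_microarray", [raw_p, noise_p, meta_p, truth_p]))

        det = ma.detection_call(raw, noise, k_sd=ma_cfg.get("k_sd", 2.0))
        min_det = ma_cfg.get("min_detected", ma.default_min_detected(raw.shape[0]))
        qc = ma.qc_filter_samples(det, min_det)
        corrected = det.corrected.copy_with(
            det.corrected.data[qc.retained], det.corrected.value_kind
        )
        filtered = ma.filter_top_expressed(
            corrected, mean_threshold=ma_cfg.get("mean_threshold", 80.0)
        )
        logged = ma.log2_transform(filtered, offset=ma_cfg.get("log2_offset", 1.0))
        normalized = ma.cyclic_loess_normalize(
            logged,
            span=ma_cfg.get("span", 0.7),
            iterations=ma_cfg.get("iterations", 3),
        )
        norm_p = out / "normalized.tsv"
        qc_p = out / "qc_report.json"
        write_expression_table(normalized, norm_p)
        qc_p.write_text(json.dumps(ma.qc_report_dict(det, qc, filtered.shape[0]), indent=2))
        stages.append(_stage("normalize", [norm_p, qc_p]))

        retained_meta = meta.subset(qc.retained)
        design = de_mod.DesignSpec.from_smoker(retained_meta)
        fits, _skipped = de_mod.fit_feature_models(normalized, design)
        results, prior = de_mod.ebayes_moderate(fits)
        up, down = de_mod.select_differential(
            results,
            lfc_cut=ma_cfg.get("lfc_cut", 0.5),
            p_cut=ma_cfg.get("p_cut", 0.05),
        )
        de_p = out / "de_results.tsv"
        volcano_p = out / "volcano.tsv"
        frame = de_mod.results_frame(results)
        frame.to_csv(de_p, sep="\t")
        frame[["logfc", "p"]].to_csv(volcano_p, sep="\t")
        stages.append(_stage("differential_expression", [de_p, volcano_p]))

        de_features = [r.feature_id for r in up + down]
        cluster_mat = normalized.copy_with(
            normalized.data.loc[de_features] if de_features else normalized.data,
            normalized.value_kind,
        )
        dist = cl.spearman_distance_matrix(cluster_mat, axis="samples", center_rows=True)
        dend, assignments = cl.ward_cluster(dist, k=ma_cfg.get("k", 2))
        purity = cl.cluster_separation_check(dend, retained_meta, "smoker")
        newick_p = out / "dendrogram.nwk"
        clusters_p = out / "clusters.tsv"
        heatmap_p = out / "heatmap.tsv"
        newick_p.write_text(dend.to_newick() + "\n")
        pd.Series(assignments, name="cluster").rename_axis("sample_id").to_csv(clusters_p, sep="\t")
        cl.heatmap_frame(cluster_mat).to_csv(heatmap_p, sep="\t")
        stages.append(_stage("cluster", [newick_p, clusters_p, heatmap_p]))

        # ------------------------------------------------------------ qPCR arm
        if "qpcr" in config:
            qcfg_block = config["qpcr"]
            qsim = sim.QpcrSimConfig(seed=seed + 1, **qcfg_block.get("simulate", {}))
            control, nicotine, qmeta, qtruth = sim.simulate_qpcr_cohort(qsim)
            ct_c_p = out / "ct_control.tsv"
            ct_n_p = out / "ct_nicotine.tsv"
            qmeta_p = out / "qpcr_samples.csv"
            write_expression_table(control.matrix, ct_c_p)
            write_expression_table(nicotine.matrix, ct_n_p)
            write_sample_metadata(qmeta, qmeta_p)
            stages.append(_stage("simulate_qpcr", [ct_c_p, ct_n_p, qmeta_p]))

            panel = qsim.panel
            q_control = qp.quantity_table(control)
            q_nicotine = qp.quantity_table(nicotine)
            merged = q_control.copy_with(
                pd.concat([q_control.data, q_nicotine.data], axis=1), q_control.value_kind
            )
            rq = qp.relative_quantity_to_median(merged, q_control.sample_ids)
            rq_p = out / "rq.tsv"
            write_expression_table(rq.matrix, rq_p)

            ratios_ctrl, sizes = rt.classify_ratio(
                rt.mrna_mir_ratio(
                    qp.RQMatrix(
                        rq.matrix.copy_with(
                            rq.matrix.data[q_control.sample_ids], rq.matrix.value_kind
                        ),
                        rq.normalization_scope,
                    ),
                    panel,
                ),
                hi_cut=qcfg_block.get("hi_cut", rt.HI_CUT_DEFAULT),
                lo_cut=qcfg_block.get("lo_cut", rt.LO_CUT_DEFAULT),
            )
            ratios_nic = rt.mrna_mir_ratio(
                qp.RQMatrix(
                    rq.matrix.copy_with(
                        rq.matrix.data[q_nicotine.sample_ids], rq.matrix.value_kind
                    ),
                    rq.normalization_scope,
                ),
                panel,
            )
            shifts = rt.nicotine_response_shift(ratios_ctrl, ratios_nic, qmeta)
            ratio_p = out / "ratios.tsv"
            sizes_p = out / "group_sizes.json"
            shifts_p = out / "shift_summaries.json"
            rt.ratio_frame(ratios_ctrl).to_csv(ratio_p, sep="\t")
            sizes_p.write_text(json.dumps(sizes, indent=2))
            shifts_p.write_text(
                json.dumps(
                    [
                        {
                            "group": s.group,
                            "n_pairs": s.n_pairs,
                            "direction_counts": s.direction_counts,
                            "p": s.test.p_two_sided,
                            "method": s.test.method,
                        }
                        for s in shifts
                    ],
                    indent=2,
                )
            )
            stages.append(_stage("qpcr_ratio", [rq_p, ratio_p, sizes_p, shifts_p]))
        else:
            stages.append({"name": "qpcr_ratio", "skipped": True, "outputs": {}})

        # ------------------------------------------------------- phenotype arm
        ph_cfg = config.get("phenotype", {})
        markers, pmeta, ptruth = sim.simulate_phenotype_markers(
            n_samples=ph_cfg.get("n_samples", 29),
            n_naive_memory=ph_cfg.get("n_naive_memory", 13),
            seed=seed + 2,
            smoker_counts=tuple(ph_cfg["smoker_counts"]) if "smoker_counts" in ph_cfg else None,
        )
        calls = ph.score_naive_memory(markers, ph.variant_a())
        table, or_, fisher = ph.phenotype_smoking_association(calls, pmeta)
        calls_p = out / "phenotype_calls.tsv"
        assoc_p = out / "phenotype_association.json"
        ph.calls_frame(calls).to_csv(calls_p, sep="\t")
        assoc_p.write_text(
            json.dumps(
                {
                    "table": [[table.a, table.b], [table.c, table.d]],
                    "odds_ratio": float(or_),
                    "fisher_p": fisher.p_two_sided,
                },
                indent=2,
            )
        )
        stages.append(_stage("phenotype_score", [calls_p, assoc_p]))
    except Cd8mirError:
        flush("failed")
        raise
    return flush("complete")
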