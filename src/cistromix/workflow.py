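"""End-to-end orchestration: annotate -> integrate -> atac-rank -> enrich -> motif-cluster.

Consumes a bundle directory laid out the way the synthetic generator writes
one (the same standard formats apply to real data dropped into that
layout), runs every stage in order, and writes per-stage TSVs, a summary
YAML, and a machine-readable manifest recording every parameter. Any stage
failure aborts the run with the failing stage named; partial outputs are
kept next to a FAILED marker file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accessibility as acc
from . import annotation as anno
from . import expression as expr
from . import io as cio
from . import motifs as mot

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Input locations and parameter overrides for a full run."""

    input_dir: str
    output_dir: str
    promoter_window: int = 2000
    tss_proximity_window: int = 5000
    far_limit: int = 1_000_000
    n_bins: int = 100
    fc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    min_rpkm: float = 1.0
    atac_pseudocount: float = 1.0
    enrichment_weight: float = 1.0
    motif_cut: int = 2
    use_atac_tracks: bool = True
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input_dir {self.input_dir} does not exist")
        if self.promoter_window < 0 or self.n_bins < 1:
            raise ValueError("promoter_window must be >= 0 and n_bins >= 1")


def _load_inputs(config: RunConfig) -> dict:
    src = Path(config.input_dir)
    chrom_lengths = {}
    sizes = src / "chrom_sizes.tsv"
    if sizes.exists():
        for line in sizes.read_text().splitlines():
            c, n = line.split("\t")
            chrom_lengths[c] = int(n)
    inputs = {
        "genes": cio.read_tss_table(src / "tss.tsv"),
        "peaks_tf_a": cio.read_peak_table(src / "peaks_tf_a.tsv"),
        "h3k27ac": cio.read_bed_intervals(src / "h3k27ac.bed"),
        "cpg": cio.read_bed_intervals(src / "cpg_islands.bed"),
        "expression": cio.read_expression_table(src / "expression.tsv"),
        "motif_hits": cio.read_motif_hits(src / "motif_hits.tsv"),
        "chrom_lengths": chrom_lengths,
    }
    tfb = src / "peaks_tf_b.tsv"
    inputs["peaks_tf_b"] = cio.read_peak_table(tfb) if tfb.exists() else None
    atac = {}
    for path in sorted(src.glob("atac_*_rep*.narrowPeak")):
        cond, rep = path.stem.split("_")[1], int(path.stem.split("rep")[1])
        atac[(cond, rep)] = cio.read_peaks(path)
    inputs["atac_peaks"] = atac
    tracks: dict[str, list] = {}
    if config.use_atac_tracks:
        for cond in ("control", "ko"):
            paths = sorted(src.glob(f"atac_{cond}_rep*.bedGraph"))
            if paths:
                tracks[cond] = [
                    cio.read_bedgraph(p, chrom_lengths or None) for p in paths
                ]
    inputs["atac_tracks"] = tracks
    return inputs


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the summary dict it also writes."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("cistromix")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.verbosity.upper(), logging.INFO))
    summary: dict = {}
    stage = "load"
    try:
        inputs = _load_inputs(config)
        logger.info("load: %d genes, %d TF-A peaks", len(inputs["genes"]), len(inputs["peaks_tf_a"]))

        stage = "annotate"
        annotations = anno.annotate_peaks(
            inputs["peaks_tf_a"], inputs["genes"], inputs["h3k27ac"],
            promoter_window=config.promoter_window, cpg_islands=inputs["cpg"],
        )
        anno_df = anno.annotation_table(annotations)
        anno_df.to_csv(out / "annotation_tf_a.tsv", sep="\t", index=False)
        summary["tf_a_category_counts"] = (
            anno_df["category"].value_counts().to_dict()
        )
        summary["tf_a_cpg_fraction"] = float(
            anno.cpg_overlap_fraction(inputs["peaks_tf_a"], inputs["cpg"])
        )
        summary["tf_a_tss5kb_fraction"] = float(
            anno.tss_proximal_fraction(
                inputs["peaks_tf_a"], inputs["genes"], config.tss_proximity_window
            )
        )
        dist_a = anno.distances_to_nearest_tss(inputs["peaks_tf_a"], inputs["genes"])
        pd.DataFrame({"distance": dist_a}).to_csv(
            out / "tss_distances_tf_a.tsv", sep="\t", index=False
        )
        if inputs["peaks_tf_b"] is not None:
            anno_b = anno.annotation_table(
                anno.annotate_peaks(
                    inputs["peaks_tf_b"], inputs["genes"], inputs["h3k27ac"],
                    promoter_window=config.promoter_window, cpg_islands=inputs["cpg"],
                )
            )
            anno_b.to_csv(out / "annotation_tf_b.tsv", sep="\t", index=False)
            summary["tf_b_category_counts"] = anno_b["category"].value_counts().to_dict()
            summary["tf_b_tss5kb_fraction"] = float(
                anno.tss_proximal_fraction(
                    inputs["peaks_tf_b"], inputs["genes"], config.tss_proximity_window
                )
            )
            dist_b = anno.distances_to_nearest_tss(inputs["peaks_tf_b"], inputs["genes"])
            stat, p = anno.epps_singleton_test(dist_a, dist_b)
            summary["tss_distance_epps_singleton"] = {"w2": float(stat), "p": float(p)}
        logger.info("annotate: %d peaks in, %d annotated", len(inputs["peaks_tf_a"]), len(anno_df))

        stage = "integrate"
        table = inputs["expression"]
        groups = cio.expression_sample_columns(table)
        ctrl_cols, ko_cols = groups.get("control", []), groups.get("ko", [])
        table = expr.filter_expressed(table, ctrl_cols + ko_cols, config.min_rpkm)
        table = table.assign(
            log2fc=expr.log2_fold_change(
                table[ko_cols].mean(axis=1), table[ctrl_cols].mean(axis=1)
            )
        )
        if "p_value" in table.columns:
            table = table.assign(fdr=expr.bh_fdr(table["p_value"]))
            table = table.assign(
                reg_class=expr.classify_regulation(
                    table["log2fc"], table["fdr"],
                    config.fc_threshold, config.fdr_threshold,
                )
            )
        sig = expr.gene_signals(
            inputs["genes"], inputs["peaks_tf_a"],
            promoter_window=config.promoter_window, far_limit=config.far_limit,
        ).set_index("gene_id")
        table = table.assign(signal=sig.loc[table["gene_id"], "promoter_signal"].to_numpy())
        table.to_csv(out / "gene_table.tsv", sep="\t", index=False)
        trend = expr.binned_occupancy_trend(table, n_bins=min(config.n_bins, len(table)))
        trend.to_csv(out / "bin_trend.tsv", sep="\t", index=False)
        if "reg_class" in table.columns:
            by_class = {
                k: grp["signal"].to_numpy() for k, grp in table.groupby("reg_class")
            }
            mw = expr.signal_by_class_test(by_class)
            mw.to_csv(out / "signal_by_class.tsv", sep="\t", index=False)
            summary["class_counts"] = table["reg_class"].value_counts().to_dict()
        summary["n_expressed_genes"] = int(len(table))
        logger.info("integrate: %d expressed genes, %d bins", len(table), len(trend))

        stage = "atac-rank"
        atac = inputs["atac_peaks"]
        ctrl_reps = [atac[k] for k in sorted(atac) if k[0] == "control"]
        ko_reps = [atac[k] for k in sorted(atac) if k[0] == "ko"]
        consensus = acc.merge_consensus(
            ctrl_reps[0], ko_reps[0],
            tracks_control=inputs["atac_tracks"].get("control"),
            tracks_ko=inputs["atac_tracks"].get("ko"),
        )
        acc.rank_peaks(consensus)
        cons_df = acc.consensus_table(consensus)
        cons_df.to_csv(out / "atac_consensus.tsv", sep="\t", index=False)
        logger.info("atac-rank: %d consensus peaks", len(consensus))

        stage = "enrich"
        atac_sig = acc.gene_atac_signals(
            inputs["genes"], consensus, window=config.promoter_window
        )
        metric = acc.atac_rank_metric(
            atac_sig["atac_control"], atac_sig["atac_ko"], config.atac_pseudocount
        )
        order = np.argsort(-metric, kind="mergesort")
        ranked = list(atac_sig["gene_id"].to_numpy()[order])
        promoter_peak_genes = set(
            anno_df.loc[anno_df["category"] == "promoter", "nearest_tss_gene"]
        )
        if "reg_class" in table.columns:
            down_genes = set(table.loc[table["reg_class"] == "down", "gene_id"])
        else:
            down_genes = set(table.nsmallest(150, "log2fc")["gene_id"])
        query = down_genes & promoter_peak_genes & set(ranked)
        if query:
            res = acc.enrichment_score(
                ranked, query, metric=np.asarray(metric)[order],
                weight_exponent=config.enrichment_weight,
            )
            pd.DataFrame(
                {"gene_id": ranked, "running_sum": res.running_sum}
            ).to_csv(out / "enrichment_running_sum.tsv", sep="\t", index=False)
            summary["enrichment"] = {
                "es": float(res.es),
                "n_query": len(query),
                "n_leading_edge": len(res.leading_edge),
            }
        else:
            logger.warning("enrich: empty query set, stage skipped")
        logger.info("enrich: %d genes ranked, |query| = %d", len(ranked), len(query))

        stage = "motif-cluster"
        dist = mot.cooccurrence_distance(inputs["motif_hits"])
        labels, tree = mot.cluster_motifs(dist, n_clusters=config.motif_cut)
        labels.to_frame().to_csv(out / "motif_clusters.tsv", sep="\t")
        mot.merge_tree_table(tree).to_csv(out / "motif_merge_tree.tsv", sep="\t", index=False)
        anchor_cols = [c for c in inputs["motif_hits"].columns if c.startswith("anchor_")]
        if anchor_cols:
            mot.anchor_association(inputs["motif_hits"], anchor_cols[0]).to_csv(
                out / "motif_anchor_association.tsv", sep="\t", index=False
            )
        summary["motif_clusters"] = {str(k): int(v) for k, v in labels.items()}
        logger.info("motif-cluster: %d factors, cut %d", len(labels), config.motif_cut)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    manifest = {"parameters": asdict(config), "outputs": sorted(p.name for p in out.iterdir())}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return summary
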