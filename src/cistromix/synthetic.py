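"""Seeded synthetic epigenome with planted ground truth.

Generates a toy multi-assay liver-like dataset carrying the statistical
structure the pipeline is built to recover:

* a promoter-biased transactivator (TF-A, the KLF15 archetype) with a
  configurable fraction of peaks at promoters (default 0.70 within 5 kb of
  a TSS) and the contrast factor TF-B (HNF4a archetype, default 0.40);
* knockout expression decline proportional to promoter occupancy — the
  planted log2 fold change is ``-beta * q + noise`` where ``q`` is the
  quantile (rank / n) of a bound gene's background-subtracted promoter
  signal among bound genes, and unbound genes sit at q = 0;
* indirect up-regulation planted only at genes with no local binding;
* knockout accessibility loss (a fixed AUC fraction) only at TF-A-bound
  promoter ATAC peaks;
* a two-block motif co-occurrence structure over open-chromatin regions.

One RNG stream per output artifact, derived from the master seed by stable
labels, so adding an output never perturbs existing ones. A fixed seed
yields byte-identical file bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import io as cio
from .annotation import GeneModel
from .core import GenomicInterval, Peak, SignalTrack

# stable RNG stream labels (order must never change; append only)
_STREAMS = {
    "genome": 0,
    "peaks_tf_a": 1,
    "peaks_tf_b": 2,
    "expression": 3,
    "atac": 4,
    "motifs": 5,
    "cpg": 6,
    "enhancers": 7,
}

PROMOTER_MOTIF_BLOCK = ("KLF15", "SP1", "E2F4", "ZFX")
DISTAL_MOTIF_BLOCK = ("HNF4A", "NR2F2", "PPARA", "PPARG")

TRACK_BASELINE = 0.02  # rpm/bp noise floor shared by TF and background tracks


@dataclass
class SimConfig:
    """Study conditions for the synthetic epigenome."""

    seed: int = 0
    n_chromosomes: int = 8
    chrom_length: int = 2_000_000
    n_genes: int = 2000
    n_peaks_tf_a: int = 2000
    promoter_fraction_tf_a: float = 0.70
    n_peaks_tf_b: int = 2000
    promoter_fraction_tf_b: float = 0.40
    effect_beta: float = 1.0
    n_indirect_up: int = 200
    noise_sd_log2fc: float = 0.3
    atac_loss_fraction: float = 0.5
    motif_noise_flip_rate: float = 0.05
    n_replicates: int = 2
    # layout / nuisance parameters
    gene_spacing: int = 6000
    cpg_gene_fraction: float = 0.6
    n_open_regions: int = 500
    n_distal_open: int = 300
    replicate_noise_log2: float = 0.1
    nonexpressed_fraction: float = 0.02
    make_tracks: bool = True

    def validate(self) -> None:
        for name in ("promoter_fraction_tf_a", "promoter_fraction_tf_b",
                     "cpg_gene_fraction", "atac_loss_fraction", "motif_noise_flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chromosomes", "chrom_length", "n_genes", "n_peaks_tf_a",
                     "n_peaks_tf_b", "n_replicates", "gene_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for tf, n_peaks, frac in (
            ("tf_a", self.n_peaks_tf_a, self.promoter_fraction_tf_a),
            ("tf_b", self.n_peaks_tf_b, self.promoter_fraction_tf_b),
        ):
            if round(frac * n_peaks) > self.n_genes:
                raise ValueError(
                    f"infeasible config: {tf} wants {round(frac * n_peaks)} promoter "
                    f"peaks but only {self.n_genes} promoters exist"
                )
        per_chrom = -(-self.n_genes // self.n_chromosomes)
        if 10_000 + per_chrom * self.gene_spacing + 120_000 > self.chrom_length:
            raise ValueError("infeasible config: genes + desert do not fit the chromosome")


@dataclass
class GroundTruth:
    """Planted quantities, sufficient to score every recovery property."""

    genes: pd.DataFrame
    peaks_tf_a: pd.DataFrame
    peaks_tf_b: pd.DataFrame
    atac: pd.DataFrame
    motif_blocks: pd.DataFrame
    config: SimConfig


@dataclass
class SimBundle:
    """In-memory synthetic dataset (what the file bundle round-trips to)."""

    chrom_lengths: dict[str, int]
    genes: list[GeneModel]
    peaks_tf_a: list[Peak]
    peaks_tf_b: list[Peak]
    h3k27ac: list[GenomicInterval]
    h3k4me1: list[GenomicInterval]
    cpg_islands: list[GenomicInterval]
    expression: pd.DataFrame
    atac_peaks: dict[tuple[str, int], list[Peak]]  # (condition, replicate) -> peaks
    motif_hits: pd.DataFrame
    tf_a_track: SignalTrack | None = None
    background_track: SignalTrack | None = None
    atac_tracks: dict[str, list[SignalTrack]] = field(default_factory=dict)

    @property
    def control_columns(self) -> list[str]:
        return [c for c in self.expression.columns if c.startswith("control:")]

    @property
    def ko_columns(self) -> list[str]:
        return [c for c in self.expression.columns if c.startswith("ko:")]


def _rng(config: SimConfig, label: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[label]])


def _layout(config: SimConfig):
    """Chromosome sizes, TSS grid, and per-chromosome gene-desert spans."""
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    lengths = {c: config.chrom_length for c in chroms}
    per_chrom = -(-config.n_genes // config.n_chromosomes)
    rng = _rng(config, "genome")
    genes: list[GeneModel] = []
    deserts: dict[str, tuple[int, int]] = {}
    i = 0
    for chrom in chroms:
        n_here = min(per_chrom, config.n_genes - i)
        for j in range(n_here):
            tss = 10_000 + j * config.gene_spacing
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene_{i + 1:05d}", chrom, strand, tss))
            i += 1
        gene_end = 10_000 + per_chrom * config.gene_spacing
        deserts[chrom] = (gene_end + 10_000, config.chrom_length - 1_000)
    return lengths, genes, deserts


def _make_peaks(
    config: SimConfig,
    label: str,
    n_peaks: int,
    promoter_fraction: float,
    genes: list[GeneModel],
    deserts: dict[str, tuple[int, int]],
    prefix: str,
):
    """Plant promoter and desert (distal) peaks with log-normal AUCs."""
    rng = _rng(config, label)
    n_prom = int(round(promoter_fraction * n_peaks))
    bound_idx = rng.choice(len(genes), size=n_prom, replace=False)
    peaks: list[Peak] = []
    rows = []
    chroms = sorted(deserts)
    for k in range(n_peaks):
        if k < n_prom:
            g = genes[int(bound_idx[k])]
            summit = g.tss + int(rng.integers(-500, 501))
            gene_id, category = g.gene_id, "promoter"
            chrom = g.chrom
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            lo, hi = deserts[chrom]
            summit = int(rng.integers(lo, hi))
            gene_id, category = "", "distal"
        width = int(rng.uniform(200, 600))
        start = max(summit - width // 2, 0)
        end = start + width
        height = rng.lognormal(2.0, 0.5)
        auc = height * width
        background_auc = max(0.1 * auc * (1.0 + rng.normal(0, 0.1)), 0.0)
        peaks.append(
            Peak(
                GenomicInterval(chrom, start, end),
                summit=summit,
                auc=auc,
                background_auc=background_auc,
                name=f"{prefix}_{k + 1:05d}",
            )
        )
        rows.append(
            {
                "name": peaks[-1].name,
                "planted_category": category,
                "gene_id": gene_id,
                "auc": auc,
                "background_auc": background_auc,
            }
        )
    return peaks, pd.DataFrame(rows)


def _flat_block_track(
    chrom_lengths: dict[str, int],
    blocks: list[tuple[GenomicInterval, float]],
    baseline: float = 0.0,
) -> SignalTrack:
    data = {
        c: np.full(n, baseline, dtype=np.float32) for c, n in chrom_lengths.items()
    }
    for iv, value in blocks:
        vec = data[iv.chrom]
        vec[iv.start : min(iv.end, len(vec))] = baseline + value
    return SignalTrack(data={c: v for c, v in data.items()})


def simulate(config: SimConfig, out_dir: str | Path | None = None) -> tuple[SimBundle, GroundTruth]:
    """Generate the bundle (and optionally write it as a file set)."""
    config.validate()
    chrom_lengths, genes, deserts = _layout(config)

    peaks_a, truth_a = _make_peaks(
        config, "peaks_tf_a", config.n_peaks_tf_a, config.promoter_fraction_tf_a,
        genes, deserts, "tfa",
    )
    peaks_b, truth_b = _make_peaks(
        config, "peaks_tf_b", config.n_peaks_tf_b, config.promoter_fraction_tf_b,
        genes, deserts, "tfb",
    )

    # CpG islands at an exact count of promoters; truth records realized overlap
    rng_cpg = _rng(config, "cpg")
    n_cpg = int(round(config.cpg_gene_fraction * config.n_genes))
    cpg_gene_idx = set(int(i) for i in rng_cpg.choice(config.n_genes, n_cpg, replace=False))
    cpg_islands = [
        GenomicInterval(g.chrom, max(g.tss - 300, 0), g.tss + 300)
        for i, g in enumerate(genes)
        if i in cpg_gene_idx
    ]
    cpg_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in cpg_islands:
        cpg_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    def overlaps_cpg(p: Peak) -> bool:
        return any(
            p.interval.start < e and s < p.interval.end
            for s, e in cpg_by_chrom.get(p.chrom, [])
        )

    for peaks, truth in ((peaks_a, truth_a), (peaks_b, truth_b)):
        truth["cpg_overlap"] = [overlaps_cpg(p) for p in peaks]

    # enhancer-mark intervals: all promoters carry H3K27ac; most desert peaks
    # sit in an H3K27ac+H3K4me1 enhancer region
    rng_enh = _rng(config, "enhancers")
    h3k27ac = [
        GenomicInterval(g.chrom, max(g.tss - 1000, 0), g.tss + 1000) for g in genes
    ]
    h3k4me1 = []
    distal_peaks = [
        p
        for p, cat in zip(
            peaks_a + peaks_b,
            list(truth_a["planted_category"]) + list(truth_b["planted_category"]),
        )
        if cat == "distal"
    ]
    for p in distal_peaks:
        if rng_enh.random() < 0.8:
            iv = GenomicInterval(p.chrom, max(p.summit - 500, 0), p.summit + 500)
            h3k27ac.append(iv)
            h3k4me1.append(iv)

    # expression: decline proportional to promoter-occupancy quantile
    rng_expr = _rng(config, "expression")
    n = config.n_genes
    promoter_signal_true = np.zeros(n)
    gene_pos = {g.gene_id: i for i, g in enumerate(genes)}
    for _, row in truth_a.iterrows():
        if row["planted_category"] == "promoter":
            promoter_signal_true[gene_pos[row["gene_id"]]] += max(
                row["auc"] - row["background_auc"], 0.0
            )
    bound = promoter_signal_true > 0
    quantile = np.zeros(n)
    if bound.any():
        ranks = stats.rankdata(promoter_signal_true[bound])
        quantile[bound] = ranks / bound.sum()

    unbound_idx = np.flatnonzero(~bound)
    if config.n_indirect_up > len(unbound_idx):
        raise ValueError("infeasible config: n_indirect_up exceeds unbound gene count")
    up_idx = rng_expr.choice(unbound_idx, size=config.n_indirect_up, replace=False)
    status = np.where(bound, "direct_down", "null").astype(object)
    status[up_idx] = "indirect_up"

    log2fc_true = -config.effect_beta * quantile + rng_expr.normal(
        0.0, config.noise_sd_log2fc, n
    )
    log2fc_true[up_idx] = rng_expr.uniform(1.2, 2.5, size=len(up_idx)) + (
        rng_expr.normal(0.0, config.noise_sd_log2fc, len(up_idx))
        if config.noise_sd_log2fc > 0
        else 0.0
    )

    base_rpkm = rng_expr.lognormal(3.0, 1.0, n)
    n_nonexpr = int(round(config.nonexpressed_fraction * n))
    null_idx = np.flatnonzero(status == "null")
    nonexpr_idx = rng_expr.choice(null_idx, size=min(n_nonexpr, len(null_idx)), replace=False)
    base_rpkm[nonexpr_idx] = rng_expr.uniform(0.05, 0.8, size=len(nonexpr_idx))
    status[nonexpr_idx] = "nonexpressed"

    reps = config.n_replicates
    ctrl = base_rpkm[:, None] * 2.0 ** rng_expr.normal(
        0.0, config.replicate_noise_log2, (n, reps)
    )
    ko = (base_rpkm * 2.0 ** log2fc_true)[:, None] * 2.0 ** rng_expr.normal(
        0.0, config.replicate_noise_log2, (n, reps)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        tt = stats.ttest_ind(np.log2(ctrl + 0.01), np.log2(ko + 0.01), axis=1)
    p_values = np.where(np.isnan(tt.pvalue), 1.0, tt.pvalue)

    expression = pd.DataFrame({"gene_id": [g.gene_id for g in genes]})
    for r in range(reps):
        expression[f"control:rep{r + 1}"] = ctrl[:, r]
    for r in range(reps):
        expression[f"ko:rep{r + 1}"] = ko[:, r]
    expression["p_value"] = p_values

    genes_truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
            "bound_tf_a": bound,
            "promoter_signal_true": promoter_signal_true,
            "occupancy_quantile": quantile,
            "log2fc_true": log2fc_true,
            "status": status,
            "base_rpkm": base_rpkm,
            "cpg_promoter": [i in cpg_gene_idx for i in range(n)],
        }
    )

    # ATAC: open promoter per gene plus desert open regions; KO loses a fixed
    # AUC fraction only at TF-A-bound promoters
    rng_atac = _rng(config, "atac")
    atac_rows = []
    atac_intervals: list[GenomicInterval] = []
    for i, g in enumerate(genes):
        iv = GenomicInterval(g.chrom, max(g.tss - 250, 0), g.tss + 250)
        height = rng_atac.lognormal(2.0, 0.5)
        control_auc = height * iv.width
        loss = config.atac_loss_fraction if bound[i] else 0.0
        atac_rows.append(
            {
                "name": f"atac_{i + 1:05d}",
                "gene_id": g.gene_id,
                "bound_tf_a": bool(bound[i]),
                "control_auc_base": control_auc,
                "ko_auc_base": control_auc * (1.0 - loss),
                "loss_fraction": loss,
            }
        )
        atac_intervals.append(iv)
    chroms = sorted(deserts)
    for j in range(config.n_distal_open):
        chrom = chroms[int(rng_atac.integers(len(chroms)))]
        lo, hi = deserts[chrom]
        pos = int(rng_atac.integers(lo, hi))
        width = int(rng_atac.uniform(300, 700))
        iv = GenomicInterval(chrom, max(pos - width // 2, 0), pos + width // 2)
        height = rng_atac.lognormal(2.0, 0.5)
        atac_rows.append(
            {
                "name": f"atac_d{j + 1:04d}",
                "gene_id": "",
                "bound_tf_a": False,
                "control_auc_base": height * iv.width,
                "ko_auc_base": height * iv.width,
                "loss_fraction": 0.0,
            }
        )
        atac_intervals.append(iv)
    atac_truth = pd.DataFrame(atac_rows)

    atac_peaks: dict[tuple[str, int], list[Peak]] = {}
    rep_factors = {}
    for cond, col in (("control", "control_auc_base"), ("ko", "ko_auc_base")):
        for r in range(reps):
            factors = 2.0 ** rng_atac.normal(0.0, config.replicate_noise_log2, len(atac_truth))
            rep_factors[(cond, r)] = factors
            atac_peaks[(cond, r + 1)] = [
                Peak(iv, auc=float(aucb * f), name=nm)
                for iv, aucb, f, nm in zip(
                    atac_intervals,
                    atac_truth[col].to_numpy(),
                    factors,
                    atac_truth["name"],
                )
            ]

    # motif co-occurrence: two planted blocks over open-chromatin regions
    rng_motif = _rng(config, "motifs")
    n_regions = config.n_open_regions
    n_anchor = n_regions // 2
    group_a = np.zeros(n_regions, dtype=bool)
    group_a[:n_anchor] = True
    factors_all = list(PROMOTER_MOTIF_BLOCK) + list(DISTAL_MOTIF_BLOCK)
    hit_cols = {}
    for f in factors_all:
        in_promoter_block = f in PROMOTER_MOTIF_BLOCK
        base = group_a if in_promoter_block else ~group_a
        flips = rng_motif.random(n_regions) < config.motif_noise_flip_rate
        hit_cols[f] = (base ^ flips).astype(int)
    motif_hits = pd.DataFrame(hit_cols, index=[f"region_{i + 1:04d}" for i in range(n_regions)])
    motif_hits.insert(0, "anchor_tf_a", group_a.astype(int))
    motif_hits.insert(1, "anchor_tf_b", (~group_a).astype(int))
    motif_hits.index.name = "peak_id"
    motif_blocks = pd.DataFrame(
        {
            "factor": factors_all,
            "planted_block": [
                "promoter" if f in PROMOTER_MOTIF_BLOCK else "distal" for f in factors_all
            ],
        }
    )

    # coverage tracks (flat blocks over peak spans on a shared baseline)
    tf_a_track = background_track = None
    atac_tracks: dict[str, list[SignalTrack]] = {}
    if config.make_tracks:
        tf_a_track = _flat_block_track(
            chrom_lengths,
            [(p.interval, p.auc / p.interval.width) for p in peaks_a],
            baseline=TRACK_BASELINE,
        )
        background_track = _flat_block_track(
            chrom_lengths,
            [(p.interval, p.background_auc / p.interval.width) for p in peaks_a],
            baseline=TRACK_BASELINE,
        )
        for cond in ("control", "ko"):
            atac_tracks[cond] = [
                _flat_block_track(
                    chrom_lengths,
                    [(p.interval, p.auc / p.interval.width) for p in atac_peaks[(cond, r + 1)]],
                )
                for r in range(reps)
            ]

    bundle = SimBundle(
        chrom_lengths=chrom_lengths,
        genes=genes,
        peaks_tf_a=peaks_a,
        peaks_tf_b=peaks_b,
        h3k27ac=h3k27ac,
        h3k4me1=h3k4me1,
        cpg_islands=cpg_islands,
        expression=expression,
        atac_peaks=atac_peaks,
        motif_hits=motif_hits,
        tf_a_track=tf_a_track,
        background_track=background_track,
        atac_tracks=atac_tracks,
    )
    truth = GroundTruth(
        genes=genes_truth,
        peaks_tf_a=truth_a,
        peaks_tf_b=truth_b,
        atac=atac_truth,
        motif_blocks=motif_blocks,
        config=config,
    )
    if out_dir is not None:
        write_bundle(bundle, truth, out_dir)
    return bundle, truth


def write_bundle(bundle: SimBundle, truth: GroundTruth, out_dir: str | Path) -> None:
    """Write the bundle in the standard formats plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def record(name: str) -> Path:
        files[name] = name
        return out / name

    with open(record("chrom_sizes.tsv"), "w") as fh:
        for c, n in bundle.chrom_lengths.items():
            fh.write(f"{c}\t{n}\n")
    cio.write_tss_table(bundle.genes, record("tss.tsv"))
    cio.write_peak_table(bundle.peaks_tf_a, record("peaks_tf_a.tsv"))
    cio.write_peak_table(bundle.peaks_tf_b, record("peaks_tf_b.tsv"))
    cio.write_narrowpeak(bundle.peaks_tf_a, record("peaks_tf_a.narrowPeak"))
    cio.write_narrowpeak(bundle.peaks_tf_b, record("peaks_tf_b.narrowPeak"))
    cio.write_bed_intervals(bundle.h3k27ac, record("h3k27ac.bed"))
    cio.write_bed_intervals(bundle.h3k4me1, record("h3k4me1.bed"))
    cio.write_bed_intervals(bundle.cpg_islands, record("cpg_islands.bed"))
    bundle.expression.to_csv(record("expression.tsv"), sep="\t", index=False)
    bundle.motif_hits.to_csv(record("motif_hits.tsv"), sep="\t")
    for (cond, rep), peaks in bundle.atac_peaks.items():
        cio.write_narrowpeak(peaks, record(f"atac_{cond}_rep{rep}.narrowPeak"))
    if bundle.tf_a_track is not None:
        cio.write_bedgraph(bundle.tf_a_track, record("tf_a.bedGraph"))
        cio.write_bedgraph(bundle.background_track, record("wce.bedGraph"))
        for cond, tracks in bundle.atac_tracks.items():
            for r, tr in enumerate(tracks, start=1):
                cio.write_bedgraph(tr, record(f"atac_{cond}_rep{r}.bedGraph"))
    truth.genes.to_csv(record("truth_genes.tsv"), sep="\t", index=False)
    truth.peaks_tf_a.to_csv(record("truth_peaks_tf_a.tsv"), sep="\t", index=False)
    truth.peaks_tf_b.to_csv(record("truth_peaks_tf_b.tsv"), sep="\t", index=False)
    truth.atac.to_csv(record("truth_atac.tsv"), sep="\t", index=False)
    truth.motif_blocks.to_csv(record("truth_motifs.tsv"), sep="\t", index=False)
    manifest = {
        "config": asdict(truth.config),
        "rng_streams": dict(_STREAMS),
        "files": sorted(files),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def simulate_microarray(
    seed: int = 0,
    n_genes: int = 800,
    n_samples_per_group: int = 4,
    n_down: int = 20,
    archetype_gene: str = "cbg_archetype",
    archetype_log2fc: float = -np.log2(14.0),
    archetype_rank: int = 4,
    noise_sd: float = 0.15,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic stand-in for a knockout-liver microarray probe matrix.

    Plants ``n_down`` strongly down-regulated genes; the CBG archetype (a
    14-fold-down gene, mirroring the flagship direct target) is placed at
    ``archetype_rank`` of the planted down-ordering. Genes carry 1-3 probes
    each. Returns (probe_df with wt/ko sample columns, truth table with the
    planted log2 fold changes).
    """
    rng = np.random.default_rng([seed, 97])
    names = [f"arr_gene_{i + 1:04d}" for i in range(n_genes)]
    log2fc = rng.normal(0.0, 0.15, n_genes)
    # planted down genes: strictly decreasing severity around the archetype
    stronger = np.linspace(-5.5, archetype_log2fc - 0.3, archetype_rank - 1)
    weaker = np.linspace(archetype_log2fc + 0.3, -1.5, n_down - archetype_rank)
    down_idx = rng.choice(n_genes, size=n_down, replace=False)
    planted = np.concatenate((stronger, [archetype_log2fc], weaker))
    log2fc[down_idx] = planted
    names[int(down_idx[archetype_rank - 1])] = archetype_gene

    wt_cols = [f"wt:{i + 1}" for i in range(n_samples_per_group)]
    ko_cols = [f"ko:{i + 1}" for i in range(n_samples_per_group)]
    rows = []
    for i, name in enumerate(names):
        base = rng.lognormal(6.0, 1.0)
        for _ in range(int(rng.integers(1, 4))):
            row = {"gene_id": name}
            for c in wt_cols:
                row[c] = base * 2.0 ** rng.normal(0.0, noise_sd)
            for c in ko_cols:
                row[c] = base * 2.0 ** (log2fc[i] + rng.normal(0.0, noise_sd))
            rows.append(row)
    probe_df = pd.DataFrame(rows)
    truth = pd.DataFrame({"gene_id": names, "log2fc_true": log2fc})
    return probe_df, truth


def score_recovery(bundle: SimBundle, truth: GroundTruth, n_bins: int = 100) -> dict:
    """Run the pipeline stages on a bundle and score them against the truth.

    Raises on mismatched gene universes. Returns a flat report dict.
    """
    from scipy.stats import spearmanr

    from . import accessibility as acc
    from . import annotation as anno
    from . import expression as expr
    from . import motifs as mot

    if set(bundle.expression["gene_id"]) != set(truth.genes["gene_id"]):
        raise ValueError("bundle and truth describe different gene universes")
    config = truth.config

    report: dict[str, float] = {}
    report["tf_a_tss5kb_fraction"] = anno.tss_proximal_fraction(
        bundle.peaks_tf_a, bundle.genes, window=5000
    )
    report["tf_b_tss5kb_fraction"] = anno.tss_proximal_fraction(
        bundle.peaks_tf_b, bundle.genes, window=5000
    )
    report["tf_a_fraction_error"] = abs(
        report["tf_a_tss5kb_fraction"] - config.promoter_fraction_tf_a
    )
    report["tf_b_fraction_error"] = abs(
        report["tf_b_tss5kb_fraction"] - config.promoter_fraction_tf_b
    )

    # occupancy-expression trend on expressed genes
    ctrl_cols, ko_cols = bundle.control_columns, bundle.ko_columns
    tab = expr.filter_expressed(bundle.expression, ctrl_cols + ko_cols)
    sig = expr.gene_signals(bundle.genes, bundle.peaks_tf_a).set_index("gene_id")
    tab = tab.assign(
        signal=sig.loc[tab["gene_id"], "promoter_signal"].to_numpy(),
        log2fc=expr.log2_fold_change(
            tab[ko_cols].mean(axis=1), tab[ctrl_cols].mean(axis=1)
        ),
    )
    trend = expr.binned_occupancy_trend(tab, n_bins=min(n_bins, len(tab)))
    rho = spearmanr(trend["median_signal"], trend["median_log2fc"]).statistic
    report["trend_spearman"] = float(rho)

    # planted direct-down vs indirect-up promoter-signal gap
    status = truth.genes.set_index("gene_id")["status"]
    down_sig = sig.loc[status[status == "direct_down"].index, "promoter_signal"]
    up_sig = sig.loc[status[status == "indirect_up"].index, "promoter_signal"]
    report["signal_gap_down_minus_up"] = float(down_sig.mean() - up_sig.mean())
    if len(down_sig) and len(up_sig):
        mw = expr.signal_by_class_test(
            {"down": down_sig.to_numpy(), "up": up_sig.to_numpy()},
            pairs=[("down", "up")],
        )
        report["signal_gap_mannwhitney_p"] = float(mw["p_value"].iloc[0])

    # ATAC rank shift + leading-edge enrichment
    consensus = acc.merge_consensus(
        bundle.atac_peaks[("control", 1)],
        bundle.atac_peaks[("ko", 1)],
        tracks_control=bundle.atac_tracks.get("control"),
        tracks_ko=bundle.atac_tracks.get("ko"),
    )
    acc.rank_peaks(consensus)
    from .annotation import _tss_index, nearest_tss

    tss_idx = _tss_index(bundle.genes)
    bound_genes = set(truth.genes.loc[truth.genes["bound_tf_a"], "gene_id"])
    drops_bound, drops_unbound = [], []
    for cp in consensus:
        gid, dist = nearest_tss(cp.summit, cp.interval.chrom, tss_idx)
        drop = cp.rank_control - cp.rank_ko
        if dist is not None and dist <= 2000 and gid in bound_genes:
            drops_bound.append(drop)
        else:
            drops_unbound.append(drop)
    report["rank_drop_bound_median"] = float(np.median(drops_bound)) if drops_bound else 0.0
    report["rank_drop_unbound_median"] = (
        float(np.median(drops_unbound)) if drops_unbound else 0.0
    )

    atac_sig = acc.gene_atac_signals(bundle.genes, consensus)
    metric = acc.atac_rank_metric(atac_sig["atac_control"], atac_sig["atac_ko"])
    order = np.argsort(-metric, kind="mergesort")
    ranked = atac_sig["gene_id"].to_numpy()[order]
    query = bound_genes & set(
        truth.genes.loc[truth.genes["status"] == "direct_down", "gene_id"]
    )
    if query:
        res = acc.enrichment_score(list(ranked), query, metric=np.asarray(metric)[order])
        report["leading_edge_es"] = res.es

    # motif block recovery
    dist = mot.cooccurrence_distance(bundle.motif_hits)
    labels, _ = mot.cluster_motifs(dist, n_clusters=2)
    planted = truth.motif_blocks.set_index("factor")["planted_block"]
    report["motif_adjusted_rand"] = mot.adjusted_rand_index(
        labels.reindex(planted.index), planted
    )
    return report
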