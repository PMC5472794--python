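"""End-to-end orchestration: simulate -> segment -> quantify -> cluster ->
null -> genomics, with a serialized, hashed configuration for provenance.

Every output table starts with a ``# config_hash=...`` comment line so any
result file can be traced back to the exact configuration that produced
it. Stages run in dependency order; a failing stage aborts the run with
the stage named, keeping whatever partial outputs already exist.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster3d, focus_quant, genomics, imaging, spatial_null, synthetic

__all__ = ["RunConfig", "run_pipeline", "report_summary", "PipelineError"]

log = logging.getLogger("nanofoci")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All tunable parameters of a full synthetic run.

    The imaging geometry is a scaled-down nucleus (2.5 um radius sphere in
    a 44 x 160 x 160 grid at 39/125 nm voxels) so a complete run stays fast;
    thresholds and physical parameters keep their standard values
    (focus threshold 1000, minimum focus volume 0.001 um^3, nominal
    touching-object volume 0.05 um^3, 3-voxel shells, 500 nm cluster
    cutoff, 10 kb bins, ploidy factor 3.12).
    """

    seed: int = 0
    conditions: list = field(default_factory=lambda: [
        {"label": "0.5h", "n_clusters": 5, "foci_per_cluster": 4},
    ])
    n_nuclei: int = 1
    # imaging geometry
    shape: tuple = (44, 160, 160)
    voxel_size_nm: tuple = (39.0, 125.0)
    nucleus_radius_um: float = 2.5
    intra_cluster_sigma_nm: float = 100.0
    min_inter_cluster_nm: float = 2000.0
    channels: tuple = ("dapi", "gamma")
    # segmentation
    nucleus_threshold: float = 1000.0
    min_nucleus_volume_um3: float = 20.0
    focus_threshold: float = 1000.0
    min_focus_volume_um3: float = 0.001
    nominal_volume_um3: float = 0.05
    shell_dilation_voxels: int = 3
    # quantification / clustering
    cutoff_nm: float = 500.0
    ploidy_factor: float = 3.12
    haploid_reference_mbp: float = 3100.0
    cell_cycle_factor: float = 1.0
    # null model
    null_iterations: int = 100
    # genomics
    genome_length_bp: int = 20_000_000
    bin_size_bp: int = 10_000
    n_planted_domains: int = 20
    domain_bins: int = 5
    background_rate: float = 1.0
    enrichment_rate: float = 10.0

    @property
    def genome_size_mbp(self) -> float:
        return self.haploid_reference_mbp * self.ploidy_factor

    def validate(self) -> None:
        if self.cutoff_nm <= 0:
            raise ValueError("cutoff_nm must be positive")
        if self.shell_dilation_voxels < 1:
            raise ValueError("shell_dilation_voxels must be >= 1")
        if self.bin_size_bp <= 0 or self.genome_length_bp <= 0:
            raise ValueError("genomic sizes must be positive")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if not self.conditions:
            raise ValueError("at least one condition is required")
        for cond in self.conditions:
            if "label" not in cond:
                raise ValueError("every condition needs a label")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": asdict(self), "hash": self.config_hash()},
                      fh, indent=2, default=list)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _process_nucleus(cfg: RunConfig, label: str, seed: int):
    """Simulate and fully quantify one nucleus; returns (foci, clusters, summary)."""
    stack, truth = synthetic.make_nucleus_image(
        shape=tuple(cfg.shape),
        voxel_size_nm=tuple(cfg.voxel_size_nm),
        n_clusters=next(c["n_clusters"] for c in cfg.conditions
                        if c["label"] == label),
        foci_per_cluster=next(c["foci_per_cluster"] for c in cfg.conditions
                              if c["label"] == label),
        intra_cluster_sigma_nm=cfg.intra_cluster_sigma_nm,
        min_inter_cluster_nm=cfg.min_inter_cluster_nm,
        channels=tuple(cfg.channels),
        nucleus_radius_um=cfg.nucleus_radius_um,
        seed=seed,
    )
    nucleus = imaging.segment_nucleus(
        stack, "dapi", threshold=cfg.nucleus_threshold,
        min_volume_um3=cfg.min_nucleus_volume_um3,
    )
    labels = imaging.detect_foci(
        stack, "gamma", nucleus,
        intensity_threshold=cfg.focus_threshold,
        min_volume_um3=cfg.min_focus_volume_um3,
    )
    labels = imaging.separate_touching(
        labels, stack.channel("gamma"), stack.voxel_size_nm,
        nominal_volume_um3=cfg.nominal_volume_um3,
        min_volume_um3=cfg.min_focus_volume_um3,
    )
    foci = imaging.foci_table(labels, stack, "gamma", nucleus)
    dna_cfg = focus_quant.DnaContentConfig(
        genome_size_mbp=cfg.genome_size_mbp,
        ploidy_factor=cfg.ploidy_factor,
        cell_cycle_factor=cfg.cell_cycle_factor,
    )
    foci = focus_quant.estimate_dna_content(foci, nucleus, dna_cfg)
    vf = focus_quant.volume_fraction(foci, nucleus)

    pts = foci[["centroid_x_nm", "centroid_y_nm", "centroid_z_nm"]].to_numpy()
    assignments = cluster3d.cluster_foci(pts, cfg.cutoff_nm)
    clusters = cluster3d.cluster_table(foci, assignments) if len(foci) \
        else pd.DataFrame()
    foci = foci.assign(cluster_id=assignments if len(foci) else [])

    summary = {
        "condition": label,
        "seed": seed,
        "n_foci": int(len(foci)),
        "n_clusters": int(len(clusters)),
        "median_foci_per_cluster": float(clusters["n_foci"].median())
        if len(clusters) else np.nan,
        "volume_fraction_pct": vf,
        "nucleus_volume_um3": nucleus.volume_um3,
    }
    return foci, clusters, summary


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute every stage; returns the run directory.

    Outputs: ``config.json``, ``foci.tsv``, ``clusters.tsv``,
    ``summary.tsv``, ``null_quantiles.tsv``, ``domains.bed`` and
    ``report.txt``, all stamped with the config hash.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    cfg.to_json(out / "config.json")
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "simulate/segment/quantify/cluster"
    try:
        rng = np.random.default_rng(cfg.seed)
        all_foci, all_clusters, summaries = [], [], []
        for cond in cfg.conditions:
            for i in range(cfg.n_nuclei):
                sub_seed = int(rng.integers(0, 2**31 - 1))
                foci, clusters, summary = _process_nucleus(
                    cfg, cond["label"], sub_seed
                )
                nucleus_id = f"{cond['label']}_{i}"
                foci.insert(0, "nucleus", nucleus_id)
                if len(clusters):
                    clusters.insert(0, "nucleus", nucleus_id)
                summary["nucleus"] = nucleus_id
                all_foci.append(foci)
                all_clusters.append(clusters)
                summaries.append(summary)
                log.info("nucleus %s: %d foci, %d clusters", nucleus_id,
                         summary["n_foci"], summary["n_clusters"])
        foci_df = pd.concat(all_foci, ignore_index=True)
        clusters_df = pd.concat([c for c in all_clusters if len(c)],
                                ignore_index=True) if any(
            len(c) for c in all_clusters) else pd.DataFrame()

        stage = "null"
        n_query = max(int(foci_df.groupby("nucleus").size().mean()), 1)
        n_target = max(int(len(clusters_df)) // max(len(summaries), 1), 1)
        radius_um = (3.0 * np.mean([s["nucleus_volume_um3"] for s in summaries])
                     / (4.0 * np.pi)) ** (1.0 / 3.0)
        null_cfg = spatial_null.NullConfig(
            sphere_radius_um=float(radius_um), n_query=n_query,
            n_target=n_target, n_iter=cfg.null_iterations, seed=cfg.seed,
        )
        null_res = spatial_null.simulate_null(null_cfg)
        null_q = spatial_null.null_quantile_table(null_res)

        stage = "genomics"
        # planted domains spread over the synthetic genome, bin-aligned
        gap = cfg.genome_length_bp // (cfg.n_planted_domains + 1)
        gap -= gap % cfg.bin_size_bp
        ivals = [
            ("chr1", (k + 1) * gap,
             (k + 1) * gap + cfg.domain_bins * cfg.bin_size_bp)
            for k in range(cfg.n_planted_domains)
        ]
        truth = synthetic.TrackTruth(
            domain_intervals=ivals, background_rate=cfg.background_rate,
            enrichment_rate=cfg.enrichment_rate, seed=cfg.seed,
        )
        track = synthetic.make_chipseq_track(cfg.genome_length_bp,
                                             cfg.bin_size_bp, truth)
        vf_mean = float(np.mean([s["volume_fraction_pct"] for s in summaries]))
        match = genomics.match_smoothing(
            track, vf_mean, n_nanofoci=len(foci_df),
            ploidy_factor=cfg.ploidy_factor,
        )
        summary_df = pd.DataFrame(summaries)
        summary_df["domain_count"] = len(match.domains)
        summary_df["chosen_w"] = match.chosen_w

        stage = "write"
        _write_table(foci_df, out / "foci.tsv", cfg_hash)
        _write_table(clusters_df, out / "clusters.tsv", cfg_hash)
        _write_table(summary_df, out / "summary.tsv", cfg_hash)
        _write_table(null_q, out / "null_quantiles.tsv", cfg_hash)
        with open(out / "domains.bed", "w") as fh:
            fh.write(f"# config_hash={cfg_hash}\n")
            for _, d in match.domains.iterrows():
                fh.write(f"{d.chrom}\t{d.start}\t{d.end}\n")
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def report_summary(run_dir: str | Path) -> pd.DataFrame:
    """Per-nucleus summary of a completed (or partial) run.

    Missing stage outputs yield an empty frame rather than an error, so a
    partial run can still be inspected.
    """
    path = Path(run_dir) / "summary.tsv"
    if not path.exists():
        return pd.DataFrame()
    return read_table(path)
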