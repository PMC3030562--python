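"""End-to-end runner: simulate -> call peaks -> atlas -> score -> test -> motifs,
with the expression branch alongside, under a single seeded configuration.

Every stage writes its standard output files into the run directory, and the
machine-readable ``summary.json`` records the configuration hash, seed,
atlas size, differential-region counts, per-motif Z-scores and the
expression-set sizes.  Reruns with an identical configuration and seed
reproduce the summary exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import atlas as atlas_mod
from . import difftest, expression, io, motifs, peaks, synthetic

log = logging.getLogger("acetylscan")


@dataclass
class PipelineConfig:
    """Flat configuration for a full synthetic run; defaults are the study
    conditions the generators emulate."""

    seed: int = 1
    # synthetic genome / regions
    n_chroms: int = 2
    length_per_chrom: int = 500_000
    gc_fraction: float = 0.45
    n_regions: int = 200
    region_width: int = 400
    base_enrichment: float = 10.0
    fraction_group_effect: float = 0.4
    effect_fold: float = 0.25
    # motif planting: id -> (iupac, rate in affected regions, rate elsewhere)
    motif_spec: dict[str, tuple[str, float, float]] = field(
        default_factory=lambda: {
            "Gata2": ("WGATAR", 3.0, 1.0),
            "Cebpa": ("TTGCNNAA", 1.0, 1.0),
        }
    )
    # ChIP simulation
    chip_depth: int = 100_000
    fragment_len: int = 200
    chip_replicates: int = 2
    # peak calling / atlas / scoring
    extension: int = 200
    peak_fdr: float = 0.05
    null_mode: str = "poisson"
    mc_iterations: int = 200
    atlas_width: int = 400
    # differential acetylation
    p_threshold: float = 0.05
    prior_df: float = 10.0
    window: int = 101
    # motif enrichment
    bootstrap_samples: int = 1000
    z_threshold: float = 3.0
    # expression branch
    expr_replicates: int = 3
    n_probes: int = 10_000
    n_de_per_transition: int = 100
    expr_log_fc: float = 3.0  # strong planted effect: 6x the replicate noise SD
    expr_noise_sd: float = 0.5
    detection_fraction: float = 0.458
    expr_fdr: float = 0.001
    detection_threshold: float = 0.01
    n_shared_up: int = 40
    n_shared_down: int = 88

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["motif_spec"] = {k: list(v) for k, v in self.motif_spec.items()}
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "motif_spec" in raw:
            raw["motif_spec"] = {k: tuple(v) for k, v in raw["motif_spec"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute the full synthetic pipeline and return the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    config.to_yaml(outdir / "config.yaml")
    t0 = time.time()

    def stage(name: str) -> None:
        log.info("[%7.2fs] stage %s", time.time() - t0, name)

    # --- simulate -----------------------------------------------------------
    stage("simulate")
    genome = synthetic.generate_genome(
        config.n_chroms, config.length_per_chrom, config.gc_fraction,
        synthetic.derive_seed(config.seed, "genome"),
    )
    genome, planted = synthetic.plant_regions(
        genome,
        config.n_regions,
        config.region_width,
        config.motif_spec,
        config.fraction_group_effect,
        config.effect_fold,
        synthetic.derive_seed(config.seed, "plant"),
        base_enrichment=config.base_enrichment,
    )
    chip_design = synthetic.SampleDesign(
        replicates_per_condition=config.chip_replicates
    )
    tag_sets = synthetic.simulate_chip_tags(
        genome, planted, chip_design, config.chip_depth, config.fragment_len,
        synthetic.derive_seed(config.seed, "chip"),
    )
    io.write_fasta(genome, outdir / "genome.fa")
    for sid, ts in tag_sets.items():
        io.write_tags_bed(ts, outdir / f"tags_{sid}.bed")

    # --- peaks + atlas + scores --------------------------------------------
    stage("callpeaks")
    chrom_lengths = genome.lengths
    params = peaks.PeakCallParams(
        extension=config.extension,
        peak_fdr=config.peak_fdr,
        null_mode=config.null_mode,
        mc_iterations=config.mc_iterations,
        seed=synthetic.derive_seed(config.seed, "mc-null"),
    )
    per_sample_windows = {}
    for sid, ts in tag_sets.items():
        called = peaks.call_peaks(ts, params, chrom_lengths)
        io.write_peaks_bed(called, outdir / f"peaks_{sid}.bed")
        per_sample_windows[sid] = atlas_mod.summit_windows(
            called, config.atlas_width, chrom_lengths, sample_id=sid
        )

    stage("atlas")
    region_atlas = atlas_mod.build_atlas(per_sample_windows, config.atlas_width)
    io.write_atlas_bed(region_atlas, outdir / "atlas.bed")

    stage("score")
    scores = atlas_mod.score_regions(
        region_atlas, tag_sets, config.extension, chrom_lengths
    )
    io.write_score_matrix(scores, outdir / "scores")

    # --- differential acetylation ------------------------------------------
    stage("difftest")
    comparison = difftest.GroupComparison(
        chip_design.samples_in_group("A"), chip_design.samples_in_group("B")
    )
    tparams = difftest.RegTTestParams(
        prior_df=config.prior_df,
        window=config.window,
        p_threshold=config.p_threshold,
    )
    diff = difftest.differential_test(scores.rpm, comparison, tparams)
    diff.to_csv(outdir / "differential_regions.tsv", sep="\t")
    counts = difftest.class_counts(diff)

    # --- motif enrichment in the deprived / enriched sets -------------------
    stage("motif")
    motif_objs = [
        motifs.ConsensusMotif(mid, spec[0]) for mid, spec in config.motif_spec.items()
    ]
    count_table = motifs.region_count_table(region_atlas, genome, motif_objs)
    motif_results: dict[str, Any] = {}
    for label in ("deprived", "enriched"):
        ids = diff.index[diff["class"] == label].tolist()
        if not ids:
            motif_results[label] = {}
            continue
        observed = count_table.loc[ids].sum(axis=0).astype(int).to_dict()
        nulls = motifs.bootstrap_null(
            region_atlas, genome, motif_objs,
            set_size=len(ids), B=config.bootstrap_samples,
            seed=synthetic.derive_seed(config.seed, f"bootstrap-{label}"),
            count_table=count_table,
        )
        results = motifs.z_scores(observed, nulls, config.z_threshold)
        motifs.enrichment_table(results).to_csv(
            outdir / f"motif_enrichment_{label}.tsv", sep="\t"
        )
        motif_results[label] = {
            r.motif_id: {"observed": r.observed, "z": r.z_score, "call": r.call}
            for r in results
        }

    # --- expression branch ---------------------------------------------------
    stage("express")
    expr_design = synthetic.SampleDesign(
        replicates_per_condition=config.expr_replicates
    )
    matrix, expr_truth = synthetic.simulate_expression(
        expr_design,
        config.n_probes,
        config.n_de_per_transition,
        log_fc=config.expr_log_fc,
        noise_sd=config.expr_noise_sd,
        detection_fraction=config.detection_fraction,
        seed=synthetic.derive_seed(config.seed, "expression"),
        n_shared_up=config.n_shared_up,
        n_shared_down=config.n_shared_down,
    )
    io.write_expression(matrix, outdir / "expression")
    expressed = expression.detection_filter(matrix, config.detection_threshold)
    de_lists = {}
    for frm, to in synthetic.DEFAULT_TRANSITIONS:
        comp = expression.TransitionComparison(f"{frm}_vs_{to}", frm, to)
        de = expression.moderated_de(
            matrix, comp, fdr_threshold=config.expr_fdr, probes=expressed
        )
        de.to_csv(outdir / f"de_{comp.name}.tsv", sep="\t")
        de_lists[comp.name] = de
    nr = expression.nonredundant_de(de_lists)
    nr.to_csv(outdir / "nr_de.tsv", sep="\t")
    me_name = "{}_vs_{}".format(*synthetic.SHARED_TRANSITIONS[0])
    mt_name = "{}_vs_{}".format(*synthetic.SHARED_TRANSITIONS[1])
    shared_up, shared_down = expression.shared_progression_sets(
        de_lists[me_name], de_lists[mt_name]
    )

    summary = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "genome_length": genome.total_length,
        "n_planted_regions": len(planted),
        "atlas_size": len(region_atlas),
        "region_class_counts": counts,
        "motif_enrichment": motif_results,
        "n_probes": config.n_probes,
        "n_expressed_probes": len(expressed),
        "n_nonredundant_de": int(len(nr)),
        "n_shared_up": len(shared_up),
        "n_shared_down": len(shared_down),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    stage("done")
    return summary
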