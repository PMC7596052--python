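"""End-to-end orchestration: sim -> call -> chimera -> homology -> clusters
-> imaging, with a resolved-config record and a machine-readable summary.

Reruns with the same config and seed produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping

import numpy as np
import pandas as pd
import yaml

from . import chimeras as chi
from . import clusters as clu
from . import homology as hom
from . import imaging as img
from . import simulate as sim
from . import toposites as tps
from .core import (
    coverage_to_bedgraph,
    write_bed,
    write_bedgraph,
    write_bedpe,
    write_pairs_table,
)

log = logging.getLogger("etipseq")

STAGES = ("sim", "call", "chimera", "homology", "clusters", "imaging")


@dataclass
class RunConfig:
    """All stage parameters with their documented defaults."""

    sim: sim.SimSpec = field(default_factory=sim.SimSpec)
    stages: List[str] = field(default_factory=lambda: list(STAGES))
    peak_mode: str = "local-poisson"
    peak_q_threshold: float = 0.01
    evidence_map: Dict[str, str] = field(
        default_factory=lambda: dict(tps.DEFAULT_EVIDENCE_MAP)
    )
    assign_window: int = 2000
    max_homology_chimeras: int = 300
    n_control_pairs: int = 200
    cluster_thresholds: Dict[str, float] = field(
        default_factory=lambda: dict(clu.DEFAULT_THRESHOLDS)
    )
    dsp_cluster_threshold: float = clu.DEFAULT_DSP_THRESHOLD
    write_tracks: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "sim" in data:
            data["sim"] = sim.SimSpec.from_dict(data["sim"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in dependency order.

    Writes per-stage outputs and ``summary.json`` under ``outdir`` and
    returns the summary dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.resolved.yaml")
    summary: dict = {"seed": config.sim.seed}
    enabled = set(config.stages)
    missing = enabled - set(STAGES)
    if missing:
        raise ValueError(f"unknown stages: {sorted(missing)}")

    # --- sim ---------------------------------------------------------------
    if "sim" not in enabled:
        raise ValueError(
            "stage 'sim' is required: downstream stages consume its outputs"
        )
    log.info("sim: generating genome, reads, chimeras")
    genome, truth = sim.simulate_genome(config.sim)
    reads = sim.simulate_etipa_reads(config.sim, truth)
    chim_pairs = sim.simulate_chimeras(config.sim, truth)
    genome.to_fasta(outdir / "genome.fa")
    write_bed(
        truth.toposites.rename(columns={"class": "name"}),
        outdir / "truth_toposites.bed",
    )
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    truth.repeats.to_csv(outdir / "truth_repeats.tsv", sep="\t", index=False)
    for fraction, df in reads.items():
        write_pairs_table(df, outdir / f"reads_{fraction}.tsv")
    write_pairs_table(chim_pairs, outdir / "chimera_pairs.tsv")
    truth.chimeras.to_csv(outdir / "truth_chimeras.tsv", sep="\t",
                          index=False)
    summary["sim"] = {
        "genome_bp": int(sum(config.sim.chrom_lengths.values())),
        "n_toposites_planted": {
            cls: int(n) for cls, n in
            truth.toposites["class"].value_counts().sort_index().items()
        },
        "n_repeat_families": int(len(truth.repeats)),
        "n_read_pairs": {k: int(len(v)) for k, v in reads.items()},
        "n_chimera_pairs": int(len(chim_pairs)),
    }

    # --- call --------------------------------------------------------------
    sites = None
    if "call" in enabled:
        log.info("call: filtering pairs and calling peaks per fraction")
        peaks = {}
        for fraction, df in reads.items():
            kept = tps.filter_read_pairs(df)
            log.info("call: %s %d/%d pairs kept", fraction, len(kept),
                     len(df))
            cov = tps.coverage_track(
                kept, config.sim.chrom_lengths, config.sim.extension
            )
            if config.write_tracks:
                write_bedgraph(
                    coverage_to_bedgraph(cov),
                    outdir / f"coverage_{fraction}.bedgraph",
                )
            peaks[fraction] = tps.call_peaks(
                cov, mode=config.peak_mode,
                q_threshold=config.peak_q_threshold,
                extension=config.sim.extension,
            )
        sites = tps.classify_toposites(
            peaks["P1"], peaks["P2"], config.evidence_map
        )
        sites, density = tps.annotate_regions(
            sites, truth.genes, config.sim.chrom_lengths
        )
        write_bed(
            sites.rename(columns={"class": "name"}).assign(
                score=lambda d: d.q
            ),
            outdir / "toposites.bed",
        )
        density.to_csv(outdir / "region_density.tsv", sep="\t", index=False)
        summary["call"] = {
            "n_peaks": {k: int(len(v)) for k, v in peaks.items()},
            "n_toposites": {
                cls: int(n) for cls, n in
                sites["class"].value_counts().sort_index().items()
            },
            "region_density": density.round(6).to_dict("records"),
        }

    # --- chimera -----------------------------------------------------------
    chim = None
    if "chimera" in enabled:
        if sites is None:
            raise RuntimeError("stage 'chimera' needs outputs of 'call'")
        log.info("chimera: loading and annotating chimera pairs")
        chim = chi.load_chimeras(chim_pairs)
        chim = chi.assign_ends(chim, sites, window=config.assign_window)
        combo = chi.combination_stats(chim)
        orient = chi.orientation_table(chim)
        write_bedpe(
            chim.assign(
                chrom1=chim.chrom, start1=chim.ustart, end1=chim.uend,
                chrom2=chim.chrom, start2=chim.dstart, end2=chim.dend,
                name=".", score=0,
                strand1=chim.ustrand, strand2=chim.dstrand,
            ),
            outdir / "chimeras.bedpe",
        )
        combo.to_csv(outdir / "combination_stats.tsv", sep="\t", index=False)
        orient.to_csv(outdir / "orientation_table.tsv", sep="\t", index=False)
        span_counts = chim.span_class.value_counts()
        summary["chimera"] = {
            "n_loaded": int(len(chim)),
            "n_inter_chromosomal": int(
                chim.attrs.get("n_inter_chromosomal", 0)
            ),
            "n_by_span_class": {
                k: int(span_counts.get(k, 0)) for k in chi.SPAN_CLASSES
            },
            "n_assigned": int((chim.combo != "unassigned").sum()),
            "combination_stats": json.loads(
                combo.round(6).to_json(orient="records")
            ),
            "orientation_table": json.loads(
                orient.round(6).to_json(orient="records")
            ),
        }

    # --- homology ----------------------------------------------------------
    if "homology" in enabled:
        if chim is None:
            raise RuntimeError("stage 'homology' needs outputs of 'chimera'")
        log.info("homology: scoring DSP end windows")
        dsp = chim[
            (chim.span_class == "DSP")
            & chim.combo.isin(["Ts2-Ts2", "Ts3-Ts3"])
        ]
        dsp = dsp.sort_values(
            ["chrom", "ustart", "dstart"], kind="stable"
        ).head(config.max_homology_chimeras)
        calls = hom.homology_table(dsp, genome)
        calls.to_csv(outdir / "homology_calls.tsv", sep="\t", index=False)
        conc = hom.concordance(calls)
        controls = hom.control_chimeras(
            genome, n=config.n_control_pairs, seed=config.sim.seed + 7
        )
        ctrl_scores = hom.control_scores(controls)
        from scipy import stats as _st

        mw = _st.mannwhitneyu(
            calls.max_score, ctrl_scores, alternative="greater"
        )
        summary["homology"] = {
            "n_scored": int(len(calls)),
            "verdicts": {
                k: int(v) for k, v in
                calls.verdict.value_counts().sort_index().items()
            },
            "concordance": round(conc["concordance"], 6),
            "fisher_p": conc["fisher_p"],
            "control_median_score": float(np.median(ctrl_scores)),
            "dsp_median_score": float(calls.max_score.median()),
            "mannwhitney_p_dsp_gt_control": float(mw.pvalue),
        }

    # --- clusters ----------------------------------------------------------
    if "clusters" in enabled:
        if sites is None or chim is None:
            raise RuntimeError(
                "stage 'clusters' needs outputs of 'call' and 'chimera'"
            )
        log.info("clusters: density maps, clusters, hotspots")
        tcl = clu.toposite_clusters(
            sites, config.sim.chrom_lengths, config.cluster_thresholds
        )
        dcl = clu.dsp_clusters(
            chim, config.sim.chrom_lengths, config.dsp_cluster_threshold
        )
        hot = clu.define_hotspots(tcl, dcl)
        write_bed(tcl.rename(columns={"class": "name"}),
                  outdir / "toposite_clusters.bed")
        write_bed(dcl.rename(columns={"class": "name"}),
                  outdir / "dsp_clusters.bed")
        write_bed(hot.rename(columns={"class": "name"}),
                  outdir / "hotspots.bed")
        summary["clusters"] = {
            "n_toposite_clusters": {
                cls: int((tcl["class"] == cls).sum())
                for cls in config.cluster_thresholds
            },
            "n_dsp_clusters": {
                cls: int((dcl["class"] == f"DSP-{cls}").sum())
                for cls in ("Ts2", "Ts3")
            },
            "n_hotspots": {
                cls: int((hot["class"] == cls).sum())
                for cls in ("Ts2", "Ts3")
            },
        }

    # --- imaging -----------------------------------------------------------
    if "imaging" in enabled:
        log.info("imaging: synthetic nuclei and condensation analysis")
        stacks, ntruth = sim.simulate_nuclei(config.sim)
        ntruth.to_csv(outdir / "truth_nuclei.tsv", sep="\t", index=False)
        result = img.analyze_conditions(
            stacks, voxel_size=config.sim.nuclei.voxel_size
        )
        rows = []
        for cond in stacks:
            for i, (fr, vol) in enumerate(zip(
                result["condensed_fraction"][cond],
                result["volume_um3"][cond],
            )):
                rows.append((cond, i, fr, vol))
        pd.DataFrame(
            rows,
            columns=["condition", "nucleus", "condensed_fraction",
                     "volume_um3"],
        ).to_csv(outdir / "nuclei_measurements.tsv", sep="\t", index=False)
        conds = list(stacks)
        tests = {}
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                key = f"{conds[i]}_vs_{conds[j]}"
                tests[key] = img.compare_groups(
                    result["condensed_fraction"][conds[i]],
                    result["condensed_fraction"][conds[j]],
                )["p"]
        summary["imaging"] = {
            "isosbestic_point": int(result["isosbestic"]),
            "median_condensed_fraction": {
                c: float(np.median(result["condensed_fraction"][c]))
                for c in conds
            },
            "median_volume_um3": {
                c: float(np.median(result["volume_um3"][c])) for c in conds
            },
            "mannwhitney_p": tests,
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True,
                  default=_json_default)
        fh.write("\n")
    return summary
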