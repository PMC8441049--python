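"""End-to-end orchestration: simulate -> normalize -> metrics -> screens.

One TOML config drives every stage; per-module threshold sections mirror
the threshold dataclasses and default to the published filter values.
Every output table records the seed, and a run report counts candidates
in and out of each filter stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import antisense as anti
from . import metrics, readthrough, spikenorm
from .coverage import StrandedCoverage
from .genome import GenomeAnnotation
from .simulate import (
    SimulationConfig,
    simulate_all_replicates,
    simulate_dataset,
    write_fixture,
)

log = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    outdir: str = "crypterm_out"
    seed: int = 0
    normalization_mode: str = "spike_with_input"
    log_level: str = "INFO"
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    readthrough_thresholds: readthrough.ReadthroughThresholds = field(
        default_factory=readthrough.ReadthroughThresholds
    )
    discovery_thresholds: anti.DiscoveryThresholds = field(
        default_factory=anti.DiscoveryThresholds
    )
    tr_window: int = metrics.DEFAULT_TR_WINDOW
    metagene_flank: int = metrics.DEFAULT_FLANK
    metagene_bin: int = metrics.DEFAULT_BIN
    metagene_trim: int = metrics.DEFAULT_TRIM

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def _build(klass, section):
            known = {f.name for f in dataclasses.fields(klass)}
            bad = set(section) - known
            if bad:
                raise PipelineConfigError(f"unknown keys for {klass.__name__}: {bad}")
            try:
                return klass(**section)
            except ValueError as exc:
                raise PipelineConfigError(str(exc)) from exc

        cfg = cls(
            outdir=raw.get("outdir", "crypterm_out"),
            seed=int(raw.get("seed", 0)),
            normalization_mode=raw.get("normalization_mode", "spike_with_input"),
            log_level=raw.get("log_level", "INFO"),
            simulate=_build(SimulationConfig, raw.get("simulate", {})),
            readthrough_thresholds=_build(
                readthrough.ReadthroughThresholds, raw.get("readthrough", {})
            ),
            discovery_thresholds=_build(
                anti.DiscoveryThresholds, raw.get("antisense", {})
            ),
        )
        for key in ("tr_window", "metagene_flank", "metagene_bin", "metagene_trim"):
            if key in raw.get("metrics", {}):
                setattr(cfg, key, int(raw["metrics"][key]))
        cfg.simulate.seed = cfg.seed
        if cfg.normalization_mode not in spikenorm.MODES:
            raise PipelineConfigError(
                f"unknown normalization mode {cfg.normalization_mode!r}"
            )
        return cfg


def discover_antisense_transcripts(
    annot: GenomeAnnotation,
    wt_reps: list[StrandedCoverage],
    mut_reps: list[StrandedCoverage],
    factors: dict[str, spikenorm.NormalizationFactors] | None = None,
    thresholds: anti.DiscoveryThresholds = anti.DiscoveryThresholds(),
) -> tuple[list[anti.NovelTranscript], dict[str, int]]:
    """Full novel-transcript chain; returns transcripts + stage counts."""
    stages: dict[str, int] = {}
    per_cond = {}
    for cond, reps in (("WT", wt_reps), ("mutant", mut_reps)):
        assembled = [anti.assemble_segments(c, thresholds) for c in reps]
        stages[f"assembled_{cond}"] = sum(len(a) for a in assembled)
        repro = assembled[0]
        for other in assembled[1:]:
            repro = anti.reproducible_segments(repro, other)
        per_cond[cond] = repro
        stages[f"reproducible_{cond}"] = len(repro)
    combined = anti.merge_strata(per_cond["WT"], per_cond["mutant"],
                                 thresholds.merge_gap)
    stages["combined"] = len(combined)
    candidates = anti.discover_novel(combined, annot, thresholds)
    stages["after_overlap_length_filters"] = len(candidates)
    selected = anti.quantify_and_select(candidates, wt_reps, mut_reps, factors,
                                        thresholds)
    stages["selected"] = len(selected)
    selected = [anti.classify_origin(nt, annot, thresholds) for nt in selected]
    return selected, stages


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on a simulated dataset; write tables + report."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    stage = "simulate"
    try:
        annot, truth = simulate_dataset(config.simulate)
        covs = simulate_all_replicates(annot, truth, config.simulate)
        write_fixture(annot, truth, covs["WT"] + covs["mutant"],
                      outdir / "fixture")
        report["stages"]["simulate"] = {
            "n_tus": len(annot),
            "truth_readthrough": int(truth.tus.readthrough.sum()),
            "truth_antisense": int((truth.segments.kind == "antisense").sum()),
        }

        stage = "normalize"
        factors = {
            c.sample_id: spikenorm.compute_scale_factor(
                c.species_counts, config.normalization_mode
            )
            for c in covs["WT"] + covs["mutant"]
        }
        pd.DataFrame(
            [{"sample_id": k, "scale": v.scale, "mode": v.mode,
              "mixing_ratio": v.mixing_ratio} for k, v in factors.items()]
        ).to_csv(outdir / "normalization_factors.tsv", sep="\t", index=False)

        stage = "traveling_ratio"
        tr_tables = {}
        for cond in ("WT", "mutant"):
            cov = spikenorm.normalize_coverage(
                covs[cond][0], factors[covs[cond][0].sample_id]
            )
            tr_tables[cond] = metrics.traveling_ratio_table(
                cov, annot, window=config.tr_window
            )
            tr_tables[cond].to_csv(outdir / f"traveling_ratio_{cond}.tsv", sep="\t")
        usable = ~tr_tables["WT"].excluded_short
        report["stages"]["traveling_ratio"] = {
            "n_scored": int(usable.sum()),
            "median_wt": float(tr_tables["WT"].tr[usable].median()),
            "median_mutant": float(tr_tables["mutant"].tr[usable].median()),
        }

        stage = "readthrough"
        rt_table, called = readthrough.screen_readthrough(
            annot, covs["WT"], covs["mutant"], config.readthrough_thresholds
        )
        rt_table.to_csv(outdir / "readthrough.tsv", sep="\t")
        conv = int((rt_table.orientation[rt_table.verdict] == "convergent").sum()) \
            if not rt_table.empty else 0
        report["stages"]["readthrough"] = {
            "eligible": int(len(rt_table)),
            "called": len(called),
            "called_convergent": conv,
        }

        stage = "antisense"
        novel, disc_stages = discover_antisense_transcripts(
            annot, covs["WT"], covs["mutant"], factors,
            config.discovery_thresholds,
        )
        linkage = anti.link_readthrough_antisense(
            novel, called, annot, window=config.discovery_thresholds.origin_window
        )
        anti.novel_to_bed6(novel, outdir / "novel_transcripts.bed6")
        anti.novel_to_frame(novel).to_csv(
            outdir / "novel_transcripts.tsv", sep="\t", index=False
        )
        linkage.to_csv(outdir / "readthrough_linkage.tsv", sep="\t", index=False)
        nonoverlap = annot.select_tus("nonoverlapping")
        screen = anti.antisense_count_screen(
            annot, nonoverlap, covs["WT"], covs["mutant"], factors,
            min_fc=config.discovery_thresholds.min_fc,
        )
        screen.to_csv(outdir / "antisense_screen.tsv", sep="\t")
        report["stages"]["antisense"] = {
            **disc_stages,
            "terminator_proximal": sum(
                nt.origin == "terminator_proximal" for nt in novel
            ),
            "linked_to_readthrough": linkage.attrs["n_linked"],
            "nonoverlapping_tus": len(nonoverlap),
            "screen_up": int(screen.up.sum()) if len(screen) else 0,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
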