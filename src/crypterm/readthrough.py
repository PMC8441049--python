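"""3' read-through caller.

For each TU that has no other same-strand gene within 250 bp, read density
is measured in 250-bp windows immediately upstream and downstream of the
PAS (TU sense), averaged over biological replicates per condition.  The
mutant/WT downstream ratio is corrected for expression changes by the
matching upstream ratio:

    R = ((mu_down_mut + eps) / (mu_down_wt + eps))
      / ((mu_up_mut + eps) / (mu_up_wt + eps))

A TU is called read-through when all four published filters pass:
R > 2 (1.5 relaxed), normalized SD of the mutant downstream densities
(coefficient of variation) < 0.6, WT upstream >= 10 read-equivalents, and
mutant downstream >= 5 read-equivalents.  The count filters use raw
(un-pseudocounted) means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageError, StrandedCoverage
from .genome import GenomeAnnotation, TranscriptionUnit

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadthroughThresholds:
    window: int = 250
    min_ratio: float = 2.0  # 1.5 for the relaxed screen
    max_norm_sd: float = 0.6
    min_wt_upstream: float = 10.0  # read-equivalents
    min_mut_downstream: float = 5.0
    pseudocount: float = 1.0  # read-equivalents, ratio denominators only
    # which condition's downstream CV the norm-SD filter targets
    cv_target: str = "mutant"  # or "both" (max of the two CVs)

    def __post_init__(self):
        for name in ("window", "min_ratio", "max_norm_sd",
                     "min_wt_upstream", "min_mut_downstream", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cv_target not in ("mutant", "both"):
            raise ValueError("cv_target must be 'mutant' or 'both'")


@dataclass(frozen=True)
class ReadthroughStats:
    tu_id: str
    up_wt: tuple[float, ...]
    up_mut: tuple[float, ...]
    down_wt: tuple[float, ...]
    down_mut: tuple[float, ...]
    mu_up_wt: float
    mu_up_mut: float
    mu_down_wt: float
    mu_down_mut: float
    sd_down_wt: float
    sd_down_mut: float
    norm_sd: float
    ratio: float
    pass_ratio: bool
    pass_norm_sd: bool
    pass_wt_upstream: bool
    pass_mut_downstream: bool
    verdict: bool


def _pas_windows(tu: TranscriptionUnit, window: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """(upstream, downstream) genomic windows around the PAS, TU sense."""
    if tu.strand == "+":
        return (tu.pas - window, tu.pas), (tu.pas, tu.pas + window)
    return (tu.pas, tu.pas + window), (tu.pas - window, tu.pas)


def _window_reads(
    reps: list[StrandedCoverage], tu: TranscriptionUnit, window: tuple[int, int]
) -> tuple[float, ...]:
    out = []
    for c in reps:
        try:
            out.append(
                c.window_stat(tu.chrom, window[0], window[1], tu.strand,
                              "read_equivalents")
            )
        except CoverageError:  # window entirely beyond the chromosome end
            log.warning("window %s outside chromosome for %s; counted as 0",
                        window, tu.id)
            out.append(0.0)
    return tuple(out)


def readthrough_stats(
    tu: TranscriptionUnit,
    wt_reps: list[StrandedCoverage],
    mut_reps: list[StrandedCoverage],
    thresholds: ReadthroughThresholds = ReadthroughThresholds(),
) -> ReadthroughStats:
    """Window statistics, corrected ratio and filter verdict for one TU."""
    if len(wt_reps) < 2 or len(mut_reps) < 2:
        raise ValueError("need >= 2 replicates per condition")
    up_win, down_win = _pas_windows(tu, thresholds.window)
    up_wt = _window_reads(wt_reps, tu, up_win)
    up_mut = _window_reads(mut_reps, tu, up_win)
    down_wt = _window_reads(wt_reps, tu, down_win)
    down_mut = _window_reads(mut_reps, tu, down_win)

    mu_up_wt, mu_up_mut = float(np.mean(up_wt)), float(np.mean(up_mut))
    mu_down_wt, mu_down_mut = float(np.mean(down_wt)), float(np.mean(down_mut))
    sd_down_wt = float(np.std(down_wt, ddof=1))
    sd_down_mut = float(np.std(down_mut, ddof=1))

    cv_mut = sd_down_mut / mu_down_mut if mu_down_mut > 0 else np.inf
    if thresholds.cv_target == "mutant":
        norm_sd = cv_mut
    else:
        cv_wt = sd_down_wt / mu_down_wt if mu_down_wt > 0 else np.inf
        norm_sd = max(cv_mut, cv_wt)

    eps = thresholds.pseudocount
    ratio = ((mu_down_mut + eps) / (mu_down_wt + eps)) / (
        (mu_up_mut + eps) / (mu_up_wt + eps)
    )

    pass_ratio = ratio > thresholds.min_ratio
    pass_norm_sd = norm_sd < thresholds.max_norm_sd
    pass_wt_upstream = mu_up_wt >= thresholds.min_wt_upstream
    pass_mut_downstream = mu_down_mut >= thresholds.min_mut_downstream
    return ReadthroughStats(
        tu_id=tu.id,
        up_wt=up_wt, up_mut=up_mut, down_wt=down_wt, down_mut=down_mut,
        mu_up_wt=mu_up_wt, mu_up_mut=mu_up_mut,
        mu_down_wt=mu_down_wt, mu_down_mut=mu_down_mut,
        sd_down_wt=sd_down_wt, sd_down_mut=sd_down_mut,
        norm_sd=norm_sd, ratio=ratio,
        pass_ratio=pass_ratio, pass_norm_sd=pass_norm_sd,
        pass_wt_upstream=pass_wt_upstream,
        pass_mut_downstream=pass_mut_downstream,
        verdict=pass_ratio and pass_norm_sd and pass_wt_upstream
        and pass_mut_downstream,
    )


def screen_readthrough(
    annot: GenomeAnnotation,
    wt_reps: list[StrandedCoverage],
    mut_reps: list[StrandedCoverage],
    thresholds: ReadthroughThresholds = ReadthroughThresholds(),
) -> tuple[pd.DataFrame, set[str]]:
    """Genome-wide read-through screen.

    Applies the same-strand isolation filter (flank = PAS window), scores
    every surviving TU, and returns the full statistics table (with the
    TU's convergent/tandem/... orientation) plus the called id set.
    """
    eligible = annot.select_tus("isolated_same_strand", flank=thresholds.window)
    rows = []
    for tu in annot.tus:
        if tu.id not in eligible:
            continue
        st = readthrough_stats(tu, wt_reps, mut_reps, thresholds)
        rec = st.__dict__.copy()
        rec["orientation"] = annot.classify_orientation(tu.id)
        rows.append(rec)
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.set_index("tu_id")
        called = set(table.index[table.verdict])
    else:
        called = set()
    log.info("read-through screen: %d eligible, %d called", len(rows), len(called))
    return table, called
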