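"""RNAPII occupancy metrics: traveling ratio, metagene matrices, group tests.

The *traveling ratio* summarizes how far polymerase travels into a gene
body: log2 of 5'-window over 3'-window occupancy.  A shift of the
traveling-ratio distribution toward higher values indicates impaired
elongation (polymerase enriched near the promoter relative to the
terminator).  Metagene matrices align TUs at the TSS with fixed flanks for
heatmap-style output; scaled metagenes stretch each gene body onto a
common 0-1 axis.  Group comparisons use the Mann-Whitney U test for
independent gene sets and the Wilcoxon signed-rank test for matched sets,
with Bonferroni correction across the comparison family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import StrandedCoverage
from .genome import GenomeAnnotation, TranscriptionUnit

DEFAULT_TR_WINDOW = 200
DEFAULT_TR_PSEUDOCOUNT = 1.0  # read-equivalents per window
DEFAULT_FLANK = 500
DEFAULT_BIN = 10
DEFAULT_TRIM = 4500
DEFAULT_COMPARE_WINDOW = 150  # centered on the site


@dataclass(frozen=True)
class TravelingRatioEntry:
    tu_id: str
    occ5: float
    occ3: float
    tr: float
    excluded_short: bool = False


@dataclass
class MetageneMatrix:
    """TU-by-bin signal matrix aligned at the TSS (rows sorted by length)."""

    values: np.ndarray  # (n_tus, n_bins), NaN where undefined
    tu_ids: list[str]
    flank: int
    bin: int
    trim: int

    def column_median(self) -> np.ndarray:
        return np.nanmedian(self.values, axis=0)

    def column_quartiles(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.nanpercentile(self.values, 25, axis=0),
            np.nanpercentile(self.values, 75, axis=0),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.tu_ids)


@dataclass(frozen=True)
class GroupCompareResult:
    group_a_size: int
    group_b_size: int
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float
    n_comparisons: int


def traveling_ratio(
    cov: StrandedCoverage,
    tu: TranscriptionUnit,
    window: int = DEFAULT_TR_WINDOW,
    pseudocount: float = DEFAULT_TR_PSEUDOCOUNT,
) -> TravelingRatioEntry:
    """tr = log2((occ5 + eps) / (occ3 + eps)) for one TU.

    occ5 is the read-equivalent sum over the first ``window`` bp after the
    TSS, occ3 over the last ``window`` bp before the PAS, both in TU-sense
    orientation.  TUs shorter than two windows are flagged, not scored.
    """
    if tu.length < 2 * window:
        return TravelingRatioEntry(tu.id, np.nan, np.nan, np.nan, excluded_short=True)
    if tu.strand == "+":
        w5 = (tu.start, tu.start + window)
        w3 = (tu.end - window, tu.end)
    else:
        w5 = (tu.end - window, tu.end)
        w3 = (tu.start, tu.start + window)
    occ5 = cov.window_stat(tu.chrom, *w5, tu.strand, "read_equivalents")
    occ3 = cov.window_stat(tu.chrom, *w3, tu.strand, "read_equivalents")
    tr = float(np.log2((occ5 + pseudocount) / (occ3 + pseudocount)))
    return TravelingRatioEntry(tu.id, occ5, occ3, tr)


def traveling_ratio_table(
    cov: StrandedCoverage,
    annot: GenomeAnnotation,
    window: int = DEFAULT_TR_WINDOW,
    pseudocount: float = DEFAULT_TR_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Batch traveling ratios; short TUs carry ``excluded_short=True``."""
    rows = [
        traveling_ratio(cov, tu, window=window, pseudocount=pseudocount)
        for tu in annot.tus
    ]
    return pd.DataFrame(rows).set_index("tu_id")


def _sense_window_values(
    cov: StrandedCoverage, tu: TranscriptionUnit, start: int, end: int
) -> np.ndarray:
    """Per-base values over a genomic window, NaN outside the chromosome,
    returned 5'->3' of the TU."""
    length = cov.chrom_sizes[tu.chrom]
    out = np.full(end - start, np.nan)
    cs, ce = max(0, start), min(length, end)
    if cs < ce:
        out[cs - start:ce - start] = cov.vector(tu.chrom, tu.strand)[cs:ce]
    if tu.strand == "-":
        out = out[::-1]
    return out


def metagene_matrix(
    cov: StrandedCoverage,
    annot: GenomeAnnotation,
    tu_ids: list[str] | None = None,
    flank: int = DEFAULT_FLANK,
    bin: int = DEFAULT_BIN,
    trim: int = DEFAULT_TRIM,
) -> MetageneMatrix:
    """TSS-aligned binned matrix over [TSS-flank, min(PAS, TSS+trim)+flank).

    Rows are sorted by TU length (longest first) and padded with NaN past
    each TU's span; bodies longer than ``trim`` are truncated there.
    """
    if flank <= 0 or bin <= 0 or trim <= 0:
        raise ValueError("flank, bin and trim must be positive")
    tus = annot.tus if tu_ids is None else [annot[i] for i in tu_ids]
    if not tus:
        raise ValueError("empty TU set")
    tus = sorted(tus, key=lambda t: (-t.length, t.id))
    spans = [flank + min(t.length, trim) + flank for t in tus]
    nbins = int(np.ceil(max(spans) / bin))
    values = np.full((len(tus), nbins), np.nan)
    for i, (tu, span) in enumerate(zip(tus, spans)):
        if tu.strand == "+":
            g0 = tu.start - flank
            row = _sense_window_values(cov, tu, g0, g0 + span)
        else:
            g1 = tu.end + flank
            row = _sense_window_values(cov, tu, g1 - span, g1)
        edges = np.arange(0, span, bin)
        counts = np.add.reduceat((~np.isnan(row)).astype(float), edges)
        with np.errstate(invalid="ignore"):
            binned = np.add.reduceat(np.nan_to_num(row), edges) / counts
        binned[counts == 0] = np.nan  # bin entirely off-chromosome
        values[i, :binned.size] = binned
    return MetageneMatrix(values, [t.id for t in tus], flank, bin, trim)


def scaled_metagene(
    cov: StrandedCoverage,
    annot: GenomeAnnotation,
    tu_ids: list[str] | None = None,
    nbins: int = 100,
) -> pd.DataFrame:
    """Per-TU gene-body signal min-max scaled to [0, 1] on ``nbins`` bins.

    Each body is first scaled x' = (x - min) / (max - min), then length-
    normalized to ``nbins`` points by linear interpolation.  Constant rows
    map to all-zeros by convention.
    """
    if nbins < 2:
        raise ValueError("nbins must be >= 2")
    tus = annot.tus if tu_ids is None else [annot[i] for i in tu_ids]
    rows = np.zeros((len(tus), nbins))
    for i, tu in enumerate(tus):
        body = _sense_window_values(cov, tu, tu.start, tu.end)
        lo, hi = np.nanmin(body), np.nanmax(body)
        if hi > lo:
            scaled = (body - lo) / (hi - lo)
            x = np.linspace(0, body.size - 1, nbins)
            rows[i] = np.interp(x, np.arange(body.size), scaled)
    return pd.DataFrame(rows, index=[t.id for t in tus])


def group_window_compare(
    per_tu_stat: dict[str, float],
    group_a: set[str],
    group_b: set[str],
    paired: bool = False,
    n_comparisons: int = 1,
) -> GroupCompareResult:
    """Rank test between two gene sets on a per-TU statistic.

    Independent sets use the two-sided Mann-Whitney U test; matched sets
    (``paired=True``, equal sizes, matching by shared sorted order of ids)
    use the Wilcoxon signed-rank test.  The adjusted p-value is
    min(1, p * n_comparisons) (Bonferroni).
    """
    a = np.array([per_tu_stat[i] for i in sorted(group_a)])
    b = np.array([per_tu_stat[i] for i in sorted(group_b)])
    if min(a.size, b.size) < 3:
        raise ValueError("group size < 3")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal group sizes")
        diffs = a - b
        if np.all(diffs == 0):
            stat, p = 0.0, 1.0  # degenerate: identical matched samples
        else:
            stat, p = stats.wilcoxon(a, b, alternative="two-sided")
        test = "signed_rank_paired"
    else:
        if group_a & group_b:
            raise ValueError("independent groups must be disjoint")
        if np.all(a == a[0]) and np.all(b == a[0]):
            stat, p = a.size * b.size / 2.0, 1.0  # all-tie degenerate case
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "rank_sum_independent"
    return GroupCompareResult(
        group_a_size=a.size,
        group_b_size=b.size,
        test=test,
        statistic=float(stat),
        p_raw=float(p),
        p_adjusted=min(1.0, float(p) * n_comparisons),
        n_comparisons=n_comparisons,
    )


def sample_control_group(
    annot: GenomeAnnotation,
    size: int,
    rng: np.random.Generator,
    exclude: set[str] = frozenset(),
) -> set[str]:
    """Random control gene set (e.g. 2x the test set, as in screens that
    compare a gene group against twice as many random genes)."""
    pool = [t.id for t in annot.tus if t.id not in exclude]
    if size > len(pool):
        raise ValueError("not enough TUs outside the excluded set")
    return set(rng.choice(pool, size=size, replace=False))


def site_window_stat(
    cov: StrandedCoverage,
    tu: TranscriptionUnit,
    site: str = "PAS",
    width: int = DEFAULT_COMPARE_WINDOW,
    antisense: bool = False,
) -> float:
    """Read-equivalents in a ``width``-nt window centered on the TSS or PAS,
    on the TU's own strand (or the opposite one with ``antisense=True``)."""
    if site not in ("TSS", "PAS"):
        raise ValueError("site must be 'TSS' or 'PAS'")
    center = tu.tss if site == "TSS" else tu.pas
    strand = tu.strand
    if antisense:
        strand = "-" if strand == "+" else "+"
    return cov.window_stat(
        tu.chrom, center - width // 2, center + width - width // 2, strand,
        "read_equivalents",
    )
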