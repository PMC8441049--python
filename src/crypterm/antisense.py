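"""Novel-transcript assembly, filtering, origin classification and screens.

Transcribed segments are assembled directly from stranded coverage as
maximal runs of per-base signal, merging runs separated by at most 5 nt.
Candidates are kept only when reproducible in both replicates, when they
fail a 10% reciprocal-overlap test against every same-strand annotated TU,
and when 50 bp <= length <= 5 kb.  Selected novel transcripts must exceed
1 FPKM in the mutant and a 1.5-fold change over WT.  Each is classified by
where its predicted TSS falls: within +/-300 nt of an annotated PAS
(terminator_proximal), else within +/-300 nt of an opposite-strand TSS
(promoter_proximal), else other.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .coverage import StrandedCoverage
from .genome import GenomeAnnotation
from .spikenorm import NormalizationFactors


@dataclass(frozen=True, order=True)
class Segment:
    """A stranded interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty segment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Predicted TSS: the segment's 5' end on its own strand."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class DiscoveryThresholds:
    min_cov: float = 1.0  # per-base units
    merge_gap: int = 5  # nt
    min_len: int = 50  # bp, inclusive
    max_len: int = 5000  # bp, inclusive
    reciprocal_frac: float = 0.10
    min_fpkm: float = 1.0
    min_fc: float = 1.5
    origin_window: int = 300  # nt
    fc_pseudocount: float = 0.1  # FPKM units

    def __post_init__(self):
        for name in ("min_cov", "merge_gap", "min_len", "max_len",
                     "reciprocal_frac", "min_fpkm", "min_fc",
                     "origin_window", "fc_pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be < max_len")


@dataclass(frozen=True)
class NovelTranscript:
    segment: Segment
    fpkm_wt: float = np.nan
    fpkm_mut: float = np.nan
    fold_change: float = np.nan
    origin: str = "unclassified"
    dist_to_pas: int | None = None
    dist_to_opposite_tss: int | None = None
    opposite_overlap: bool = False
    convergent_locus: bool = False
    linked_readthrough_tu: str | None = None

    @property
    def tss(self) -> int:
        return self.segment.tss


# ---------------------------------------------------------------- assembly


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    """Merge sorted runs whose separation is <= gap."""
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def assemble_segments(
    cov: StrandedCoverage, thresholds: DiscoveryThresholds = DiscoveryThresholds()
) -> list[Segment]:
    """Maximal covered runs per strand, merged across gaps <= merge_gap."""
    out: list[Segment] = []
    for (chrom, strand), vec in sorted(cov.data.items()):
        mask = np.concatenate(([False], vec >= thresholds.min_cov, [False]))
        edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
        runs = list(zip(edges[0::2], edges[1::2]))
        for s, e in _merge_runs(runs, thresholds.merge_gap):
            out.append(Segment(chrom, int(s), int(e), strand))
    return sorted(out)


def reproducible_segments(
    rep1: list[Segment], rep2: list[Segment]
) -> list[Segment]:
    """Same-strand overlapping portions of the two replicate segment sets,
    merged (overlap/adjacency) within each strand."""
    out: list[Segment] = []
    keys = {(s.chrom, s.strand) for s in rep1} & {(s.chrom, s.strand) for s in rep2}
    for chrom, strand in sorted(keys):
        a = sorted((s.start, s.end) for s in rep1
                   if (s.chrom, s.strand) == (chrom, strand))
        b = sorted((s.start, s.end) for s in rep2
                   if (s.chrom, s.strand) == (chrom, strand))
        i = j = 0
        pieces: list[tuple[int, int]] = []
        while i < len(a) and j < len(b):
            s = max(a[i][0], b[j][0])
            e = min(a[i][1], b[j][1])
            if s < e:
                pieces.append((s, e))
            if a[i][1] <= b[j][1]:
                i += 1
            else:
                j += 1
        for s, e in _merge_runs(sorted(pieces), 0):
            out.append(Segment(chrom, s, e, strand))
    return sorted(out)


def merge_strata(
    wt_segments: list[Segment],
    mut_segments: list[Segment],
    merge_gap: int = DiscoveryThresholds().merge_gap,
) -> list[Segment]:
    """Union of the two segment lists, sorted and merged per strand
    (gap <= merge_gap)."""
    out: list[Segment] = []
    pool = list(wt_segments) + list(mut_segments)
    keys = sorted({(s.chrom, s.strand) for s in pool})
    for chrom, strand in keys:
        runs = sorted((s.start, s.end) for s in pool
                      if (s.chrom, s.strand) == (chrom, strand))
        for s, e in _merge_runs(runs, merge_gap):
            out.append(Segment(chrom, s, e, strand))
    return sorted(out)


# --------------------------------------------------------------- filtering


def discover_novel(
    segments: list[Segment],
    annot: GenomeAnnotation,
    thresholds: DiscoveryThresholds = DiscoveryThresholds(),
) -> list[NovelTranscript]:
    """Reciprocal-overlap and length filters.

    A segment is discarded when some same-strand annotated TU overlaps it
    by at least ``reciprocal_frac`` of *both* lengths, or when its length
    falls outside [min_len, max_len].
    """
    f = thresholds.reciprocal_frac
    kept: list[NovelTranscript] = []
    for seg in segments:
        if not thresholds.min_len <= seg.length <= thresholds.max_len:
            continue
        idx = annot.chrom_arrays(seg.chrom)
        same = idx["plus"] == (seg.strand == "+")
        ov = np.minimum(idx["end"], seg.end) - np.maximum(idx["start"], seg.start)
        ov = np.where(same, np.maximum(ov, 0), 0)
        glen = idx["end"] - idx["start"]
        if np.any((ov >= f * seg.length) & (ov >= f * glen)):
            continue
        kept.append(NovelTranscript(segment=seg))
    return kept


def quantify_and_select(
    candidates: list[NovelTranscript],
    wt_reps: list[StrandedCoverage],
    mut_reps: list[StrandedCoverage],
    factors: dict[str, NormalizationFactors] | None = None,
    thresholds: DiscoveryThresholds = DiscoveryThresholds(),
) -> list[NovelTranscript]:
    """Abundance (FPKM) and fold-change selection.

    FPKM uses the sample's primary-species library size; when per-sample
    normalization factors are supplied, the effective library is the
    spike-equivalent size 1e6 / alpha instead.  Per-condition FPKM is the
    replicate mean; keep when fpkm_mut > min_fpkm and
    (fpkm_mut + eps) / (fpkm_wt + eps) > min_fc.
    """

    def _lib(cov: StrandedCoverage) -> float:
        if factors is not None and cov.sample_id in factors:
            return 1e6 / factors[cov.sample_id].scale
        return cov.species_counts.primary_reads

    def _fpkm(cov: StrandedCoverage, seg: Segment) -> float:
        re = cov.window_stat(seg.chrom, seg.start, seg.end, seg.strand,
                             "read_equivalents")
        return re * 1e9 / (seg.length * _lib(cov))

    eps = thresholds.fc_pseudocount
    selected: list[NovelTranscript] = []
    for nt in candidates:
        fw = float(np.mean([_fpkm(c, nt.segment) for c in wt_reps]))
        fm = float(np.mean([_fpkm(c, nt.segment) for c in mut_reps]))
        fc = (fm + eps) / (fw + eps)
        if fm > thresholds.min_fpkm and fc > thresholds.min_fc:
            selected.append(replace(nt, fpkm_wt=fw, fpkm_mut=fm, fold_change=fc))
    return selected


def classify_origin(
    nt: NovelTranscript,
    annot: GenomeAnnotation,
    thresholds: DiscoveryThresholds = DiscoveryThresholds(),
) -> NovelTranscript:
    """Assign terminator/promoter origin and convergence context.

    terminator_proximal: predicted TSS within +/-origin_window of any PAS
    (either strand); else promoter_proximal if within the window of an
    opposite-strand TSS; else other.  PAS alignment takes precedence.
    """
    seg = nt.segment
    w = thresholds.origin_window
    d_pas = annot.nearest_feature_distance(
        seg.tss, seg.chrom, "PAS", "any", seg.strand
    )
    d_tss = annot.nearest_feature_distance(
        seg.tss, seg.chrom, "TSS", "opposite", seg.strand
    )
    if d_pas is not None and abs(d_pas) <= w:
        origin = "terminator_proximal"
    elif d_tss is not None and abs(d_tss) <= w:
        origin = "promoter_proximal"
    else:
        origin = "other"
    idx = annot.chrom_arrays(seg.chrom)
    opp = idx["plus"] == (seg.strand == "-")
    ov = np.minimum(idx["end"], seg.end) - np.maximum(idx["start"], seg.start)
    hits = np.flatnonzero(opp & (ov > 0))
    opposite_overlap = hits.size > 0
    convergent = any(
        annot.classify_orientation(idx["ids"][h]) == "convergent" for h in hits
    )
    return replace(
        nt,
        origin=origin,
        dist_to_pas=d_pas,
        dist_to_opposite_tss=d_tss,
        opposite_overlap=opposite_overlap,
        convergent_locus=convergent,
    )


# ----------------------------------------------------------------- screens


def antisense_count_screen(
    annot: GenomeAnnotation,
    tu_ids: set[str],
    wt_reps: list[StrandedCoverage],
    mut_reps: list[StrandedCoverage],
    factors: dict[str, NormalizationFactors] | None = None,
    min_fc: float = 1.5,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-TU antisense read screen over non-overlapping TUs.

    Counts opposite-strand read-equivalents within each TU interval per
    sample, scales by the sample's normalization factor, and reports the
    log2 mutant/WT fold change with up/down flags at ``min_fc``.  The
    strain-level medians of log2(normalized counts + pseudocount) are
    attached as ``DataFrame.attrs['median_log2_normalized']``.
    """

    def _alpha(cov: StrandedCoverage) -> float:
        if factors is not None and cov.sample_id in factors:
            return factors[cov.sample_id].scale
        return 1.0

    rows = []
    per_sample: dict[str, list[float]] = {}
    for tu_id in sorted(tu_ids):
        tu = annot[tu_id]
        anti = "-" if tu.strand == "+" else "+"
        vals = {}
        for cov in list(wt_reps) + list(mut_reps):
            v = cov.window_stat(tu.chrom, tu.start, tu.end, anti,
                                "read_equivalents") * _alpha(cov)
            vals[cov.sample_id] = v
            per_sample.setdefault(cov.sample_id, []).append(v)
        wt_mean = float(np.mean([vals[c.sample_id] for c in wt_reps]))
        mut_mean = float(np.mean([vals[c.sample_id] for c in mut_reps]))
        log2fc = float(np.log2((mut_mean + pseudocount) / (wt_mean + pseudocount)))
        rows.append({
            "tu_id": tu_id,
            **{f"as_{k}": v for k, v in vals.items()},
            "as_wt_mean": wt_mean,
            "as_mut_mean": mut_mean,
            "log2_fc": log2fc,
            "up": log2fc > np.log2(min_fc),
            "down": log2fc < -np.log2(min_fc),
        })
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.set_index("tu_id")
    table.attrs["median_log2_normalized"] = {
        sid: float(np.median(np.log2(np.asarray(v) + pseudocount)))
        for sid, v in per_sample.items()
    }
    return table


def link_readthrough_antisense(
    novel: list[NovelTranscript],
    readthrough_calls: set[str],
    annot: GenomeAnnotation,
    window: int = 300,
) -> pd.DataFrame:
    """Link novel transcripts to called read-through genes.

    A transcript links to TU g when g is on the transcript's strand, g's
    PAS lies 5' of the predicted TSS within ``window`` bp, and g was
    called read-through — i.e. the transcript plausibly continues g's
    uncontrolled 3' extension rather than initiating de novo.
    """
    rows = []
    for nt in novel:
        seg = nt.segment
        linked = None
        best = None
        for tu in annot.tus:
            if tu.chrom != seg.chrom or tu.strand != seg.strand:
                continue
            if tu.id not in readthrough_calls:
                continue
            d = (seg.tss - tu.pas) if seg.strand == "+" else (tu.pas - seg.tss)
            if 0 <= d <= window and (best is None or d < best):
                best, linked = d, tu.id
        rows.append({
            "chrom": seg.chrom, "start": seg.start, "end": seg.end,
            "strand": seg.strand, "tss": seg.tss,
            "linked_readthrough_tu": linked,
        })
    df = pd.DataFrame(rows)
    df.attrs["n_linked"] = int(df["linked_readthrough_tu"].notna().sum()) if len(df) else 0
    df.attrs["n_unlinked"] = len(df) - df.attrs["n_linked"]
    return df


def novel_to_bed6(novel: list[NovelTranscript], path) -> None:
    """Selected novel transcripts as BED6 (name = origin class)."""
    with open(path, "w") as fh:
        for i, nt in enumerate(novel, 1):
            s = nt.segment
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\tnovel_{i}_{nt.origin}\t0\t{s.strand}\n"
            )


def novel_to_frame(novel: list[NovelTranscript]) -> pd.DataFrame:
    rows = []
    for nt in novel:
        s = nt.segment
        rows.append({
            "chrom": s.chrom, "start": s.start, "end": s.end, "strand": s.strand,
            "length": s.length, "tss": s.tss,
            "fpkm_wt": nt.fpkm_wt, "fpkm_mut": nt.fpkm_mut,
            "fold_change": nt.fold_change, "origin": nt.origin,
            "dist_to_pas": nt.dist_to_pas,
            "dist_to_opposite_tss": nt.dist_to_opposite_tss,
            "opposite_overlap": nt.opposite_overlap,
            "convergent_locus": nt.convergent_locus,
            "linked_readthrough_tu": nt.linked_readthrough_tu,
        })
    return pd.DataFrame(rows)
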