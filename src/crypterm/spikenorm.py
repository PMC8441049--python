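"""Dual-species spike-in scaling and log2 ratio tracks.

Samples are sequenced from a mixture of the primary species with a fixed
proportion of spike-in cells from a second species.  Because enrichment
(IP) distorts the primary:spike read balance in proportion to true
occupancy, the spike read count is an internal yardstick: scaling by it
makes absolute occupancy comparable between samples.  Sequencing the
non-enriched input of the same mixture measures the realized cell mixing
ratio ``m = input_spike / input_primary`` and corrects for pipetting
variation (ChIP-Rx-style with input correction):

    spike_with_input:  alpha = 1e6 * m / spike_reads
    spike_only:        alpha = 1e6 / spike_reads
    library_size:      alpha = 1e6 / primary_reads

The 1e6 constant puts tracks on a per-million scale; it cancels in every
ratio downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import SpeciesCounts, StrandedCoverage

MODES = ("spike_with_input", "spike_only", "library_size")

DEFAULT_RATIO_PSEUDOCOUNT = 0.1


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-sample scale factor alpha, with the mixing ratio that produced it."""

    scale: float
    mode: str
    mixing_ratio: float | None = None

    def __post_init__(self):
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise NormalizationError(f"scale must be finite and > 0, got {self.scale}")
        if self.mode not in MODES:
            raise NormalizationError(f"unknown mode {self.mode!r}")
        if (self.mixing_ratio is not None) != (self.mode == "spike_with_input"):
            raise NormalizationError(
                "mixing_ratio present iff mode is spike_with_input"
            )


def compute_scale_factor(counts: SpeciesCounts, mode: str) -> NormalizationFactors:
    """Spike-in (optionally input-corrected) or library-size scale factor."""
    if mode not in MODES:
        raise NormalizationError(f"unknown mode {mode!r}")
    if mode == "library_size":
        return NormalizationFactors(scale=1e6 / counts.primary_reads, mode=mode)
    if counts.spike_reads <= 0:
        raise NormalizationError("spike normalization requested with zero spike reads")
    if mode == "spike_only":
        return NormalizationFactors(scale=1e6 / counts.spike_reads, mode=mode)
    if not counts.input_primary_reads or counts.input_spike_reads is None:
        raise NormalizationError("spike_with_input requires input read totals")
    if counts.input_spike_reads <= 0:
        raise NormalizationError("spike_with_input requires input spike reads > 0")
    m = counts.input_spike_reads / counts.input_primary_reads
    return NormalizationFactors(
        scale=1e6 * m / counts.spike_reads, mode=mode, mixing_ratio=m
    )


def normalize_coverage(
    cov: StrandedCoverage, factors: NormalizationFactors
) -> StrandedCoverage:
    """Multiply every per-base value by the sample's scale factor."""
    return cov.scaled(factors.scale, mode=factors.mode)


def log2_ratio_track(
    cov_a: StrandedCoverage,
    cov_b: StrandedCoverage,
    bin: int = 10,
    pseudocount: float = DEFAULT_RATIO_PSEUDOCOUNT,
) -> dict[tuple[str, str], np.ndarray]:
    """Per-bin log2((mean_a + eps) / (mean_b + eps)) for two samples.

    Both samples should already be normalized to a common scale.  Bins are
    anchored at position 0 of each chromosome; the union of strands
    present in either sample is reported.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if cov_a.chrom_sizes != cov_b.chrom_sizes:
        raise NormalizationError("mismatched chromosome sets")
    def _genomic_bins(cov: StrandedCoverage, chrom: str, strand: str) -> np.ndarray:
        vec = cov.vector(chrom, strand)
        edges = np.arange(0, vec.size, bin)
        widths = np.minimum(edges + bin, vec.size) - edges
        return np.add.reduceat(vec, edges) / widths

    out: dict[tuple[str, str], np.ndarray] = {}
    for key in sorted(set(cov_a.data) | set(cov_b.data)):
        chrom, strand = key
        a = _genomic_bins(cov_a, chrom, strand)
        b = _genomic_bins(cov_b, chrom, strand)
        out[key] = np.log2((a + pseudocount) / (b + pseudocount))
    return out


def write_ratio_track(track: dict, chrom_sizes: dict[str, int], bin: int, path) -> None:
    """Emit a binned log2-ratio track as bedGraph (genomic coordinates)."""
    with open(path, "w") as fh:
        for (chrom, strand), vals in track.items():
            for i, v in enumerate(vals):
                s = i * bin
                e = min(s + bin, chrom_sizes[chrom])
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
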