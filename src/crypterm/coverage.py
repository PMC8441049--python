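"""Strand-specific per-base signal with bedGraph I/O and window statistics.

Coverage (not read alignments) is the unit of exchange: each sample is a
pair of bedGraph files, one per strand, expanded to dense per-base vectors.
Read-count filters elsewhere in the pipeline operate on *read equivalents*,
defined as coverage sum divided by the read length (default 50 bp).
Minus-strand values are stored non-negative; strandedness is carried by the
file/vector, not by the sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

DEFAULT_READ_LENGTH = 50

SAMPLE_TSV_COLUMNS = [
    "sample_id", "condition", "replicate", "plus_path", "minus_path",
    "primary_reads", "spike_reads", "input_primary_reads",
    "input_spike_reads", "read_length",
]


class CoverageError(ValueError):
    """Malformed coverage input or out-of-range window."""


@dataclass(frozen=True)
class SpeciesCounts:
    """Primary- and spike-species read totals for one sample.

    ``input_*`` totals come from sequencing the (non-enriched) input of the
    same cell mixture and estimate the spike:primary mixing ratio.
    """

    primary_reads: int
    spike_reads: int = 0
    input_primary_reads: int | None = None
    input_spike_reads: int | None = None

    def __post_init__(self):
        if self.primary_reads <= 0:
            raise ValueError("primary_reads must be > 0")
        if self.spike_reads < 0:
            raise ValueError("spike_reads must be >= 0")


class StrandedCoverage:
    """Per-base, per-strand signal for one sample.

    ``data`` maps ``(chrom, strand)`` to a nonnegative float vector of the
    chromosome's length.  Missing (chrom, strand) keys are treated as
    all-zero on access.
    """

    def __init__(
        self,
        chrom_sizes: dict[str, int],
        data: dict[tuple[str, str], np.ndarray] | None = None,
        sample_id: str = "sample",
        condition: str = "other",
        replicate: int = 1,
        read_length: int = DEFAULT_READ_LENGTH,
        species_counts: SpeciesCounts | None = None,
        scale_applied: float | None = None,
        norm_mode: str | None = None,
    ):
        self.chrom_sizes = dict(chrom_sizes)
        self.data: dict[tuple[str, str], np.ndarray] = {}
        for key, vec in (data or {}).items():
            chrom, strand = key
            vec = np.asarray(vec, dtype=np.float64)
            if chrom not in self.chrom_sizes:
                raise CoverageError(f"unknown chromosome {chrom!r}")
            if vec.shape != (self.chrom_sizes[chrom],):
                raise CoverageError(
                    f"{chrom} {strand}: vector length {vec.size} != "
                    f"chromosome length {self.chrom_sizes[chrom]}"
                )
            if not np.all(np.isfinite(vec)) or (vec < 0).any():
                raise CoverageError(f"{chrom} {strand}: values must be finite and >= 0")
            self.data[key] = vec
        self.sample_id = sample_id
        self.condition = condition
        self.replicate = int(replicate)
        self.read_length = int(read_length)
        self.species_counts = species_counts
        self.scale_applied = scale_applied
        self.norm_mode = norm_mode

    def vector(self, chrom: str, strand: str) -> np.ndarray:
        """Per-base vector, materializing zeros for untouched strands."""
        if chrom not in self.chrom_sizes:
            raise CoverageError(f"unknown chromosome {chrom!r}")
        key = (chrom, strand)
        if key not in self.data:
            self.data[key] = np.zeros(self.chrom_sizes[chrom])
        return self.data[key]

    def scaled(self, factor: float, mode: str | None = None) -> "StrandedCoverage":
        """A copy with every per-base value multiplied by ``factor``."""
        return StrandedCoverage(
            self.chrom_sizes,
            {k: v * factor for k, v in self.data.items()},
            sample_id=self.sample_id,
            condition=self.condition,
            replicate=self.replicate,
            read_length=self.read_length,
            species_counts=self.species_counts,
            scale_applied=factor if self.scale_applied is None
            else self.scale_applied * factor,
            norm_mode=mode or self.norm_mode,
        )

    # -------------------------------------------------------------- stats

    def _clip_window(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        if start >= end:
            raise CoverageError(f"empty window [{start}, {end})")
        length = self.chrom_sizes[chrom]
        cs, ce = max(0, start), min(length, end)
        if cs >= ce:
            raise CoverageError(
                f"window [{start}, {end}) entirely outside {chrom} (length {length})"
            )
        if (cs, ce) != (start, end):
            log.warning(
                "window [%d, %d) clipped to [%d, %d) on %s",
                start, end, cs, ce, chrom,
            )
        return cs, ce

    def window_stat(
        self, chrom: str, start: int, end: int, strand: str, stat: str = "sum"
    ) -> float:
        """Sum, mean, or read-equivalents of per-base signal in a window.

        Windows partially off-chromosome are clipped (with a warning);
        fully off-chromosome windows raise.
        """
        cs, ce = self._clip_window(chrom, start, end)
        vec = self.vector(chrom, strand)
        total = float(vec[cs:ce].sum())
        if stat == "sum":
            return total
        if stat == "mean":
            return total / (ce - cs)
        if stat == "read_equivalents":
            return total / self.read_length
        raise ValueError(f"unknown stat {stat!r}")

    def bin_signal(
        self, chrom: str, start: int, end: int, strand: str, bin: int = 10
    ) -> np.ndarray:
        """Binned means over a window, reported 5'->3' of ``strand``.

        Bins are anchored at the 5' end; a final partial bin is averaged
        over its actual width.
        """
        if bin < 1:
            raise ValueError("bin must be >= 1")
        cs, ce = self._clip_window(chrom, start, end)
        vec = self.vector(chrom, strand)[cs:ce]
        if strand == "-":
            vec = vec[::-1]
        n = vec.size
        edges = np.arange(0, n, bin)
        sums = np.add.reduceat(vec, edges)
        widths = np.minimum(edges + bin, n) - edges
        return sums / widths

    def fpkm(
        self, chrom: str, start: int, end: int, strand: str, library_reads: int
    ) -> float:
        """Fragments per kb of segment per million library reads.

        FPKM = read_equivalents * 1e9 / (segment_length * library_reads).
        """
        if library_reads <= 0:
            raise ValueError("library_reads must be > 0")
        if end <= start:
            raise CoverageError("zero-length segment")
        re = self.window_stat(chrom, start, end, strand, "read_equivalents")
        return re * 1e9 / ((end - start) * library_reads)

    # ---------------------------------------------------------------- I/O

    def save_bedgraph(self, plus_path, minus_path) -> None:
        """Write one 4-column bedGraph per strand (zero runs omitted)."""
        import pandas as pd

        for strand, path in (("+", plus_path), ("-", minus_path)):
            with open(path, "w") as fh:
                for chrom in self.chrom_sizes:
                    key = (chrom, strand)
                    if key not in self.data:
                        continue
                    vec = self.data[key]
                    change = np.flatnonzero(np.diff(vec)) + 1
                    starts = np.concatenate(([0], change))
                    ends = np.concatenate((change, [vec.size]))
                    vals = vec[starts]
                    keep = vals != 0
                    if not keep.any():
                        continue
                    pd.DataFrame({
                        "chrom": chrom,
                        "start": starts[keep],
                        "end": ends[keep],
                        "value": vals[keep],
                    }).to_csv(fh, sep="\t", header=False, index=False,
                              float_format="%.17g")


def _expand_bedgraph(path, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Dense per-base expansion of a 4-column bedGraph (one strand)."""
    records: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise CoverageError(f"{path}:{lineno}: expected 4 columns")
            chrom = parts[0]
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise CoverageError(f"{path}:{lineno}: bad record {line!r}") from None
            if chrom not in chrom_sizes:
                raise CoverageError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not 0 <= start < end <= chrom_sizes[chrom]:
                raise CoverageError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside {chrom}"
                )
            if value < 0:
                raise CoverageError(f"{path}:{lineno}: negative value {value}")
            records.setdefault(chrom, []).append((start, end, value))
    out: dict[str, np.ndarray] = {}
    for chrom, recs in records.items():
        recs.sort()
        starts = np.array([r[0] for r in recs], dtype=np.int64)
        ends = np.array([r[1] for r in recs], dtype=np.int64)
        vals = np.array([r[2] for r in recs])
        if (starts[1:] < ends[:-1]).any():
            raise CoverageError(f"{path}: overlapping records on {chrom}")
        # interleave zero gaps with records, then expand by run length
        gap_lens = starts - np.concatenate(([0], ends[:-1]))
        lens = np.empty(2 * len(recs) + 1, dtype=np.int64)
        values = np.zeros(2 * len(recs) + 1)
        lens[0::2][:-1] = gap_lens
        lens[1::2] = ends - starts
        lens[-1] = chrom_sizes[chrom] - ends[-1]
        values[1::2] = vals
        out[chrom] = np.repeat(values, lens)
    return out


def load_stranded_coverage(
    plus_path,
    minus_path,
    chrom_sizes: dict[str, int],
    sample_id: str = "sample",
    condition: str = "other",
    replicate: int = 1,
    read_length: int = DEFAULT_READ_LENGTH,
    species_counts: SpeciesCounts | None = None,
) -> StrandedCoverage:
    """Load a plus/minus bedGraph pair into a :class:`StrandedCoverage`."""
    data: dict[tuple[str, str], np.ndarray] = {}
    for strand, path in (("+", plus_path), ("-", minus_path)):
        for chrom, vec in _expand_bedgraph(path, chrom_sizes).items():
            data[(chrom, strand)] = vec
    return StrandedCoverage(
        chrom_sizes, data,
        sample_id=sample_id, condition=condition, replicate=replicate,
        read_length=read_length, species_counts=species_counts,
    )


def load_samples_tsv(path, chrom_sizes: dict[str, int]) -> list[StrandedCoverage]:
    """Load every sample listed in a metadata TSV (columns as documented)."""
    import pandas as pd

    meta = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_TSV_COLUMNS) - set(meta.columns)
    if missing:
        raise CoverageError(f"{path}: missing columns {sorted(missing)}")
    covs = []
    for _, row in meta.iterrows():
        counts = SpeciesCounts(
            primary_reads=int(row.primary_reads),
            spike_reads=int(row.spike_reads),
            input_primary_reads=None if pd.isna(row.input_primary_reads)
            else int(row.input_primary_reads),
            input_spike_reads=None if pd.isna(row.input_spike_reads)
            else int(row.input_spike_reads),
        )
        covs.append(
            load_stranded_coverage(
                row.plus_path, row.minus_path, chrom_sizes,
                sample_id=row.sample_id, condition=row.condition,
                replicate=int(row.replicate), read_length=int(row.read_length),
                species_counts=counts,
            )
        )
    return covs
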