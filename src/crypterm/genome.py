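"""Annotation data model and interval queries.

Transcription units (TUs) are stranded genomic intervals held in 0-based
half-open coordinates throughout the package.  GFF3 input (1-based closed)
is converted at the parsing boundary; BED6 is taken as-is.  A TU's TSS and
PAS are derived from its interval boundaries:

* ``+`` strand: TSS = start, PAS = end
* ``-`` strand: TSS = end, PAS = start

Minus-strand sites are the half-open boundaries themselves (not boundary-1)
so that window arithmetic is symmetric between strands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STRANDS = ("+", "-")
BIOTYPES = ("coding", "noncoding", "multicistronic")

#: default horizon (bp) when deciding whether a TU has a neighbor at all
DEFAULT_NEIGHBOR_HORIZON = 1000


class AnnotationError(ValueError):
    """Malformed annotation input or invariant violation."""


@dataclass(frozen=True)
class TranscriptionUnit:
    """A stranded transcribed interval (0-based half-open)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "coding"
    score: str = "0"  # carried through BED6 round-trips

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise AnnotationError(f"TU {self.id}: bad strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise AnnotationError(
                f"TU {self.id}: invalid interval [{self.start}, {self.end})"
            )
        if self.biotype not in BIOTYPES:
            raise AnnotationError(f"TU {self.id}: bad biotype {self.biotype!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def pas(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeAnnotation:
    """A set of TUs plus chromosome sizes, with per-chromosome indexes."""

    def __init__(self, chrom_sizes: dict[str, int], tus: list[TranscriptionUnit]):
        self.chrom_sizes = dict(chrom_sizes)
        self.tus = list(tus)
        self._by_id: dict[str, TranscriptionUnit] = {}
        for tu in self.tus:
            if tu.id in self._by_id:
                raise AnnotationError(f"duplicate TU id {tu.id!r}")
            if tu.chrom not in self.chrom_sizes:
                raise AnnotationError(f"TU {tu.id}: unknown chromosome {tu.chrom!r}")
            if tu.end > self.chrom_sizes[tu.chrom]:
                raise AnnotationError(
                    f"TU {tu.id}: end {tu.end} exceeds length of {tu.chrom}"
                )
            self._by_id[tu.id] = tu
        # per-chromosome coordinate arrays for vectorized queries
        self._index: dict[str, dict[str, np.ndarray]] = {}
        for chrom in self.chrom_sizes:
            sub = [t for t in self.tus if t.chrom == chrom]
            self._index[chrom] = {
                "ids": np.array([t.id for t in sub], dtype=object),
                "start": np.array([t.start for t in sub], dtype=np.int64),
                "end": np.array([t.end for t in sub], dtype=np.int64),
                "plus": np.array([t.strand == "+" for t in sub], dtype=bool),
            }

    def __len__(self) -> int:
        return len(self.tus)

    def __contains__(self, tu_id: str) -> bool:
        return tu_id in self._by_id

    def __getitem__(self, tu_id: str) -> TranscriptionUnit:
        try:
            return self._by_id[tu_id]
        except KeyError:
            raise KeyError(f"no TU with id {tu_id!r}") from None

    def chrom_arrays(self, chrom: str) -> dict[str, np.ndarray]:
        return self._index[chrom]

    # ------------------------------------------------------------------ I/O

    def to_bed6(self, path) -> None:
        with open(path, "w") as fh:
            for tu in self.tus:
                fh.write(
                    f"{tu.chrom}\t{tu.start}\t{tu.end}\t{tu.id}\t{tu.score}\t{tu.strand}\n"
                )

    # ------------------------------------------------------------- queries

    def classify_orientation(
        self, tu_id: str, horizon: int = DEFAULT_NEIGHBOR_HORIZON
    ) -> str:
        """Label a TU convergent / tandem / divergent / isolated.

        The label comes from the nearest TU interval lying 3' of (or
        overlapping) this TU's PAS: opposite strand means the pair faces
        each other (convergent), same strand means tandem.  If nothing lies
        within ``horizon`` bp on the 3' side, the 5' side of the TSS is
        inspected symmetrically (opposite strand there = divergent).  With
        no neighbor within the horizon on either side the TU is isolated.
        """
        tu = self[tu_id]
        idx = self._index[tu.chrom]
        other = idx["ids"] != tu.id
        starts, ends, plus = idx["start"][other], idx["end"][other], idx["plus"][other]
        if starts.size == 0:
            return "isolated"
        sense_plus = tu.strand == "+"

        def _side(anchor: int, downstream: bool):
            """gap and strand of nearest interval beyond/overlapping anchor."""
            if downstream == sense_plus:  # rightward along the genome
                mask = ends > anchor
                gaps = np.maximum(0, starts - anchor)
            else:  # leftward
                mask = starts < anchor
                gaps = np.maximum(0, anchor - ends)
            if not mask.any():
                return None
            gaps = np.where(mask, gaps, np.iinfo(np.int64).max)
            j = int(np.argmin(gaps))
            return int(gaps[j]), bool(plus[j])

        hit = _side(tu.pas, downstream=True)
        if hit is not None and hit[0] <= horizon:
            return "tandem" if hit[1] == sense_plus else "convergent"
        hit = _side(tu.tss, downstream=False)
        if hit is not None and hit[0] <= horizon:
            return "tandem" if hit[1] == sense_plus else "divergent"
        return "isolated"

    def select_tus(self, mode: str, flank: int = 250) -> set[str]:
        """Select TU ids by neighborhood criteria.

        ``isolated_same_strand`` keeps TUs with no other same-strand TU
        intersecting [start-flank, end+flank); ``nonoverlapping`` keeps TUs
        whose interval overlaps no other TU on either strand.
        """
        if flank < 0:
            raise ValueError("flank must be >= 0")
        if mode not in ("isolated_same_strand", "nonoverlapping"):
            raise ValueError(f"unknown selection mode {mode!r}")
        keep: set[str] = set()
        for chrom, idx in self._index.items():
            n = idx["ids"].size
            for i in range(n):
                s, e = idx["start"][i], idx["end"][i]
                if mode == "isolated_same_strand":
                    same = idx["plus"] == idx["plus"][i]
                    same[i] = False
                    clash = (
                        (idx["start"] < e + flank) & (idx["end"] > s - flank) & same
                    ).any()
                else:
                    othr = np.ones(n, dtype=bool)
                    othr[i] = False
                    clash = ((idx["start"] < e) & (idx["end"] > s) & othr).any()
                if not clash:
                    keep.add(idx["ids"][i])
        return keep

    def feature_positions(
        self, chrom: str, feature: str, strand: str | None = None
    ) -> np.ndarray:
        """All TSS or PAS coordinates on a chromosome, optionally per strand."""
        if feature not in ("TSS", "PAS"):
            raise ValueError("feature must be 'TSS' or 'PAS'")
        idx = self._index[chrom]
        plus = idx["plus"]
        if feature == "TSS":
            pos = np.where(plus, idx["start"], idx["end"])
        else:
            pos = np.where(plus, idx["end"], idx["start"])
        if strand is not None:
            pos = pos[plus if strand == "+" else ~plus]
        return pos

    def nearest_feature_distance(
        self,
        pos: int,
        chrom: str,
        feature: str,
        strand_mode: str = "any",
        query_strand: str = "+",
    ) -> int | None:
        """Signed distance to the nearest TSS/PAS under a strand filter.

        Positive means downstream of ``pos`` in the sense of
        ``query_strand``; ``None`` when the chromosome carries no
        qualifying feature.  Ties in |distance| resolve downstream.
        """
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if strand_mode == "any":
            feats = self.feature_positions(chrom, feature)
        elif strand_mode == "same":
            feats = self.feature_positions(chrom, feature, query_strand)
        elif strand_mode == "opposite":
            opp = "-" if query_strand == "+" else "+"
            feats = self.feature_positions(chrom, feature, opp)
        else:
            raise ValueError(f"unknown strand_mode {strand_mode!r}")
        if feats.size == 0:
            return None
        signed = (feats - pos) if query_strand == "+" else (pos - feats)
        order = np.lexsort((-signed, np.abs(signed)))  # nearest, downstream on tie
        return int(signed[order[0]])


# ------------------------------------------------------------------- parsing


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise AnnotationError(f"{path}:{lineno}: expected 2 columns")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer length {parts[1]!r}"
                ) from None
    return sizes


def read_annotation(
    path, fmt: str, chrom_sizes: dict[str, int] | None = None
) -> GenomeAnnotation:
    """Read a BED6 or GFF3 annotation into a :class:`GenomeAnnotation`.

    GFF3 records (1-based closed) are converted to internal 0-based
    half-open coordinates; BED6 is already in the internal convention.
    When ``chrom_sizes`` is omitted, sizes are taken as the maximum end
    coordinate seen per chromosome.
    """
    if fmt not in ("bed6", "gff3"):
        raise ValueError(f"unknown annotation format {fmt!r}")
    tus: list[TranscriptionUnit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if fmt == "bed6":
                    if len(parts) < 6:
                        raise ValueError("expected 6 columns")
                    chrom, start, end, name, score, strand = parts[:6]
                    start, end = int(start), int(end)
                else:
                    if len(parts) < 9:
                        raise ValueError("expected 9 columns")
                    chrom, _, _, start, end, score, strand = parts[:7]
                    start, end = int(start) - 1, int(end)  # 1-based closed -> half-open
                    attrs = dict(
                        kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                    )
                    name = attrs.get("ID", f"feature_{lineno}")
                tu = TranscriptionUnit(
                    id=name, chrom=chrom, start=start, end=end, strand=strand,
                    score=score,
                )
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from None
            tus.append(tu)
    if chrom_sizes is None:
        chrom_sizes = {}
        for tu in tus:
            chrom_sizes[tu.chrom] = max(chrom_sizes.get(tu.chrom, 0), tu.end)
    return GenomeAnnotation(chrom_sizes, tus)
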