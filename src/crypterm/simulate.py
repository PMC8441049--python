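"""Ground-truth-labelled synthetic genomes and stranded coverage.

The generator emulates the statistical structure the analysis assumes:

* a small multi-chromosome genome packed with TUs, a configurable fraction
  of which are laid out as convergent pairs (3' ends facing);
* sense coverage proportional to a log-normal expression level, with a
  multiplicative per-kb 5'->3' decay in the mutant (elongation defect);
* a small exponential read-through tail past every PAS in both conditions
  (baseline termination leakage), amplified ``readthrough_effect``-fold in
  the mutant at truth-flagged TUs;
* terminator-initiated antisense segments on the strand opposite selected
  TUs, expressed in the mutant only, plus decoy segments that must fail
  the discovery filters (too weak, or equally expressed in WT);
* negative-binomial per-base counting noise with shared dispersion, and a
  per-sample sequencing-depth factor;
* spike-in read totals under a controllable spike:primary mixing ratio
  with per-sample jitter, plus matched input totals measuring that ratio.

Everything is deterministic per (seed, condition, replicate).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import SpeciesCounts, StrandedCoverage
from .genome import GenomeAnnotation, TranscriptionUnit

CONDITIONS = ("WT", "mutant")


class SimulationError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    # genome layout
    n_chroms: int = 5
    chrom_length: int = 120_000
    n_genes: int = 200
    fraction_convergent_pairs: float = 0.25
    gene_length_median: float = 1500.0
    gene_length_sigma: float = 0.35  # log-normal sigma (natural log)
    gap_min: int = 600
    gap_max: int = 1500
    pair_gap_min: int = 100  # PAS-to-PAS gap inside a convergent pair
    pair_gap_max: int = 300
    # expression
    expression_median: float = 20.0  # mean read depth per base
    expression_sigma: float = 0.4
    expression_scale: float = 1.0  # global occupancy multiplier
    # mutant elongation defect: per-kb multiplicative decay in (0, 1]
    elongation_decay_mutant: float = 0.85
    # read-through
    baseline_readthrough_frac: float = 0.05  # tail start / gene-end level, both conditions
    readthrough_effect: float = 4.0  # extra factor at flagged TUs, mutant only
    readthrough_n: int = 20
    readthrough_min_expression: float = 15.0
    tail_mean: float = 500.0  # bp, exponential decay length
    tail_max: int = 1500  # bp, tail painted no further than this
    # antisense
    antisense_n: int = 15
    antisense_offset_max: int = 100  # |segment TSS - target PAS|
    antisense_len_min: int = 300
    antisense_len_max: int = 2000
    antisense_depth: float = 10.0  # per-base, mutant only
    decoy_equal_n: int = 5  # same depth in both conditions (fold change ~1)
    decoy_equal_depth: float = 8.0
    decoy_low_n: int = 5  # weak, mutant only (below discovery abundance)
    decoy_low_depth: float = 0.5
    antisense_clearance: int = 300  # bp free of other features around a segment
    # noise / sequencing
    n_replicates: int = 2
    dispersion: float = 0.1  # NB phi; 0 -> Poisson
    noise_model: str = "nb"  # nb | none
    depth_jitter_sigma: float = 0.15  # log-normal sigma of per-sample depth
    read_length: int = 50
    library_reads: int = 20_000_000  # primary-species library size
    # spike-in
    mixing_ratio: float = 0.1  # spike cells : primary cells
    mixing_jitter_sigma: float = 0.05
    spike_material: float = 2e6  # spike read yield per unit mixing ratio
    input_depth: int = 1_000_000  # input library primary reads
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.fraction_convergent_pairs <= 1:
            raise SimulationError("fraction_convergent_pairs must be in [0, 1]")
        for name in ("readthrough_n", "antisense_n", "decoy_equal_n", "decoy_low_n"):
            if getattr(self, name) < 0 or getattr(self, name) > self.n_genes:
                raise SimulationError(f"{name} must be in [0, n_genes]")
        if not 0 < self.elongation_decay_mutant <= 1:
            raise SimulationError("elongation_decay_mutant must be in (0, 1]")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        if self.noise_model not in ("nb", "none"):
            raise SimulationError(f"unknown noise_model {self.noise_model!r}")
        if self.gap_min > self.gap_max or self.pair_gap_min > self.pair_gap_max:
            raise SimulationError("gap bounds inverted")
        if self.n_genes > 0 and self.gene_length_median + self.gap_min > self.chrom_length:
            raise SimulationError("genes do not fit the chromosome")


@dataclass
class TruthSet:
    """Per-TU ground truth plus the injected opposite-strand segments."""

    tus: pd.DataFrame  # tu_id, orientation, expression, readthrough, ...
    segments: pd.DataFrame  # kind, target_tu, chrom, start, end, strand, depth, tss

    def readthrough_ids(self) -> set[str]:
        return set(self.tus.index[self.tus.readthrough])

    def antisense_target_ids(self) -> set[str]:
        return set(self.segments.target_tu[self.segments.kind == "antisense"])


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *key]))


# ------------------------------------------------------------------ layout


def _place_genes(config: SimulationConfig, rng: np.random.Generator):
    """Pack genes chromosome by chromosome; convergent pairs share a unit."""
    tus: list[TranscriptionUnit] = []
    gid = 0
    remaining = config.n_genes
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = int(rng.integers(config.gap_min, config.gap_max + 1))
        while remaining > 0:
            pair = (
                remaining >= 2
                and rng.random() < config.fraction_convergent_pairs
            )
            lens = np.maximum(
                50,
                np.round(
                    config.gene_length_median
                    * np.exp(rng.normal(0, config.gene_length_sigma, 2 if pair else 1))
                ).astype(int),
            )
            if pair:
                pg = int(rng.integers(config.pair_gap_min, config.pair_gap_max + 1))
                span = int(lens[0] + pg + lens[1])
            else:
                span = int(lens[0])
            if cursor + span > config.chrom_length:
                break  # next chromosome
            if pair:
                gid += 1
                tus.append(TranscriptionUnit(
                    f"g{gid}", chrom, cursor, cursor + int(lens[0]), "+"))
                gid += 1
                b0 = cursor + int(lens[0]) + pg
                tus.append(TranscriptionUnit(
                    f"g{gid}", chrom, b0, b0 + int(lens[1]), "-"))
                remaining -= 2
            else:
                gid += 1
                strand = "+" if rng.random() < 0.5 else "-"
                tus.append(TranscriptionUnit(
                    f"g{gid}", chrom, cursor, cursor + span, strand))
                remaining -= 1
            cursor += span + int(rng.integers(config.gap_min, config.gap_max + 1))
        if remaining == 0:
            break
    if remaining > 0:
        raise SimulationError(
            f"could not place {config.n_genes} genes on "
            f"{config.n_chroms} x {config.chrom_length} bp"
        )
    return tus


def _strand_occupied(
    annot: GenomeAnnotation, truth_rt: set[str], config: SimulationConfig
) -> dict[tuple[str, str], list[tuple[int, int]]]:
    """Intervals per (chrom, strand) where sense signal may appear:
    TU bodies plus tail extents (every TU leaks a baseline tail)."""
    occ: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for tu in annot.tus:
        if tu.strand == "+":
            iv = (tu.start, min(tu.end + config.tail_max, annot.chrom_sizes[tu.chrom]))
        else:
            iv = (max(0, tu.start - config.tail_max), tu.end)
        occ.setdefault((tu.chrom, tu.strand), []).append(iv)
    return occ


def simulate_dataset(config: SimulationConfig) -> tuple[GenomeAnnotation, TruthSet]:
    """Generate an annotation and its ground-truth labels (deterministic)."""
    config.validate()
    rng = _rng(config, 0)
    chrom_sizes = {f"chr{i + 1}": config.chrom_length
                   for i in range(config.n_chroms)}
    if config.n_genes == 0:
        annot = GenomeAnnotation(chrom_sizes, [])
        empty_tus = pd.DataFrame(
            columns=["orientation", "expression", "readthrough",
                     "tail_mean", "tail_frac", "antisense_target"]
        )
        empty_tus.index.name = "tu_id"
        segs = pd.DataFrame(columns=["kind", "target_tu", "chrom", "start",
                                     "end", "strand", "depth", "tss"])
        return annot, TruthSet(empty_tus, segs)

    tus = _place_genes(config, rng)
    annot = GenomeAnnotation(chrom_sizes, tus)

    expr = config.expression_median * np.exp(
        rng.normal(0, config.expression_sigma, len(tus))
    )
    expression = {tu.id: float(e) for tu, e in zip(tus, expr)}
    orientation = {tu.id: annot.classify_orientation(tu.id) for tu in tus}

    # --- read-through truth: isolated, expressed, clear 3' run-out
    isolated = annot.select_tus("isolated_same_strand", flank=250)

    def _clear_downstream(tu: TranscriptionUnit) -> bool:
        idx = annot.chrom_arrays(tu.chrom)
        same = (idx["plus"] == (tu.strand == "+")) & (idx["ids"] != tu.id)
        reach = config.tail_max + 50
        if tu.strand == "+":
            if tu.pas + reach > annot.chrom_sizes[tu.chrom]:
                return False
            hit = same & (idx["start"] < tu.pas + reach) & (idx["end"] > tu.pas)
        else:
            if tu.pas - reach < 0:
                return False
            hit = same & (idx["end"] > tu.pas - reach) & (idx["start"] < tu.pas)
        return not hit.any()

    rt_eligible = sorted(
        tu.id for tu in tus
        if tu.id in isolated
        and expression[tu.id] >= config.readthrough_min_expression
        and _clear_downstream(tu)
    )
    if len(rt_eligible) < config.readthrough_n:
        raise SimulationError(
            f"only {len(rt_eligible)} TUs eligible for read-through truth, "
            f"{config.readthrough_n} requested"
        )
    rt_ids = set(rng.choice(rt_eligible, size=config.readthrough_n, replace=False)) \
        if config.readthrough_n else set()

    # --- antisense truth and decoys: opposite-strand terminator segments
    occupied = _strand_occupied(annot, rt_ids, config)
    placed: dict[tuple[str, str], list[tuple[int, int]]] = {}

    def _free(chrom: str, strand: str, start: int, end: int) -> bool:
        clear = config.antisense_clearance
        for s, e in occupied.get((chrom, strand), []) + placed.get((chrom, strand), []):
            if start - clear < e and end + clear > s:
                return False
        return 0 <= start and end <= annot.chrom_sizes[chrom]

    def _try_place(tu: TranscriptionUnit) -> tuple[int, int, str] | None:
        """An opposite-strand segment whose TSS sits near the TU's PAS and
        which runs back across the TU body (antisense overlap)."""
        anti = "-" if tu.strand == "+" else "+"
        for _ in range(8):
            length = int(rng.integers(config.antisense_len_min,
                                      config.antisense_len_max + 1))
            off = int(rng.integers(-config.antisense_offset_max,
                                   config.antisense_offset_max + 1))
            if tu.strand == "+":
                end = tu.pas + off  # segment TSS (- strand) near the PAS
                start = end - length
            else:
                start = tu.pas + off  # segment TSS (+ strand) near the PAS
                end = start + length
            if start < 0 or end > annot.chrom_sizes[tu.chrom]:
                continue
            if _free(tu.chrom, anti, start, end):
                return start, end, anti
        return None

    seg_rows = []
    used_targets: set[str] = set()
    candidates = sorted(
        (tu.id for tu in tus if tu.id not in rt_ids), key=lambda i: annot[i].start
    )
    candidates = list(rng.permutation(candidates))
    quotas = [
        ("antisense", config.antisense_n, config.antisense_depth),
        ("decoy_equal", config.decoy_equal_n, config.decoy_equal_depth),
        ("decoy_low", config.decoy_low_n, config.decoy_low_depth),
    ]
    for kind, n, depth in quotas:
        count = 0
        for tid in candidates:
            if count >= n:
                break
            if tid in used_targets:
                continue
            tu = annot[tid]
            hit = _try_place(tu)
            if hit is None:
                continue
            start, end, anti = hit
            seg_rows.append({
                "kind": kind, "target_tu": tid, "chrom": tu.chrom,
                "start": start, "end": end, "strand": anti, "depth": depth,
                "tss": start if anti == "+" else end,
            })
            placed.setdefault((tu.chrom, anti), []).append((start, end))
            used_targets.add(tid)
            count += 1
        if count < n:
            raise SimulationError(
                f"could only place {count}/{n} {kind} segments; "
                "relax clearance or enlarge the genome"
            )

    tu_table = pd.DataFrame({
        "tu_id": [t.id for t in tus],
        "chrom": [t.chrom for t in tus],
        "start": [t.start for t in tus],
        "end": [t.end for t in tus],
        "strand": [t.strand for t in tus],
        "orientation": [orientation[t.id] for t in tus],
        "expression": [expression[t.id] for t in tus],
        "readthrough": [t.id in rt_ids for t in tus],
        "tail_mean": config.tail_mean,
        "tail_frac": [
            config.baseline_readthrough_frac
            * (config.readthrough_effect if t.id in rt_ids else 1.0)
            for t in tus
        ],
        "antisense_target": [t.id in {r["target_tu"] for r in seg_rows
                                      if r["kind"] == "antisense"} for t in tus],
    }).set_index("tu_id")
    seg_table = pd.DataFrame(
        seg_rows,
        columns=["kind", "target_tu", "chrom", "start", "end", "strand",
                 "depth", "tss"],
    )
    return annot, TruthSet(tu_table, seg_table)


# ---------------------------------------------------------------- coverage


def expected_signal(
    annot: GenomeAnnotation,
    truth: TruthSet,
    condition: str,
    config: SimulationConfig,
) -> dict[tuple[str, str], np.ndarray]:
    """Noise-free expected per-base signal for one condition."""
    if condition not in CONDITIONS:
        raise SimulationError(f"unknown condition {condition!r}")
    mutant = condition == "mutant"
    decay = config.elongation_decay_mutant if mutant else 1.0
    arrays = {
        (chrom, strand): np.zeros(size)
        for chrom, size in annot.chrom_sizes.items()
        for strand in "+-"
    }
    for tu in annot.tus:
        row = truth.tus.loc[tu.id]
        level = row.expression * config.expression_scale
        x = np.arange(tu.length, dtype=float)
        body = level * decay ** (x / 1000.0)
        arr = arrays[(tu.chrom, tu.strand)]
        if tu.strand == "+":
            arr[tu.start:tu.end] += body
        else:
            arr[tu.start:tu.end] += body[::-1]
        # exponential read-through tail past the PAS
        frac = row.tail_frac if mutant else config.baseline_readthrough_frac
        end_level = level * decay ** (tu.length / 1000.0)
        d = np.arange(config.tail_max, dtype=float)
        tail = frac * end_level * np.exp(-d / row.tail_mean)
        size = annot.chrom_sizes[tu.chrom]
        if tu.strand == "+":
            hi = min(size, tu.pas + config.tail_max)
            arr[tu.pas:hi] += tail[: hi - tu.pas]
        else:
            lo = max(0, tu.pas - config.tail_max)
            arr[lo:tu.pas] += tail[: tu.pas - lo][::-1]
    for _, seg in truth.segments.iterrows():
        if seg.kind in ("antisense", "decoy_low") and not mutant:
            continue
        depth = seg.depth * config.expression_scale
        arrays[(seg.chrom, seg.strand)][seg.start:seg.end] += depth
    return arrays


def simulate_replicate_coverage(
    annot: GenomeAnnotation,
    truth: TruthSet,
    condition: str,
    replicate: int,
    config: SimulationConfig,
) -> StrandedCoverage:
    """One replicate of observed coverage plus its species read totals."""
    if condition not in CONDITIONS:
        raise SimulationError(f"unknown condition {condition!r}")
    cond_idx = CONDITIONS.index(condition)
    rng = _rng(config, 1, cond_idx, replicate)
    depth_factor = float(np.exp(rng.normal(0, config.depth_jitter_sigma))) \
        if config.depth_jitter_sigma > 0 else 1.0
    expected = expected_signal(annot, truth, condition, config)
    data: dict[tuple[str, str], np.ndarray] = {}
    for key, mu in expected.items():
        mu = mu * depth_factor
        if config.noise_model == "none":
            data[key] = mu
        elif config.dispersion == 0:
            data[key] = rng.poisson(mu).astype(float)
        else:
            shape = 1.0 / config.dispersion
            lam = np.where(mu > 0, rng.gamma(shape, 1.0, mu.size) * mu
                           * config.dispersion, 0.0)
            data[key] = rng.poisson(lam).astype(float)

    spike_rng = _rng(config, 2, cond_idx, replicate)
    m_actual = config.mixing_ratio * float(
        np.exp(spike_rng.normal(0, config.mixing_jitter_sigma))
    ) if config.mixing_jitter_sigma > 0 else config.mixing_ratio
    spike_mu = depth_factor * m_actual * config.spike_material
    spike_reads = max(1, int(spike_rng.poisson(spike_mu))) \
        if config.noise_model != "none" else max(1, round(spike_mu))
    counts = SpeciesCounts(
        primary_reads=max(1, round(depth_factor * config.library_reads)),
        spike_reads=spike_reads,
        input_primary_reads=config.input_depth,
        input_spike_reads=max(1, round(m_actual * config.input_depth)),
    )
    return StrandedCoverage(
        annot.chrom_sizes, data,
        sample_id=f"{condition}_rep{replicate}",
        condition=condition, replicate=replicate,
        read_length=config.read_length, species_counts=counts,
    )


def simulate_all_replicates(
    annot: GenomeAnnotation, truth: TruthSet, config: SimulationConfig
) -> dict[str, list[StrandedCoverage]]:
    """All replicates for both conditions, keyed by condition."""
    return {
        cond: [
            simulate_replicate_coverage(annot, truth, cond, rep, config)
            for rep in range(1, config.n_replicates + 1)
        ]
        for cond in CONDITIONS
    }


# ---------------------------------------------------------------- fixtures


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture(
    annot: GenomeAnnotation,
    truth: TruthSet,
    coverages: list[StrandedCoverage],
    outdir,
) -> dict:
    """Write annotation, coverage, metadata and truth; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    bed = outdir / "annotation.bed6"
    annot.to_bed6(bed)
    files.append(bed)

    sizes = outdir / "chrom.sizes"
    with open(sizes, "w") as fh:
        for chrom, size in annot.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    files.append(sizes)

    meta_rows = []
    for cov in coverages:
        plus = outdir / f"{cov.sample_id}.plus.bedgraph"
        minus = outdir / f"{cov.sample_id}.minus.bedgraph"
        cov.save_bedgraph(plus, minus)
        files += [plus, minus]
        sc = cov.species_counts
        meta_rows.append({
            "sample_id": cov.sample_id, "condition": cov.condition,
            "replicate": cov.replicate,
            "plus_path": plus.name, "minus_path": minus.name,
            "primary_reads": sc.primary_reads, "spike_reads": sc.spike_reads,
            "input_primary_reads": sc.input_primary_reads,
            "input_spike_reads": sc.input_spike_reads,
            "read_length": cov.read_length,
        })
    samples = outdir / "samples.tsv"
    pd.DataFrame(meta_rows).to_csv(samples, sep="\t", index=False)
    files.append(samples)

    truth_tus = outdir / "truth_tus.tsv"
    truth.tus.to_csv(truth_tus, sep="\t")
    files.append(truth_tus)
    truth_segs = outdir / "truth_segments.tsv"
    truth.segments.to_csv(truth_segs, sep="\t", index=False)
    files.append(truth_segs)

    manifest = {
        "files": {f.name: _sha256(f) for f in files},
        "n_samples": len(coverages),
        "n_tus": len(annot),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_fixture(outdir) -> tuple[GenomeAnnotation, list[StrandedCoverage]]:
    """Reload a written fixture (annotation + all samples)."""
    from .coverage import load_samples_tsv
    from .genome import read_annotation, read_chrom_sizes

    outdir = Path(outdir)
    sizes = read_chrom_sizes(outdir / "chrom.sizes")
    annot = read_annotation(outdir / "annotation.bed6", "bed6", sizes)
    meta = pd.read_csv(outdir / "samples.tsv", sep="\t")
    for col in ("plus_path", "minus_path"):
        meta[col] = [str(outdir / p) for p in meta[col]]
    tmp = outdir / "_samples_abs.tsv"
    meta.to_csv(tmp, sep="\t", index=False)
    covs = load_samples_tsv(tmp, sizes)
    tmp.unlink()
    return annot, covs
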