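# Methods

## Coordinate and signal conventions

All intervals are 0-based half-open; GFF3 (1-based closed) is converted
at the parsing boundary. A TU's TSS/PAS are its interval boundaries
(`+`: TSS = start, PAS = end; `-`: TSS = end, PAS = start), so windows
on the two strands are mirror images with no off-by-one asymmetry.

Coverage, not read alignments, is the unit of exchange: one bedGraph per
strand per sample, expanded to dense per-base vectors. Filters phrased
in "reads" operate on *read equivalents* = coverage sum / read length
(default 50 bp, per-sample configurable). This keeps the whole pipeline
runnable from bedGraph without BAM handling; absolute read-count
thresholds (≥ 10 WT upstream, ≥ 5 mutant downstream) therefore assume
the read length recorded in the sample metadata is accurate.

Windows partially off a chromosome end are clipped with a logged
warning; fully off-chromosome windows raise, except in the batch
read-through screen where the (rare, terminal-gene) downstream window
beyond the chromosome end counts as zero signal rather than aborting a
genome-wide run.

## Spike-in normalization

The scale factor is `α = 10⁶ · m / spike_reads` with
`m = input_spike / input_primary` (mode `spike_with_input`); without
input libraries, `α = 10⁶ / spike_reads` (`spike_only`), and
`α = 10⁶ / primary_reads` gives plain library-size scaling. The
input-corrected form satisfies two properties the analysis depends on:
changing the physical mixing ratio leaves normalized tracks unchanged
(m cancels), and doubling true occupancy genome-wide with the spike
fixed doubles normalized signal. The 10⁶ scale is an arbitrary
per-million convention; it cancels in every ratio. Phospho-over-total
style tracks are composed as `log2_ratio_track(phospho, total)` after
each sample is spike-normalized (per-bin pseudocount ε = 0.1 normalized
units, bounding log-ratios at empty bins without masking signal).

## Traveling ratio and metagenes

`TR = log2((occ5′ + ε)/(occ3′ + ε))` with 200-bp windows at the TU ends
(TU sense) and ε = 1 read-equivalent per window: unexpressed TUs stay
finite without perturbing expressed ones; TR is exactly
scale-invariant at ε = 0 on positive windows. TUs shorter than two
windows (400 bp) are flagged and excluded from distributions rather
than scored. Metagene matrices align TUs at the TSS with 500-bp flanks,
10-bp bins and a 4.5-kb body trim; rows are length-sorted and padded
with NaN, and exported curves report column medians and quartiles
(no confidence-band construction is attempted). Scaled metagenes
min-max-scale each body to [0, 1] then length-normalize by linear
interpolation; constant rows map to zeros by convention.

Group comparisons use the Mann-Whitney U test for independent gene sets
and the Wilcoxon signed-rank test for matched sets, two-sided, with
Bonferroni adjustment over the declared comparison family. 150-nt
site windows are centered on the TSS/PAS ([site − 75, site + 75)); the
anchoring is configurable since centering is a symmetry choice, not a
forced one. A degenerate paired comparison (all differences zero)
reports p = 1. A random-control sampler draws gene sets of twice the
test-set size, the usual control design for these screens.

## Read-through caller

Windows are [PAS − 250, PAS) and [PAS, PAS + 250) in TU sense; only TUs
with no same-strand neighbor within 250 bp are screened, so the
downstream window cannot sit inside another gene on the same strand.
Replicate read-equivalents are averaged per condition (sample SD with
n − 1). The "normalized SD" filter is interpreted as the coefficient of
variation of the *mutant* downstream densities — the signal being
called; a `cv_target="both"` switch applies it to the worse of the two
conditions instead, since the original description does not pin the
target down. The corrected ratio uses a pseudocount of 1 read-
equivalent in all four means so that zero WT downstream signal yields a
finite, conservative ratio; the two absolute count filters use raw
(un-pseudocounted) means. All four filters are individually monotone:
relaxing any threshold can only grow the called set.

## Antisense discovery

Segments are maximal runs of per-base coverage ≥ 1 (in the sample's
native units), merged across gaps ≤ 5 nt — a coverage-run assembler
implementing the same merging semantics an external transcript
assembler would be followed by, which removes that dependency.
Reproducibility keeps same-strand overlapping portions of the two
replicates; WT and mutant strata are then unioned and re-merged.
The reciprocal-overlap filter discards a segment only when some
same-strand TU overlaps it by ≥ 10% of both lengths; length bounds
50 bp and 5 kb are inclusive. FPKM is computed against the sample's
primary-species library size (or the spike-equivalent library
10⁶ / α when normalization factors are passed); the condition value is
the replicate mean, and fold change uses an FPKM pseudocount of 0.1 so
mutant-only transcripts get finite values. Differential antisense
abundance is reported as normalized fold changes with up/down flags at
1.5-fold — a deliberate simplification; no count-model shrinkage or FDR
machinery is attached.

Origin classification gives PAS alignment precedence: terminator-
proximal when the predicted TSS is within ± 300 nt of any annotated
PAS, else promoter-proximal within ± 300 nt of an opposite-strand TSS,
else other. The promoter window width mirrors the PAS window since no
independent value is established for it. Read-through linkage connects
a novel transcript to a called read-through gene on the same strand
whose PAS lies ≤ 300 bp 5′ of the transcript's TSS.

## Synthetic data generator

The generator is first-class, tested code; its defaults define the
study conditions used throughout the tests:

* **Layout** — 200 genes over 5 × 120-kb chromosomes; 25% of placement
  units are convergent pairs (PAS-to-PAS gap 100–300 bp), the rest
  single genes of random strand; intergenic gaps uniform 600–1500 bp
  (so most TUs pass the 250-bp isolation filter); gene lengths
  log-normal, median 1.5 kb, σ(ln) = 0.35.
* **Expression** — log-normal per-TU mean depth, median 20 per base,
  σ(ln) = 0.4.
* **Elongation defect** — mutant body signal decays ×0.85 per kb from
  the TSS, producing the 5′-biased mutant profile and a positive
  traveling-ratio shift.
* **Read-through** — every TU leaks a baseline exponential tail past
  its PAS in *both* conditions (5% of the gene-end level, mean length
  500 bp, painted to 1.5 kb). Truth-flagged TUs get 4× that fraction in
  the mutant. The baseline makes the null screen non-trivial: the
  ≥ 5-read mutant-downstream filter is exercised against real WT-level
  signal rather than empty windows. Flags are drawn only from TUs that
  are isolated, expressed ≥ 15 per base, and have ≥ 1.55 kb of
  same-strand clearance past the PAS — termination defects are only
  measurable at expressed genes whose tail is attributable to them
  (the ≥ 10-read WT filter embodies the same logic on real data).
* **Antisense** — 15 opposite-strand segments with TSS within ± 100 bp
  of a target PAS, length 300–2000 bp, depth 10 per base, mutant only;
  targets are chosen so the segment (plus 300 bp clearance) is free of
  other features on its own strand, which prevents assembly merges and
  screen cross-talk. Decoys: 5 segments expressed equally in both
  conditions (depth 8, fold change ≈ 1) and 5 weak mutant-only segments
  (depth 0.5, below both the assembly and abundance gates). Because
  antisense targets are deliberately placed away from read-through
  genes, the default fixture yields zero read-through-linked antisense
  transcripts; linkage is exercised by direct unit tests instead.
* **Noise** — per-base negative-binomial counts (gamma-Poisson) with
  dispersion φ = 0.1 (φ = 0 gives Poisson; `noise_model="none"` gives
  expected values for exactness checks), and a per-sample log-normal
  depth factor (σ = 0.15) that models library-size variation.
* **Spike-in** — mixing ratio 0.1 (1 spike : 10 primary cells) with 5%
  per-sample jitter; IP spike reads Poisson around depth × m × 2·10⁶;
  input libraries of 10⁶ primary reads measure the realized m. The
  primary library size defaults to 2·10⁷ reads independent of the
  painted TU coverage — as in a real ~80× fission-yeast library, where
  depth-1 coverage corresponds to roughly 1 FPKM — so FPKM thresholds
  behave realistically on the small synthetic genome.

Determinism: every stream derives from `SeedSequence([seed, stage,
condition, replicate])`, so annotation, truth and each sample are
byte-reproducible per seed and unaffected by which other samples are
generated.

What the generator does **not** emulate: mappability artifacts,
fragment-length smoothing (per-base NB noise is rougher than read-shaped
coverage), exon structure, copy-number or rDNA-like repeats, batch
effects beyond a scalar depth factor, and partial (graded) termination
defects. Passing recovery tests therefore demonstrates correctness of
the rules and robustness to overdispersed counting noise and depth
imbalance — not performance on every artifact of real libraries.

## Fixture and test sizing

Tests run simulated genomes of 30–200 genes (60–600 kb total) with two
replicates per condition; the null-calibration batteries use 100–200
seeded runs of reduced genomes (40–100 genes). These sizes give the
screens hundreds of eligible windows per run while keeping the whole
suite around a minute of compute; recovery margins are large at the
default effect sizes, so conclusions do not hinge on fixture scale.

## Known limitations

* The read-through caller windows exactly 250 bp past the PAS; it does
  not estimate tail length or refine transcript 3′ boundaries.
* Assembly is coverage-threshold based; at depths near the 1×
  threshold, segments fragment and short fragments fall to the length
  filter (visible as occasional marginal discoveries from baseline
  tails in noisy fixtures).
* Antisense significance is flag-based (normalized fold change), with
  no multiple-testing-controlled p-value per TU.
* FPKM against total primary reads is switchable to spike-equivalent
  libraries but the two differ by a per-sample constant; analyses that
  mix the two conventions are not meaningful.
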