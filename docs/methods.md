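# Methods

## The analysis model

The package operates on scored, summit-bearing ChIP-seq peaks (MACS-style
caller output), gene models collapsed to one transcription unit per gene
(TSS = strand-aware 5′-most position), chromatin-mark region sets, and
per-gene differential-expression records. All coordinates are 0-based
half-open internally; 1-based formats (GTF) are converted only in readers.

### Genomic location classes

A peak's class is decided by its **summit**, not by any-overlap: summits are
the best point estimate of the binding site and the same anchor drives the
motif analysis, so the two views stay consistent. Classes are exclusive with
precedence TSSA > IG > CI/FI. The TSSA window is −500..+100 bp of a TSS in
the direction of transcription (both ends inclusive); CI/FI are split at a
nearest-TSS distance of 20 kb measured to the TSS (not the gene edge), with
CI strictly below the cutoff. Equidistant nearest-TSS ties break
lexicographically by gene id for determinism. Peaks on chromosomes absent
from the annotation classify FI with a warning (configurable to an error).
The peak→target-gene rule (containing transcription unit, else nearest TSS)
is a documented choice — the field has no single convention — and is the one
place where two equally defensible rules would change target counts.

### Overlap rule

Two peaks overlap when their intersection is at least `min_frac` (default
0.5) of the **shorter** peak. That is the strictest symmetric reading of a
"50% or more overlapping sequences" rule; `frac_of ∈ {shorter, either, both,
a, b}` preserves the alternatives. Mark overlap for chromatin-state calls
defaults to any-overlap (≥ 1 bp): marks are broad domains and a
fraction-of-peak rule (available via `min_frac`) would make state calls
depend on peak width. States are exclusive by precedence
promoter > bivalent_enhancer > enhancer so fractions are well defined.

### Consensus scanning

The four motifs are short IUPAC consensus strings (OCTA `TGATXXAT`, DECA
`TGAXTGACAG`, HEXA `TGACAX`, AP-1 `TGASTCA`; X ≡ N). The AP-1 "TGAC/GTCA"
slash notation is read as C-or-G at position 4 (S), the standard Jun/Fos
heptamer. Each consensus becomes a PWM: a degenerate code spreads
probability uniformly over its bases, smoothed with a background-weighted
pseudocount (default 0.1); N/X columns carry the background exactly, so they
contribute zero log-odds. Scanning is FIMO-style: log₂-odds scores against a
0-order, strand-symmetrised background (estimated from the scanned windows
by default), both strands, windows containing N skipped.

The score threshold for a match p-value is computed by **exact enumeration**
of the score distribution of all 4ʷ words under the background (widths are
≤ 10, so enumeration is trivial and exact): the threshold is the smallest
score whose upper-tail probability is ≤ p. Score distributions of short
degenerate motifs are coarse: OCTA has only six informative positions, so
its best attainable match p-value is 4⁻⁶ ≈ 2.4·10⁻⁴ and *no* threshold can
satisfy p ≤ 10⁻⁴. In that case the scanner falls back to the top score
(exact-consensus words only) so the consensus itself is always detectable;
the attained per-position p-value is exposed (`PWM.attained_pvalue`) and is
the quantity the false-positive calibration is checked against (for AP-1 it
is 1.22·10⁻⁴, i.e. the requested 10⁻⁴ regime; for DECA, 3.8·10⁻⁶).

Peaks are scanned in fixed 300-bp windows centred on the summit (truncated
at contig edges). For Table-style classification a peak counts as carrying a
motif if it has ≥ 1 hit (multiple hits collapse); all hits are kept for the
positional profiles. HEXA is scanned and reported but excluded from the
specific/AP-1 classification. The AP-1-summit subset takes peaks with an
AP-1 hit midpoint within ±30 bp of the peak midpoint and no OCTA hit
anywhere in the scanned window (the anchor is switchable to the summit).
Score comparisons between motif classes use the two-sided Mann–Whitney
rank-sum test — peak scores are heavy-tailed, so rank-based inference.

### Signatures and enrichment

DE selection is strict p < 0.05 on the contrast vs the empty-vector line,
split by the sign of log2FC (zero fold changes are excluded with a warning).
"Targets shared with WT" are gene sets (bound-and-upregulated in the WT
contrast), not peak sets: the subtraction feeds gene-level term enrichment.
Each subtraction step records how many genes it removed from what remained,
and the invariants (telescoping counts, disjointness from every subtracted
set) are asserted on every run. Enrichment is the upper-tail hypergeometric
probability P(X ≥ k | N, K, n) over an **explicit** universe (the background
choice is a known sensitivity, so it is a required input); raw-p flags at
10⁻⁴ reproduce the GOrilla-style convention and BH q-values are reported
alongside. The threshold-free mHG statistic is deliberately not implemented
— the inputs here are fixed gene lists.

## The synthetic-data generator

The generator emulates a five-cell-line dosage study (relative Meis1/Prep1
levels: WT 1/1, ev 0.3/0, M 4.4/0, P 0.1/5, MP 1.75/4.2):

* **Counts.** Expected peaks per factor = `peaks_per_unit_level` × level
  (default 400/unit, a desk-scale stand-in for the genome-wide ~6,200/unit).
  A deterministic **core** prefix of shared sites — same positions across
  profiles on the same genome and seed, `core_fraction` (default 0.9, the
  observed retention of low-expression sites in overexpressing lines) — is
  emitted first; dosage-dependent "extra" sites fill to a Poisson-distributed
  total. Poisson is an assumption: the study reports only point counts, with
  no replicate variance to calibrate against.
* **Placement.** Summits are sampled from per-bp class maps built with the
  same definitions as the annotation module (defaults FI 55%, IG 27%,
  CI 17.1%, TSSA 0.9%, the observed Meis1 pattern normalised to sum to 1),
  with ≥ 1 peak width separation within a factor's landscape so windows do
  not cross-contaminate.
* **Motifs.** Each peak draws a motif class from a per-factor mix (Meis1:
  35% OCTA / 45% AP-1 / 2% both / 18% neither; Prep1: 70% DECA / 16% AP-1 /
  4% both / 10% neither — loosely the observed WT composition). An exact
  consensus instance (random degenerate expansion) is written into the
  sequence at summit ± Gaussian jitter (sd 8 bp; the "both" class puts AP-1
  45–110 bp off-summit). Background is i.i.d. at the requested GC and is
  **scrubbed** of chance exact-consensus words by default: a 300-bp
  double-strand window has a ~13% chance of containing a spurious OCTA word,
  which would swamp a ±3-point composition comparison; scrubbing makes the
  embedded composition exactly recoverable and is switchable off
  (`scrub_motifs=None`) when natural background statistics matter.
* **Scores.** Lognormal (ln-scale μ 4.0, σ 0.5) with per-(factor, motif
  class) multipliers; the default doubles Prep1 DECA-peak scores, emulating
  the observed higher scores of specific-consensus Prep1 peaks.
* **Displacement.** Optionally, when Prep1 exceeds a threshold level,
  a fraction of AP-1-class *extra* Meis1 peaks is removed (demo: 0.4),
  reproducing qualitatively the competitive loss of Meis1 AP-1 sites under
  Prep1 co-overexpression.
* **Expression.** True-DE genes (default 15% of genes; 45% of them bound,
  81% of the bound ones upregulated — the observed integration structure)
  get |log2FC| ~ |Normal(effect, sd)| with p ~ Beta(a, 1) concentrated near
  zero (default a = 0.01); nulls get Normal(0, sd) fold changes and uniform
  p-values. Ground-truth flags ride along in the returned table.

What the generator does **not** emulate: read-level noise, peak-width
variation, chromatin-domain structure, correlated placement of marks and
peaks, and mapping artefacts. Passing recovery tests therefore demonstrate
that the analysis logic is correct and calibrated on data satisfying its
assumptions — not that the thresholds are optimal for any particular real
dataset.

## Numerical and design notes

* Interval overlap uses per-chromosome interval trees; correctness is
  checked against an O(n²) all-pairs oracle. Scan thresholds use a small
  (10⁻⁹) epsilon so float round-off cannot drop boundary-score matches.
* All randomness flows through `numpy.random.Generator` seeded by explicit
  `SeedSequence` entries (run seed, factor index, profile-name CRC), so any
  profile's landscape is reproducible independently of generation order.
* Degenerate inputs: empty peak sets propagate as empty results with
  NaN fractions and a warning; a factor at level 0 yields an empty peak set
  (not an error); all-equal protein levels make the dosage fit an error;
  score-class comparisons with < 2 peaks per class are skipped with a
  warning.
* Problem sizes in the test-suite and acceptance runs (desk-scale genomes of
  4 × 2–3 Mb, 240–1,200 genes, 10²–10⁴ peaks, 20–50 replicate landscapes for
  slope recovery) were chosen so every statistical check has comfortable
  power while the whole suite stays interactive.
* The signature-recovery check uses a strong-signal expression scenario
  (p ~ Beta(0.001, 1) for true DE genes, |log2FC| ≈ 2.5): with per-gene
  sensitivity ≈ 0.985 and a handful of expected null leak-ins per contrast,
  the thresholded pipeline should reproduce ground-truth signatures at
  Jaccard ≥ 0.95, and does. With weaker effects the p < 0.05 threshold's 5%
  null leakage dominates — a property of threshold-based selection, not of
  the implementation.

## Known limitations

* Consensus-derived PWMs are information-poor compared to matrices learned
  de novo from the peaks; motif percentages on real data will differ from
  counts produced by discovery-based matrices.
* The hypergeometric enrichment treats terms independently (no ontology DAG
  propagation) and the raw-p flag convention inflates discoveries across
  many terms — hence the accompanying q-values.
* The 50%-of-shorter overlap rule is asymmetricly permissive for nested
  peaks of very different widths; alternatives are exposed but results are
  reported for the default only.
* Target-gene assignment is proximity-based; no enhancer–promoter contact
  information is used.
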