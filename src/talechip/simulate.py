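"""Synthetic genomes, dosage-dependent binding landscapes, chromatin marks
and differential-expression tables.

The generator emulates the statistical structure of a five-cell-line
TALE-factor dosage study:

* per-line relative protein levels drive the expected peak count linearly
  (Poisson noise on the dosage-dependent "extra" peaks);
* a core subset of binding sites is shared across lines at the same genome
  and seed, so low-expression landscapes are near-subsets of
  high-expression ones;
* peaks are placed into the four genomic location classes (TSSA/IG/CI/FI)
  at configurable proportions, and carry exact consensus-motif instances
  written into the sequence at summit +/- jitter;
* expression tables flag ground-truth DE genes with a configurable bound
  fraction and up-regulated fraction, p-values concentrated near zero for
  true DE genes (Beta(a, 1)) and uniform for nulls.

Background sequence is i.i.d. at the requested GC content and, by default,
scrubbed of chance exact-consensus occurrences so that embedded-motif
composition is exactly recoverable by the scanner (see docs/methods.md).
"""

from __future__ import annotations

import re
import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotate import AnnotationConfig, tssa_window
from .core import GeneModel, Genome, GenomicInterval, Peak, PeakSet
from .motifs import IUPAC, MOTIF_LIBRARY, SPECIFIC_MOTIF

#: Relative protein levels (WT = 1.0) of the five study cell lines.
PROFILE_LEVELS = {
    "WT": (1.0, 1.0),
    "ev": (0.3, 0.0),
    "M": (4.4, 0.0),
    "P": (0.1, 5.0),
    "MP": (1.75, 4.2),
}

FACTORS = ("Meis1", "Prep1")
_FACTOR_IDX = {"Meis1": 1, "Prep1": 2}

_CLASS_CODES = {"TSSA": 0, "IG": 1, "CI": 2, "FI": 3}

MOTIF_CLASSES = ("specific", "ap1", "both", "none")


@dataclass(frozen=True)
class CellLineProfile:
    """A named condition with relative Meis1/Prep1 protein levels."""

    name: str
    level_meis1: float
    level_prep1: float

    def __post_init__(self):
        if self.level_meis1 < 0 or self.level_prep1 < 0:
            raise ValueError("protein levels must be >= 0")

    @classmethod
    def standard(cls, name: str) -> "CellLineProfile":
        m, p = PROFILE_LEVELS[name]
        return cls(name, m, p)


def standard_profiles() -> list[CellLineProfile]:
    return [CellLineProfile.standard(n) for n in PROFILE_LEVELS]


@dataclass(frozen=True)
class MotifMix:
    """Fractions of peaks carrying the factor-specific consensus, AP-1,
    both, or neither."""

    specific: float
    ap1: float
    both: float
    none: float

    def __post_init__(self):
        vals = (self.specific, self.ap1, self.both, self.none)
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError("motif mix fractions must be in [0, 1]")
        if abs(sum(vals) - 1) > 1e-9:
            raise ValueError("motif mix fractions must sum to 1")

    def as_probs(self) -> np.ndarray:
        return np.array([self.specific, self.ap1, self.both, self.none])


# Default compositions loosely follow the observed WT landscape: the
# factor-specific consensus and AP-1 are both common, rarely together for
# Meis1; the Prep1 decamer dominates Prep1 peaks.
DEFAULT_MOTIF_MIX = {
    "Meis1": MotifMix(specific=0.35, ap1=0.45, both=0.02, none=0.18),
    "Prep1": MotifMix(specific=0.70, ap1=0.16, both=0.04, none=0.10),
}

DEFAULT_CLASS_PROPORTIONS = {"FI": 0.55, "IG": 0.27, "CI": 0.171, "TSSA": 0.009}


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of the dosage-dependent binding landscape."""

    peaks_per_unit_level: float = 400.0
    core_fraction: float = 0.9
    motif_mix: dict = field(default_factory=lambda: dict(DEFAULT_MOTIF_MIX))
    summit_jitter_sd: float = 8.0
    peak_width: int = 300
    score_mu: float = 4.0       # ln-scale location of the lognormal score
    score_sigma: float = 0.5
    score_multipliers: dict = field(
        default_factory=lambda: {"Prep1": {"specific": 2.0}})
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    displacement_fraction: float = 0.0
    displacement_prep1_threshold: float = 1.0
    core_pool_max_level: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.core_fraction <= 1):
            raise ValueError("core_fraction must be in [0, 1]")
        if not (0 <= self.displacement_fraction <= 1):
            raise ValueError("displacement_fraction must be in [0, 1]")
        total = sum(self.class_proportions.values())
        if abs(total - 1) > 1e-6:
            raise ValueError("class proportions must sum to 1")


@dataclass(frozen=True)
class DESpec:
    """Parameters of the synthetic differential-expression table."""

    n_genes: int | None = None       # default: all supplied genes
    fraction_de: float = 0.15        # fraction of genes truly DE
    fraction_bound_de: float = 0.45  # fraction of DE genes that are bound
    fraction_up: float = 0.81        # upregulated fraction among bound DE genes
    effect_size: float = 2.0         # mean |log2FC| of true DE genes
    noise_sd: float = 0.4
    p_alpha: float = 0.01            # true-DE p-values ~ Beta(p_alpha, 1)
    seed: int = 0


# ---------------------------------------------------------------------------
# Genome generation


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> bytes:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(alphabet, size=length, p=probs).tobytes()


_RC_IUPAC = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
             "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
             "D": "H", "H": "D", "N": "N", "X": "X"}


def _iupac_regex(iupac: str) -> str:
    parts = []
    for ch in iupac.upper():
        bases = IUPAC[ch]
        parts.append("." if len(bases) == 4 else (bases if len(bases) == 1 else f"[{bases}]"))
    return "".join(parts)


def _informative_offset(iupac: str) -> tuple[int, set[str]]:
    for i, ch in enumerate(iupac.upper()):
        if len(IUPAC[ch]) < 4:
            return i, set(IUPAC[ch])
    raise ValueError("motif has no informative position")


def scrub_consensus_sites(sequence: str, motifs, rng: np.random.Generator,
                          max_passes: int = 8) -> str:
    """Remove chance exact-consensus occurrences from a background sequence
    by mutating one informative position of every match (both strands)."""
    patterns = []
    for m in motifs:
        if isinstance(m, str):
            m = MOTIF_LIBRARY[m]
        rc = "".join(_RC_IUPAC[ch] for ch in reversed(m.iupac.upper()))
        for iupac in (m.iupac.upper(), rc):
            off, allowed = _informative_offset(iupac)
            pattern = re.compile(f"(?=({_iupac_regex(iupac)}))")
            patterns.append((pattern, off, sorted(set("ACGT") - allowed)))
    seq = bytearray(sequence.encode())
    for _ in range(max_passes):
        dirty = False
        text = seq.decode()
        for pattern, off, choices in patterns:
            for match in pattern.finditer(text):
                pos = match.start() + off
                seq[pos] = ord(rng.choice(choices))
                dirty = True
        if not dirty:
            return seq.decode()
    warnings.warn("consensus scrubbing did not converge; residual matches remain")
    return seq.decode()


def generate_genome(n_chrom: int = 4, chrom_length: int = 2_000_000,
                    n_genes: int = 240, gc_content: float = 0.5, seed: int = 0,
                    gene_length_range: tuple[int, int] = (5_000, 20_000),
                    margin: int = 150_000, min_gap: int = 2_000,
                    scrub_motifs=("OCTA", "DECA", "AP1")) -> tuple[Genome, list[GeneModel]]:
    """Generate a random genome with non-overlapping genes on both strands.

    Chromosome-end margins and randomly sized intergenic gaps leave room for
    both close (<20 kb) and far (>20 kb) intergenic peak placements. Raises
    if the requested genes cannot be packed. The background is scrubbed of
    chance consensus matches unless ``scrub_motifs`` is empty/None.
    """
    if not (0 <= gc_content <= 1):
        raise ValueError("gc_content must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0)
                 for i in range(n_chrom)]
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    gene_no = 0
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        k = per_chrom[ci]
        lengths = rng.integers(gene_length_range[0], gene_length_range[1] + 1, size=k)
        slack = chrom_length - 2 * margin - int(lengths.sum()) - max(0, k - 1) * min_gap
        if k and slack < 0:
            raise ValueError(
                f"cannot place {k} genes of total length {int(lengths.sum())} "
                f"on a {chrom_length} bp chromosome")
        extra = rng.multinomial(slack, np.full(k + 1, 1 / (k + 1))) if k else []
        pos = margin
        for gi in range(k):
            pos += int(extra[gi]) + (min_gap if gi else 0)
            start, end = pos, pos + int(lengths[gi])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene_{gene_no:04d}",
                                   GenomicInterval(chrom, start, end), strand))
            gene_no += 1
            pos = end
        seq = _random_sequence(rng, chrom_length, gc_content).decode()
        if scrub_motifs:
            seq = scrub_consensus_sites(seq, scrub_motifs, rng)
        sequences[chrom] = seq
    return Genome(sequences, genome_id=f"synthetic_seed{seed}"), genes


# ---------------------------------------------------------------------------
# Peak placement


class PlacementIndex:
    """Per-bp genomic-location class maps used to place synthetic summits.

    Built with the same class definitions (and precedence) the annotation
    module uses, so placed summits classify back to their intended class.
    """

    def __init__(self, genome: Genome, genes: list[GeneModel],
                 cfg: AnnotationConfig = AnnotationConfig(), edge_margin: int = 400):
        self.cfg = cfg
        self.chroms = list(genome.chroms)
        # global coordinates: chromosomes separated by > any min_sep
        pad = 100_000
        self.offsets = {}
        offset = 0
        for chrom in self.chroms:
            self.offsets[chrom] = offset
            offset += genome.length(chrom) + pad
        pools: dict[int, list[np.ndarray]] = {c: [] for c in _CLASS_CODES.values()}
        by_chrom: dict[str, list[GeneModel]] = {c: [] for c in self.chroms}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom in self.chroms:
            length = genome.length(chrom)
            arr = np.full(length, _CLASS_CODES["FI"], dtype=np.int8)
            gg = by_chrom[chrom]
            if gg:
                tss = np.sort(np.array([g.tss for g in gg]))
                pos = np.arange(length)
                idx = np.searchsorted(tss, pos)
                left = tss[np.clip(idx - 1, 0, len(tss) - 1)]
                right = tss[np.clip(idx, 0, len(tss) - 1)]
                dist = np.minimum(np.abs(pos - left), np.abs(pos - right))
                arr[dist < cfg.ci_cutoff] = _CLASS_CODES["CI"]
                for g in gg:
                    arr[g.interval.start:g.interval.end] = _CLASS_CODES["IG"]
                for g in gg:
                    lo, hi = tssa_window(g, cfg)
                    arr[max(0, lo):min(length, hi)] = _CLASS_CODES["TSSA"]
            arr[:edge_margin] = -1
            arr[length - edge_margin:] = -1
            for name, code in _CLASS_CODES.items():
                positions = np.flatnonzero(arr == code)
                if len(positions):
                    pools[code].append(positions + self.offsets[chrom])
        self.pools = {code: (np.concatenate(p) if p else np.array([], dtype=int))
                      for code, p in pools.items()}
        self._bounds = sorted((off, chrom) for chrom, off in self.offsets.items())

    def decode(self, global_pos: int) -> tuple[str, int]:
        lo = 0
        for off, chrom in self._bounds:
            if global_pos >= off:
                lo, best = off, chrom
        return best, global_pos - lo


def _sample_summits(rng: np.random.Generator, placement: PlacementIndex,
                    class_probs: dict[str, float], n: int, min_sep: int,
                    taken: list[int]) -> tuple[list[int], list[str]]:
    """Sample n summit positions with the requested class composition,
    keeping every position >= min_sep from each other and from ``taken``."""
    import bisect

    names = list(class_probs)
    counts = rng.multinomial(n, np.array([class_probs[c] for c in names]))
    quota = dict(zip(names, (int(c) for c in counts)))
    kept = sorted(taken)
    out_pos: list[int] = []
    out_cls: list[str] = []

    def far_enough(pos: int) -> bool:
        i = bisect.bisect_left(kept, pos)
        if i < len(kept) and kept[i] - pos < min_sep:
            return False
        if i > 0 and pos - kept[i - 1] < min_sep:
            return False
        return True

    for _ in range(60):
        pending = [(c, k) for c, k in quota.items() if k > 0]
        if not pending:
            break
        for cls, k in pending:
            pool = placement.pools[_CLASS_CODES[cls]]
            if not len(pool):
                raise ValueError(f"no genomic positions available for class {cls}")
            draws = rng.choice(pool, size=min(len(pool), 2 * k + 8), replace=True)
            for pos in draws:
                if quota[cls] == 0:
                    break
                pos = int(pos)
                if far_enough(pos):
                    bisect.insort(kept, pos)
                    out_pos.append(pos)
                    out_cls.append(cls)
                    quota[cls] -= 1
    if any(k > 0 for k in quota.values()):
        raise ValueError("could not place all peaks: genome too small for the "
                         "requested peak count and separation")
    return out_pos, out_cls


# ---------------------------------------------------------------------------
# Landscape generation


@dataclass
class _Site:
    chrom: str
    summit: int
    region_class: str
    motif_class: str
    embeds: list[tuple[str, int, str]]  # motif name, genome start, word


def _make_sites(rng: np.random.Generator, placement: PlacementIndex,
                spec: LandscapeSpec, factor: str, n: int,
                taken: list[int]) -> list[_Site]:
    if n == 0:
        return []
    positions, classes = _sample_summits(rng, placement, spec.class_proportions,
                                         n, spec.peak_width, taken)
    specific = SPECIFIC_MOTIF[factor]
    mix = spec.motif_mix[factor]
    motif_classes = rng.choice(MOTIF_CLASSES, size=n, p=mix.as_probs())
    sites = []
    half = spec.peak_width // 2
    for gpos, region_class, mclass in zip(positions, classes, motif_classes):
        chrom, summit = placement.decode(int(gpos))
        embeds = []

        def place(motif_name: str, center_offset: float) -> None:
            motif = MOTIF_LIBRARY[motif_name]
            word = motif.expansions()[rng.integers(len(motif.expansions()))]
            start = int(round(summit + center_offset - motif.width // 2))
            lo = summit - half + 1
            hi = summit + (spec.peak_width - half) - motif.width - 1
            start = int(np.clip(start, lo, hi))
            embeds.append((motif_name, start, word))

        if mclass in ("specific", "both"):
            place(specific, rng.normal(0, spec.summit_jitter_sd))
        if mclass in ("ap1", "both"):
            if mclass == "ap1":
                place("AP1", rng.normal(0, spec.summit_jitter_sd))
            else:
                side = 1 if rng.random() < 0.5 else -1
                place("AP1", side * rng.integers(45, 110))
        sites.append(_Site(chrom, summit, region_class, str(mclass), embeds))
    # acceptance order is grouped by class; randomise so that any prefix of
    # the list (e.g. the core sites a low-expression profile uses) has the
    # requested class and motif composition
    return [sites[i] for i in rng.permutation(len(sites))]


@dataclass
class Landscape:
    """Peak sets per factor plus the ground-truth sidecar table."""

    profile: CellLineProfile
    peaksets: dict[str, PeakSet]
    truth: pd.DataFrame  # factor, peak, chrom, summit, region_class, motif_class, is_core


def _core_pool(spec: LandscapeSpec, placement: PlacementIndex, factor: str) -> list[_Site]:
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, _FACTOR_IDX[factor], 0xC0DE]))
    n_pool = int(round(spec.core_fraction * spec.peaks_per_unit_level
                       * spec.core_pool_max_level))
    return _make_sites(rng, placement, spec, factor, n_pool, [])


def generate_landscape(profile: CellLineProfile, spec: LandscapeSpec, genome: Genome,
                       genes: list[GeneModel],
                       placement: PlacementIndex | None = None) -> Landscape:
    """Generate the per-factor peak sets of one cell line.

    The expected peak count per factor is peaks_per_unit_level x protein
    level: a deterministic core prefix (shared across profiles at the same
    spec seed and genome) plus Poisson-distributed dosage-dependent extras.
    Motif instances are written into the genome sequence at summit +/-
    jitter. A factor at level 0 yields an empty peak set.
    """
    if placement is None:
        placement = PlacementIndex(genome, genes)
    peaksets: dict[str, PeakSet] = {}
    truth_rows = []
    levels = {"Meis1": profile.level_meis1, "Prep1": profile.level_prep1}
    for factor, level in levels.items():
        label = f"{factor}@{profile.name}"
        if level == 0:
            peaksets[factor] = PeakSet(label, [], genome_id=genome.genome_id)
            continue
        expected = spec.peaks_per_unit_level * level
        pool = _core_pool(spec, placement, factor)
        n_core = int(round(spec.core_fraction * expected))
        overflow = max(0, n_core - len(pool))
        n_core = min(n_core, len(pool))
        rng = np.random.default_rng(np.random.SeedSequence(
            [spec.seed, _FACTOR_IDX[factor],
             zlib.crc32(profile.name.encode()) & 0x7FFFFFFF]))
        n_extra = int(rng.poisson(expected - spec.core_fraction * expected)) + overflow
        core_sites = pool[:n_core]
        taken = [placement.offsets[s.chrom] + s.summit for s in pool]
        extra_sites = _make_sites(rng, placement, spec, factor, n_extra, taken)

        # competitive displacement: high Prep1 removes AP-1-class extra
        # Meis1 peaks
        if (factor == "Meis1" and spec.displacement_fraction > 0
                and profile.level_prep1 > spec.displacement_prep1_threshold):
            survivors = []
            for s in extra_sites:
                if s.motif_class == "ap1" and rng.random() < spec.displacement_fraction:
                    continue
                survivors.append(s)
            extra_sites = survivors

        half = spec.peak_width // 2
        peaks = []
        mult = spec.score_multipliers.get(factor, {})
        for i, (site, is_core) in enumerate(
                [(s, True) for s in core_sites] + [(s, False) for s in extra_sites]):
            for motif_name, start, word in site.embeds:
                genome.embed(site.chrom, start, word)
            start = int(np.clip(site.summit - half, 0,
                                genome.length(site.chrom) - spec.peak_width))
            score = float(rng.lognormal(spec.score_mu, spec.score_sigma))
            score *= float(mult.get(site.motif_class, 1.0))
            name = f"{factor}_{profile.name}_{i:05d}"
            peaks.append(Peak(GenomicInterval(site.chrom, start, start + spec.peak_width),
                              site.summit, score, name))
            truth_rows.append((factor, name, site.chrom, site.summit,
                               site.region_class, site.motif_class, is_core))
        peaksets[factor] = PeakSet(label, peaks, genome_id=genome.genome_id)
    truth = pd.DataFrame(truth_rows, columns=["factor", "peak", "chrom", "summit",
                                              "region_class", "motif_class", "is_core"])
    return Landscape(profile, peaksets, truth)


# ---------------------------------------------------------------------------
# Chromatin marks


def generate_marks(genome: Genome, gene_models: list[GeneModel], seed: int = 0,
                   promoter_fraction: float = 0.6, n_enhancers: int | None = None,
                   acetyl_fraction: float = 0.5, enhancer_width: int = 1_500,
                   min_tss_distance: int = 5_000) -> dict[str, list[GenomicInterval]]:
    """Place promoter marks (PolII + H3K4me3) around a subset of TSSs and
    enhancer marks (H3K4me1, a fraction also H3K27ac) at TSS-distal sites."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    marks: dict[str, list[GenomicInterval]] = {m: [] for m in
                                               ("PolII", "H3K4me3", "H3K4me1", "H3K27ac")}
    genes = list(gene_models)
    n_prom = int(round(promoter_fraction * len(genes)))
    chosen = rng.choice(len(genes), size=n_prom, replace=False) if n_prom else []
    for gi in sorted(int(i) for i in np.atleast_1d(chosen)):
        g = genes[gi]
        length = genome.length(g.chrom)
        lo, hi = max(0, g.tss - 1_000), min(length, g.tss + 1_000)
        marks["PolII"].append(GenomicInterval(g.chrom, lo, hi))
        lo, hi = max(0, g.tss - 800), min(length, g.tss + 800)
        marks["H3K4me3"].append(GenomicInterval(g.chrom, lo, hi))

    if n_enhancers is None:
        n_enhancers = len(genes)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}
    chroms = genome.chroms
    placed = 0
    attempts = 0
    while placed < n_enhancers and attempts < 50 * max(1, n_enhancers):
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = genome.length(chrom)
        pos = int(rng.integers(enhancer_width, length - enhancer_width))
        tss = tss_by_chrom.get(chrom)
        if tss is not None and len(tss):
            i = int(np.searchsorted(tss, pos))
            near = min(abs(pos - int(tss[j])) for j in (i - 1, i) if 0 <= j < len(tss))
            if near < min_tss_distance:
                continue
        iv = GenomicInterval(chrom, pos, pos + enhancer_width)
        marks["H3K4me1"].append(iv)
        if rng.random() < acetyl_fraction:
            marks["H3K27ac"].append(iv)
        placed += 1
    return marks


# ---------------------------------------------------------------------------
# Differential expression


def generate_expression(gene_models, bound_genes: set[str], de_spec: DESpec) -> pd.DataFrame:
    """Generate a DE table with ground-truth flags.

    Columns: gene_id, log2fc, p_value plus truth columns true_de, true_up
    and bound. Among bound true-DE genes the up-regulated fraction is
    fraction_up (assigned as an exact count, randomly allocated); unbound
    true-DE genes split 50/50. True-DE p-values ~ Beta(p_alpha, 1), null
    p-values ~ Uniform(0, 1); null log2FC ~ Normal(0, noise_sd) so that
    effect_size = 0 makes DE and non-DE fold changes indistinguishable.
    """
    for name in ("fraction_de", "fraction_bound_de", "fraction_up"):
        v = getattr(de_spec, name)
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    gene_ids = [g.gene_id if isinstance(g, GeneModel) else str(g) for g in gene_models]
    if de_spec.n_genes is not None:
        gene_ids = gene_ids[:de_spec.n_genes]
    n = len(gene_ids)
    cols = ["gene_id", "log2fc", "p_value", "true_de", "true_up", "bound"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(np.random.SeedSequence([de_spec.seed, 23]))
    bound_mask = np.array([g in bound_genes for g in gene_ids])
    n_de = int(round(de_spec.fraction_de * n))
    n_bound_de = int(round(de_spec.fraction_bound_de * n_de))
    bound_idx = np.flatnonzero(bound_mask)
    unbound_idx = np.flatnonzero(~bound_mask)
    if n_bound_de > len(bound_idx):
        warnings.warn(f"only {len(bound_idx)} bound genes available for "
                      f"{n_bound_de} bound-DE slots; capping")
        n_bound_de = len(bound_idx)
    n_unbound_de = min(n_de - n_bound_de, len(unbound_idx))
    de_bound = rng.choice(bound_idx, size=n_bound_de, replace=False) if n_bound_de else []
    de_unbound = rng.choice(unbound_idx, size=n_unbound_de, replace=False) if n_unbound_de else []

    true_de = np.zeros(n, dtype=bool)
    true_de[np.asarray(de_bound, dtype=int)] = True
    true_de[np.asarray(de_unbound, dtype=int)] = True
    true_up = np.zeros(n, dtype=bool)
    n_up_bound = int(round(de_spec.fraction_up * n_bound_de))
    if n_bound_de:
        up_sel = rng.choice(np.asarray(de_bound, dtype=int), size=n_up_bound, replace=False)
        true_up[up_sel] = True
    if n_unbound_de:
        arr = np.asarray(de_unbound, dtype=int)
        up_sel = rng.choice(arr, size=int(round(0.5 * len(arr))), replace=False)
        true_up[up_sel] = True

    log2fc = rng.normal(0.0, de_spec.noise_sd, size=n)
    magnitude = np.abs(rng.normal(de_spec.effect_size, de_spec.noise_sd, size=n))
    sign = np.where(true_up, 1.0, -1.0)
    log2fc = np.where(true_de, sign * magnitude, log2fc)
    p = rng.uniform(0, 1, size=n)
    if de_spec.p_alpha <= 0:
        raise ValueError("p_alpha must be > 0")
    p_de = rng.beta(de_spec.p_alpha, 1.0, size=n)
    p = np.where(true_de, p_de, p)
    p = np.clip(p, 1e-300, 1.0)
    return pd.DataFrame({"gene_id": gene_ids, "log2fc": log2fc, "p_value": p,
                         "true_de": true_de, "true_up": true_up, "bound": bound_mask})


def write_de_table(df: pd.DataFrame, path, include_truth: bool = False) -> None:
    cols = ["gene_id", "log2fc", "p_value"]
    if include_truth:
        cols += [c for c in ("true_de", "true_up", "bound") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)
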