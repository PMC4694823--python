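"""Consensus-motif scanning and per-peak motif classification.

The motifs of interest are short IUPAC consensus sequences: the Meis1
octamer OCTA (TGATXXAT), the Prep1 decamer DECA (TGAXTGACAG), the Meis1
hexamer HEXA (TGACAX) and the Jun/Fos AP-1 heptamer (TGASTCA, the
"TGAC/GTCA" element; S = C or G). X is a wildcard and is treated as N.

Each consensus is bridged to a position weight matrix: degenerate codes
spread probability uniformly over their bases (after pseudocount
smoothing), N/X columns carry the background exactly. Scanning is
FIMO-style: log-odds scores against a 0-order background on both strands,
with the score threshold derived from a match p-value by exact enumeration
of the score distribution under the background. When a motif is so short or
degenerate that even its best score cannot reach the requested p-value
(e.g. OCTA has six informative positions, so its best attainable match
p-value is 4^-6 ~ 2.4e-4), the threshold falls back to the top score so
that exact consensus instances are always detectable; the attained
per-position p-value is exposed as ``PWM.attained_pvalue``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import Genome, Peak, PeakSet

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "X": "ACGT",
}

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class ConsensusMotif:
    name: str
    iupac: str

    def __post_init__(self):
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.name}: illegal IUPAC characters {sorted(bad)}")

    @property
    def width(self) -> int:
        return len(self.iupac)

    def expansions(self) -> list[str]:
        """All exact words matching the consensus."""
        words = [""]
        for ch in self.iupac.upper():
            words = [w + b for w in words for b in IUPAC[ch]]
        return words


#: The motif library: factor-specific consensus sequences plus the AP-1 element.
MOTIF_LIBRARY = {
    "OCTA": ConsensusMotif("OCTA", "TGATXXAT"),
    "DECA": ConsensusMotif("DECA", "TGAXTGACAG"),
    "HEXA": ConsensusMotif("HEXA", "TGACAX"),
    "AP1": ConsensusMotif("AP1", "TGASTCA"),
}

#: Factor-specific consensus used for Table-1-style classification.
SPECIFIC_MOTIF = {"Meis1": "OCTA", "Prep1": "DECA"}

UNIFORM_BG = np.full(4, 0.25)


@dataclass
class MotifHit:
    motif: str
    strand: str
    start: int          # leftmost offset of the match (forward coordinates)
    score: float
    peak: str | None = None
    summit_distance: float | None = None  # hit midpoint minus summit, bp


@dataclass
class PWM:
    """Probability matrix with log-odds scores against a 0-order background."""

    name: str
    matrix: np.ndarray      # (width, 4) probabilities, columns sum to 1
    background: np.ndarray  # (4,) base frequencies

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (width, 4)")
        if np.any(np.abs(self.matrix.sum(axis=1) - 1) > 1e-9):
            raise ValueError("PWM columns must sum to 1")
        self._threshold_cache: dict[float, tuple[float, float]] = {}

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix) - np.log2(self.background)

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def score_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact (score, probability) of every word under the background.

        Enumerates all 4^width words by iterated outer sums; fine for the
        short consensus motifs this package works with (width <= ~10).
        """
        lo = self.log_odds
        scores = np.zeros(1)
        probs = np.ones(1)
        for j in range(self.width):
            scores = (scores[:, None] + lo[j][None, :]).ravel()
            probs = (probs[:, None] * self.background[None, :]).ravel()
        return scores, probs

    def score_threshold(self, p_value: float = 1e-4) -> tuple[float, float]:
        """Smallest score whose upper-tail probability under the background
        is <= p_value; returns (threshold, attained p-value).

        If no score qualifies, returns the top score with its tail
        probability (the motif's minimum attainable p-value).
        """
        if not (0 < p_value <= 1):
            raise ValueError("p_value must be in (0, 1]")
        if p_value in self._threshold_cache:
            return self._threshold_cache[p_value]
        scores, probs = self.score_distribution()
        scores = np.round(scores, 9)
        order = np.argsort(scores)[::-1]
        s_sorted = scores[order]
        tail = np.cumsum(probs[order])
        uniq, last_idx = np.unique(-s_sorted, return_index=True)
        # last occurrence of each unique score in the descending array
        uniq_scores = -uniq
        bounds = np.append(last_idx[1:], len(s_sorted)) - 1
        uniq_tail = tail[bounds]
        ok = uniq_tail <= p_value
        if np.any(ok):
            k = int(np.max(np.nonzero(ok)[0]))
        else:
            k = 0  # fall back to exact best matches
        result = (float(uniq_scores[k]), float(uniq_tail[k]))
        self._threshold_cache[p_value] = result
        return result

    def attained_pvalue(self, p_value: float = 1e-4) -> float:
        return self.score_threshold(p_value)[1]


def consensus_to_pwm(motif: ConsensusMotif, background=UNIFORM_BG,
                     pseudocount: float = 0.1) -> PWM:
    """Build a PWM from an IUPAC consensus.

    Each degenerate code spreads probability uniformly over its bases,
    smoothed with ``pseudocount`` weighted by the background; N/X columns
    carry the background exactly (log-odds 0 everywhere).
    """
    bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    rows = []
    for ch in motif.iupac.upper():
        bases = IUPAC[ch]
        if len(bases) == 4:
            rows.append(bg.copy())
            continue
        counts = np.zeros(4)
        for b in bases:
            counts[_CODE[b]] = 1.0 / len(bases)
        rows.append((counts + pseudocount * bg) / (1.0 + pseudocount))
    return PWM(motif.name, np.array(rows), bg)


def estimate_background(sequences) -> np.ndarray:
    """0-order, strand-symmetric base frequencies from a set of sequences."""
    counts = np.zeros(4)
    for seq in sequences:
        for b, i in _CODE.items():
            counts[i] += seq.upper().count(b)
    if counts.sum() == 0:
        return UNIFORM_BG.copy()
    counts = (counts + counts[::-1]) / 2.0  # A<->T, C<->G symmetry
    return counts / counts.sum()


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3; any other character as 4 (treated as N)."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _CODE.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)]


def _window_scores(lo: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Per-offset PWM scores over a coded sequence; NaN where a window
    contains N."""
    w = lo.shape[0]
    lo5 = np.hstack([lo, np.full((w, 1), np.nan)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return lo5[np.arange(w)[None, :], windows].sum(axis=1)


def scan_sequence(pwm: PWM, sequence: str, p_threshold: float = 1e-4) -> list[MotifHit]:
    """Report PWM matches on both strands of a sequence.

    Offsets are leftmost positions in forward-strand coordinates. Windows
    containing N are skipped; sequences shorter than the motif yield no hits.
    """
    w = pwm.width
    if len(sequence) < w:
        return []
    threshold, _ = pwm.score_threshold(p_threshold)
    codes = encode_sequence(sequence)
    lo = pwm.log_odds
    lo_rc = lo[::-1, ::-1]
    hits = []
    for strand, mat in (("+", lo), ("-", lo_rc)):
        scores = _window_scores(mat, codes)
        # small epsilon so float round-off cannot drop boundary-score matches
        for off in np.nonzero(scores >= threshold - 1e-9)[0]:
            hits.append(MotifHit(pwm.name, strand, int(off), float(scores[off])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def peak_window(peak: Peak, genome: Genome, window: int = 300) -> tuple[int, str]:
    """Fixed-width window centred on the summit, truncated at contig edges.

    Returns (window start coordinate, sequence).
    """
    half = window // 2
    lo = max(0, peak.summit - half)
    hi = min(genome.length(peak.chrom), peak.summit + (window - half))
    return lo, genome.fetch(peak.chrom, lo, hi)


def scan_peakset(peak_set: PeakSet, genome: Genome, motifs=None, window: int = 300,
                 p_threshold: float = 1e-4, background=None) -> list[MotifHit]:
    """Scan summit-centred windows of every peak for the given motifs.

    ``motifs`` may be ConsensusMotif objects, library names, or prebuilt
    PWMs; by default the background is estimated from the scanned windows
    themselves (0-order, strand-symmetric).
    """
    if motifs is None:
        motifs = list(MOTIF_LIBRARY)
    seqs = {}
    for p in peak_set:
        if p.chrom not in genome:
            raise KeyError(f"peak {p.name}: no sequence for chromosome {p.chrom}")
        seqs[p.name] = peak_window(p, genome, window)
    pwms = []
    if background is None:
        background = estimate_background(s for _, s in seqs.values())
    for m in motifs:
        if isinstance(m, PWM):
            pwms.append(m)
        else:
            if isinstance(m, str):
                m = MOTIF_LIBRARY[m]
            pwms.append(consensus_to_pwm(m, background))
    hits = []
    for p in peak_set:
        win_start, seq = seqs[p.name]
        for pwm in pwms:
            for h in scan_sequence(pwm, seq, p_threshold):
                pos = win_start + h.start
                mid = pos + (pwm.width - 1) / 2.0
                hits.append(replace(h, start=pos, peak=p.name,
                                    summit_distance=mid - p.summit))
    return hits


@dataclass
class MotifClassTable:
    """Per-peak motif content and Table-1-style set-level percentages.

    A peak may carry both the factor-specific consensus and AP-1, so the
    specific and AP-1 counts can sum to more than the number of peaks.
    """

    label: str
    factor: str
    specific_motif: str
    table: pd.DataFrame  # peak, has_specific, has_ap1, both, neither
    hits: list[MotifHit] = field(default_factory=list, repr=False)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def counts(self) -> dict[str, int]:
        t = self.table
        return {
            "specific": int(t["has_specific"].sum()),
            "ap1": int(t["has_ap1"].sum()),
            "both": int(t["both"].sum()),
            "neither": int(t["neither"].sum()),
        }

    @property
    def percentages(self) -> dict[str, float]:
        if not self.n:
            return {k: float("nan") for k in self.counts}
        return {k: 100.0 * v / self.n for k, v in self.counts.items()}


def classify_peaks(peak_set: PeakSet, genome: Genome, factor: str, window: int = 300,
                   p_threshold: float = 1e-4, background=None) -> MotifClassTable:
    """Classify each peak by motif content: the factor-specific consensus
    (OCTA for Meis1, DECA for Prep1) and the AP-1 element.

    Sequences are fixed-width windows centred on the summit. Multiple hits of
    one motif in one peak collapse to presence/absence for classification;
    all hits (with summit distances) are kept on the result for positional
    profiles.
    """
    if factor not in SPECIFIC_MOTIF:
        raise ValueError(f"unknown factor {factor!r}; expected one of {list(SPECIFIC_MOTIF)}")
    specific = SPECIFIC_MOTIF[factor]
    hits = scan_peakset(peak_set, genome, [specific, "AP1"], window, p_threshold, background)
    by_peak: dict[str, set[str]] = {p.name: set() for p in peak_set}
    for h in hits:
        by_peak[h.peak].add(h.motif)
    rows = []
    for p in peak_set:
        has_spec = specific in by_peak[p.name]
        has_ap1 = "AP1" in by_peak[p.name]
        rows.append((p.name, has_spec, has_ap1, has_spec and has_ap1,
                     not has_spec and not has_ap1))
    table = pd.DataFrame(rows, columns=["peak", "has_specific", "has_ap1", "both", "neither"])
    return MotifClassTable(peak_set.label, factor, specific, table, hits)


def summit_profile(hits: list[MotifHit], window: int = 150, bin_width: int = 10):
    """Histogram of hit-midpoint distance to the peak summit, binned
    symmetrically around 0 within +/- window.

    Returns (counts, edges); counts sum to the number of hits within the
    window.
    """
    n_bins = int(np.ceil(window / bin_width))
    edges = np.arange(-n_bins, n_bins + 1) * bin_width
    dists = [h.summit_distance for h in hits if h.summit_distance is not None]
    counts, _ = np.histogram(dists, bins=edges)
    return counts, edges


def summit_coincident_subset(peak_set: PeakSet, genome: Genome, window: int = 30,
                             scan_window: int = 300, p_threshold: float = 1e-4,
                             background=None, anchor: str = "midpoint") -> PeakSet:
    """Peaks with an AP-1 hit centred at the peak midpoint (+/- window bp)
    and no OCTA hit anywhere in the scanned sequence.

    ``anchor`` selects the reference point the AP-1 hit must coincide with:
    the peak interval midpoint (default) or the summit.
    """
    if anchor not in ("midpoint", "summit"):
        raise ValueError("anchor must be 'midpoint' or 'summit'")
    hits = scan_peakset(peak_set, genome, ["AP1", "OCTA"], scan_window, p_threshold, background)
    ap1_mid: dict[str, list[float]] = {}
    has_octa: set[str] = set()
    for h in hits:
        if h.motif == "AP1":
            ap1_mid.setdefault(h.peak, []).append(h.start + (MOTIF_LIBRARY["AP1"].width - 1) / 2.0)
        else:
            has_octa.add(h.peak)
    selected = []
    for p in peak_set:
        if p.name in has_octa or p.name not in ap1_mid:
            continue
        ref = p.midpoint if anchor == "midpoint" else p.summit
        if any(abs(mid - ref) <= window for mid in ap1_mid[p.name]):
            selected.append(p)
    return PeakSet(f"{peak_set.label}_ap1_summit", selected, genome_id=peak_set.genome_id)


def score_by_motif_class(peak_set: PeakSet, class_table: MotifClassTable) -> dict:
    """Peak-score summaries per motif class plus rank-based comparisons.

    Classes are specific-only, AP-1-only and both (peaks with neither are
    summarised but not tested). Pairwise comparisons use the two-sided
    Mann-Whitney rank-sum test; classes with fewer than 2 peaks are skipped
    with a warning.
    """
    scores = {p.name: p.score for p in peak_set}
    t = class_table.table
    groups = {
        "specific_only": t.loc[t["has_specific"] & ~t["has_ap1"], "peak"],
        "ap1_only": t.loc[t["has_ap1"] & ~t["has_specific"], "peak"],
        "both": t.loc[t["both"], "peak"],
        "neither": t.loc[t["neither"], "peak"],
    }
    values = {k: np.array([scores[name] for name in v]) for k, v in groups.items()}
    summaries = {}
    for k, v in values.items():
        if len(v):
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            summaries[k] = {"n": int(len(v)), "median": float(med),
                            "iqr": [float(q1), float(q3)]}
        else:
            summaries[k] = {"n": 0, "median": float("nan"), "iqr": [float("nan")] * 2}
    tests = {}
    tested = ("specific_only", "ap1_only", "both")
    for i, ka in enumerate(tested):
        for kb in tested[i + 1:]:
            if len(values[ka]) < 2 or len(values[kb]) < 2:
                warnings.warn(f"score comparison {ka} vs {kb} skipped: class with <2 peaks")
                continue
            res = stats.mannwhitneyu(values[ka], values[kb], alternative="two-sided")
            tests[f"{ka}_vs_{kb}"] = {"statistic": float(res.statistic),
                                      "p_value": float(res.pvalue)}
    return {"summaries": summaries, "tests": tests}
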