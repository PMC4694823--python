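"""Inter-peak-set overlap (reciprocal 50% rule) and chromatin-state partition.

Two peaks count as overlapping when their intersection covers at least
``min_frac`` of a reference length (default: the shorter peak, the strictest
symmetric reading of "50% or more overlapping sequences"). Peaks are
partitioned into chromatin states from promoter (PolII + H3K4me3), enhancer
(H3K4me1) and bivalent-enhancer (H3K4me1 + H3K27ac) mark regions with
precedence promoter > bivalent_enhancer > enhancer, so the states are
exclusive and their fractions well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .core import GenomicInterval, Peak, PeakSet

FRAC_OF = ("shorter", "either", "both", "a", "b")

MARK_TRACKS = ("PolII", "H3K4me3", "H3K4me1", "H3K27ac")

CHROM_STATES = ("promoter", "bivalent_enhancer", "enhancer", "none")


def peaks_overlap(a: Peak, b: Peak, min_frac: float = 0.5, frac_of: str = "shorter") -> bool:
    """True iff a and b overlap by at least min_frac of the reference length.

    frac_of selects the denominator: 'shorter' (== 'either'; intersection >=
    min_frac of the shorter peak), 'both' (of the longer, i.e. the rule must
    hold for both peaks), 'a' or 'b'. With min_frac == 0 any 1-bp overlap
    qualifies. Peaks on different chromosomes never overlap.
    """
    if frac_of not in FRAC_OF:
        raise ValueError(f"frac_of must be one of {FRAC_OF}")
    inter = a.interval.intersection_length(b.interval)
    if inter <= 0:
        return False
    if frac_of in ("shorter", "either"):
        denom = min(a.length, b.length)
    elif frac_of == "both":
        denom = max(a.length, b.length)
    elif frac_of == "a":
        denom = a.length
    else:
        denom = b.length
    return inter >= min_frac * denom


@dataclass
class OverlapResult:
    """Counts of peaks in each set having at least one qualifying partner."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    n_a_overlapping: int
    n_b_overlapping: int
    pairs: list[tuple[str, str]] = field(default_factory=list, repr=False)

    @property
    def frac_a(self) -> float:
        return self.n_a_overlapping / self.n_a if self.n_a else float("nan")

    @property
    def frac_b(self) -> float:
        return self.n_b_overlapping / self.n_b if self.n_b else float("nan")

    def venn(self) -> dict[str, int]:
        """Venn counts reported from each side (the 'both' region generally
        differs between sides because overlap is not one-to-one)."""
        return {
            "a_only": self.n_a - self.n_a_overlapping,
            "a_both": self.n_a_overlapping,
            "b_only": self.n_b - self.n_b_overlapping,
            "b_both": self.n_b_overlapping,
        }


def overlap_peaksets(A: PeakSet, B: PeakSet, min_frac: float = 0.5,
                     frac_of: str = "shorter", keep_pairs: bool = True) -> OverlapResult:
    """All qualifying overlap pairs between two peak sets.

    Equivalent to brute-force all-pairs evaluation of :func:`peaks_overlap`;
    candidate pairs are pruned with a per-chromosome interval tree.
    """
    trees: dict[str, IntervalTree] = {}
    for j, b in enumerate(B):
        trees.setdefault(b.chrom, IntervalTree())[b.start:b.end] = j
    a_hit: set[int] = set()
    b_hit: set[int] = set()
    pairs: list[tuple[str, str]] = []
    for i, a in enumerate(A):
        tree = trees.get(a.chrom)
        if tree is None:
            continue
        for iv in sorted(tree[a.start:a.end], key=lambda iv: iv.data):
            b = B[iv.data]
            if peaks_overlap(a, b, min_frac, frac_of):
                a_hit.add(i)
                b_hit.add(iv.data)
                if keep_pairs:
                    pairs.append((a.name, b.name))
    return OverlapResult(A.label, B.label, len(A), len(B), len(a_hit), len(b_hit), pairs)


@dataclass
class ChromStateResult:
    label: str
    table: pd.DataFrame  # peak, state
    fractions: dict[str, float] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        vc = self.table["state"].value_counts()
        return {s: int(vc.get(s, 0)) for s in CHROM_STATES}


def _region_trees(regions: list[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree())[r.start:r.end] = True
    return trees


def _peak_in_marks(peak: Peak, trees: dict[str, IntervalTree], min_frac: float) -> bool:
    tree = trees.get(peak.chrom)
    if tree is None:
        return False
    need = max(1.0, min_frac * peak.length)
    for iv in tree[peak.start:peak.end]:
        inter = min(peak.end, iv.end) - max(peak.start, iv.begin)
        if inter >= need:
            return True
    return False


def chrom_state_partition(peak_set: PeakSet, marks: dict[str, list[GenomicInterval]],
                          min_frac: float = 0.0) -> ChromStateResult:
    """Partition peaks into promoter/enhancer/bivalent_enhancer/none states.

    ``marks`` must contain all four tracks (PolII, H3K4me3, H3K4me1, H3K27ac);
    empty region lists are allowed. By default a peak carries a mark when it
    overlaps a mark region by at least one bp (marks are broad domains); a
    fraction-of-peak rule is available via ``min_frac``.
    """
    for track in MARK_TRACKS:
        if track not in marks:
            raise KeyError(f"missing chromatin-mark track {track!r}")
    trees = {track: _region_trees(marks[track]) for track in MARK_TRACKS}
    rows = []
    for p in peak_set:
        polii = _peak_in_marks(p, trees["PolII"], min_frac)
        k4me3 = _peak_in_marks(p, trees["H3K4me3"], min_frac)
        k4me1 = _peak_in_marks(p, trees["H3K4me1"], min_frac)
        k27ac = _peak_in_marks(p, trees["H3K27ac"], min_frac)
        if polii and k4me3:
            state = "promoter"
        elif k4me1 and k27ac:
            state = "bivalent_enhancer"
        elif k4me1:
            state = "enhancer"
        else:
            state = "none"
        rows.append((p.name, state))
    table = pd.DataFrame(rows, columns=["peak", "state"])
    if len(table):
        fractions = {s: float((table["state"] == s).mean()) for s in CHROM_STATES}
    else:
        warnings.warn(f"{peak_set.label}: empty peak set, state fractions undefined")
        fractions = {s: float("nan") for s in CHROM_STATES}
    return ChromStateResult(peak_set.label, table, fractions)
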