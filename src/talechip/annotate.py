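"""Genomic-location classification of peaks and target-gene assignment.

Peaks are partitioned, by their summit, into four exclusive location classes:

* TSSA — summit within -500..+100 bp of a TSS (strand-aware, in the
  direction of transcription);
* IG   — summit inside a transcription unit;
* CI   — intergenic, nearest TSS closer than 20 kb;
* FI   — intergenic, nearest TSS 20 kb or farther.

Precedence is TSSA > IG > CI/FI, so a summit inside a gene body but also
inside a TSSA window counts as TSSA. The class boundaries are the defaults of
:class:`AnnotationConfig` and are configurable.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GeneModel, Peak, PeakSet

REGION_CLASSES = ("TSSA", "IG", "CI", "FI")


@dataclass(frozen=True)
class AnnotationConfig:
    tssa_upstream: int = 500      # bp upstream of the TSS in the TSSA window
    tssa_downstream: int = 100    # bp downstream
    ci_cutoff: int = 20_000       # nearest-TSS distance separating CI from FI
    missing_chrom: str = "warn"   # peaks on unannotated chromosomes: warn -> FI


def tssa_window(gene: GeneModel, cfg: AnnotationConfig = AnnotationConfig()) -> tuple[int, int]:
    """Half-open genome-coordinate extent of the gene's TSSA window."""
    if gene.strand == "+":
        return gene.tss - cfg.tssa_upstream, gene.tss + cfg.tssa_downstream + 1
    return gene.tss - cfg.tssa_downstream, gene.tss + cfg.tssa_upstream + 1


class GeneIndex:
    """Per-chromosome lookup structures over a set of gene models."""

    def __init__(self, genes: list[GeneModel], cfg: AnnotationConfig = AnnotationConfig()):
        if not genes:
            raise ValueError("gene annotation is empty")
        self.cfg = cfg
        self.genes = list(genes)
        self._body: dict[str, IntervalTree] = {}
        self._tssa: dict[str, IntervalTree] = {}
        self._tss: dict[str, np.ndarray] = {}
        self._tss_genes: dict[str, list[GeneModel]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gg in by_chrom.items():
            body = IntervalTree()
            tssa = IntervalTree()
            for g in gg:
                body[g.interval.start:g.interval.end] = g
                lo, hi = tssa_window(g, cfg)
                tssa[lo:hi] = g
            self._body[chrom] = body
            self._tssa[chrom] = tssa
            order = sorted(gg, key=lambda g: (g.tss, g.gene_id))
            self._tss[chrom] = np.array([g.tss for g in order])
            self._tss_genes[chrom] = order

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._tss

    def nearest_tss_gene(self, chrom: str, pos: int) -> tuple[GeneModel, int]:
        """Gene with the TSS nearest to pos (ties broken by lexicographic
        gene_id) and the unsigned distance."""
        tss = self._tss[chrom]
        i = int(np.searchsorted(tss, pos))
        candidates = []
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(tss):
                candidates.append((abs(int(tss[j]) - pos), self._tss_genes[chrom][j].gene_id, j))
        # several genes may share a TSS coordinate; widen to all with the
        # minimal distance
        dmin = min(c[0] for c in candidates)
        lo = bisect.bisect_left(tss, pos - dmin)
        hi = bisect.bisect_right(tss, pos + dmin)
        best = min(
            ((abs(int(tss[j]) - pos), self._tss_genes[chrom][j].gene_id, j) for j in range(lo, hi)),
        )
        return self._tss_genes[chrom][best[2]], best[0]

    def tssa_genes(self, chrom: str, pos: int) -> list[GeneModel]:
        return sorted((iv.data for iv in self._tssa[chrom][pos]), key=lambda g: g.gene_id)

    def containing_genes(self, chrom: str, pos: int) -> list[GeneModel]:
        return sorted((iv.data for iv in self._body[chrom][pos]), key=lambda g: g.gene_id)


def signed_tss_distance(pos: int, gene: GeneModel) -> int:
    """Distance from pos to the gene's TSS, positive downstream (in the
    direction of transcription), negative upstream."""
    return pos - gene.tss if gene.strand == "+" else gene.tss - pos


def _as_index(gene_models, cfg: AnnotationConfig) -> GeneIndex:
    if isinstance(gene_models, GeneIndex):
        return gene_models
    return GeneIndex(list(gene_models), cfg)


def classify_peak(peak: Peak, gene_models, cfg: AnnotationConfig = AnnotationConfig()) -> str:
    """Classify one peak (anchored at its summit) into TSSA/IG/CI/FI."""
    index = _as_index(gene_models, cfg)
    cfg = index.cfg
    chrom, pos = peak.chrom, peak.summit
    if not index.has_chrom(chrom):
        if cfg.missing_chrom == "error":
            raise KeyError(f"peak {peak.name}: chromosome {chrom} absent from annotation")
        warnings.warn(f"peak {peak.name}: chromosome {chrom} absent from annotation; "
                      "classified FI")
        return "FI"
    if index.tssa_genes(chrom, pos):
        return "TSSA"
    if index.containing_genes(chrom, pos):
        return "IG"
    _, dist = index.nearest_tss_gene(chrom, pos)
    return "CI" if dist < cfg.ci_cutoff else "FI"


@dataclass
class AnnotationResult:
    label: str
    table: pd.DataFrame  # peak, chrom, summit, region_class, nearest_gene, tss_distance
    fractions: dict[str, float] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        vc = self.table["region_class"].value_counts()
        return {c: int(vc.get(c, 0)) for c in REGION_CLASSES}


def annotate_peakset(peak_set: PeakSet, gene_models,
                     cfg: AnnotationConfig = AnnotationConfig()) -> AnnotationResult:
    """Classify every peak and report per-class fractions.

    Empty peak sets yield an empty table with fractions set to NaN.
    """
    index = _as_index(gene_models, cfg)
    rows = []
    for p in peak_set:
        cls = classify_peak(p, index)
        if index.has_chrom(p.chrom):
            gene, _ = index.nearest_tss_gene(p.chrom, p.summit)
            dist = signed_tss_distance(p.summit, gene)
            gene_id = gene.gene_id
        else:
            gene_id, dist = "", np.nan
        rows.append((p.name, p.chrom, p.summit, cls, gene_id, dist))
    table = pd.DataFrame(rows, columns=["peak", "chrom", "summit", "region_class",
                                        "nearest_gene", "tss_distance"])
    if len(table):
        fractions = {c: float((table["region_class"] == c).mean()) for c in REGION_CLASSES}
    else:
        warnings.warn(f"{peak_set.label}: empty peak set, class fractions undefined")
        fractions = {c: float("nan") for c in REGION_CLASSES}
    return AnnotationResult(peak_set.label, table, fractions)


def tss_distance_histogram(peak_set: PeakSet, gene_models, bin_edges,
                           cfg: AnnotationConfig = AnnotationConfig()):
    """Histogram of signed summit-to-nearest-TSS distances.

    Returns (counts, edges) where counts has len(edges)+1 entries: the first
    and last are open-ended bins below the first / at-or-above the last edge,
    so the counts always sum to the number of peaks.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    index = _as_index(gene_models, cfg)
    dists = []
    for p in peak_set:
        if not index.has_chrom(p.chrom):
            continue
        gene, _ = index.nearest_tss_gene(p.chrom, p.summit)
        dists.append(signed_tss_distance(p.summit, gene))
    full_edges = np.concatenate(([-np.inf], edges, [np.inf]))
    counts, _ = np.histogram(dists, bins=full_edges)
    return counts, edges


def assign_target_genes(peak_set: PeakSet, gene_models,
                        cfg: AnnotationConfig = AnnotationConfig()):
    """Assign each peak to a target gene and report the target-gene set.

    A peak targets the gene whose transcription unit contains its summit;
    otherwise the gene with the nearest TSS. Ties (several containing genes,
    or equidistant TSSs) are broken by lexicographic gene_id. Returns
    (mapping gene_id -> list of peak names, set of target gene_ids).
    """
    index = _as_index(gene_models, cfg)
    targets: dict[str, list[str]] = {}
    for p in peak_set:
        if not index.has_chrom(p.chrom):
            continue
        containing = index.containing_genes(p.chrom, p.summit)
        if containing:
            if len(containing) > 1:
                gene = min(containing,
                           key=lambda g: (abs(signed_tss_distance(p.summit, g)), g.gene_id))
            else:
                gene = containing[0]
        else:
            gene, _ = index.nearest_tss_gene(p.chrom, p.summit)
        targets.setdefault(gene.gene_id, []).append(p.name)
    return targets, set(targets)
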