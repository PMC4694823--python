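"""Hypergeometric term enrichment and the dosage-binding linear fit."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class TermDatabase:
    """Mapping of annotation terms to gene sets over an explicit universe.

    The universe (background gene list) must be supplied explicitly: the
    choice of background is a known sensitivity of enrichment analysis.
    """

    terms: dict[str, set[str]]
    universe: set[str]
    names: dict[str, str] | None = None

    def __post_init__(self):
        for term_id, genes in self.terms.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(f"term {term_id}: {len(extra)} genes outside universe")

    @classmethod
    def from_tsv(cls, terms_path: str | Path, universe_path: str | Path,
                 names_path: str | Path | None = None) -> "TermDatabase":
        """Two-column TSV (term_id, gene_id), a one-gene-per-line universe
        file, and an optional (term_id, name) TSV."""
        with open(universe_path) as fh:
            universe = {line.strip() for line in fh if line.strip()}
        terms: dict[str, set[str]] = {}
        with open(terms_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{terms_path}: line {lineno}: expected term<TAB>gene")
                terms.setdefault(fields[0], set()).add(fields[1])
        names = None
        if names_path is not None:
            names = {}
            with open(names_path) as fh:
                for line in fh:
                    if line.strip():
                        term_id, name = line.rstrip("\n").split("\t")[:2]
                        names[term_id] = name
        return cls(terms, universe, names)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) of drawing k or more
    term genes in a signature of size n from a universe of N containing K
    term genes."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(signature: set[str], term_db: TermDatabase,
                         p_cutoff: float = 1e-4) -> pd.DataFrame:
    """Rank terms by upper-tail hypergeometric enrichment in a signature.

    Signature genes outside the universe are dropped with a warning. Rows
    with raw p < p_cutoff carry enriched=True (the raw-p convention of
    GOrilla-style analyses); Benjamini-Hochberg q-values are reported
    alongside.
    """
    if not term_db.universe:
        raise ValueError("empty gene universe")
    sig = set(signature) & term_db.universe
    dropped = len(set(signature)) - len(sig)
    if dropped:
        warnings.warn(f"{dropped} signature genes outside the universe were dropped")
    N, n = len(term_db.universe), len(sig)
    rows = []
    for term_id, genes in term_db.terms.items():
        K = len(genes)
        k = len(sig & genes)
        p = hypergeom_pvalue(k, K, n, N)
        expected = K * n / N if N else float("nan")
        ratio = (k / expected) if expected > 0 else float("nan")
        name = (term_db.names or {}).get(term_id, term_id)
        rows.append((term_id, name, k, K, n, N, p, ratio))
    df = pd.DataFrame(rows, columns=["term_id", "name", "k", "K", "n", "N",
                                     "p_value", "enrichment_ratio"])
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["q_value"] = pd.Series(dtype=float)
    df["enriched"] = df["p_value"] < p_cutoff
    return df.sort_values(["p_value", "term_id"]).reset_index(drop=True)


@dataclass
class DosageFit:
    """Least-squares line through (relative protein level, peak count)."""

    slope: float
    intercept: float
    correlation: float
    levels: np.ndarray
    counts: np.ndarray

    @property
    def residuals(self) -> np.ndarray:
        return self.counts - (self.slope * self.levels + self.intercept)


def dosage_binding_fit(points) -> DosageFit:
    """Fit peak count vs relative protein level across cell lines.

    ``points`` is an iterable of (level, peak_count). At least two points
    with distinct levels are required.
    """
    pts = list(points)
    if len(pts) < 2:
        raise ValueError("dosage fit needs at least two (level, count) points")
    levels = np.array([p[0] for p in pts], dtype=float)
    counts = np.array([p[1] for p in pts], dtype=float)
    if np.allclose(levels, levels[0]):
        raise ValueError("degenerate dosage fit: all protein levels equal")
    res = stats.linregress(levels, counts)
    r = res.rvalue if not np.isnan(res.rvalue) else 0.0
    return DosageFit(float(res.slope), float(res.intercept), float(r), levels, counts)
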