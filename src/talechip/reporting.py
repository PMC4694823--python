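"""Fraction/ratio reporting helpers and Table-style motif summaries."""

from __future__ import annotations

import pandas as pd

from .motifs import MotifClassTable


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Percentage of count over total, rounded to the given precision."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


def fold_ratio(a: float, b: float, decimals: int = 1) -> float:
    """a/b rounded to the given precision (e.g. peak-count fold changes)."""
    if b == 0:
        raise ValueError("denominator must be nonzero")
    return round(a / b, decimals)


def motif_class_report(tables: list[MotifClassTable]) -> pd.DataFrame:
    """Table-style motif composition summary across (factor, cell line)
    peak sets: peak counts and the percentage carrying the factor-specific
    consensus and/or AP-1 (a peak can carry both, so percentages can sum to
    more than 100)."""
    rows = []
    for t in tables:
        c = t.counts
        rows.append({
            "peak_set": t.label,
            "factor": t.factor,
            "specific_motif": t.specific_motif,
            "n_peaks": t.n,
            "n_specific": c["specific"],
            "pct_specific": percentage(c["specific"], t.n) if t.n else float("nan"),
            "n_ap1": c["ap1"],
            "pct_ap1": percentage(c["ap1"], t.n) if t.n else float("nan"),
            "n_both": c["both"],
            "pct_both": percentage(c["both"], t.n) if t.n else float("nan"),
        })
    return pd.DataFrame(rows)
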