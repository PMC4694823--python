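"""Independent brute-force oracles used to validate the package's
optimised implementations. These deliberately avoid the code paths they
check."""

from __future__ import annotations

import math

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_force_overlap_counts(peaks_a, peaks_b, min_frac=0.5, frac_of="shorter"):
    """All-pairs O(n^2) evaluation of the reciprocal-overlap rule.

    Returns (n_a_overlapping, n_b_overlapping, set of qualifying (i, j))."""
    a_hit, b_hit, pairs = set(), set(), set()
    for i, a in enumerate(peaks_a):
        for j, b in enumerate(peaks_b):
            if a.chrom != b.chrom:
                continue
            inter = min(a.end, b.end) - max(a.start, b.start)
            if inter <= 0:
                continue
            la, lb = a.end - a.start, b.end - b.start
            if frac_of in ("shorter", "either"):
                denom = min(la, lb)
            elif frac_of == "both":
                denom = max(la, lb)
            elif frac_of == "a":
                denom = la
            else:
                denom = lb
            if inter >= min_frac * denom:
                a_hit.add(i)
                b_hit.add(j)
                pairs.add((i, j))
    return len(a_hit), len(b_hit), pairs


def naive_scan(log_odds, sequence, threshold):
    """Exhaustive per-position, per-strand PWM scoring with plain Python.

    log_odds is a (width, 4) array-like over A,C,G,T. Returns a set of
    (strand, offset) with score >= threshold; windows containing characters
    outside ACGT are skipped."""
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = len(log_odds)
    seq = sequence.upper()
    hits = set()
    for off in range(len(seq) - w + 1):
        window = seq[off:off + w]
        if any(c not in base_index for c in window):
            continue
        fwd = sum(log_odds[j][base_index[c]] for j, c in enumerate(window))
        rc = "".join(COMPLEMENT[c] for c in reversed(window))
        rev = sum(log_odds[j][base_index[c]] for j, c in enumerate(rc))
        if fwd >= threshold - 1e-9:
            hits.add(("+", off))
        if rev >= threshold - 1e-9:
            hits.add(("-", off))
    return hits


def hypergeom_upper_tail(k, K, n, N):
    """P(X >= k) by direct pmf enumeration with exact integer arithmetic."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total


def set_subtraction_oracle(base, subtract_sets):
    """Signature set algebra by element-wise membership tests."""
    return {g for g in base if not any(g in s for s in subtract_sets)}
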