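"""ChIP x RNA integration: direct-target selection and gene signatures.

A signature is the set of genes both bound by a factor (ChIP target genes)
and upregulated in the matching expression contrast (vs the empty-vector
line), minus baseline-shared targets (genes also bound-and-upregulated in
the WT contrast) and, for the single-overexpression signatures, minus the
genes upregulated by both factors in the double-overexpression (MP) line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SIGNATURE_NAMES = ("M-Meis1", "MP-Meis1", "MP-Prep1", "P-Prep1", "MP-common")


@dataclass
class DESelection:
    """Differentially expressed genes split by direction of change."""

    up: set[str]
    down: set[str]
    n_tested: int
    p_cutoff: float

    @property
    def genes(self) -> set[str]:
        return self.up | self.down


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def select_de_genes(de_table: pd.DataFrame, p_cutoff: float = 0.05) -> DESelection:
    """Select genes with p < p_cutoff (strict) and split by log2fc sign.

    Genes with log2fc exactly 0 are excluded with a warning; duplicate
    gene_ids are an error.
    """
    if de_table["gene_id"].duplicated().any():
        dup = de_table.loc[de_table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in DE table: {dup!r}")
    selected = de_table[de_table["p_value"] < p_cutoff]
    zeros = selected[selected["log2fc"] == 0]
    if len(zeros):
        warnings.warn(f"{len(zeros)} selected genes with log2fc == 0 excluded")
    up = set(selected.loc[selected["log2fc"] > 0, "gene_id"])
    down = set(selected.loc[selected["log2fc"] < 0, "gene_id"])
    return DESelection(up, down, len(de_table), p_cutoff)


@dataclass
class BoundDE:
    """Intersection of DE genes with ChIP target genes."""

    bound_de: set[str]
    fraction_bound: float
    up: set[str]
    down: set[str]


def bound_and_de(de_genes: DESelection, target_genes: set[str]) -> BoundDE:
    """Fraction of DE genes directly bound, with the bound set split by
    direction. An empty DE set yields fraction NaN with a warning."""
    de_all = de_genes.genes
    bound = de_all & target_genes
    if not de_all:
        warnings.warn("empty DE gene set; bound fraction undefined")
        frac = float("nan")
    else:
        frac = len(bound) / len(de_all)
    return BoundDE(bound, frac, de_genes.up & target_genes, de_genes.down & target_genes)


@dataclass
class SignatureResult:
    name: str
    genes: set[str]
    n_input: int
    provenance: list[dict] = field(default_factory=list)

    def check(self, subtract_sets: dict[str, set[str]]) -> None:
        """Assert the bookkeeping invariants: telescoping counts and
        disjointness from every subtracted set."""
        removed = sum(step["n_removed"] for step in self.provenance)
        assert self.n_input - removed == len(self.genes), "provenance does not telescope"
        for label, s in subtract_sets.items():
            assert not (self.genes & s), f"signature {self.name} intersects {label}"


def derive_signature(name: str, bound_up: set[str],
                     subtract_sets: dict[str, set[str]]) -> SignatureResult:
    """Subtract each named set in turn from bound_up, recording how many
    genes each step removed from what remained."""
    remaining = set(bound_up)
    provenance = []
    for label, s in subtract_sets.items():
        removed = remaining & s
        remaining -= removed
        provenance.append({"subtracted": label, "set_size": len(s),
                           "n_removed": len(removed)})
    result = SignatureResult(name, remaining, len(bound_up), provenance)
    result.check(subtract_sets)
    return result


def run_signature_suite(target_genes: dict[tuple[str, str], set[str]],
                        de_selections: dict[str, DESelection]) -> dict[str, SignatureResult]:
    """Derive the five signatures from per-(factor, line) target-gene sets
    and per-line DE selections (contrasts vs the empty-vector line).

    Required targets: (Meis1, M), (Meis1, MP), (Meis1, WT), (Prep1, MP),
    (Prep1, P), (Prep1, WT). Required contrasts: M, MP, P, WT.

    * MP-common  = bound-up by Meis1 in MP  AND  bound-up by Prep1 in MP
    * M-Meis1    = bound-up by Meis1 in M  minus (shared with WT) minus MP-common
    * MP-Meis1   = bound-up by Meis1 in MP minus (shared with WT)
    * MP-Prep1   = bound-up by Prep1 in MP minus (shared with WT)
    * P-Prep1    = bound-up by Prep1 in P  minus (shared with WT) minus MP-common

    where "shared with WT" is the intersection with the same factor's
    bound-up set in the WT contrast.
    """
    for contrast in ("M", "MP", "P", "WT"):
        if contrast not in de_selections:
            raise KeyError(f"missing expression contrast {contrast!r}")
    for key in (("Meis1", "M"), ("Meis1", "MP"), ("Meis1", "WT"),
                ("Prep1", "MP"), ("Prep1", "P"), ("Prep1", "WT")):
        if key not in target_genes:
            raise KeyError(f"missing target-gene set for factor/line {key!r}")

    def bound_up(factor: str, line: str) -> set[str]:
        return target_genes[(factor, line)] & de_selections[line].up

    mp_common = bound_up("Meis1", "MP") & bound_up("Prep1", "MP")
    results = {
        "MP-common": SignatureResult("MP-common", mp_common, len(mp_common), []),
        "M-Meis1": derive_signature(
            "M-Meis1", bound_up("Meis1", "M"),
            {"shared_with_WT": bound_up("Meis1", "M") & bound_up("Meis1", "WT"),
             "MP-common": mp_common}),
        "MP-Meis1": derive_signature(
            "MP-Meis1", bound_up("Meis1", "MP"),
            {"shared_with_WT": bound_up("Meis1", "MP") & bound_up("Meis1", "WT")}),
        "MP-Prep1": derive_signature(
            "MP-Prep1", bound_up("Prep1", "MP"),
            {"shared_with_WT": bound_up("Prep1", "MP") & bound_up("Prep1", "WT")}),
        "P-Prep1": derive_signature(
            "P-Prep1", bound_up("Prep1", "P"),
            {"shared_with_WT": bound_up("Prep1", "P") & bound_up("Prep1", "WT"),
             "MP-common": mp_common}),
    }
    return results


def write_signature(result: SignatureResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(result.genes):
            fh.write(gene + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
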