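"""End-to-end orchestration: simulate five cell lines, then run annotation,
overlap, chromatin-state, motif, signature and enrichment analyses and write
a report directory."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, enrichment, motifs, overlap, reporting, signatures, simulate
from .core import write_bed, write_gene_annotation

log = logging.getLogger("talechip")


@dataclass
class RunConfig:
    """All analysis thresholds (defaults are the study's stated values) and
    the synthetic-data scale used by the demo."""

    # analysis thresholds
    tssa_upstream: int = 500
    tssa_downstream: int = 100
    ci_cutoff: int = 20_000
    overlap_min_frac: float = 0.5
    motif_p_threshold: float = 1e-4
    peak_window: int = 300
    summit_window: int = 30
    de_p_cutoff: float = 0.05
    enrichment_p_cutoff: float = 1e-4
    # synthetic-data scale
    n_chrom: int = 4
    chrom_length: int = 2_000_000
    n_genes: int = 240
    gc_content: float = 0.5
    genome_margin: int = 150_000
    gene_length_range: tuple = (5_000, 20_000)
    peaks_per_unit_level: float = 400.0
    core_fraction: float = 0.9
    displacement_fraction: float = 0.4
    n_random_terms: int = 25
    seed: int = 0

    def annotation_config(self) -> annotate.AnnotationConfig:
        return annotate.AnnotationConfig(self.tssa_upstream, self.tssa_downstream,
                                         self.ci_cutoff)

    def landscape_spec(self) -> simulate.LandscapeSpec:
        return simulate.LandscapeSpec(
            peaks_per_unit_level=self.peaks_per_unit_level,
            core_fraction=self.core_fraction,
            displacement_fraction=self.displacement_fraction,
            peak_width=self.peak_window,
            seed=self.seed,
        )


def simulate_study(config: RunConfig, de_spec: simulate.DESpec | None = None):
    """Generate genome, gene models, per-line landscapes, marks and
    per-contrast DE tables (contrasts vs the empty-vector line).

    ``de_spec`` provides the expression-table parameters; its seed is
    re-derived per contrast from the run seed.
    """
    genome, genes = simulate.generate_genome(
        n_chrom=config.n_chrom, chrom_length=config.chrom_length,
        n_genes=config.n_genes, gc_content=config.gc_content, seed=config.seed,
        margin=config.genome_margin, gene_length_range=config.gene_length_range)
    placement = simulate.PlacementIndex(genome, genes, config.annotation_config())
    spec = config.landscape_spec()
    landscapes = {}
    for profile in simulate.standard_profiles():
        landscapes[profile.name] = simulate.generate_landscape(
            profile, spec, genome, genes, placement)
    marks = simulate.generate_marks(genome, genes, seed=config.seed)

    targets: dict[tuple[str, str], set[str]] = {}
    cfg = config.annotation_config()
    index = annotate.GeneIndex(genes, cfg)
    for line, landscape in landscapes.items():
        for factor, ps in landscape.peaksets.items():
            if len(ps):
                _, target_set = annotate.assign_target_genes(ps, index)
            else:
                target_set = set()
            targets[(factor, line)] = target_set

    template = de_spec or simulate.DESpec()
    de_tables = {}
    for i, contrast in enumerate(("WT", "M", "MP", "P")):
        bound = targets.get(("Meis1", contrast), set()) | targets.get(("Prep1", contrast), set())
        spec_i = replace(template, seed=config.seed * 101 + i + 1)
        de_tables[contrast] = simulate.generate_expression(genes, bound, spec_i)
    return genome, genes, landscapes, marks, targets, de_tables


def signature_truth(target_genes: dict[tuple[str, str], set[str]],
                    de_tables: dict[str, pd.DataFrame]) -> dict[str, set[str]]:
    """Ground-truth signatures from the generator's truth flags, using the
    same set algebra as the pipeline."""
    def bound_up(factor, line):
        t = de_tables[line]
        up = set(t.loc[t["true_de"] & t["true_up"], "gene_id"])
        return target_genes[(factor, line)] & up

    mp_common = bound_up("Meis1", "MP") & bound_up("Prep1", "MP")
    return {
        "MP-common": mp_common,
        "M-Meis1": bound_up("Meis1", "M") - bound_up("Meis1", "WT") - mp_common,
        "MP-Meis1": bound_up("Meis1", "MP") - bound_up("Meis1", "WT"),
        "MP-Prep1": bound_up("Prep1", "MP") - bound_up("Prep1", "WT"),
        "P-Prep1": bound_up("Prep1", "P") - bound_up("Prep1", "WT") - mp_common,
    }


def build_toy_term_database(universe: set[str], pathway_sets: dict[str, set[str]],
                            seed: int = 0, n_random_terms: int = 25,
                            term_size: tuple[int, int] = (20, 80),
                            pathway_coverage: float = 0.7) -> enrichment.TermDatabase:
    """A small synthetic ontology: random terms plus one term per supplied
    pathway set covering ~70% of its genes (padded with random genes)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    genes = np.array(sorted(universe))
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for i in range(n_random_terms):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        term_id = f"TERM:{i:04d}"
        terms[term_id] = set(rng.choice(genes, size=min(size, len(genes)), replace=False))
        names[term_id] = f"random process {i}"
    for j, (label, members) in enumerate(sorted(pathway_sets.items())):
        members = sorted(members & universe)
        if not members:
            continue
        k = max(1, int(round(pathway_coverage * len(members))))
        chosen = set(rng.choice(np.array(members), size=k, replace=False))
        pad = int(rng.integers(5, 20))
        chosen |= set(rng.choice(genes, size=pad, replace=False))
        term_id = f"PATH:{j:04d}"
        terms[term_id] = chosen
        names[term_id] = f"pathway emulating {label}"
    return enrichment.TermDatabase(terms, set(universe), names)


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_demo(seed: int, outdir: str | Path, config: RunConfig | None = None) -> dict:
    """Simulate the five-cell-line study and run the full analysis chain,
    writing TSV/JSON outputs plus a summary report. Deterministic per seed.
    Returns the report dictionary."""
    config = config or RunConfig()
    if config.seed != seed:
        config = RunConfig(**{**asdict(config), "seed": seed})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("demo: %s", json.dumps(asdict(config), sort_keys=True))

    genome, genes, landscapes, marks, targets, de_tables = simulate_study(config)
    cfg = config.annotation_config()
    index = annotate.GeneIndex(genes, cfg)
    write_gene_annotation(genes, outdir / "genes.tsv")
    report: dict = {"seed": seed, "config": asdict(config)}

    # peak sets, annotation and chromatin state
    peak_counts: dict[str, dict[str, int]] = {f: {} for f in simulate.FACTORS}
    class_rows, state_rows = [], []
    for line, landscape in landscapes.items():
        for factor, ps in landscape.peaksets.items():
            peak_counts[factor][line] = len(ps)
            if not len(ps):
                continue
            write_bed(ps, outdir / f"peaks_{factor}_{line}.bed")
            ann = annotate.annotate_peakset(ps, index)
            class_rows.append({"factor": factor, "line": line, "n": len(ps),
                               **{f"frac_{k}": v for k, v in ann.fractions.items()}})
            st = overlap.chrom_state_partition(ps, marks)
            state_rows.append({"factor": factor, "line": line,
                               **{f"frac_{k}": v for k, v in st.fractions.items()}})
    pd.DataFrame(class_rows).to_csv(outdir / "location_classes.tsv", sep="\t", index=False)
    pd.DataFrame(state_rows).to_csv(outdir / "chromatin_states.tsv", sep="\t", index=False)
    report["peak_counts"] = peak_counts

    # dosage-binding fits
    dosage = {}
    for fi, factor in enumerate(simulate.FACTORS):
        points = [(simulate.PROFILE_LEVELS[line][fi], n)
                  for line, n in peak_counts[factor].items()
                  if simulate.PROFILE_LEVELS[line][fi] > 0]
        fit = enrichment.dosage_binding_fit(points)
        dosage[factor] = {"slope": fit.slope, "intercept": fit.intercept,
                          "correlation": fit.correlation,
                          "points": [[float(a), float(b)] for a, b in points]}
    _json_dump(dosage, outdir / "dosage_fit.json")
    report["dosage_fit"] = dosage

    # overlaps (the study's Venn comparisons)
    venn = {}
    comparisons = [
        ("Meis1", "WT", "Prep1", "WT"), ("Meis1", "MP", "Prep1", "MP"),
        ("Meis1", "ev", "Meis1", "WT"), ("Meis1", "ev", "Meis1", "M"),
        ("Meis1", "MP", "Meis1", "M"), ("Prep1", "WT", "Prep1", "P"),
        ("Prep1", "MP", "Prep1", "P"),
    ]
    for fa, la, fb, lb in comparisons:
        A = landscapes[la].peaksets[fa]
        B = landscapes[lb].peaksets[fb]
        res = overlap.overlap_peaksets(A, B, config.overlap_min_frac, keep_pairs=False)
        venn[f"{fa}@{la}_vs_{fb}@{lb}"] = {
            "n_a": res.n_a, "n_b": res.n_b,
            "n_a_overlapping": res.n_a_overlapping,
            "n_b_overlapping": res.n_b_overlapping,
        }
    _json_dump(venn, outdir / "overlaps.json")
    report["overlaps"] = venn

    # motif composition, summit profile, coincident subset, score-by-class
    tables = []
    score_tests = {}
    for line, landscape in landscapes.items():
        for factor, ps in landscape.peaksets.items():
            if not len(ps):
                continue
            table = motifs.classify_peaks(ps, genome, factor, config.peak_window,
                                          config.motif_p_threshold)
            tables.append(table)
            score_tests[f"{factor}@{line}"] = motifs.score_by_motif_class(ps, table)
    motif_report = reporting.motif_class_report(tables)
    motif_report.to_csv(outdir / "motif_classes.tsv", sep="\t", index=False)
    report["motif_classes"] = motif_report.to_dict(orient="records")
    _json_dump(score_tests, outdir / "score_by_class.json")

    meis1_m = landscapes["M"].peaksets["Meis1"]
    m_table = next(t for t in tables if t.label == "Meis1@M")
    ap1_hits = [h for h in m_table.hits if h.motif == "AP1"]
    counts, edges = motifs.summit_profile(ap1_hits)
    pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}).to_csv(
        outdir / "summit_profile_Meis1_M_AP1.tsv", sep="\t", index=False)
    coincident = motifs.summit_coincident_subset(
        meis1_m, genome, config.summit_window, config.peak_window,
        config.motif_p_threshold)
    _, coincident_genes = annotate.assign_target_genes(coincident, index)
    report["ap1_summit_subset"] = {"n_peaks": len(coincident),
                                   "n_genes": len(coincident_genes)}

    # expression integration and signatures
    de_sel = {}
    bound_stats = {}
    for contrast, df in de_tables.items():
        simulate.write_de_table(df, outdir / f"de_{contrast}_vs_ev.tsv")
        de_sel[contrast] = signatures.select_de_genes(df, config.de_p_cutoff)
        bd = signatures.bound_and_de(
            de_sel[contrast],
            targets.get(("Meis1", contrast), set()) | targets.get(("Prep1", contrast), set()))
        bound_stats[contrast] = {"n_de": len(de_sel[contrast].genes),
                                 "n_bound_de": len(bd.bound_de),
                                 "fraction_bound": bd.fraction_bound,
                                 "n_up": len(bd.up), "n_down": len(bd.down)}
    report["bound_de"] = bound_stats
    sig_results = signatures.run_signature_suite(targets, de_sel)
    provenance = {}
    for name, res in sig_results.items():
        signatures.write_signature(res, outdir / f"signature_{name}.txt")
        provenance[name] = {"n_input": res.n_input, "n_final": len(res.genes),
                            "steps": res.provenance}
    _json_dump(provenance, outdir / "signature_provenance.json")
    report["signatures"] = {k: v["n_final"] for k, v in provenance.items()}

    # enrichment against a toy ontology seeded with the ground-truth signatures
    universe = {g.gene_id for g in genes}
    truth = signature_truth(targets, de_tables)
    term_db = build_toy_term_database(universe, truth, seed=config.seed,
                                      n_random_terms=config.n_random_terms)
    enriched_summary = {}
    for name, res in sig_results.items():
        table = enrichment.hypergeom_enrichment(res.genes, term_db,
                                                config.enrichment_p_cutoff)
        table.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t", index=False)
        enriched_summary[name] = int(table["enriched"].sum())
    report["n_enriched_terms"] = enriched_summary

    _json_dump(report, outdir / "report.json")
    return report
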