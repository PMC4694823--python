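"""Reported counts from the five-MEF-line TALE-factor dosage study that this
package's synthetic defaults emulate.

These printed numbers are inputs (peak calling and read alignment are outside
this package's scope): genome-wide peak counts per factor and cell line,
relative protein levels, motif-occurrence counts per peak set, and the
ChIP x RNA integration counts for the tumorigenic (M) line. They drive the
worked examples for the fraction/ratio-reporting code paths and the
dosage-binding fits.
"""

from .simulate import PROFILE_LEVELS

#: Genome-wide significant peak counts per (factor, cell line).
PEAK_COUNTS = {
    "Meis1": {"P": 3_473, "ev": 4_328, "WT": 10_399, "MP": 12_008, "M": 27_284},
    "Prep1": {"WT": 2_949, "MP": 13_562, "P": 17_450},
}

#: Motif-occurrence counts per peak set: total peaks, peaks containing the
#: factor-specific consensus (OCTA for Meis1, DECA for Prep1; None where that
#: consensus was not enriched) and peaks containing the AP-1 element. A peak
#: can carry both, so the two counts can sum to more than the total.
MOTIF_COUNTS = {
    ("Meis1", "ev"): {"n": 4_328, "specific": 1_570, "ap1": 2_854},
    ("Meis1", "WT"): {"n": 10_399, "specific": 4_049, "ap1": 4_474},
    ("Meis1", "P"): {"n": 3_473, "specific": None, "ap1": 2_214},
    ("Meis1", "MP"): {"n": 12_008, "specific": 2_498, "ap1": 5_432},
    ("Meis1", "M"): {"n": 27_284, "specific": None, "ap1": 15_334},
    ("Prep1", "WT"): {"n": 2_949, "specific": 2_267, "ap1": 466},
    ("Prep1", "MP"): {"n": 13_562, "specific": 9_882, "ap1": 2_998},
    ("Prep1", "P"): {"n": 17_450, "specific": 12_528, "ap1": 5_808},
}

#: ChIP x RNA integration in the tumorigenic line (M vs empty vector):
#: differentially expressed genes, the subset directly bound by Meis1, and
#: the bound subset that was upregulated.
INTEGRATION_M = {"n_de": 1_395, "n_bound": 635, "n_bound_up": 515}


def dosage_points(factor: str) -> list[tuple[float, int]]:
    """(relative protein level, peak count) pairs for the dosage fit."""
    idx = {"Meis1": 0, "Prep1": 1}[factor]
    return sorted((PROFILE_LEVELS[line][idx], count)
                  for line, count in PEAK_COUNTS[factor].items())
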