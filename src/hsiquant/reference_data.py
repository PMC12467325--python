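"""Bundled reference dataset from a published three-method DKK-3 concordance study.

These constants reproduce the study's printed summary tables so the
``reproduce`` command can recompute every derivable statistic from in-study
inputs and print computed-vs-printed values side by side:

* a 97-core visual-vs-digital Allred agreement table (2x2 counts),
* six exemplary cases scored by visual assessment, digital image analysis
  and hyperspectral imaging (HSI), as H-scores and Allred totals,
* the printed dichotomised category vectors and pairwise kappa values,
* the tissue-microarray design (three 30-core arrays plus one 16-core array,
  nine cores excluded as non-representative).

Some printed statistics are known not to be derivable from the printed
inputs; see ``KNOWN_DISCREPANCIES``. They are surfaced, never silently
corrected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Visual (rows: Allred 0-6, 7-8) vs digital (cols) Allred counts over 97 cores.
TABLE1_COUNTS = np.array([[63, 0], [13, 21]])
TABLE1_PRINTED_KAPPA = 0.677

#: Six exemplary cases scored by all three methods.
SIX_CASE_SCORES = pd.DataFrame(
    {
        "case": [1, 2, 3, 4, 5, 6],
        "h_visual": [300.0, 200.0, 200.0, 300.0, 140.0, 100.0],
        "allred_visual": [8, 7, 7, 8, 6, 6],
        "h_digital": [257.62, 104.81, 6.77, 215.13, 94.01, 61.97],
        "allred_digital": [8, 6, 3, 8, 6, 5],
        "h_hsi": [233.65, 146.34, 187.492, 155.988, 123.78, 200.2],
        "allred_hsi": [7, 6, 7, 7, 6, 7],
    }
).set_index("case")

#: Printed per-method means of the six-case table.
PRINTED_MEANS = {
    "h_visual": 206.67,
    "h_digital": 123.38,
    "h_hsi": 174.57,
    "allred_visual": 7.0,
    "allred_digital": 6.0,
    "allred_hsi": 7.0,
}

#: Printed dichotomised category vectors (1 = low, 2 = high), per score type.
PRINTED_CATEGORIES = {
    ("Allred", "visual"): [2, 2, 2, 2, 1, 1],
    ("Allred", "digital"): [2, 1, 1, 2, 1, 1],
    ("Allred", "hsi"): [2, 1, 2, 2, 1, 2],
    ("H", "visual"): [2, 2, 2, 2, 1, 1],
    ("H", "digital"): [2, 1, 1, 2, 1, 1],
    ("H", "hsi"): [2, 1, 2, 2, 1, 2],
}

#: Printed pairwise kappas (identical for both score types in the source table).
PRINTED_KAPPAS = {
    ("visual", "digital"): 0.40,
    ("digital", "hsi"): 0.40,
    ("visual", "hsi"): 0.42,
}

#: Printed Spearman correlation of HSI vs visual H-scores.
PRINTED_RHO_VISUAL_HSI = 0.67

#: Printed Wilcoxon p for the 97-core visual-vs-digital H-score comparison.
PRINTED_WILCOXON_P_97 = 0.278

#: Study TMA design: array core counts, exclusions, resulting analysed cores.
TMA_ARRAYS = (30, 30, 30, 16)
TMA_EXCLUDED = 9
TMA_ANALYSED = 97

#: Printed statistics that are not reproducible from the printed inputs.
KNOWN_DISCREPANCIES = (
    "kappa visual/hsi printed 0.42, but the printed dichotomised vectors give 0.25",
    "spearman rho visual/hsi printed 0.67, but the six H-score pairs give ~0.24",
    "H-score HSI case 4 is printed as category 2 (high) although its value "
    "155.99 is below the pooled mean ~168.21",
    "six-case visual vs digital H-scores: all six differences are positive, so the "
    "exact two-sided Wilcoxon p is 0.03125, although no significant difference is "
    "claimed (the printed p = 0.278 refers to the 97-core dataset)",
)
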