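"""Published reference values used to validate the reporting arithmetic.

A published two-sample MR screen of 21 inflammatory protein biomarkers
against 18 inflammatory diseases — the study design this package implements —
reported raw GSMR p-values alongside BH-adjusted FDR values computed over
the full 21 x 18 = 378-cell grid, and flagged 11 protein-disease effects as
significant at FDR < 0.05. Those printed numbers provide an exactly
reproducible fixture for the FDR step: re-running ``bh_adjust`` with
m = 378 on the printed raw p-values must recover the printed FDR column.

The published raw p-values are rounded to two significant figures, so
recomputed FDR values can differ from the printed strings in the last digit.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["MAIN_ANALYSIS_RESULTS", "M_TESTS_MAIN", "main_analysis_table"]

#: number of cells in the published main-analysis grid (21 proteins x 18 diseases)
M_TESTS_MAIN = 378

#: (protein, disease, raw GSMR p, published FDR, published OR string);
#: the 15 protein-disease pairs with printed main-analysis results — the 11
#: FDR-significant effects plus four non-significant pairs that appeared in
#: the threshold-sensitivity comparison
MAIN_ANALYSIS_RESULTS = [
    ("CD40",         "Psoriasis",             6.6e-3,  1.8e-1,  None),
    ("IL-12B",       "Psoriatic arthropathy", 4.5e-6,  3.4e-4,  "0.79 (0.72-0.87)"),
    ("IL-12B",       "Psoriasis",             2.7e-13, 1.0e-10, "0.84 (0.80-0.88)"),
    ("IL-18R1",      "Asthma",                1.6e-1,  7.5e-1,  None),
    ("IL-18R1",      "Eczema",                7.0e-5,  4.4e-3,  "1.02 (1.01-1.03)"),
    ("IL-18R1",      "Hay fever",             5.3e-4,  2.8e-2,  "1.02 (1.01-1.03)"),
    ("IL-18R1",      "Allergy",               1.4e-3,  4.8e-2,  "1.02 (1.01-1.02)"),
    ("IL-18R1",      "Celiac disease",        3.2e-3,  1.0e-1,  None),
    ("LAP-TGF-b-1",  "Osteoarthritis",        9.0e-4,  3.4e-2,  "0.94 (0.91-0.98)"),
    ("LT-a",         "Type 1 diabetes",       2.4e-10, 4.5e-8,  "0.60 (0.51-0.70)"),
    ("LT-a",         "Rheumatoid arthritis",  4.1e-6,  3.4e-4,  "0.84 (0.78-0.90)"),
    ("LT-a",         "Psoriasis",             1.5e-2,  2.9e-1,  None),
    ("LT-a",         "Celiac disease",        5.7e-9,  7.1e-7,  "1.55 (1.34-1.79)"),
    ("TWEAK",        "Asthma",                6.0e-4,  2.8e-2,  "0.92 (0.88-0.97)"),
    ("VEGF-A",       "Ulcerative colitis",    8.7e-4,  3.4e-2,  "0.86 (0.79-0.94)"),
]


def main_analysis_table() -> pd.DataFrame:
    """The published main-analysis results as a DataFrame."""
    return pd.DataFrame(
        MAIN_ANALYSIS_RESULTS,
        columns=["protein", "disease", "raw_p", "published_fdr", "published_or"],
    )
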