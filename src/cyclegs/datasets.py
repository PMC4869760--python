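"""Bundled reference tables.

A published variance-component summary from a five-cycle commercial
winter-wheat breeding program (breeding cycles 2010-2014, 659 genotyped
lines) serves as a worked example for the across-trial heritability
formula: for every trait-by-cycle cell it lists the number of retained
trials, the genetic variance, the genotype-by-trial interaction
variance, and the heritability printed alongside them (two decimals).
"""

from __future__ import annotations

import pandas as pd

from .simdata import GRAIN_YIELD, PROTEIN_CONTENT, PROTEIN_YIELD

__all__ = ["reference_variance_components"]

_CYCLES = (2010, 2011, 2012, 2013, 2014)

_TABLE = {
    GRAIN_YIELD: {
        "n_trials": (5, 6, 4, 5, 8),
        "sigma2_G": (2.28, 4.60, 5.03, 6.64, 37.00),
        "sigma2_GT": (23.70, 23.67, 17.80, 40.98, 54.48),
        "h2": (0.32, 0.54, 0.53, 0.45, 0.84),
    },
    PROTEIN_CONTENT: {
        "n_trials": (4, 2, 3, 4, 2),
        "sigma2_G": (0.23, 0.18, 0.35, 0.37, 0.33),
        "sigma2_GT": (0.36, 0.07, 0.27, 0.65, 0.65),
        "h2": (0.72, 0.84, 0.80, 0.69, 0.50),
    },
    PROTEIN_YIELD: {
        "n_trials": (4, 2, 4, 4, 3),
        "sigma2_G": (0.04, 0.03, 0.05, 0.26, 0.76),
        "sigma2_GT": (0.41, 0.38, 0.34, 0.69, 1.30),
        "h2": (0.30, 0.14, 0.37, 0.60, 0.64),
    },
}

_N_LINES = (94, 64, 165, 160, 176)


def reference_variance_components() -> pd.DataFrame:
    """Long-format reference table, one row per trait-by-cycle cell.

    Columns: trait, cycle, n_trials, sigma2_G, sigma2_GT, h2_printed,
    n_lines.
    """
    rows = []
    for trait, cols in _TABLE.items():
        for i, cyc in enumerate(_CYCLES):
            rows.append(
                {
                    "trait": trait,
                    "cycle": cyc,
                    "n_trials": cols["n_trials"][i],
                    "sigma2_G": cols["sigma2_G"][i],
                    "sigma2_GT": cols["sigma2_GT"][i],
                    "h2_printed": cols["h2"][i],
                    "n_lines": _N_LINES[i],
                }
            )
    return pd.DataFrame(rows)
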