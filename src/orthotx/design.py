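"""Design matrices for the two-factor expression model.

The study design is species (A, B) x structure (bud, flower, fruit) with
replicates.  The full model is ``species + structure + species:structure``
(6 columns, treatment coding with reference levels species A and structure
bud); the reduced model drops the two interaction columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import SPECIES_LEVELS, STRUCTURE_LEVELS

__all__ = ["build_design_matrices", "contrast_vectors", "FULL_COLUMNS"]

FULL_COLUMNS = [
    "Intercept",
    "species[B]",
    "structure[flower]",
    "structure[fruit]",
    "species[B]:structure[flower]",
    "species[B]:structure[fruit]",
]


def build_design_matrices(
    sample_meta: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(full, reduced) design matrices, samples x columns, treatment coded."""
    sp = sample_meta["species"].astype(str)
    st = sample_meta["structure"].astype(str)
    bad_sp = set(sp) - set(SPECIES_LEVELS)
    bad_st = set(st) - set(STRUCTURE_LEVELS)
    if bad_sp or bad_st:
        raise ValueError(
            f"unknown factor levels: species {bad_sp or '{}'}, "
            f"structure {bad_st or '{}'}"
        )
    n = len(sample_meta)
    X = pd.DataFrame(
        np.zeros((n, 6)), index=sample_meta.index, columns=FULL_COLUMNS
    )
    X["Intercept"] = 1.0
    X["species[B]"] = (sp == "B").astype(float)
    X["structure[flower]"] = (st == "flower").astype(float)
    X["structure[fruit]"] = (st == "fruit").astype(float)
    X["species[B]:structure[flower]"] = X["species[B]"] * X["structure[flower]"]
    X["species[B]:structure[fruit]"] = X["species[B]"] * X["structure[fruit]"]
    if np.linalg.matrix_rank(X.to_numpy()) < 6:
        raise ValueError("full design matrix is rank deficient; every "
                         "(species, structure) cell needs samples")
    return X, X[FULL_COLUMNS[:4]].copy()


def contrast_vectors() -> dict[str, np.ndarray]:
    """The 7 pairwise contrasts of the comparison scheme, on full-model
    coefficients (natural-log scale).

    Three species contrasts (B vs A within each structure) and four
    structure-transition contrasts (flower vs bud, fruit vs flower, within
    each species).
    """
    c = {}
    def vec(**kw):
        v = np.zeros(6)
        for name, val in kw.items():
            v[FULL_COLUMNS.index(name)] = val
        return v
    c["species_B_vs_A.bud"] = vec(**{"species[B]": 1.0})
    c["species_B_vs_A.flower"] = vec(**{"species[B]": 1.0,
                                        "species[B]:structure[flower]": 1.0})
    c["species_B_vs_A.fruit"] = vec(**{"species[B]": 1.0,
                                       "species[B]:structure[fruit]": 1.0})
    c["flower_vs_bud.A"] = vec(**{"structure[flower]": 1.0})
    c["fruit_vs_flower.A"] = vec(**{"structure[fruit]": 1.0,
                                    "structure[flower]": -1.0})
    c["flower_vs_bud.B"] = vec(**{"structure[flower]": 1.0,
                                  "species[B]:structure[flower]": 1.0})
    c["fruit_vs_flower.B"] = vec(**{"structure[fruit]": 1.0,
                                    "structure[flower]": -1.0,
                                    "species[B]:structure[fruit]": 1.0,
                                    "species[B]:structure[flower]": -1.0})
    return c
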