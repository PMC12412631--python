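"""Haemoglobin extinction coefficients for the modified Beer-Lambert law.

The packaged table stores base-10 molar extinction values in 1/(cm*M);
:func:`extinction_matrix` converts them to the natural-log convention in
1/(mm*uM) used throughout (optical density here is a natural logarithm).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_extinction_table", "extinction_matrix"]

_LN10 = float(np.log(10.0))
# 1/(cm*M) -> 1/(mm*uM): /10 for cm->mm, /1e6 for M->uM
_UNIT = 1e-7


def load_extinction_table() -> pd.DataFrame:
    """Raw packaged table (wavelength_nm, hbo, hbr) in base-10 1/(cm*M)."""
    with resources.files("hdnirs.data").joinpath("extinction_hb.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def extinction_matrix(wavelengths=(760.0, 850.0)) -> np.ndarray:
    """2x2 natural-log extinction matrix E, rows = wavelengths, cols = (HbO, HbR).

    Units 1/(mm*uM), so ``delta_OD = L * ppf * E @ [dHbO, dHbR]`` with the
    source-detector distance L in mm and concentrations in uM.
    """
    table = load_extinction_table().set_index("wavelength_nm")
    rows = []
    for wl in wavelengths:
        if int(round(wl)) not in table.index:
            raise KeyError(f"no extinction entry for {wl} nm")
        rec = table.loc[int(round(wl))]
        rows.append([rec["hbo"], rec["hbr"]])
    return np.asarray(rows, dtype=float) * _LN10 * _UNIT
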