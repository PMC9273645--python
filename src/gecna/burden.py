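"""Per-patient CNA burden from GISTIC-style call matrices.

Burden is the number of genes a patient carries with a non-neutral call:
positive calls are gains/amplifications, negative calls deletions. The
magnitude threshold ``m`` selects any non-neutral call (m=1, the default)
or only high-level events (m=2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CnaCallMatrix

MODES = ("total", "amp", "del")


def burden(cna: CnaCallMatrix, mode: str = "total", m: int = 1) -> pd.Series:
    """Count CNA calls per patient under one mode.

    mode="total" counts |call| >= m, "amp" counts call >= m, "del" counts
    call <= -m. Returns a patient-indexed integer Series named after the mode.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if m not in (1, 2):
        raise ValueError(f"magnitude threshold m must be 1 or 2, got {m!r}")
    calls = cna.calls.to_numpy()
    if mode == "total":
        counts = (np.abs(calls) >= m).sum(axis=0)
    elif mode == "amp":
        counts = (calls >= m).sum(axis=0)
    else:
        counts = (calls <= -m).sum(axis=0)
    return pd.Series(counts, index=cna.patients, name=mode)


def burden_table(cna: CnaCallMatrix, m: int = 1) -> pd.DataFrame:
    """All three burden modes as a patient x {total, amp, del} table."""
    table = pd.DataFrame({mode: burden(cna, mode, m) for mode in MODES})
    table["threshold"] = m
    return table
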