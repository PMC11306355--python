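"""Reproduction of the reference comparison tables as DataFrames/CSV.

Each table shows three-component partial sums of one or more compartments
on the grid tau = 0, 0.1, ..., 0.5 under all three kernels: tables 2-5
cover V, T, O, W at fractional orders mu in {0.8, 0.9}; table 6 covers
V, G, T, O and table 7 covers W at the classical order mu = 1.  Columns
for the two external comparison methods (LADM, q-HATM) are emitted as
empty placeholders so the grid shape matches; they are reference values
from other solvers and are never computed here.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .engine import solve, SourceMode
from .kernels import Kernel, KernelSpec
from .smoking import ModelParameters, build_system

DEFAULT_TAUS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)

# table id -> (states shown, fractional orders)
TABLE_LAYOUT: dict[int, tuple[tuple[str, ...], tuple[float, ...]]] = {
    2: (("V",), (0.8, 0.9)),
    3: (("T",), (0.8, 0.9)),
    4: (("O",), (0.8, 0.9)),
    5: (("W",), (0.8, 0.9)),
    6: (("V", "G", "T", "O"), (1.0,)),
    7: (("W",), (1.0,)),
}

KERNEL_COLUMNS = ("NTDM_C", "NTDM_CF", "NTDM_ABC")
PLACEHOLDER_COLUMNS = ("q-HATM", "LADM")  # external reference methods, not computed
_KERNEL_BY_COLUMN = {
    "NTDM_C": Kernel.CAPUTO,
    "NTDM_CF": Kernel.CF,
    "NTDM_ABC": Kernel.ABC,
}


def table_frame(
    table_id: int,
    params: ModelParameters | None = None,
    K: int = 2,
    taus: Sequence[float] = DEFAULT_TAUS,
    source_mode: SourceMode = "every_level",
    round_decimals: int | None = None,
) -> pd.DataFrame:
    """Build one comparison table as a tidy DataFrame.

    Columns: state, mu, tau, NTDM_C, NTDM_CF, NTDM_ABC, q-HATM, LADM.  Set
    ``round_decimals`` (the comparison files use 4, half-even) to round the
    computed columns; full precision is the default.
    """
    if table_id not in TABLE_LAYOUT:
        raise ValueError(f"unknown table id {table_id}; valid ids are {sorted(TABLE_LAYOUT)}")
    states, mus = TABLE_LAYOUT[table_id]
    system = build_system(params or ModelParameters())
    rows = []
    for mu in mus:
        sols = {
            col: solve(system, KernelSpec(kern, mu), K, source_mode)
            for col, kern in _KERNEL_BY_COLUMN.items()
        }
        for state in states:
            for tau in taus:
                row: dict = {"state": state, "mu": mu, "tau": tau}
                for col, sol in sols.items():
                    val = sol.evaluate(state, tau)
                    if round_decimals is not None:
                        val = float(np.round(val, round_decimals))
                    row[col] = val
                for col in PLACEHOLDER_COLUMNS:
                    row[col] = np.nan
                rows.append(row)
    return pd.DataFrame(rows)


def cell(
    table_id: int,
    state: str,
    mu: float,
    tau: float,
    kernel_column: str,
    params: ModelParameters | None = None,
    K: int = 2,
) -> float:
    """One computed table cell, full precision."""
    df = table_frame(table_id, params=params, K=K, taus=(tau,))
    sel = df[(df["state"] == state) & (df["mu"] == mu) & (df["tau"] == tau)]
    if sel.empty:
        raise ValueError(f"(state={state}, mu={mu}, tau={tau}) not in table {table_id}")
    return float(sel.iloc[0][kernel_column])
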