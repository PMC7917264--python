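"""Wide-format panel data container and CSV I/O.

The on-disk dialect is one row per unit with a header
``unit,<var>_<t>,...`` (column order free, names mandatory), e.g.
``unit,income_1,...,income_6,swb_1,...,swb_6``.  Blank cells are treated as
missing and masked; the number of units is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelSpec

__all__ = ["PanelData", "read_panel_csv", "write_panel_csv"]


@dataclass
class PanelData:
    """N x T x k panel with NaN marking missing cells."""

    unit_ids: tuple
    values: np.ndarray                 # (N, T, k) float64
    variable_names: tuple = field(default=())

    def __post_init__(self):
        self.unit_ids = tuple(str(u) for u in self.unit_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (N, T, k)")
        if len(self.unit_ids) != self.values.shape[0]:
            raise ValueError("unit_ids length must match values.shape[0]")
        if not self.variable_names:
            self.variable_names = tuple(f"v{j + 1}" for j in range(self.values.shape[2]))

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]

    @property
    def k(self) -> int:
        return self.values.shape[2]

    @property
    def mask(self) -> np.ndarray:
        """Boolean (N, T, k) array, True where the cell is missing."""
        return np.isnan(self.values)

    def complete_rows(self) -> np.ndarray:
        """Boolean (N,) selector of units with no missing cell."""
        return ~self.mask.reshape(self.n_units, -1).any(axis=1)

    def complete_cases(self) -> "PanelData":
        keep = self.complete_rows()
        return PanelData(tuple(np.asarray(self.unit_ids)[keep]),
                         self.values[keep], self.variable_names)

    def wide(self) -> np.ndarray:
        """(N, kT) matrix ordered occasion-major: (t1,v1..vk), (t2,v1..vk), ..."""
        return self.values.reshape(self.n_units, self.T * self.k)


def read_panel_csv(path, spec: ModelSpec) -> PanelData:
    """Read the wide CSV dialect, validated against ``spec``.

    Errors name missing columns, non-numeric cells, and duplicate unit ids
    explicitly.
    """
    df = pd.read_csv(path, dtype={"unit": str})
    if "unit" not in df.columns:
        raise ValueError("missing required column 'unit'")
    if df["unit"].duplicated().any():
        dups = df["unit"][df["unit"].duplicated()].tolist()
        raise ValueError(f"duplicate unit ids: {dups}")
    expected = [f"{v}_{t}" for v in spec.variable_names for t in range(1, spec.T + 1)]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    values = np.full((len(df), spec.T, spec.k), np.nan)
    for j, v in enumerate(spec.variable_names):
        for t in range(1, spec.T + 1):
            col = pd.to_numeric(df[f"{v}_{t}"], errors="coerce")
            bad = col.isna() & df[f"{v}_{t}"].notna() & (df[f"{v}_{t}"].astype(str).str.strip() != "")
            if bad.any():
                raise ValueError(
                    f"non-numeric cells in column {v}_{t} for units "
                    f"{df['unit'][bad].tolist()}")
            values[:, t - 1, j] = col.to_numpy()
    return PanelData(tuple(df["unit"]), values, spec.variable_names)


def write_panel_csv(panel: PanelData, path) -> None:
    """Write the wide CSV dialect (inverse of :func:`read_panel_csv`)."""
    data = {"unit": list(panel.unit_ids)}
    for j, v in enumerate(panel.variable_names):
        for t in range(1, panel.T + 1):
            data[f"{v}_{t}"] = panel.values[:, t - 1, j]
    pd.DataFrame(data).to_csv(path, index=False)
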