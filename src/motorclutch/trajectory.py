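"""Trajectory container and plain-text table I/O.

A trajectory holds snapshots taken at a fixed recording interval: a
cell-level table (time, body position in micrometres, module count, total
traction, mean retrograde flow) and a per-module sidecar table (direction,
length, force, flow for every live module at every record).  Files are
delimited text with a ``#``-prefixed metadata header embedding the full
parameter set and seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .params import SimulationParameters

NM_PER_UM = 1000.0

CELL_COLUMNS = ["t_s", "x_um", "y_um", "n_modules", "total_traction_pN",
                "mean_flow_nm_s"]
MODULE_COLUMNS = ["t_s", "module_id", "theta_rad", "length_nm", "force_pN",
                  "flow_nm_s"]


@dataclass
class Trajectory:
    """Recorded output of one simulation run."""
    cell: pd.DataFrame      # one row per record, CELL_COLUMNS
    modules: pd.DataFrame   # one row per (record, live module), MODULE_COLUMNS
    params: SimulationParameters
    record_interval: float  # s

    def __post_init__(self) -> None:
        t = self.cell["t_s"].to_numpy()
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("record times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.cell["t_s"].to_numpy()

    def positions_um(self) -> np.ndarray:
        """Body positions as an (n, 2) array in micrometres."""
        return self.cell[["x_um", "y_um"]].to_numpy()

    def after(self, t_min: float) -> "Trajectory":
        """Records at times >= t_min (s)."""
        return Trajectory(
            cell=self.cell[self.cell["t_s"] >= t_min].reset_index(drop=True),
            modules=self.modules[self.modules["t_s"] >= t_min].reset_index(drop=True),
            params=self.params, record_interval=self.record_interval)

    # -- I/O ---------------------------------------------------------------

    def write(self, path: Union[str, Path]) -> None:
        """Write ``<path>`` (cell table) and ``<path stem>_modules<ext>``."""
        path = Path(path)
        header = self._header()
        _write_table(path, self.cell, header)
        _write_table(_sidecar_path(path), self.modules, header)

    def _header(self) -> str:
        lines = ["# motorclutch trajectory",
                 f"# record_interval = {self.record_interval!r}"]
        for k, v in self.params.to_dict().items():
            lines.append(f"# param {k} = {v!r}")
        return "\n".join(lines)

    @classmethod
    def read(cls, path: Union[str, Path]) -> "Trajectory":
        path = Path(path)
        params, interval = _read_header(path)
        cell = pd.read_csv(path, sep="\t", comment="#")
        modules = pd.read_csv(_sidecar_path(path), sep="\t", comment="#")
        return cls(cell=cell, modules=modules, params=params,
                   record_interval=interval)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + "_modules" + path.suffix)


def _write_table(path: Path, df: pd.DataFrame, header: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_header(path: Path) -> tuple:
    d = {}
    interval: Optional[float] = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("record_interval"):
                interval = float(body.split("=", 1)[1])
            elif body.startswith("param "):
                k, v = body[6:].split("=", 1)
                d[k.strip()] = v.strip()
    if interval is None or not d:
        raise ValueError(f"{path}: missing trajectory metadata header")
    return SimulationParameters.from_dict(d), interval
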