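"""Shared CSV schemas and round-trip safe readers/writers.

Columns are fixed per table kind; readers accept any column order and
restore the canonical one, and reject files with missing or extra columns,
naming them.  Floats are written with ``repr`` precision so that
read(write(x)) == x.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ConfigError

__all__ = [
    "PROFILE_COLUMNS",
    "SWEEP_COLUMNS",
    "OBSERVATION_COLUMNS",
    "COMPARISON_COLUMNS",
    "write_table",
    "read_table",
]

PROFILE_COLUMNS = ("z_m", "CR_mM", "CA_mM", "CS_mM")
SWEEP_COLUMNS = ("value", "tau_min", "CR_out_mM", "CA_out_mM",
                 "conversion_pct", "eeS_pct")
OBSERVATION_COLUMNS = ("Q_mL_min", "CR0_mM", "CS0_mM", "CA0_mM",
                       "CR_mM", "CS_mM", "CA_mM", "replicate")
COMPARISON_COLUMNS = ("mode", "Q_mL_min", "C0_mM", "P_mmol_min_g")


def _check_columns(found: Sequence[str], expected: Sequence[str]) -> None:
    missing = [c for c in expected if c not in found]
    extra = [c for c in found if c not in expected]
    if missing or extra:
        raise ConfigError(
            f"table schema mismatch: missing columns {missing}, "
            f"unexpected columns {extra}; expected {list(expected)}")


def write_table(frame: pd.DataFrame, path: str | Path,
                columns: Sequence[str]) -> None:
    """Write ``frame`` as CSV in canonical column order."""
    _check_columns(list(frame.columns), columns)
    frame.loc[:, list(columns)].to_csv(path, index=False)


def read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    """Read a CSV, validate its schema, and restore canonical column order."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"table file not found: {path}")
    frame = pd.read_csv(path)
    _check_columns(list(frame.columns), columns)
    return frame.loc[:, list(columns)]
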