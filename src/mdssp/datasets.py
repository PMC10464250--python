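"""Bundled example data and lifetime-file I/O."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["fixture_failure_times", "read_lifetimes", "write_lifetimes"]

# Times (days) between successive failures of 30 repairable components,
# a classical right-skewed reliability benchmark.
_FAILURE_TIMES = (
    0.11, 0.30, 0.40, 0.45, 0.59, 0.63, 0.70, 0.71, 0.74, 0.77,
    0.94, 1.06, 1.17, 1.23, 1.23, 1.24, 1.43, 1.46, 1.49, 1.74,
    1.82, 1.86, 1.97, 2.23, 2.37, 2.46, 2.63, 3.46, 4.36, 4.73,
)


def fixture_failure_times() -> np.ndarray:
    """The 30 repairable-component failure times (days)."""
    return np.array(_FAILURE_TIMES)


def read_lifetimes(path) -> np.ndarray:
    """Read a single-column lifetimes file (CSV, header optional).

    Accepts one value per line as a degenerate CSV; a non-numeric first
    row is treated as a header and skipped.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"no data in {path}")
    start = 0
    try:
        float(lines[0].split(",")[0])
    except ValueError:
        start = 1
    values = []
    for ln in lines[start:]:
        values.append(float(ln.split(",")[0]))
    return np.asarray(values, dtype=float)


def write_lifetimes(values, path, header: str = "lifetime") -> None:
    """Write lifetimes as a single-column CSV with a header row."""
    pd.DataFrame({header: np.asarray(values, dtype=float)}).to_csv(path, index=False)
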