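"""Synthetic lot-stream generation for plan validation.

Emulates the inspection setting the sampling plans are designed for:
a sequence of lots, each yielding ``lot_n`` i.i.d. NLRD lifetimes, all
drawn by inverse-CDF sampling from a single seeded generator so a run
is reproducible from its seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .distribution import NLRDParams, nlrd_sample

__all__ = ["generate_lot_stream", "synth_generate", "read_lot_stream"]


def generate_lot_stream(
    params: NLRDParams, n_lots: int, lot_n: int, seed=None
) -> pd.DataFrame:
    """Simulate ``n_lots`` lots of ``lot_n`` NLRD lifetimes each.

    Returns a long-format frame with columns ``lot`` (1-based index)
    and ``lifetime``.
    """
    if n_lots < 1 or lot_n < 1:
        raise ValueError("n_lots and lot_n must be >= 1")
    rng = np.random.default_rng(seed)
    values = nlrd_sample(n_lots * lot_n, params, seed=rng)
    return pd.DataFrame(
        {"lot": np.repeat(np.arange(1, n_lots + 1), lot_n), "lifetime": values}
    )


def synth_generate(
    params: NLRDParams, n_lots: int, lot_n: int, seed, path
) -> Path:
    """Write a seeded lot stream to CSV (columns ``lot,lifetime``)."""
    path = Path(path)
    frame = generate_lot_stream(params, n_lots, lot_n, seed=seed)
    frame.to_csv(path, index=False, float_format="%.10g")
    return path


def read_lot_stream(path) -> pd.DataFrame:
    """Read a lot-stream CSV written by :func:`synth_generate`."""
    frame = pd.read_csv(path)
    if not {"lot", "lifetime"} <= set(frame.columns):
        raise ValueError(f"{path} is not a lot-stream file (need lot,lifetime columns)")
    return frame
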