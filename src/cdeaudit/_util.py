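"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np
import pandas as pd


def round_half_up(x, decimals: int = 1):
    """Round half away from zero, the convention used in all printed percentages.

    Works on scalars and on pandas/numpy arrays.  Python's ``round`` and
    numpy's ``np.round`` use banker's rounding, which would print 14.25%
    as 14.2%; aggregate reports here always round .5 upward.
    """
    factor = 10.0**decimals
    if isinstance(x, (pd.Series, np.ndarray)):
        arr = np.asarray(x, dtype=float)
        out = np.floor(np.abs(arr) * factor + 0.5) / factor * np.sign(arr)
        if isinstance(x, pd.Series):
            return pd.Series(out, index=x.index, name=x.name)
        return out
    return float(np.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1))


def pct(numer, denom, decimals: int = 1):
    """Percentage ``numer / denom * 100`` rounded half-up; 0 when denom is 0."""
    if np.isscalar(denom) and denom == 0:
        return 0.0
    return round_half_up(np.asarray(numer, dtype=float) / denom * 100.0, decimals) if not np.isscalar(numer) else round_half_up(numer / denom * 100.0, decimals)
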