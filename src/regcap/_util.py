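"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def round_half_up(x, decimals: int = 3):
    """Round half away from zero at ``decimals`` places.

    Published tables round 0.0005 up to 0.001, whereas IEEE / numpy rounding
    is half-to-even; comparisons against printed values therefore go through
    this helper. Accepts scalars, numpy arrays and pandas Series.
    """
    quantum = Decimal(1).scaleb(-decimals)

    def _one(v: float) -> float:
        return float(Decimal(repr(float(v))).quantize(quantum, rounding=ROUND_HALF_UP))

    if isinstance(x, pd.Series):
        return x.map(_one)
    if isinstance(x, (np.ndarray, list, tuple)):
        return np.array([_one(v) for v in np.asarray(x, dtype=float).ravel()]).reshape(
            np.asarray(x).shape
        )
    return _one(x)
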