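"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def _round_scalar(x: float, decimals: int) -> float:
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-decimals)
    # repr(float) is the shortest decimal that round-trips, which is the
    # number the table would print; quantize that, not the binary expansion
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_half_up(x, decimals: int = 3):
    """Round half away from zero, as demographic tables are printed.

    Operates elementwise on sequences/arrays; scalars come back as floats.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        return _round_scalar(float(arr), decimals)
    return np.array([_round_scalar(float(v), decimals) for v in arr.ravel()]).reshape(arr.shape)
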