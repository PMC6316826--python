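"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["round_half_up"]


def round_half_up(x, ndigits: int = 1):
    """Round with halves away from zero-ward ties going up (.25 → .3).

    Accepts scalars, numpy arrays or pandas Series; survey tables report
    percentages with this convention rather than banker's rounding.
    """
    scale = 10.0 ** ndigits
    return np.floor(np.asarray(x, dtype=float) * scale + 0.5 + 1e-9) / scale
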