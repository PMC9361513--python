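"""Diagnostic labels from MoCA screening scores.

A subject is labeled MCI (1) when the MoCA score falls below the clinical
cutoff (default 25), healthy (0) otherwise.  The soft label replaces the
hard 0/1 target with a sigmoid of the score centered between the two label
regions, ``y = 1 - sigmoid(m - 24.5)``, so that a score of 24 maps to
~0.622 and a score of 25 to ~0.378: diagnostic uncertainty near the cutoff
is encoded in the training target instead of being rounded away.

The cutoff (and hence the sigmoid center) is configurable because the
clinical threshold itself varies with context such as education level.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

DEFAULT_CUTOFF = 25
DEFAULT_CENTER = 24.5

__all__ = ["hard_label", "soft_label", "DEFAULT_CUTOFF", "DEFAULT_CENTER"]


def hard_label(m, cutoff: int = DEFAULT_CUTOFF):
    """Binary MCI label: 1 iff the MoCA score ``m`` is below ``cutoff``.

    Accepts scalars or arrays; scores must lie in [0, 30].
    """
    arr = np.asarray(m)
    if np.any((arr < 0) | (arr > 30)):
        raise ValueError(f"MoCA score outside [0, 30]: {m!r}")
    out = (arr < cutoff).astype(int)
    return out.item() if np.isscalar(m) or arr.ndim == 0 else out

def soft_label(m, center: float = DEFAULT_CENTER):
    """Soft MCI target ``y = 1 - sigmoid(m - center)``, in (0, 1).

    Strictly decreasing in ``m``; ``y > 0.5`` exactly when ``m < center``.
    Satisfies the symmetry ``y(center + d) + y(center - d) = 1``.
    """
    arr = np.asarray(m, dtype=float)
    out = 1.0 - expit(arr - center)
    return out.item() if np.isscalar(m) or arr.ndim == 0 else out
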