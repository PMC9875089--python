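"""Monotone response transforms used to meet LMM normality assumptions.

Laterality indices are bounded (LI in [-1, 1], |LI| in [0, 1]) and often
pile up at the boundaries, so model residuals can be visibly non-normal.
The registry below holds the transforms the pipeline may apply when
residual diagnostics recommend one; the transform actually used for a model
is recorded in that model's output so a run is fully reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["TRANSFORMS", "apply_transform"]

#: Boundary clamp for the logit: values are clipped to [eps, 1 - eps].
LOGIT_EPS = 0.005


def _identity(x: np.ndarray) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _signed_sqrt(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.sqrt(np.abs(x))


def _logit(x: np.ndarray) -> np.ndarray:
    """Logit for a [0, 1] response, clamped away from the boundaries."""
    x = np.clip(np.asarray(x, dtype=float), LOGIT_EPS, 1.0 - LOGIT_EPS)
    return np.log(x / (1.0 - x))


def _logit_pm1(x: np.ndarray) -> np.ndarray:
    """Logit for a [-1, 1] response (rescaled to [0, 1] first)."""
    return _logit((np.asarray(x, dtype=float) + 1.0) / 2.0)


def _rank_normal(x: np.ndarray) -> np.ndarray:
    """Blom rank-normal scores: Phi^-1((rank - 3/8) / (n + 1/4))."""
    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))


TRANSFORMS = {
    "identity": _identity,
    "sqrt": _signed_sqrt,
    "logit": _logit,
    "logit_pm1": _logit_pm1,
    "rank_normal": _rank_normal,
}


def apply_transform(name: str, values) -> np.ndarray:
    """Apply a registered transform by name; unknown names raise KeyError."""
    try:
        fn = TRANSFORMS[name]
    except KeyError:
        raise KeyError(
            f"unknown transform {name!r}; available: {sorted(TRANSFORMS)}"
        ) from None
    return fn(np.asarray(values, dtype=float))
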