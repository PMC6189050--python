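"""Per-click evidence reliability.

A single click on the fast side raises the log posterior-odds of the hidden
state by a fixed amount κ, which depends on the click rates (r1, r2) and on
the probability n that a click is heard on the wrong side:

    κ(r1, r2, n) = log[ (r1(1−n) + r2 n) / (r2(1−n) + r1 n) ]

κ is the log-likelihood ratio of one click in the instantaneous-click limit.
At n = 0 it reduces to log(r1/r2); at n = 0.5 a click carries no information
(κ = 0); at n = 1 the sides are simply relabelled (κ flips sign).
"""

from __future__ import annotations

import numpy as np


def kappa(r1, r2, n: float = 0.0):
    """Log-evidence per click (nats) at mislocalization probability ``n``.

    Broadcasts over array inputs.  Degenerate rate pairs where the effective
    rate on one side vanishes (e.g. r2 = 0, n = 0) return ±inf: a single
    click then identifies the state with certainty.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(r1 < 0) or np.any(r2 < 0) or np.any((r1 <= 0) & (r2 <= 0)):
        raise ValueError("click rates must be nonnegative with at least one positive")
    if not (0.0 <= n <= 1.0):
        raise ValueError(f"mislocalization probability must be in [0, 1], got {n}")
    num = r1 * (1.0 - n) + r2 * n
    den = r2 * (1.0 - n) + r1 * n
    with np.errstate(divide="ignore"):
        out = np.log(num) - np.log(den)
    return float(out) if out.ndim == 0 else out


def kappa_finite_dt(r1: float, r2: float, n: float, dt: float) -> float:
    """Finite-timestep log-likelihood ratio of a right click.

    Discrete-time form before the dt → 0 limit: within one bin of width dt
    a side produces a click with probability r·dt, and a heard right click
    is either a true right click kept (prob 1−n) or a left click flipped
    (prob n).  Agrees with :func:`kappa` to O(dt); used as an oracle.
    """
    num = (r1 * dt) * (1 - n) * (1 - r2 * dt) + (1 - r1 * dt) * (r2 * dt) * n
    den = (r2 * dt) * (1 - n) * (1 - r1 * dt) + (1 - r2 * dt) * (r1 * dt) * n
    return float(np.log(num / den))


def kappa_surface(rate_pairs, n: float = 0.0) -> np.ndarray:
    """Elementwise κ over a sequence of (r1, r2) pairs (e.g. r1 + r2 = 40)."""
    pairs = np.asarray(rate_pairs, dtype=float)
    return kappa(pairs[:, 0], pairs[:, 1], n)
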