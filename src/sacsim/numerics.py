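"""Fixed-step explicit integrators shared by all modules.

The reference implementation of the model used a fixed 1-ms step with a
third-order Bogacki-Shampine scheme; ``rk3_step`` reproduces that
tableau at fixed step.  A forward-Euler variant is kept for debugging
and scheme-consistency checks.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["rk3_step", "euler_step", "integrate_step"]

Deriv = Callable[[np.ndarray], np.ndarray]


def rk3_step(f: Deriv, y: np.ndarray, dt: float) -> np.ndarray:
    """One fixed step of the 3rd-order Bogacki-Shampine scheme."""
    k1 = f(y)
    k2 = f(y + 0.5 * dt * k1)
    k3 = f(y + 0.75 * dt * k2)
    return y + (dt / 9.0) * (2.0 * k1 + 3.0 * k2 + 4.0 * k3)


def euler_step(f: Deriv, y: np.ndarray, dt: float) -> np.ndarray:
    """One forward-Euler step."""
    return y + dt * f(y)


def integrate_step(f: Deriv, y: np.ndarray, dt: float, scheme: str) -> np.ndarray:
    if scheme == "rk3":
        return rk3_step(f, y, dt)
    if scheme == "euler":
        return euler_step(f, y, dt)
    raise ValueError(f"unknown integration scheme {scheme!r}")
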