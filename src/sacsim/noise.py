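"""Spatiotemporally correlated noise input to the collicular map.

One independent white-noise source per neuron is mixed spatially with
Gaussian distance-dependent weights (SD ``sigma_noise``) and filtered
temporally through per-neuron leaky integrators (time constant
``tau_noise``) -- an Ornstein-Uhlenbeck field.  The discretization uses
the exact OU update with variance correction, so the stationary
marginal SD equals ``noise_gain`` for every neuron regardless of the
step size.  The field is reset (states zeroed, RNG stream untouched)
when a saccade is triggered, which prevents a persistent fluctuation
from launching staircases of saccades.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParameters
from .sc import SCGeometry

__all__ = ["NoiseField"]


class NoiseField:
    """Stateful generator of the per-neuron noise vector.

    Parameters
    ----------
    params, geometry
        Model constants and map coordinates.
    rng
        A ``numpy.random.Generator``; the caller owns seeding.
    """

    def __init__(
        self, params: ModelParameters, geometry: SCGeometry, rng: np.random.Generator
    ) -> None:
        self.params = params
        self.rng = rng
        d = geometry.positions[:, None] - geometry.positions[None, :]
        kernel = np.exp(-(d**2) / (2.0 * params.sigma_noise**2))
        # Row-normalize in the L2 sense so every neuron's mixed white
        # input has unit variance -> identical stationary marginal SD.
        self.mixing = kernel / np.sqrt((kernel**2).sum(axis=1, keepdims=True))
        self.z = np.zeros(len(geometry.positions))

    @property
    def correlation(self) -> np.ndarray:
        """Stationary spatial correlation matrix implied by the mixing."""
        return self.mixing @ self.mixing.T

    def step(self, dt: float) -> np.ndarray:
        """Advance one step and return the noise vector (scaled by gain)."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        alpha = np.exp(-dt / self.params.tau_noise)
        white = self.rng.standard_normal(len(self.z))
        self.z = alpha * self.z + np.sqrt(1.0 - alpha**2) * (self.mixing @ white)
        return self.params.noise_gain * self.z

    def reset(self) -> None:
        """Zero the field; the RNG stream is deliberately untouched so a
        run is reproducible given the seed and the event times."""
        self.z[:] = 0.0
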