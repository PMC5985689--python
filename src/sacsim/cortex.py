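"""Cortical drive to the collicular map: FEF excitation, BG disinhibition.

Both structures are lumped: the frontal eye fields contribute a Gaussian
hill of excitation centred at the collicular location of the desired
target, and the basal ganglia contribute a complementary inhibitory
surround that suppresses the whole map except the target location.  The
FEF drive grows (and saturates) with target eccentricity, which makes
small retinal errors less likely to evoke a saccade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters
from .sc import SCGeometry, retinotopic_to_collicular

__all__ = ["CorticalDrive", "fef_eccentricity_gain", "cortical_drive"]


@dataclass(frozen=True)
class CorticalDrive:
    fef: np.ndarray          # per-neuron excitation (>= 0)
    bg: np.ndarray           # per-neuron inhibition (<= 0)
    target_error: float      # deg, desired gaze minus delayed eye position

    @property
    def total(self) -> np.ndarray:
        return self.fef + self.bg


def fef_eccentricity_gain(ecc: float, params: ModelParameters) -> float:
    """Saturating gain of the FEF drive with target eccentricity (deg).

    ``g0 + g1 * (1 - exp(-|ecc| / e_half))``; positive at zero error so
    fixation is still actively driven.
    """
    return params.fef_base + params.fef_gain * (
        1.0 - np.exp(-abs(ecc) / params.fef_ecc_scale)
    )


def cortical_drive(
    target_error: float, geometry: SCGeometry, params: ModelParameters
) -> CorticalDrive:
    """FEF and BG spatial drives for a given retinal error (deg)."""
    d_t = retinotopic_to_collicular(target_error, params)
    delta = geometry.positions - d_t
    fef = fef_eccentricity_gain(target_error, params) * np.exp(
        -(delta**2) / (2.0 * params.sigma_FEF**2)
    )
    bg = -params.bg_depth * (1.0 - np.exp(-(delta**2) / (2.0 * params.sigma_BG**2)))
    return CorticalDrive(fef=fef, bg=bg, target_error=float(target_error))
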