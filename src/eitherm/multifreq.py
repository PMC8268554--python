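"""Two-frequency separation of temperature and perfusion contributions.

With the plasma fraction alpha known at two frequencies, the weighted
difference of the fractional conductivity changes isolates the direct
temperature term,

    dsigma_LF - (aLF/aHF) dsigma_HF = (1 - aLF/aHF) Tc dT,

while the plain difference isolates the perfusion term,

    dsigma_LF - dsigma_HF = (aLF - aHF) (sqrt(omega) - 1) (1 + Tc dT).

Together they recover (dT, omega) exactly for data generated by the
forward conductivity-change model with matching parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = ["SeparationInputs", "separate_temperature", "separate_perfusion"]


@dataclass
class SeparationInputs:
    """Fractional conductivity changes at two frequencies plus model
    constants (``alpha_lf != alpha_hf`` required)."""

    delta_sigma_lf: np.ndarray
    delta_sigma_hf: np.ndarray
    alpha_lf: float = 0.24
    alpha_hf: float = 0.08
    tc: float = 0.02
    sqrt_perfusion: bool = True

    def __post_init__(self) -> None:
        self.delta_sigma_lf = np.asarray(self.delta_sigma_lf, dtype=float)
        self.delta_sigma_hf = np.asarray(self.delta_sigma_hf, dtype=float)
        if self.alpha_hf <= 0:
            raise ValueError("alpha_hf must be positive")
        if self.alpha_lf == self.alpha_hf:
            raise ValueError("separation requires alpha_lf != alpha_hf")
        if self.delta_sigma_lf.shape != self.delta_sigma_hf.shape:
            raise ValueError("LF and HF fields must have the same shape")


def separate_temperature(inputs: SeparationInputs) -> np.ndarray:
    """Temperature rise dT (degC) from the weighted two-frequency difference."""
    ratio = inputs.alpha_lf / inputs.alpha_hf
    return (inputs.delta_sigma_lf - ratio * inputs.delta_sigma_hf) / (
        (1.0 - ratio) * inputs.tc
    )


def separate_perfusion(
    inputs: SeparationInputs,
    delta_T: Union[np.ndarray, str, None] = None,
) -> np.ndarray:
    """Relative perfusion omega from the plain two-frequency difference.

    ``delta_T`` may be a per-element array (e.g. a simulation), ``None`` to
    use the two-frequency temperature estimate, or ``'neglect'`` to drop the
    ``Tc dT`` factor.  Noise-driven negative radicands are floored at
    omega = 0.
    """
    if isinstance(delta_T, str):
        if delta_T != "neglect":
            raise ValueError("delta_T must be an array, None, or 'neglect'")
        factor = 1.0
    else:
        dT = separate_temperature(inputs) if delta_T is None else np.asarray(delta_T, float)
        factor = np.asarray(1.0 + inputs.tc * dT, dtype=float)
        # noise-driven non-positive factors invalidate the voxel rather
        # than the whole map
        factor = np.where(factor > 0, factor, np.nan)
    root = (inputs.delta_sigma_lf - inputs.delta_sigma_hf) / (
        (inputs.alpha_lf - inputs.alpha_hf) * factor
    )
    if inputs.sqrt_perfusion:
        return np.maximum(1.0 + root, 0.0) ** 2
    return np.maximum(1.0 + root, 0.0)
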