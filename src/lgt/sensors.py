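"""Saturating ratiometric response model for GEVAL-type GTP sensors.

A GEVAL sensor reports free GTP through the ratio of its fluorescence under
two excitations.  The ratio rises hyperbolically with ligand concentration
from ``r_min`` (apo) to ``r_max`` (saturated); ``keff`` is the concentration
giving half of the maximal ratiometric change.  GEVAL30 has keff = 32.3 µM.
The Null variant cannot bind GTP and always reports ``r_min``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SensorModel", "GEVAL30", "GEVAL_NULL", "sensor_response"]


@dataclass(frozen=True)
class SensorModel:
    """Single-site saturating ratiometric sensor.

    Parameters
    ----------
    keff : float
        Ligand concentration (µM) at 50% of the maximal ratiometric signal.
    r_min : float
        Ratio at zero ligand.
    r_max : float
        Ratio at saturation.
    is_null : bool
        Ligand-insensitive control variant; response is ``r_min`` everywhere.
    hill : float
        Hill coefficient; 1 gives the single-site hyperbola.
    """

    keff: float = 32.3
    r_min: float = 1.0
    r_max: float = 3.0
    is_null: bool = False
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.keff <= 0:
            raise ValueError(f"keff must be positive, got {self.keff}")
        if not (0 < self.r_min < self.r_max):
            raise ValueError(
                f"need 0 < r_min < r_max, got r_min={self.r_min}, r_max={self.r_max}"
            )
        if self.hill <= 0:
            raise ValueError(f"hill must be positive, got {self.hill}")

    def response(self, conc):
        return sensor_response(self, conc)


def sensor_response(model: SensorModel, conc):
    """Ratiometric readout at GTP concentration ``conc`` (µM).

    Returns ``r_min + (r_max - r_min) * c^h / (keff^h + c^h)``; for a null
    sensor the ligand term is dropped and the ratio is ``r_min``.  Accepts
    scalars or arrays; infinite concentrations saturate to ``r_max``.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("GTP concentration must be non-negative")
    if model.is_null:
        out = np.full_like(conc, model.r_min)
        return out[()] if out.ndim == 0 else out
    ch = np.power(conc, model.hill)
    kh = model.keff**model.hill
    with np.errstate(invalid="ignore"):
        frac = np.where(np.isinf(ch), 1.0, ch / (kh + ch))
    out = model.r_min + (model.r_max - model.r_min) * frac
    return out[()] if out.ndim == 0 else out


GEVAL30 = SensorModel(keff=32.3, r_min=1.0, r_max=3.0, is_null=False)
GEVAL_NULL = SensorModel(keff=32.3, r_min=1.0, r_max=3.0, is_null=True)
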