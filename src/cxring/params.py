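"""Membrane and template constants shared by all neurons.

All values are stored in SI units internally (volts, amps, farads, ohms,
seconds).  The constructor accepts the conventional neurophysiology units
(mV, nA, nF, MOhm, ms) so that code reads like the literature.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


class ParameterError(ValueError):
    """Raised when neuron parameters violate their invariants."""


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire neuron constants.

    Parameters are given in interface units and converted to SI on access
    through the ``*_si`` properties.

    Attributes
    ----------
    C_m : float
        Membrane capacitance in nF (default 2).
    R_m : float
        Membrane resistance in MOhm (default 10).
    V_0 : float
        Resting potential in mV (default -52).
    V_thr : float
        Spike threshold in mV (default -45).
    V_max : float
        Action-potential peak in mV (default 20).
    V_min : float
        Action-potential undershoot in mV (default -72).
    t_AP : float
        Action-potential duration in ms (default 2).
    I_PSC : float
        Postsynaptic-current magnitude in nA (default 5).
    t_PSC : float
        Postsynaptic-current decay half-life in ms (default 5).
    dt : float
        Euler integration step in seconds (default 1e-4).
    """

    C_m: float = 2.0
    R_m: float = 10.0
    V_0: float = -52.0
    V_thr: float = -45.0
    V_max: float = 20.0
    V_min: float = -72.0
    t_AP: float = 2.0
    I_PSC: float = 5.0
    t_PSC: float = 5.0
    dt: float = 1e-4

    def __post_init__(self) -> None:
        if not (self.V_min < self.V_0 < self.V_thr < self.V_max):
            raise ParameterError(
                "potentials must satisfy V_min < V_0 < V_thr < V_max, got "
                f"{self.V_min}, {self.V_0}, {self.V_thr}, {self.V_max}"
            )
        for name in ("C_m", "R_m", "t_AP", "t_PSC", "dt"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")

    # --- SI conversions -------------------------------------------------
    @property
    def C_m_si(self) -> float:  # farads
        return self.C_m * 1e-9

    @property
    def R_m_si(self) -> float:  # ohms
        return self.R_m * 1e6

    @property
    def g_leak_si(self) -> float:  # siemens
        return 1.0 / self.R_m_si

    @property
    def V_0_si(self) -> float:
        return self.V_0 * 1e-3

    @property
    def V_thr_si(self) -> float:
        return self.V_thr * 1e-3

    @property
    def V_max_si(self) -> float:
        return self.V_max * 1e-3

    @property
    def V_min_si(self) -> float:
        return self.V_min * 1e-3

    @property
    def t_AP_si(self) -> float:
        return self.t_AP * 1e-3

    @property
    def I_PSC_si(self) -> float:
        return self.I_PSC * 1e-9

    @property
    def t_PSC_si(self) -> float:
        return self.t_PSC * 1e-3

    @property
    def tau_m(self) -> float:
        """Membrane time constant R_m * C_m in seconds (20 ms by default)."""
        return self.R_m_si * self.C_m_si

    @property
    def rheobase_si(self) -> float:
        """Minimum constant current (A) that can reach threshold."""
        return (self.V_thr_si - self.V_0_si) / self.R_m_si

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())
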