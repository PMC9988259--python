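"""Self-motion stimulus kinematics.

Both the motion platform and the optic-flow display follow a bell-shaped
(Gaussian) velocity profile: the trajectory is a forward translation with a
small lateral component, lasting ``duration_s`` seconds and covering
``displacement_m`` meters, with the stated peak velocity.  The temporal
standard deviation of the velocity bell is fully determined by the
displacement and the peak velocity,

    sigma_t = displacement / (peak_velocity * sqrt(2 * pi)),

and the implied peak acceleration is ``peak_velocity * exp(-1/2) / sigma_t``
(the extremum of the biphasic derivative of a Gaussian).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = ["StimulusProfile", "DEFAULT_STIMULUS"]


@dataclass(frozen=True)
class StimulusProfile:
    """Gaussian-velocity translation stimulus.

    Parameters
    ----------
    duration_s:
        Stimulus duration in seconds; velocity is zero outside ``[0, duration_s]``.
    displacement_m:
        Total displacement in meters (the integral of velocity over the stimulus).
    peak_velocity_mps:
        Peak velocity in m/s, reached at the temporal midpoint.
    """

    duration_s: float = 1.0
    displacement_m: float = 0.13
    peak_velocity_mps: float = 0.41
    sigma_t_s: float = field(init=False)

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.displacement_m <= 0 or self.peak_velocity_mps <= 0:
            raise ValueError("stimulus kinematic parameters must be positive")
        sigma = self.displacement_m / (self.peak_velocity_mps * math.sqrt(2.0 * math.pi))
        object.__setattr__(self, "sigma_t_s", sigma)

    @property
    def t_peak_s(self) -> float:
        """Time of peak velocity (stimulus midpoint)."""
        return self.duration_s / 2.0

    @property
    def peak_accel_mps2(self) -> float:
        """Peak magnitude of the biphasic acceleration profile."""
        return self.peak_velocity_mps * math.exp(-0.5) / self.sigma_t_s

    def velocity(self, t: np.ndarray | float) -> np.ndarray:
        """Velocity v(t) in m/s; zero outside the stimulus interval."""
        t = np.asarray(t, dtype=float)
        u = (t - self.t_peak_s) / self.sigma_t_s
        v = self.peak_velocity_mps * np.exp(-0.5 * u * u)
        return np.where((t >= 0.0) & (t <= self.duration_s), v, 0.0)

    def accel(self, t: np.ndarray | float) -> np.ndarray:
        """Acceleration a(t) = dv/dt in m/s^2 (biphasic)."""
        t = np.asarray(t, dtype=float)
        u = (t - self.t_peak_s) / self.sigma_t_s
        a = -self.peak_velocity_mps * u / self.sigma_t_s * np.exp(-0.5 * u * u)
        return np.where((t >= 0.0) & (t <= self.duration_s), a, 0.0)

    def velocity_modulation(self, t: np.ndarray | float) -> np.ndarray:
        """v(t) normalized to unit peak; the canonical temporal gain m(t)."""
        return self.velocity(t) / self.peak_velocity_mps


#: Study-standard profile: 1 s, 13 cm, 0.41 m/s peak (peak accel ~2.0 m/s^2).
DEFAULT_STIMULUS = StimulusProfile()
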