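"""Programmed rounding kinetics and the stadium shape family.

The generator renders silhouettes from a one-parameter family of stadium
shapes (a rectangle of length ``l`` capped by two semicircles of radius
``rho``; corner radius equals half the width, so every member is a rounded
rectangle). For elongation ``u = l / rho`` the analytic circularity is

    c(u) = pi * (pi + 2 u) / (pi + u)^2

which decreases monotonically from 1 (disc, u = 0) toward 0, so any target
circularity in (0, 1] maps to a unique elongation. This closed form is what
lets the generator program an exact circularity curve and hand it to the
measurement code as ground truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "stadium_circularity",
    "stadium_elongation",
    "aspect_to_elongation",
    "aspect_to_circularity",
    "RoundingKinetics",
]


def stadium_circularity(u: float) -> float:
    """Analytic circularity 4*pi*A/P^2 of a stadium with elongation u = l/rho."""
    if u < 0:
        raise ValueError("elongation must be >= 0")
    return math.pi * (math.pi + 2.0 * u) / (math.pi + u) ** 2


def stadium_elongation(c: float) -> float:
    """Inverse of :func:`stadium_circularity` on (0, 1]."""
    if not 0.0 < c <= 1.0:
        raise ValueError("circularity must be in (0, 1]")
    return math.pi * ((1.0 - c) + math.sqrt(1.0 - c)) / c


def aspect_to_elongation(aspect_ratio: float) -> float:
    """Elongation of a stadium with the given long:short aspect ratio (>= 1)."""
    if aspect_ratio < 1:
        raise ValueError("aspect_ratio must be >= 1")
    return 2.0 * (aspect_ratio - 1.0)


def aspect_to_circularity(aspect_ratio: float) -> float:
    """Analytic circularity of the initial rounded rectangle of a given aspect ratio."""
    return stadium_circularity(aspect_to_elongation(aspect_ratio))


def _smoothstep(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _logistic(s: np.ndarray, k: float = 6.0) -> np.ndarray:
    # rescaled so the window endpoints map exactly to 0 and 1
    raw = 1.0 / (1.0 + np.exp(-k * (np.clip(s, 0, 1) - 0.5)))
    lo, hi = 1.0 / (1.0 + math.exp(k / 2)), 1.0 / (1.0 + math.exp(-k / 2))
    return (raw - lo) / (hi - lo)


@dataclass
class RoundingKinetics:
    """Programmed circularity-versus-time curve of a rounding cell mass.

    The curve is flat at ``c0`` until ``t_latent`` (latent phase), rises to
    ``c_inf`` by ``t_static`` (rising phase) and stays flat afterwards
    (static phase). Discrete fusion events appear as instantaneous upward
    steps; the continuous rise is shrunk by the total jump amplitude so the
    programmed curve stays monotone and ends exactly at ``c_inf``.

    Parameters
    ----------
    c_inf : float
        Plateau circularity, in (0, 1].
    t_latent, t_static : float
        End of the latent phase / start of the static phase, hours.
    c0 : float or None
        Initial circularity. ``None`` means "derive from the initial shape"
        (the rounding generator fills it in from the aspect ratio).
    jumps : list of (time_h, delta)
        Instantaneous circularity steps from part-fusion events; all jump
        times must lie inside the rising window.
    shape : {"smoothstep", "logistic"}
        Functional form of the continuous rise. Both are exactly flat (or
        numerically flat) outside the rising window.
    logistic_k : float
        Steepness of the logistic rise over the unit rising window. The
        default keeps the rise confined to the window while the slope at
        the window edges stays above typical phase-detection thresholds,
        so the programmed boundaries remain well defined.
    """

    c_inf: float = 0.95
    t_latent: float = 5.0
    t_static: float = 18.0
    c0: float | None = None
    jumps: list[tuple[float, float]] = field(default_factory=list)
    shape: str = "smoothstep"
    logistic_k: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 < self.c_inf <= 1.0:
            raise ValueError("c_inf must be in (0, 1]")
        if self.t_latent >= self.t_static:
            raise ValueError("t_latent must be < t_static")
        if self.c0 is not None and not 0.0 < self.c0 <= self.c_inf:
            raise ValueError("need 0 < c0 <= c_inf")
        if any(d < 0 for _, d in self.jumps):
            raise ValueError("jump amplitudes must be >= 0")
        for t, _ in self.jumps:
            if not self.t_latent < t < self.t_static:
                raise ValueError("jump times must lie in the rising window")
        if self.shape not in ("smoothstep", "logistic"):
            raise ValueError("shape must be 'smoothstep' or 'logistic'")

    @property
    def total_jump(self) -> float:
        return float(sum(d for _, d in self.jumps))

    def curve(self, times_h: np.ndarray) -> np.ndarray:
        """Programmed circularity at the given times (hours)."""
        if self.c0 is None:
            raise ValueError("c0 is unset; provide one or let the generator derive it")
        rise = self.c_inf - self.c0
        if self.total_jump > rise + 1e-12:
            raise ValueError("sum of jump amplitudes exceeds c_inf - c0")
        t = np.asarray(times_h, dtype=float)
        s = (t - self.t_latent) / (self.t_static - self.t_latent)
        ramp = (_smoothstep(s) if self.shape == "smoothstep"
                else _logistic(s, self.logistic_k))
        c = self.c0 + (rise - self.total_jump) * ramp
        for tj, dj in self.jumps:
            c = c + dj * (t >= tj)
        return c
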