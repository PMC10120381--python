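"""Two-stage exponential model of dark adaptation.

After an intense bleach, the detection threshold (log10 cd/m^2) recovers in
two phases: an initial cone-driven exponential decay towards the cone
plateau, followed at the rod--cone break time ``tb`` by a second, slower
rod-driven exponential decay.  The threshold at time ``t`` seconds after
bleach offset is

    y(t) = Bc + Ic * exp(Rc * t)                                  t <  tb
    y(t) = Bc + Ic * exp(Rc * tb) - Ir * exp(Rr * tb)
              + Ir * exp(Rr * t)                                  t >= tb

with cone asymptote ``Bc``, cone magnitude/rate ``Ic``/``Rc``, rod
magnitude/rate ``Ir``/``Rr``.  The second branch is continuous at ``tb`` by
construction; the rod asymptote is not a free parameter but the ``t -> inf``
limit of the second branch (see :func:`rod_asymptote`).

Clinical outcomes derived from a pair of per-channel fits:

* cone threshold  -- ``Bc`` of the red-channel (625 nm) fit,
* final rod threshold -- rod asymptote of the green-channel (527 nm) fit,
* time to rod--cone break (TRCB) -- ``tb`` of the green fit, in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "DAParams",
    "DAOutcome",
    "eval_model",
    "rod_asymptote",
    "derive_outcomes",
    "DEFAULT_TEST_DURATION_S",
]

#: Default test duration, seconds (35-minute protocol).
DEFAULT_TEST_DURATION_S = 2100.0


@dataclass(frozen=True)
class DAParams:
    """Parameters of one fitted dark-adaptation curve.

    Attributes
    ----------
    Bc : float
        Cone asymptote (log10 cd/m^2).
    Ic : float
        Cone decay magnitude (log10 cd/m^2 units), >= 0.
    Rc : float
        Cone decay rate (1/s), < 0.
    Ir : float
        Rod decay magnitude (log10 cd/m^2 units), >= 0.
    Rr : float
        Rod decay rate (1/s), < 0.
    tb : float
        Rod--cone break time (s since bleach offset), within
        ``(0, test duration)``.
    """

    Bc: float
    Ic: float
    Rc: float
    Ir: float
    Rr: float
    tb: float

    def validate(self, test_duration: float = DEFAULT_TEST_DURATION_S) -> None:
        """Raise ``ValueError`` if the parameters violate the model invariants."""
        if not (self.Rc < 0 and self.Rr < 0):
            raise ValueError(f"decay rates must be negative: Rc={self.Rc}, Rr={self.Rr}")
        if self.Ic < 0 or self.Ir < 0:
            raise ValueError(f"decay magnitudes must be non-negative: Ic={self.Ic}, Ir={self.Ir}")
        if not (0 < self.tb < test_duration):
            raise ValueError(f"break time tb={self.tb} outside (0, {test_duration})")
        for name in ("Bc", "Ic", "Rc", "Ir", "Rr", "tb"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite parameter {name}")

    def as_array(self) -> np.ndarray:
        return np.array([self.Bc, self.Ic, self.Rc, self.Ir, self.Rr, self.tb], float)

    @classmethod
    def from_array(cls, arr) -> "DAParams":
        Bc, Ic, Rc, Ir, Rr, tb = (float(v) for v in arr)
        return cls(Bc=Bc, Ic=Ic, Rc=Rc, Ir=Ir, Rr=Rr, tb=tb)


@dataclass(frozen=True)
class DAOutcome:
    """The three clinical outcomes of one participant's dark-adaptation test."""

    cone_threshold: float  # log10 cd/m^2, from the red-channel fit
    rod_threshold: float   # log10 cd/m^2, from the green-channel fit
    trcb_minutes: float    # time to rod-cone break, minutes
    flags: tuple = field(default_factory=tuple)


def eval_model(params: DAParams, t: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Evaluate the two-stage decay at time(s) ``t`` seconds after bleach offset.

    Parameters
    ----------
    params : DAParams
    t : float or array-like
        Time(s) since bleach offset, seconds; must be >= 0.

    Returns
    -------
    float or ndarray
        Threshold(s) in log10 cd/m^2.  Continuous at ``tb`` and monotone
        non-increasing in ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0 (seconds since bleach offset)")
    Bc, Ic, Rc, Ir, Rr, tb = params.Bc, params.Ic, params.Rc, params.Ir, params.Rr, params.tb
    cone = Bc + Ic * np.exp(Rc * t_arr)
    level_at_tb = Bc + Ic * math.exp(Rc * tb) - Ir * math.exp(Rr * tb)
    rod = level_at_tb + Ir * np.exp(Rr * t_arr)
    out = np.where(t_arr < tb, cone, rod)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def rod_asymptote(params: DAParams) -> float:
    """Limit of the rod branch as ``t -> inf``: the final rod threshold.

    Equals ``Bc + Ic*exp(Rc*tb) - Ir*exp(Rr*tb)``, i.e. the curve value at
    the break minus the full rod magnitude remaining at ``tb``.
    """
    return float(params.Bc + params.Ic * math.exp(params.Rc * params.tb)
                 - params.Ir * math.exp(params.Rr * params.tb))


def derive_outcomes(
    red_fit: DAParams,
    green_fit: DAParams,
    *,
    trcb_channel: str = "green",
    rod_threshold_mode: str = "asymptote",
    test_duration: float = DEFAULT_TEST_DURATION_S,
) -> DAOutcome:
    """Derive the clinical outcomes from the red- and green-channel fits.

    Cone threshold is the cone asymptote of the red (625 nm) curve; the
    final rod threshold comes from the green (527 nm) curve -- by default
    its rod asymptote, alternatively (``rod_threshold_mode="test_end"``)
    the model value at the end of the test.  TRCB is the break time of the
    green fit (configurable to the red fit) in minutes.
    """
    if trcb_channel not in ("green", "red"):
        raise ValueError(f"trcb_channel must be 'green' or 'red', got {trcb_channel!r}")
    if rod_threshold_mode not in ("asymptote", "test_end"):
        raise ValueError(f"unknown rod_threshold_mode {rod_threshold_mode!r}")
    cone = float(red_fit.Bc)
    if rod_threshold_mode == "asymptote":
        rod = rod_asymptote(green_fit)
    else:
        rod = float(eval_model(green_fit, test_duration))
    tb = green_fit.tb if trcb_channel == "green" else red_fit.tb
    flags = ()
    if rod > cone:
        # pathological fit: rods ended less sensitive than cones
        flags = ("rod_above_cone",)
    return DAOutcome(cone_threshold=cone, rod_threshold=rod,
                     trcb_minutes=float(tb) / 60.0, flags=flags)
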