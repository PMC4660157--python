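"""Flagellar motor switching.

CheY-P binds the flagellar motor and raises the probability of clockwise
(CW) rotation, which produces a tumble.  The CW bias follows the sigmoidal
Hill relationship

    Bias = 1 / (1 + prefactor * (Yp* / Yp)**hill_exponent)

where ``Yp*`` is the cell's unstimulated steady-state CheY-P concentration.
Referencing each cell's own Yp* shifts the sigmoid per cell, so cells with
different total protein content (different beta) keep a sensible operating
point.  With the default prefactor 3.7 and Hill exponent 5.5 the
unstimulated CW bias is 1/4.7 ~ 0.21.

At each timestep a uniform draw r decides the flagellar state: tumble iff
Bias > r, run otherwise (ties run).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MotorError", "MotorSpec", "cw_bias", "decide_flagellar_state",
           "RUN", "TUMBLE"]

RUN = "run"
TUMBLE = "tumble"


class MotorError(ValueError):
    """Invalid motor specification or input."""


@dataclass(frozen=True)
class MotorSpec:
    """CW-bias curve: Hill exponent, prefactor, and reference CheY-P (uM)."""

    hill_exponent: float = 5.5
    prefactor: float = 3.7
    yp_star: float = 4.043

    def __post_init__(self) -> None:
        if self.hill_exponent <= 0:
            raise MotorError("hill_exponent must be positive")
        if self.prefactor <= 0:
            raise MotorError("prefactor must be positive")
        if self.yp_star <= 0:
            raise MotorError("yp_star must be positive")


def cw_bias(Yp, spec: MotorSpec, yp_star=None):
    """Clockwise (tumble) bias for CheY-P concentration ``Yp`` (uM).

    ``yp_star`` overrides the spec's reference level (scalar or per-cell
    array), used by the population engine where every cell carries its own
    unstimulated CheY-P.
    """
    Yp = np.asarray(Yp, dtype=float)
    if np.any(Yp <= 0):
        raise MotorError("Yp must be positive")
    ref = spec.yp_star if yp_star is None else np.asarray(yp_star, dtype=float)
    out = 1.0 / (1.0 + spec.prefactor * (ref / Yp) ** spec.hill_exponent)
    return out if out.shape else float(out)


def decide_flagellar_state(bias, r):
    """Per-step run/tumble decision: tumble iff ``bias > r`` (strict).

    Vectorised: returns a boolean array (True = tumble) for array input, or
    the string ``"tumble"``/``"run"`` for scalars.
    """
    bias_a = np.asarray(bias, dtype=float)
    r_a = np.asarray(r, dtype=float)
    if np.any(bias_a < 0) or np.any(bias_a > 1):
        raise MotorError("bias must lie in [0, 1]")
    if np.any(r_a < 0) or np.any(r_a > 1):
        raise MotorError("r must lie in [0, 1]")
    tumble = bias_a > r_a
    if tumble.shape:
        return tumble
    return TUMBLE if bool(tumble) else RUN
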