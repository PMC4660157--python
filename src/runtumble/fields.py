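"""Static chemoattractant fields.

All experiments take place in a fixed two-dimensional domain with one or two
stationary ligand profiles.  The workhorse is a radially symmetric exponential
bump

    [L](x, y) = scaling * ( l0 + exp(-((x - cx)^2 + (y - cy)^2) / d) )

where ``l0`` is a minimum (background) concentration in mM, ``d`` sets the
gradient steepness (large ``d`` -> shallow, small ``d`` -> steep) and
``scaling`` multiplies the whole profile.  Fields are immutable and do not
evolve in time: ligand diffusion, degradation and consumption are outside the
model (MeAsp in particular is non-metabolisable).

Two ligand species are supported, MeAsp (sensed by the Tar receptor) and
serine (sensed by Tsr).  A two-ligand field pairs one exponential profile per
species; the competition experiments centre the MeAsp bump at (-1, 0) and the
serine bump at (+1, 0) and scale them by factors conventionally called
``omega`` (MeAsp) and ``upsilon`` (serine).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple, Union

import numpy as np

__all__ = [
    "FieldSpecError",
    "NoUniquePeakError",
    "ExponentialFieldSpec",
    "ConstantFieldSpec",
    "TwoLigandFieldSpec",
    "FieldSpec",
    "eval_exponential_field",
    "eval_field_at",
    "field_peak",
    "two_ligand_field",
    "background_concentrations",
]

MEASP = "MeAsp"
SERINE = "serine"


class FieldSpecError(ValueError):
    """Invalid ligand-field specification."""


class NoUniquePeakError(FieldSpecError):
    """The field has no unique maximum (e.g. a constant field)."""


@dataclass(frozen=True)
class ExponentialFieldSpec:
    """Radially symmetric exponential bump for a single ligand species.

    Parameters
    ----------
    l0 : minimum concentration (mM), reached infinitely far from the peak.
    d : steepness divisor of the squared radius; dimensionless in domain units.
    center : (x, y) coordinates of the peak, domain units.
    scaling : multiplicative factor applied to the whole profile.
    species : ligand species name, ``"MeAsp"`` or ``"serine"``.
    """

    l0: float = 0.1
    d: float = 1.0
    center: Tuple[float, float] = (0.0, 0.0)
    scaling: float = 1.0
    species: str = MEASP

    def __post_init__(self) -> None:
        if not self.l0 >= 0:
            raise FieldSpecError(f"l0 must be >= 0, got {self.l0}")
        if not self.d > 0:
            raise FieldSpecError(f"steepness divisor d must be > 0, got {self.d}")
        if not self.scaling > 0:
            raise FieldSpecError(f"scaling must be > 0, got {self.scaling}")
        if self.species not in (MEASP, SERINE):
            raise FieldSpecError(f"unknown ligand species {self.species!r}")


@dataclass(frozen=True)
class ConstantFieldSpec:
    """Spatially uniform ligand concentration (mM)."""

    level: float = 0.1
    species: str = MEASP

    def __post_init__(self) -> None:
        if not self.level >= 0:
            raise FieldSpecError(f"level must be >= 0, got {self.level}")
        if self.species not in (MEASP, SERINE):
            raise FieldSpecError(f"unknown ligand species {self.species!r}")


@dataclass(frozen=True)
class TwoLigandFieldSpec:
    """Independent MeAsp and serine profiles evaluated side by side."""

    meAsp: Union[ExponentialFieldSpec, ConstantFieldSpec] = field(
        default_factory=lambda: ExponentialFieldSpec(species=MEASP)
    )
    serine: Union[ExponentialFieldSpec, ConstantFieldSpec] = field(
        default_factory=lambda: ExponentialFieldSpec(species=SERINE)
    )

    def __post_init__(self) -> None:
        if self.meAsp.species != MEASP:
            raise FieldSpecError("meAsp component must have species 'MeAsp'")
        if self.serine.species != SERINE:
            raise FieldSpecError("serine component must have species 'serine'")


FieldSpec = Union[ExponentialFieldSpec, ConstantFieldSpec, TwoLigandFieldSpec]


def eval_exponential_field(spec: ExponentialFieldSpec, position) -> np.ndarray:
    """Evaluate one exponential profile at ``position`` = (x, y).

    Accepts scalar coordinates or equal-shape arrays; returns mM.
    """
    x, y = position
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise FieldSpecError("position must be finite")
    cx, cy = spec.center
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    return spec.scaling * (spec.l0 + np.exp(-r2 / spec.d))


def eval_field_at(spec: FieldSpec, position) -> Dict[str, np.ndarray]:
    """Per-species ligand concentrations (mM) at ``position``.

    Returns a dict keyed by species name; a two-ligand spec yields both
    entries, single-species specs yield one.
    """
    if isinstance(spec, ExponentialFieldSpec):
        return {spec.species: eval_exponential_field(spec, position)}
    if isinstance(spec, ConstantFieldSpec):
        x = np.asarray(position[0], dtype=float)
        return {spec.species: np.broadcast_to(np.float64(spec.level), x.shape).copy()
                if x.shape else np.float64(spec.level)}
    if isinstance(spec, TwoLigandFieldSpec):
        out = eval_field_at(spec.meAsp, position)
        out.update(eval_field_at(spec.serine, position))
        return out
    raise FieldSpecError(f"unknown field spec type {type(spec).__name__}")


def field_peak(spec: FieldSpec):
    """Location and value of the field maximum.

    For an exponential spec returns ``(center, scaling * (l0 + 1))``.  For a
    two-ligand spec returns a dict of per-species peaks.  Constant fields have
    no unique maximum and raise :class:`NoUniquePeakError`.
    """
    if isinstance(spec, ExponentialFieldSpec):
        return spec.center, spec.scaling * (spec.l0 + 1.0)
    if isinstance(spec, TwoLigandFieldSpec):
        return {
            MEASP: field_peak(spec.meAsp),
            SERINE: field_peak(spec.serine),
        }
    if isinstance(spec, ConstantFieldSpec):
        raise NoUniquePeakError("a constant field has no unique peak")
    raise FieldSpecError(f"unknown field spec type {type(spec).__name__}")


def two_ligand_field(
    omega: float = 1.0,
    upsilon: float = 0.0025,
    l_a0: float = 0.1,
    l_s0: float = 0.1,
    x_a: float = 1.0,
    x_s: float = -1.0,
    d: float = 1.0,
) -> TwoLigandFieldSpec:
    """Competition field: MeAsp bump centred at (-x_a, 0), serine at (-x_s, 0).

    With the defaults x_a = 1, x_s = -1 the MeAsp gradient peaks at (-1, 0)
    and the serine gradient at (+1, 0); ``omega`` and ``upsilon`` are the
    multiplicative scalings of the two profiles.
    """
    return TwoLigandFieldSpec(
        meAsp=ExponentialFieldSpec(l0=l_a0, d=d, center=(-x_a, 0.0),
                                   scaling=omega, species=MEASP),
        serine=ExponentialFieldSpec(l0=l_s0, d=d, center=(-x_s, 0.0),
                                    scaling=upsilon, species=SERINE),
    )


def background_concentrations(spec: FieldSpec) -> Dict[str, float]:
    """Far-field ("absence of any stimulus") concentration per species.

    Used to define each cell's unstimulated reference CheY-P level: the
    exponential term vanishes far from the peak, leaving ``scaling * l0``.
    Constant fields are their own background.
    """
    if isinstance(spec, ExponentialFieldSpec):
        return {spec.species: spec.scaling * spec.l0}
    if isinstance(spec, ConstantFieldSpec):
        return {spec.species: spec.level}
    if isinstance(spec, TwoLigandFieldSpec):
        out = background_concentrations(spec.meAsp)
        out.update(background_concentrations(spec.serine))
        return out
    raise FieldSpecError(f"unknown field spec type {type(spec).__name__}")
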