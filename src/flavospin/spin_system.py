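"""Domain types for the S=1/2 spin Hamiltonian of a flavin semiquinone.

The static Hamiltonian analysed by this package is

    H = mu_B B.g.S  +  sum_j mu_N B gN_j I_j  +  sum_j S.A_j.I_j
        + sum_{j, I_j>1/2} I_j.Q_j.I_j

with one unpaired electron (S = 1/2) coupled to a set of ring nuclei, each
carrying a hyperfine tensor ``A`` and, for I >= 1, a traceless nuclear
quadrupole tensor ``Q``.  Tensors are stored by their three principal
values (MHz) plus Euler angles relating the tensor frame to the g frame;
the g-tensor z axis is perpendicular to the isoalloxazine ring plane and
the hyperfine/quadrupole frames default to collinear with g.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    GN_RATIO_14N_15N,
    NUCLEAR_G_FACTORS,
    NUCLEAR_MAGNETON,
    NUCLEAR_SPINS,
    PLANCK_H,
    PRINTED_SCALING_14N_15N,
)

__all__ = [
    "Nucleus",
    "PrincipalTensor",
    "GTensor",
    "SpinSystem",
    "decompose_tensor",
    "compose_tensor",
    "isotope_scale",
    "larmor_frequency",
    "euler_matrix",
]

_TRACELESS_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when a spin-system object violates a structural invariant."""


def euler_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Active z-y-z rotation matrix R = Rz(alpha) @ Ry(beta) @ Rz(gamma).

    Angles in degrees.  A tensor with principal values ``diag(v)`` in its
    own frame has matrix ``R @ diag(v) @ R.T`` in the g frame.
    """
    a, b, g = np.radians([alpha, beta, gamma])

    def rz(t: float) -> np.ndarray:
        c, s = math.cos(t), math.sin(t)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def ry(t: float) -> np.ndarray:
        c, s = math.cos(t), math.sin(t)
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    return rz(a) @ ry(b) @ rz(g)


@dataclass(frozen=True)
class Nucleus:
    """A magnetic nucleus on (or bound to) the isoalloxazine ring.

    Parameters
    ----------
    isotope:
        Isotope label, e.g. ``"13C"``, ``"15N"``.  Known isotopes pull
        their spin and nuclear g factor from the built-in table; custom
        isotopes must supply both explicitly.
    position:
        IUPAC ring-position label, e.g. ``"4a"``, ``"5"``, ``"10"``.
    """

    isotope: str
    position: str = ""
    spin: float | None = None
    g_factor: float | None = None

    def __post_init__(self) -> None:
        spin = self.spin
        gn = self.g_factor
        if spin is None:
            try:
                spin = NUCLEAR_SPINS[self.isotope]
            except KeyError:
                raise ValidationError(
                    f"unknown isotope {self.isotope!r}: supply spin and g_factor"
                ) from None
        if gn is None:
            try:
                gn = NUCLEAR_G_FACTORS[self.isotope]
            except KeyError:
                raise ValidationError(
                    f"no nuclear g factor on record for {self.isotope!r}"
                ) from None
        if spin not in (0.5, 1.0):
            raise ValidationError(f"nuclear spin must be 1/2 or 1, got {spin}")
        if gn == 0 or not math.isfinite(gn):
            raise ValidationError("nuclear g factor must be nonzero and finite")
        object.__setattr__(self, "spin", float(spin))
        object.__setattr__(self, "g_factor", float(gn))

    @property
    def multiplicity(self) -> int:
        return int(round(2 * self.spin + 1))


@dataclass(frozen=True)
class PrincipalTensor:
    """Interaction tensor given by principal values (MHz) and orientation.

    ``euler`` are active z-y-z Euler angles in degrees taking the tensor
    frame into the g frame; the default (0, 0, 0) means collinear axes.
    ``traceless`` asserts that the principal values sum to zero, as every
    nuclear quadrupole tensor must.
    """

    values: tuple[float, float, float]
    euler: tuple[float, float, float] = (0.0, 0.0, 0.0)
    traceless: bool = False

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) != 3 or not all(math.isfinite(v) for v in vals):
            raise ValidationError(f"need three finite principal values, got {self.values!r}")
        if self.traceless and abs(sum(vals)) > _TRACELESS_TOL:
            raise ValidationError(
                f"traceless tensor has nonzero trace {sum(vals):.3e} MHz"
            )
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "euler", tuple(float(a) for a in self.euler))

    def matrix(self) -> np.ndarray:
        """3x3 symmetric tensor in the g frame."""
        rot = euler_matrix(*self.euler)
        return rot @ np.diag(self.values) @ rot.T

    @property
    def isotropic(self) -> float:
        return float(np.mean(self.values))

    @property
    def anisotropic(self) -> tuple[float, float, float]:
        a = self.isotropic
        return tuple(v - a for v in self.values)


@dataclass(frozen=True)
class GTensor:
    """Electron Zeeman g tensor, diagonal in the molecular frame.

    Defaults are the flavin semiquinone values (gX=2.0043, gY=2.0036,
    gZ=2.0022) with z perpendicular to the ring plane.
    """

    gx: float = 2.0043
    gy: float = 2.0036
    gz: float = 2.0022

    def __post_init__(self) -> None:
        for g in (self.gx, self.gy, self.gz):
            if not (1.5 <= g <= 2.5):
                raise ValidationError(f"implausible g value {g}")

    @property
    def values(self) -> tuple[float, float, float]:
        return (self.gx, self.gy, self.gz)

    def effective(self, n_hat: np.ndarray) -> float:
        """Effective g along the unit field direction ``n_hat``."""
        n = np.asarray(n_hat, dtype=float)
        g = np.array(self.values)
        return float(np.sqrt(np.sum((g * n) ** 2, axis=-1)))


@dataclass
class NucleusEntry:
    nucleus: Nucleus
    hyperfine: PrincipalTensor
    quadrupole: PrincipalTensor | None = None


@dataclass
class SpinSystem:
    """One S=1/2 electron plus its set of coupled ring nuclei."""

    g: GTensor = field(default_factory=GTensor)
    nuclei: list[NucleusEntry] = field(default_factory=list)
    name: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        for entry in self.nuclei:
            self._validate_entry(entry)

    @staticmethod
    def _validate_entry(entry: NucleusEntry) -> None:
        if entry.quadrupole is not None:
            if entry.nucleus.spin <= 0.5:
                raise ValidationError(
                    f"nucleus {entry.nucleus.isotope}({entry.nucleus.position}) has "
                    "I=1/2: a quadrupole tensor is only defined for I>1/2"
                )
            if not entry.quadrupole.traceless:
                raise ValidationError("quadrupole tensor must be flagged traceless")

    def add_nucleus(
        self,
        nucleus: Nucleus,
        hyperfine: PrincipalTensor,
        quadrupole: PrincipalTensor | None = None,
    ) -> None:
        entry = NucleusEntry(nucleus, hyperfine, quadrupole)
        self._validate_entry(entry)
        self.nuclei.append(entry)

    def copy(self) -> "SpinSystem":
        return copy.deepcopy(self)

    def with_hyperfine(self, index: int, tensor: PrincipalTensor) -> "SpinSystem":
        """Return a copy with nucleus ``index`` carrying a new hyperfine tensor."""
        out = self.copy()
        out.nuclei[index] = replace(out.nuclei[index], hyperfine=tensor)
        return out

    def with_quadrupole(self, index: int, tensor: PrincipalTensor) -> "SpinSystem":
        out = self.copy()
        out.nuclei[index] = replace(out.nuclei[index], quadrupole=tensor)
        self._validate_entry(out.nuclei[index])
        return out


def decompose_tensor(values) -> tuple[float, tuple[float, float, float]]:
    """Split principal hyperfine values into isotropic and traceless parts.

    Returns ``(a_iso, (T1, T2, T3))`` with ``a_iso`` the arithmetic mean
    and ``T_i = value_i - a_iso`` (so ``sum(T) == 0``), the standard
    a/T decomposition used to compare measured and calculated couplings.
    """
    vals = np.asarray(values, dtype=float)
    if vals.shape != (3,) or not np.all(np.isfinite(vals)):
        raise ValidationError(f"need three finite principal values, got {values!r}")
    a_iso = float(vals.mean())
    t = vals - a_iso
    return a_iso, (float(t[0]), float(t[1]), float(t[2]))


def compose_tensor(a_iso: float, t) -> tuple[float, float, float]:
    """Inverse of :func:`decompose_tensor`."""
    t = np.asarray(t, dtype=float)
    vals = a_iso + t
    return (float(vals[0]), float(vals[1]), float(vals[2]))


def isotope_scale(
    values,
    factor: float | None = None,
    mode: str = "preserve-printed-sign",
) -> tuple[float, float, float]:
    """Scale hyperfine principal values between isotopes at the same site.

    Hyperfine couplings are proportional to the nuclear g factor, so a
    tensor measured for one isotope converts to another by the ratio of
    g factors; for 15N -> 14N that ratio is about -0.71.

    Parameters
    ----------
    values:
        Three principal values, MHz.
    factor:
        Scaling factor.  Defaults to the conventional printed 15N -> 14N
        magnitude 0.71 in ``"preserve-printed-sign"`` mode and to the
        signed full-precision gN ratio in ``"strict-sign"`` mode.
    mode:
        ``"preserve-printed-sign"`` multiplies by ``|factor|`` so that a
        tensor quoted with positive principal values stays positive, the
        convention used when tabulating flavin couplings.
        ``"strict-sign"`` applies the signed factor.
    """
    vals = np.asarray(values, dtype=float)
    if vals.shape != (3,) or not np.all(np.isfinite(vals)):
        raise ValidationError(f"need three finite principal values, got {values!r}")
    if mode not in ("preserve-printed-sign", "strict-sign"):
        raise ValidationError(f"unknown sign mode {mode!r}")
    if factor is None:
        factor = PRINTED_SCALING_14N_15N if mode == "preserve-printed-sign" else GN_RATIO_14N_15N
    if factor == 0:
        raise ValidationError("scaling factor must be nonzero")
    eff = abs(factor) if mode == "preserve-printed-sign" else factor
    out = vals * eff
    return (float(out[0]), float(out[1]), float(out[2]))


def larmor_frequency(nucleus: Nucleus | str, field_mT: float) -> float:
    """Nuclear Larmor frequency |gN| mu_N B / h in MHz at a field in mT.

    The sign of gN (and hence the sense of precession) is available from
    ``nucleus.g_factor``; the returned frequency is the non-negative
    magnitude used in spectra.
    """
    if isinstance(nucleus, str):
        nucleus = Nucleus(nucleus)
    if field_mT < 0:
        raise ValidationError("magnetic field must be non-negative")
    b_tesla = field_mT * 1e-3
    nu_hz = abs(nucleus.g_factor) * NUCLEAR_MAGNETON * b_tesla / PLANCK_H
    return nu_hz * 1e-6


def larmor_frequency_signed(nucleus: Nucleus | str, field_mT: float) -> float:
    """Signed Larmor frequency gN mu_N B / h in MHz (sign of gN kept)."""
    if isinstance(nucleus, str):
        nucleus = Nucleus(nucleus)
    nu = larmor_frequency(nucleus, field_mT)
    return math.copysign(nu, nucleus.g_factor)
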