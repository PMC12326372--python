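"""Nuclear transition frequencies within each electron-spin manifold.

At Q-band fields the electron Zeeman interaction dominates the spin
Hamiltonian, so the nuclear sub-Hamiltonian can be evaluated separately
in each electron manifold mS = +/-1/2 (high-field approximation).  The
nucleus then sees an effective field (in frequency units)

    v = mS * (n_hat . A) - nu_L * n_hat           [MHz]

where ``A`` is the hyperfine matrix in the g frame, ``n_hat`` the unit
field direction and ``nu_L`` the signed nuclear Larmor frequency.  For
I = 1/2 the single transition frequency per manifold is |v|; for I = 1
the three nuclear sublevels of H_mS = v.I + I.Q.I give two single-quantum
lines and one double-quantum line per manifold.

The first-order strong/weak-coupling formulas

    strong (|A| > 2 nu_L):  nu_± = |A|/2 ± nu_L
    weak   (|A| < 2 nu_L):  nu_± = nu_L ± |A|/2

are provided for the closed-form analysis of ELDOR-detected NMR edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spin_system import (
    SpinSystem,
    ValidationError,
    larmor_frequency_signed,
)

__all__ = [
    "NuclearTransitionSet",
    "effective_field_vector",
    "nuclear_frequencies_exact",
    "nuclear_frequencies_first_order",
    "coupling_regime",
]

# spin-1 operators in the |mI=+1,0,-1> basis
_SQ2 = np.sqrt(2.0) / 2.0
_IX1 = np.array([[0, _SQ2, 0], [_SQ2, 0, _SQ2], [0, _SQ2, 0]])
_IY1 = np.array([[0, -_SQ2, 0], [_SQ2, 0, -_SQ2], [0, _SQ2, 0]]) * 1j
_IZ1 = np.diag([1.0, 0.0, -1.0]).astype(complex)
_I1_OPS = (_IX1.astype(complex), _IY1, _IZ1)

_CANCEL_TOL = 1e-6


@dataclass(frozen=True)
class NuclearTransitionSet:
    """Nuclear transition frequencies, per electron manifold.

    ``transitions`` maps mS (+0.5 / -0.5) to a list of
    ``(label, frequency_MHz)`` with labels ``"sq"`` for I=1/2 and
    ``"sq1"``, ``"sq2"``, ``"dq"`` for I=1.  Within a manifold entries
    are sorted by descending frequency, ties broken by label order
    (sq1, sq2, dq).
    """

    transitions: dict[float, tuple[tuple[str, float], ...]]

    def frequencies(self, ms: float) -> tuple[float, ...]:
        return tuple(f for _, f in self.transitions[ms])

    def single_quantum(self, ms: float) -> tuple[float, ...]:
        return tuple(f for lab, f in self.transitions[ms] if lab.startswith("sq"))


_LABEL_ORDER = {"sq": 0, "sq1": 0, "sq2": 1, "dq": 2}


def _sorted_entries(entries: list[tuple[str, float]]) -> tuple[tuple[str, float], ...]:
    return tuple(sorted(entries, key=lambda e: (-e[1], _LABEL_ORDER[e[0]])))


def effective_field_vector(
    a_matrix: np.ndarray, n_hat, ms: float, nu_larmor: float
) -> np.ndarray:
    """Effective field (MHz) seen by the nucleus in electron manifold mS.

    ``v = mS * (n_hat^T A) - nu_L * n_hat^T`` with ``nu_L`` signed.
    """
    n = np.asarray(n_hat, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-8:
        raise ValidationError(f"n_hat must be a unit vector, |n|={np.linalg.norm(n):.6f}")
    a = np.asarray(a_matrix, dtype=float)
    return ms * (n @ a) - nu_larmor * n


def _i1_frequencies(v: np.ndarray, q_matrix: np.ndarray | None) -> list[tuple[str, float]]:
    """Transition frequencies of H = v.I + I.Q.I for I=1."""
    h = sum(vi * op for vi, op in zip(v, _I1_OPS))
    if q_matrix is not None:
        q = np.asarray(q_matrix, dtype=complex)
        for i in range(3):
            for j in range(3):
                if q[i, j] != 0:
                    h = h + q[i, j] * (_I1_OPS[i] @ _I1_OPS[j])
    evals = np.linalg.eigvalsh(h)
    e0, e1, e2 = np.sort(evals)
    return [("sq1", float(e2 - e1)), ("sq2", float(e1 - e0)), ("dq", float(e2 - e0))]


def manifold_frequencies_bulk(
    system: SpinSystem,
    nucleus_index: int,
    dirs: np.ndarray,
    field_mT: float,
) -> dict[float, tuple[np.ndarray, tuple[str, ...]]]:
    """Vectorised manifold frequencies for many orientations at once.

    Returns, per electron manifold mS, an (n_orientations, n_transitions)
    frequency array and the matching transition labels.  Same physics as
    :func:`nuclear_frequencies_exact`, evaluated in bulk.
    """
    if field_mT <= 0:
        raise ValidationError("field must be positive")
    entry = system.nuclei[nucleus_index]
    dirs = np.asarray(dirs, dtype=float)
    nu_l = larmor_frequency_signed(entry.nucleus, field_mT)
    a = entry.hyperfine.matrix()
    out: dict[float, tuple[np.ndarray, tuple[str, ...]]] = {}
    if entry.nucleus.spin == 0.5:
        for ms in (0.5, -0.5):
            v = ms * (dirs @ a) - nu_l * dirs
            out[ms] = (np.linalg.norm(v, axis=1)[:, None], ("sq",))
        return out
    q = entry.quadrupole.matrix() if entry.quadrupole is not None else None
    q_term = np.zeros((3, 3), dtype=complex)
    if q is not None:
        for i in range(3):
            for j in range(3):
                if q[i, j] != 0:
                    q_term += q[i, j] * (_I1_OPS[i] @ _I1_OPS[j])
    ops = np.stack(_I1_OPS)  # (3, 3, 3)
    for ms in (0.5, -0.5):
        v = ms * (dirs @ a) - nu_l * dirs  # (n, 3)
        h = np.einsum("nk,kij->nij", v, ops) + q_term
        evals = np.linalg.eigvalsh(h)  # (n, 3) ascending
        sq1 = evals[:, 2] - evals[:, 1]
        sq2 = evals[:, 1] - evals[:, 0]
        dq = evals[:, 2] - evals[:, 0]
        out[ms] = (np.column_stack([sq1, sq2, dq]), ("sq1", "sq2", "dq"))
    return out


def nuclear_frequencies_exact(
    system: SpinSystem,
    nucleus_index: int,
    n_hat,
    field_mT: float,
) -> NuclearTransitionSet:
    """Nuclear frequencies of one nucleus, exact within each manifold.

    Diagonalises the (2I+1)-dimensional nuclear sub-Hamiltonian for each
    electron manifold; at Q-band fields this agrees with diagonalisation
    of the full electron-nuclear Hamiltonian to well below 1 %.
    """
    if field_mT <= 0:
        raise ValidationError("field must be positive")
    if not 0 <= nucleus_index < len(system.nuclei):
        raise ValidationError(
            f"nucleus index {nucleus_index} out of range (system has {len(system.nuclei)})"
        )
    entry = system.nuclei[nucleus_index]
    n = np.asarray(n_hat, dtype=float)
    nu_l = larmor_frequency_signed(entry.nucleus, field_mT)
    a = entry.hyperfine.matrix()
    q = entry.quadrupole.matrix() if entry.quadrupole is not None else None

    out: dict[float, tuple[tuple[str, float], ...]] = {}
    for ms in (0.5, -0.5):
        v = effective_field_vector(a, n, ms, nu_l)
        if entry.nucleus.spin == 0.5:
            entries = [("sq", float(np.linalg.norm(v)))]
        else:
            entries = _i1_frequencies(v, q)
        out[ms] = _sorted_entries(entries)
    return NuclearTransitionSet(out)


def coupling_regime(a_eff: float, nu_larmor: float) -> str:
    """Classify a secular coupling as strong, weak or at exact cancellation.

    Strong coupling means |A| > 2 nu_L (the nuclear Zeeman term is the
    smaller one and the HYSCORE correlations fall in the (+,-) quadrant).
    """
    if nu_larmor < 0:
        raise ValidationError("Larmor frequency must be non-negative")
    gap = abs(a_eff) - 2.0 * nu_larmor
    if abs(gap) < _CANCEL_TOL:
        return "cancellation"
    return "strong" if gap > 0 else "weak"


def nuclear_frequencies_first_order(
    a_eff: float, nu_larmor: float
) -> tuple[float, float, str]:
    """First-order nuclear frequencies (nu_plus, nu_minus, regime).

    Strong coupling: nu_± = |A|/2 ± nu_L, so nu_+ - nu_- = 2 nu_L and
    nu_+ + nu_- = |A|.  Weak coupling: nu_± = nu_L ± |A|/2.
    """
    if nu_larmor < 0:
        raise ValidationError("Larmor frequency must be non-negative")
    regime = coupling_regime(a_eff, nu_larmor)
    half_a = abs(a_eff) / 2.0
    if regime == "strong":
        nu_plus, nu_minus = half_a + nu_larmor, half_a - nu_larmor
    else:
        nu_plus, nu_minus = nu_larmor + half_a, abs(nu_larmor - half_a)
    return (nu_plus, nu_minus, regime)
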