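"""Independent brute-force oracles used by the tests.

The full-Hamiltonian oracle diagonalises the complete
(2S+1)(2I+1)-dimensional electron-nuclear Hamiltonian in frequency units
and reads nuclear transition frequencies from eigenvalue differences
within each electron manifold (states classified by the sign of the
electron-spin projection along the effective Zeeman axis).  It shares no
code with the package's per-manifold engine.
"""

from __future__ import annotations

import numpy as np

from flavospin.constants import BOHR_MAGNETON, NUCLEAR_MAGNETON, PLANCK_H

SIGMA = {
    "x": np.array([[0, 0.5], [0.5, 0]], dtype=complex),
    "y": np.array([[0, -0.5j], [0.5j, 0]], dtype=complex),
    "z": np.array([[0.5, 0], [0, -0.5]], dtype=complex),
}

_SQ2 = np.sqrt(2.0) / 2.0
SPIN1 = {
    "x": np.array([[0, _SQ2, 0], [_SQ2, 0, _SQ2], [0, _SQ2, 0]], dtype=complex),
    "y": np.array([[0, -_SQ2, 0], [_SQ2, 0, -_SQ2], [0, _SQ2, 0]], dtype=complex) * 1j,
    "z": np.diag([1.0, 0.0, -1.0]).astype(complex),
}


def _nuclear_ops(spin: float) -> list[np.ndarray]:
    if spin == 0.5:
        return [SIGMA["x"], SIGMA["y"], SIGMA["z"]]
    return [SPIN1["x"], SPIN1["y"], SPIN1["z"]]


def full_hamiltonian_frequencies(
    g_values,
    a_matrix,
    n_hat,
    field_mT,
    gn,
    spin,
    q_matrix=None,
):
    """Nuclear transition frequencies from the full Hamiltonian (MHz).

    Returns ``{+0.5: sorted_freqs, -0.5: sorted_freqs}`` with the
    electron manifolds identified by the expectation value of the
    electron spin along the Zeeman quantisation axis.  For I=1 the
    returned triple is (sq_high, sq_low, dq) sorted descending within
    the single-quantum pair plus the double-quantum difference.
    """
    n = np.asarray(n_hat, dtype=float)
    b_tesla = field_mT * 1e-3
    # electron Zeeman vector in MHz (g tensor diagonal in the molecular frame)
    g_vec = np.asarray(g_values, dtype=float) * n
    omega_e = BOHR_MAGNETON * b_tesla / PLANCK_H * 1e-6 * g_vec
    nu_l = gn * NUCLEAR_MAGNETON * b_tesla / PLANCK_H * 1e-6

    s_ops = [SIGMA["x"], SIGMA["y"], SIGMA["z"]]
    i_ops = _nuclear_ops(spin)
    dim_i = i_ops[0].shape[0]
    eye_s = np.eye(2)
    eye_i = np.eye(dim_i)

    h = np.zeros((2 * dim_i, 2 * dim_i), dtype=complex)
    for k in range(3):
        h += omega_e[k] * np.kron(s_ops[k], eye_i)
        h += -nu_l * n[k] * np.kron(eye_s, i_ops[k])
    a = np.asarray(a_matrix, dtype=float)
    for k in range(3):
        for m in range(3):
            if a[k, m] != 0:
                h += a[k, m] * np.kron(s_ops[k], i_ops[m])
    if q_matrix is not None:
        q = np.asarray(q_matrix, dtype=float)
        for k in range(3):
            for m in range(3):
                if q[k, m] != 0:
                    h += q[k, m] * np.kron(eye_s, i_ops[k] @ i_ops[m])

    evals, evecs = np.linalg.eigh(h)
    u = omega_e / np.linalg.norm(omega_e)
    s_u = sum(u[k] * np.kron(s_ops[k], eye_i) for k in range(3))
    proj = np.real(np.einsum("ij,jk,ki->i", evecs.conj().T, s_u, evecs))

    out = {}
    for ms, mask in ((0.5, proj > 0), (-0.5, proj < 0)):
        levels = np.sort(evals[mask])
        if levels.size == 2:
            out[ms] = np.array([levels[1] - levels[0]])
        else:
            e0, e1, e2 = levels
            sq = sorted([e2 - e1, e1 - e0], reverse=True)
            out[ms] = np.array([sq[0], sq[1], e2 - e0])
    return out


def first_derivative(y, x):
    """Reference numerical derivative (centred differences)."""
    return np.gradient(y, x)
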