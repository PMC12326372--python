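"""Physical constants (CODATA 2018) and nuclear data used throughout.

All spectroscopic quantities in this package are expressed in the units
conventional for pulse EPR: magnetic fields in mT, couplings and
frequencies in MHz.
"""

from __future__ import annotations

#: Planck constant, J s
PLANCK_H = 6.62607015e-34
#: Bohr magneton, J/T
BOHR_MAGNETON = 9.2740100783e-24
#: Nuclear magneton, J/T
NUCLEAR_MAGNETON = 5.0507837461e-27
#: Free-electron g factor (magnitude)
G_E = 2.00231930436256

#: Field-to-frequency conversion constant C = h/(g_e mu_B) in mT/MHz.
#: A hyperfine coupling of A MHz splits a field-swept line by C*A mT
#: (to first order, for g close to g_e).
FIELD_PER_MHZ = PLANCK_H / (G_E * BOHR_MAGNETON) * 1e9  # mT/MHz

#: Nuclear g factors (signed, dimensionless) for the isotopes handled here.
NUCLEAR_G_FACTORS: dict[str, float] = {
    "1H": 5.5856947,
    "13C": 1.4048236,
    "14N": 0.4037610,
    "15N": -0.5663796,
}

#: Nuclear spins for the same isotopes.
NUCLEAR_SPINS: dict[str, float] = {
    "1H": 0.5,
    "13C": 0.5,
    "14N": 1.0,
    "15N": 0.5,
}

#: Exact gN(14N)/gN(15N) ratio implied by the table above.
GN_RATIO_14N_15N = NUCLEAR_G_FACTORS["14N"] / NUCLEAR_G_FACTORS["15N"]

#: The conventional rounded scaling factor used when converting published
#: 15N hyperfine tensors to 14N (magnitude of the gN ratio, two decimals).
#: Printed tensor values in the literature round-trip with this factor,
#: not with the full-precision ratio.
PRINTED_SCALING_14N_15N = 0.71
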