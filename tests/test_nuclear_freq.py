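"""Nuclear transition frequencies: closed forms, exact engine, oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flavospin.nuclear_freq import (
    coupling_regime,
    effective_field_vector,
    manifold_frequencies_bulk,
    nuclear_frequencies_exact,
    nuclear_frequencies_first_order,
)
from flavospin.spin_system import (
    GTensor,
    Nucleus,
    PrincipalTensor,
    SpinSystem,
    ValidationError,
    larmor_frequency,
)
from flavospin.synthetic import make_fixture

from oracles import full_hamiltonian_frequencies


def test_effective_field_examples():
    a_iso = np.diag([40.0, 40.0, 40.0])
    v = effective_field_vector(a_iso, (0, 0, 1), 0.5, 13.1)
    assert v == pytest.approx((0.0, 0.0, 6.9))

    v = effective_field_vector(np.zeros((3, 3)), (0, 1, 0), 0.5, 13.1)
    assert np.linalg.norm(v) == pytest.approx(13.1)

    v = effective_field_vector(np.diag([-10.0, -10.0, 40.0]), (1, 0, 0), -0.5, 13.1)
    assert v == pytest.approx((-8.1, 0.0, 0.0))


def test_effective_field_requires_unit_vector():
    with pytest.raises(ValidationError):
        effective_field_vector(np.eye(3), (0, 0, 2.0), 0.5, 1.0)


class TestFirstOrder:
    def test_strong_coupling_identities(self):
        nu_p, nu_m, regime = nuclear_frequencies_first_order(40.0, 13.0)
        assert regime == "strong"
        assert (nu_p, nu_m) == (33.0, 7.0)
        assert nu_p - nu_m == pytest.approx(2 * 13.0)
        assert nu_p + nu_m == pytest.approx(40.0)

    def test_uncoupled(self):
        nu_p, nu_m, _ = nuclear_frequencies_first_order(0.0, 13.0)
        assert nu_p == nu_m == 13.0

    def test_weak_coupling(self):
        nu_p, nu_m, regime = nuclear_frequencies_first_order(10.0, 13.0)
        assert regime == "weak"
        assert (nu_p, nu_m) == (18.0, 8.0)

    @given(
        st.floats(min_value=0.01, max_value=120.0),
        st.floats(min_value=0.01, max_value=30.0),
    )
    def test_identities_hold_everywhere(self, a, nu_l):
        nu_p, nu_m, regime = nuclear_frequencies_first_order(a, nu_l)
        assert nu_p >= nu_m >= 0
        if regime == "strong":
            assert nu_p - nu_m == pytest.approx(2 * nu_l)
            assert nu_p + nu_m == pytest.approx(abs(a))
        elif regime == "weak":
            assert nu_p + nu_m == pytest.approx(2 * nu_l)


@pytest.mark.parametrize(
    "a, nu_l, expected",
    [(40.0, 13.1, "strong"), (10.0, 13.1, "weak"), (26.2, 13.1, "cancellation")],
)
def test_coupling_regime(a, nu_l, expected):
    assert coupling_regime(a, nu_l) == expected


class TestExactEngine:
    def test_13c4a_canonical_z(self):
        """Manifold frequencies at the ring normal, frozen from the
        full-Hamiltonian oracle: |A_z/2 -/+ nu_L| = 6.88 / 33.12 MHz."""
        system = make_fixture("13C4a")
        tset = nuclear_frequencies_exact(system, 0, (0, 0, 1), 1225.0)
        freqs = sorted([tset.transitions[0.5][0][1], tset.transitions[-0.5][0][1]])
        assert freqs == pytest.approx([6.88, 33.12], abs=0.01)

    def test_13c4a_in_plane(self):
        """In-plane the coupling (~9-13.5 MHz) is weak: the larger line
        sits near 18 MHz as in the experiment."""
        system = make_fixture("13C4a")
        tset = nuclear_frequencies_exact(system, 0, (0, 1, 0), 1225.0)
        freqs = sorted(tset.frequencies(0.5) + tset.frequencies(-0.5))
        assert 16.5 < max(freqs) < 19.0
        assert 7.5 < min(freqs) < 9.5

    def test_14n10_sq_pair_separation(self):
        """At the z orientation the two single-quantum lines of an I=1
        nucleus are split by 3|Qz| in each manifold."""
        system = make_fixture("14N10")
        qz = system.nuclei[0].quadrupole.values[2]
        tset = nuclear_frequencies_exact(system, 0, (0, 0, 1), 1225.0)
        for ms in (0.5, -0.5):
            sq = tset.single_quantum(ms)
            assert abs(sq[0] - sq[1]) == pytest.approx(3 * abs(qz), abs=1e-9)

    def test_transition_set_invariants(self):
        system = make_fixture("14N5")
        tset = nuclear_frequencies_exact(system, 0, (0.6, 0.0, 0.8), 1222.0)
        for ms in (0.5, -0.5):
            freqs = tset.frequencies(ms)
            assert all(f >= 0 for f in freqs)
            assert list(freqs) == sorted(freqs, reverse=True)
            labels = [lab for lab, _ in tset.transitions[ms]]
            assert sorted(labels) == ["dq", "sq1", "sq2"]
            sq = tset.single_quantum(ms)
            dq = [f for lab, f in tset.transitions[ms] if lab == "dq"][0]
            assert dq <= sq[0] + sq[1] + 1e-6

    def test_exact_matches_first_order_at_canonical_axis(self):
        """With a collinear axial tensor and the field on z, the exact
        and first-order frequencies coincide to numerical precision."""
        system = SpinSystem(g=GTensor())
        system.add_nucleus(Nucleus("13C"), PrincipalTensor((5.0, 5.0, 40.0)))
        nu_l = larmor_frequency("13C", 1225.0)
        tset = nuclear_frequencies_exact(system, 0, (0, 0, 1), 1225.0)
        nu_p, nu_m, _ = nuclear_frequencies_first_order(40.0, nu_l)
        exact = sorted([tset.transitions[0.5][0][1], tset.transitions[-0.5][0][1]])
        assert exact == pytest.approx(sorted([nu_p, nu_m]), abs=1e-6)

    def test_input_validation(self):
        system = make_fixture("13C4a")
        with pytest.raises(ValidationError):
            nuclear_frequencies_exact(system, 0, (0, 0, 1), -5.0)
        with pytest.raises(ValidationError):
            nuclear_frequencies_exact(system, 3, (0, 0, 1), 1225.0)

    def test_bulk_path_matches_scalar_path(self, rng):
        system = make_fixture("14N5")
        dirs = rng.normal(size=(12, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        bulk = manifold_frequencies_bulk(system, 0, dirs, 1223.0)
        for i, n in enumerate(dirs):
            tset = nuclear_frequencies_exact(system, 0, n, 1223.0)
            for ms in (0.5, -0.5):
                freqs, labels = bulk[ms]
                by_label = dict(zip(labels, freqs[i]))
                for lab, f in tset.transitions[ms]:
                    assert by_label[lab] == pytest.approx(f, abs=1e-9)


class TestOracleEquivalence:
    """The per-manifold engine against full-Hamiltonian diagonalisation.

    Relative error is measured against the larger of the transition
    frequency and the nuclear Larmor frequency, since lines near exact
    cancellation can have arbitrarily small absolute frequency.
    """

    def _relative_errors(self, n_trials, seed):
        rng = np.random.default_rng(seed)
        errs = {0.5: [], 1.0: []}
        for _ in range(n_trials):
            iso = rng.choice(["13C", "15N", "1H", "14N"])
            spin = {"13C": 0.5, "15N": 0.5, "1H": 0.5, "14N": 1.0}[iso]
            vals = tuple(rng.uniform(-80, 80, 3))
            euler = tuple(rng.uniform(0, 180, 3))
            q = None
            if spin == 1.0:
                q1, q2 = rng.uniform(-1.5, 1.5, 2)
                q = PrincipalTensor((q1, q2, -(q1 + q2)), tuple(rng.uniform(0, 180, 3)),
                                    traceless=True)
            system = SpinSystem(g=GTensor())
            system.add_nucleus(Nucleus(iso), PrincipalTensor(vals, euler), q)
            v = rng.normal(size=3)
            n_hat = v / np.linalg.norm(v)
            field = rng.uniform(1200, 1230)
            nu_l = larmor_frequency(iso, field)
            mine = nuclear_frequencies_exact(system, 0, n_hat, field)
            ref = full_hamiltonian_frequencies(
                system.g.values, system.nuclei[0].hyperfine.matrix(), n_hat, field,
                system.nuclei[0].nucleus.g_factor, spin,
                system.nuclei[0].quadrupole.matrix() if q is not None else None,
            )
            for ms in (0.5, -0.5):
                if spin == 0.5:
                    got = np.array([mine.transitions[ms][0][1]])
                else:
                    sq = sorted(mine.single_quantum(ms), reverse=True)
                    dq = [f for lab, f in mine.transitions[ms] if lab == "dq"][0]
                    got = np.array(sq + [dq])
                rel = np.max(np.abs(got - ref[ms]) / np.maximum(ref[ms], nu_l))
                errs[spin].append(rel)
        return errs

    def test_agreement_with_full_hamiltonian(self):
        errs = self._relative_errors(200, seed=7)
        assert max(errs[0.5]) < 0.005
        assert max(errs[1.0]) < 0.01
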