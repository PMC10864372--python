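"""Hamiltonian construction and singlet-yield evaluation."""

import numpy as np
import pytest

from rpmspin.constants import gamma_e
from rpmspin.rp_model import (
    EigenSystem,
    Isotope,
    KineticsParams,
    RadicalPairParams,
    ResolutionError,
    build_hamiltonian,
    eigensystem,
    isotope_averaged_yield,
    larmor_frequency,
    singlet_yield,
    singlet_yield_liouville,
    singlet_yield_timedomain,
)
from rpmspin.spin_core import electron_spin_ops, nuclear_spin_ops, singlet_projector
from rpmspin.synthetic_data import RandomRPSpec, random_radical_pair


def closed_form_no_hyperfine(kin):
    return 0.25 + 0.75 * kin.k / (kin.k + kin.r)


class TestLarmor:
    def test_zero_field(self):
        assert larmor_frequency(0.0) == 0.0

    def test_known_value_at_100mT(self):
        # γ_e ≈ 1.7608e11 rad/s/T for the free-electron g-factor
        assert np.isclose(larmor_frequency(100.0), 1.761e10, rtol=1e-3)
        assert np.isclose(gamma_e(), 1.7608e11, rtol=1e-4)

    def test_linearity(self):
        assert np.isclose(larmor_frequency(34.2), 2 * larmor_frequency(17.1))

    def test_rejects_negative_field(self):
        with pytest.raises(ValueError):
            larmor_frequency(-1.0)


class TestHamiltonian:
    def test_all_zero_parameters_give_zero_matrix(self):
        H, system = build_hamiltonian(RadicalPairParams(B=0.0))
        assert system.dim == 4
        np.testing.assert_allclose(H, 0, atol=0)

    def test_dimensions_per_isotopologue(self):
        ser_mg25 = RadicalPairParams(B=0.15, a_A=7.45, spin_A=0.5, a_B=-11.22, spin_B=2.5)
        H, system = build_hamiltonian(ser_mg25)
        assert H.shape == (48, 48) and system.dim == 4 * 2 * 6
        H0, system0 = build_hamiltonian(ser_mg25.with_isotope(0.0, 0.0))
        assert H0.shape == (8, 8)

    def test_hermitian_and_conserves_total_jz(self):
        """Isotropic hyperfine + z-Zeeman commute with total Jz."""
        params = RadicalPairParams(B=3.3, a_A=7.45, spin_A=0.5, a_B=-11.22, spin_B=2.5)
        H, system = build_hamiltonian(params)
        np.testing.assert_allclose(H, H.conj().T, atol=1e-6)
        Jz = electron_spin_ops(system, "A")[2] + electron_spin_ops(system, "B")[2]
        Jz = Jz + nuclear_spin_ops(system, "A", 0)[2] + nuclear_spin_ops(system, "B", 0)[2]
        comm = H @ Jz - Jz @ H
        assert np.linalg.norm(comm) <= 1e-9 * np.linalg.norm(H)

    def test_dimension_cap(self):
        big = RadicalPairParams(B=1.0, a_A=1.0, spin_A=2.5, a_B=1.0, spin_B=2.5)
        with pytest.raises(ValueError):
            build_hamiltonian(big, dim_cap=100)

    def test_eigensystem_contract(self):
        params = RadicalPairParams(B=10.0, a_A=7.45, spin_A=0.5)
        H, system = build_hamiltonian(params)
        eigs = eigensystem(H, system)
        U = eigs.eigenvectors
        np.testing.assert_allclose(U.conj().T @ U, np.eye(system.dim), atol=1e-10)
        np.testing.assert_allclose(
            U @ np.diag(eigs.eigenvalues) @ U.conj().T, H, atol=1e-6 * np.abs(H).max()
        )


def _closed_form(params, kin):
    H, system = build_hamiltonian(params)
    return singlet_yield(eigensystem(H, system), singlet_projector(system), kin)


class TestClosedFormLimits:
    def test_no_hyperfine_r0_gives_unity(self):
        params = RadicalPairParams(B=50.0)
        phi = _closed_form(params, KineticsParams(k=3e6, r=0.0))
        assert np.isclose(phi, 1.0, atol=1e-12)

    def test_no_hyperfine_general_r(self, rng):
        """Φ_S = ¼ + ¾ k/(k+r) exactly when both hyperfine terms vanish."""
        for _ in range(20):
            k, r = 10 ** rng.uniform(4, 8, size=2)
            kin = KineticsParams(k=k, r=r)
            phi = _closed_form(RadicalPairParams(B=rng.uniform(0, 200)), kin)
            assert np.isclose(phi, closed_form_no_hyperfine(kin), atol=1e-12)

    def test_equal_rates_give_0625(self):
        kin = KineticsParams(k=1e6, r=1e6)
        assert np.isclose(_closed_form(RadicalPairParams(B=1.0), kin), 0.625, atol=1e-12)

    def test_rejects_degenerate_kinetics(self):
        with pytest.raises(ValueError):
            KineticsParams(k=0.0, r=0.0)


class TestYieldBoundsAndSymmetries:
    @pytest.mark.parametrize("seed", range(8))
    def test_phi_bounded(self, seed):
        """Φ_S ∈ [¼, 1]: the maximally relaxed floor and singlet ceiling."""
        params, kin = random_radical_pair(RandomRPSpec(seed=seed))
        phi = _closed_form(params, kin)
        assert 0.25 - 1e-9 <= phi <= 1 + 1e-9

    def test_field_sign_symmetry(self):
        """Negating the Larmor term leaves Φ_S unchanged (isotropic HFI)."""
        params = RadicalPairParams(B=5.0, a_A=7.45, spin_A=0.5, a_B=-11.22, spin_B=2.5)
        kin = KineticsParams(k=2e6, r=1e6)
        H, system = build_hamiltonian(params)
        omega = larmor_frequency(params.B, params.g)
        Sz = electron_spin_ops(system, "A")[2] + electron_spin_ops(system, "B")[2]
        H_neg = H - 2 * omega * Sz
        P = singlet_projector(system)
        phi_pos = singlet_yield(eigensystem(H, system), P, kin)
        phi_neg = singlet_yield(eigensystem(H_neg, system), P, kin)
        assert np.isclose(phi_pos, phi_neg, rtol=1e-10)

    def test_hyperfine_sign_symmetry(self):
        """Φ_S depends on a_B only through the spectrum: ±a_B agree."""
        kin = KineticsParams(k=2e6, r=1e6)
        for B in (0.15, 10.0, 100.0):
            base = RadicalPairParams(B=B, a_A=7.45, spin_A=0.5)
            plus = _closed_form(base.with_isotope(2.5, 11.22), kin)
            minus = _closed_form(base.with_isotope(2.5, -11.22), kin)
            assert np.isclose(plus, minus, rtol=1e-9)


class TestOracles:
    @pytest.mark.parametrize("seed", range(12))
    def test_closed_form_matches_liouville_solve(self, seed):
        """Eigenbasis double sum vs exact resolvent solution of the
        Liouville–von Neumann time integral."""
        params, kin = random_radical_pair(RandomRPSpec(seed=1000 + seed))
        H, system = build_hamiltonian(params)
        P = singlet_projector(system)
        phi_cf = singlet_yield(eigensystem(H, system), P, kin)
        phi_lv = singlet_yield_liouville(H, P, kin)
        assert np.isclose(phi_cf, phi_lv, rtol=1e-3)
        assert np.isclose(phi_cf, phi_lv, rtol=1e-9)  # agreement is exact

    @pytest.mark.parametrize(
        "params, kin",
        [
            (RadicalPairParams(B=1.0, a_A=1.0, spin_A=0.5), KineticsParams(k=2e6, r=1e6)),
            (RadicalPairParams(B=0.5, a_A=-0.8, spin_A=1.0), KineticsParams(k=5e6, r=2e6)),
            (RadicalPairParams(B=2.0, a_A=0.5, spin_A=0.5, a_B=0.7, spin_B=0.5),
             KineticsParams(k=4e6, r=4e6)),
        ],
    )
    def test_closed_form_matches_time_stepping(self, params, kin):
        """Brute-force propagator quadrature agrees to 1e-4."""
        H, system = build_hamiltonian(params)
        P = singlet_projector(system)
        phi_cf = singlet_yield(eigensystem(H, system), P, kin)
        phi_td = singlet_yield_timedomain(H, P, kin)
        assert np.isclose(phi_td, phi_cf, rtol=1e-4)

    def test_time_stepping_no_hyperfine_limits(self):
        H, system = build_hamiltonian(RadicalPairParams(B=1.0))
        P = singlet_projector(system)
        phi = singlet_yield_timedomain(H, P, KineticsParams(k=1e6, r=1e6))
        assert np.isclose(phi, 0.625, rtol=1e-6)
        phi1 = singlet_yield_timedomain(H, P, KineticsParams(k=1e6, r=0.0))
        assert np.isclose(phi1, 1.0, rtol=1e-6)

    def test_time_stepping_refuses_unresolvable_grids(self):
        params = RadicalPairParams(B=200.0, a_A=15.0, spin_A=2.5, a_B=-11.0, spin_B=2.5)
        H, system = build_hamiltonian(params)
        P = singlet_projector(system)
        slow = KineticsParams(k=1e4, r=1e4)
        with pytest.raises(ResolutionError):
            singlet_yield_timedomain(H, P, slow, max_steps=10_000)
        with pytest.raises(ResolutionError):
            singlet_yield_timedomain(H, P, slow, n_steps=100)


class TestIsotopeAveraging:
    base = RadicalPairParams(B=0.15, a_A=7.45, spin_A=0.5, label="Ser")
    kin = KineticsParams(k=2e6, r=1e6)

    def test_single_spin0_row_reduces_to_proton_system(self):
        res = isotope_averaged_yield(self.base, self.kin, [Isotope(1.0, 0.0, 0.0)])
        direct = _closed_form(self.base.with_isotope(0.0, 0.0), self.kin)
        assert np.isclose(res.phi_s, direct, atol=1e-14)

    def test_split_identical_isotopologues_is_linear(self):
        whole = isotope_averaged_yield(self.base, self.kin, [Isotope(1.0, 2.5, -11.22)])
        split = isotope_averaged_yield(
            self.base, self.kin, [Isotope(0.5, 2.5, -11.22), Isotope(0.5, 2.5, -11.22)]
        )
        assert np.isclose(whole.phi_s, split.phi_s, atol=1e-14)

    def test_permutation_invariance(self):
        table = [Isotope(0.9, 0.0, 0.0), Isotope(0.1, 2.5, -11.22)]
        a = isotope_averaged_yield(self.base, self.kin, table).phi_s
        b = isotope_averaged_yield(self.base, self.kin, table[::-1]).phi_s
        assert np.isclose(a, b, atol=1e-14)

    def test_rejects_unnormalized_weights(self):
        with pytest.raises(ValueError):
            isotope_averaged_yield(self.base, self.kin, [Isotope(0.5, 0.0, 0.0)])

    def test_result_contract(self):
        res = isotope_averaged_yield(self.base, self.kin)
        assert np.isclose(sum(res.weights), 1.0, atol=1e-12)
        assert 0 <= res.phi_s <= 1
        assert len(res.per_isotopologue) == 2
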