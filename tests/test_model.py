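"""Network definition: parameters, propensities, stoichiometry and the
exact occupancy-based spatial correction term."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from deltacle import (
    SpatialState,
    WellMixedState,
    compute_delta,
    egfr_parameters,
    propensities,
    stoichiometry,
)
from deltacle.model import CHANNELS, RateConstants


def crossterm_delta(R, L):
    """Brute-force oracle: sum over ordered pairs i != j of R_i L_j, over R L."""
    R = np.asarray(R, dtype=float)
    L = np.asarray(L, dtype=float)
    total = 0.0
    for i in range(R.size):
        for j in range(L.size):
            if i != j:
                total += R[i] * L[j]
    return total / (R.sum() * L.sum())


class TestEgfrParameters:
    def test_printed_rates(self):
        k = egfr_parameters()
        assert k.k_off == 0.24
        assert k.k_t == 0.02
        assert k.k_e == 0.15
        assert k.Q_R == 4000.0
        assert k.F(0.0) == 0.0 and k.F(123.4) == 0.0

    def test_derived_binding_constants(self):
        # K_D = 2.47e-9 M * N_av * V_cell, evaluated independently
        k = egfr_parameters()
        K_D = k.k_off / k.k_on
        assert K_D == pytest.approx(5.950724e5, rel=1e-6)
        assert k.k_on == pytest.approx(4.0331e-7, rel=1e-4)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            RateConstants(k_on=-1.0, k_off=0.1, k_e=0.1, k_t=0.1, Q_R=0.0)


class TestPropensities:
    def test_wellmixed_impulse_state(self, egfr, impulse_init):
        a = propensities(impulse_init, egfr, delta=0.0)
        assert a[0] == pytest.approx(egfr.k_on * 2e9)      # k_on R L
        assert a[1] == 0.0                                  # no complexes yet
        assert a[2] == 0.0
        assert a[3] == pytest.approx(0.02 * 200_000)
        assert a[4] == 0.0
        assert a[5] == 4000.0

    def test_delta_one_switches_off_association_only(self, egfr):
        s = WellMixedState(0.0, 1234, 56, 789)
        a0 = propensities(s, egfr, delta=0.0)
        a1 = propensities(s, egfr, delta=1.0)
        assert a1[0] == 0.0
        np.testing.assert_allclose(a1[1:], a0[1:])

    def test_delta_scales_bimolecular_term_linearly(self, egfr):
        s = WellMixedState(0.0, 1000, 10, 500)
        for d in (0.25, 0.5, 0.75):
            a = propensities(s, egfr, delta=d)
            assert a[0] == pytest.approx((1 - d) * egfr.k_on * 1000 * 500)

    def test_empty_state_sources_only(self, egfr):
        a = propensities(WellMixedState(0.0, 0, 0, 0), egfr, delta=0.5)
        assert np.count_nonzero(a) == 1 and a[5] == egfr.Q_R

    @pytest.mark.parametrize("delta", [-0.1, 1.01])
    def test_delta_domain_error(self, egfr, delta):
        with pytest.raises(ValueError):
            propensities(WellMixedState(0.0, 1, 1, 1), egfr, delta=delta)


class TestComputeDelta:
    def test_common_subvolume_is_wellmixed(self):
        s = SpatialState(0.0, R=[100, 0, 0], L=[50, 0, 0], C=[0, 0, 0])
        assert compute_delta(s) == 0.0

    def test_complete_separation(self):
        s = SpatialState(0.0, R=[100, 0], L=[0, 50], C=[0, 0])
        assert compute_delta(s) == 1.0

    @pytest.mark.parametrize("M", [2, 4, 8, 16])
    def test_equal_partition(self, M):
        s = SpatialState(0.0, R=[400 // M] * M, L=[1600 // M] * M, C=[0] * M)
        assert compute_delta(s) == pytest.approx(1.0 - 1.0 / M, abs=1e-12)

    def test_undefined_without_both_species(self):
        with pytest.raises(ValueError):
            compute_delta(SpatialState(0.0, R=[5, 5], L=[0, 0], C=[0, 0]))

    @given(
        R=arrays(np.int64, st.integers(2, 8), elements=st.integers(0, 1000)),
        L=arrays(np.int64, st.integers(2, 8), elements=st.integers(0, 1000)),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_crossterm_oracle_and_unit_interval(self, R, L):
        n = min(R.size, L.size)
        R, L = R[:n], L[:n]
        if R.sum() == 0 or L.sum() == 0:
            return
        s = SpatialState(0.0, R=R, L=L, C=np.zeros(n, dtype=np.int64))
        d = compute_delta(s)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(crossterm_delta(R, L), rel=1e-12, abs=1e-12)

    @given(
        R=arrays(np.int64, 6, elements=st.integers(0, 500)),
        L=arrays(np.int64, 6, elements=st.integers(0, 500)),
        perm=st.permutations(range(6)),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_subvolume_relabelling_invariance(self, R, L, perm):
        if R.sum() == 0 or L.sum() == 0:
            return
        z = np.zeros(6, dtype=np.int64)
        p = np.asarray(perm)
        d1 = compute_delta(SpatialState(0.0, R=R, L=L, C=z))
        d2 = compute_delta(SpatialState(0.0, R=R[p], L=L[p], C=z))
        assert d1 == pytest.approx(d2, abs=1e-14)


class TestStoichiometry:
    def test_change_vectors(self):
        S = stoichiometry()
        assert S.shape == (len(CHANNELS), 3)
        np.testing.assert_array_equal(S[0], [-1, +1, -1])   # association
        np.testing.assert_array_equal(S[0] + S[1], [0, 0, 0])  # reverse cancels
        np.testing.assert_array_equal(S[5], [+1, 0, 0])     # receptor source
        np.testing.assert_array_equal(S[4], [0, 0, +1])     # ligand source
        np.testing.assert_array_equal(S[2], [0, -1, 0])
        np.testing.assert_array_equal(S[3], [-1, 0, 0])


class TestConfigLoading:
    def test_explicit_and_derived_k_on(self, tmp_path):
        from deltacle import load_rate_config

        p = tmp_path / "r.yaml"
        p.write_text("k_off: 0.24\nK_D_molar: 2.47e-9\nV_cell: 4.0e-10\n"
                     "k_e: 0.15\nk_t: 0.02\nQ_R: 4000\nF_const: 2.5\n")
        k = load_rate_config(p)
        assert k.k_on == pytest.approx(egfr_parameters().k_on, rel=1e-12)
        assert k.F(3.0) == 2.5

    def test_rejects_negative_and_unknown_keys(self, tmp_path):
        from deltacle import load_rate_config

        p = tmp_path / "bad.yaml"
        p.write_text("k_on: 1e-7\nk_off: -0.1\nk_e: 0.1\nk_t: 0.1\nQ_R: 10\n")
        with pytest.raises(ValueError):
            load_rate_config(p)
        p.write_text("k_on: 1e-7\nk_off: 0.1\nk_e: 0.1\nk_t: 0.1\nQ_R: 10\nbogus: 1\n")
        with pytest.raises(ValueError, match="unknown"):
            load_rate_config(p)
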