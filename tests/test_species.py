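"""Reaction-diffusion operators: oracles, conservation, golden values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atherosim import params
from atherosim.species import (TransportModel, ValidationError, diffuse,
                               diffuse_implicit, il10_clearance,
                               ldl_wall_concentration, ldl_wall_influx,
                               make_stencil, oxidize_ldl, produce_cytokines,
                               substep_count)


def box_stencil(n):
    mask = np.ones((n, n, n), dtype=bool)
    return make_stencil(mask)


def point_source(n, value=1000.0):
    vals = np.zeros(n ** 3)
    vals[np.ravel_multi_index((n // 2,) * 3, (n,) * 3)] = value
    return vals


class TestDiffusion:
    def test_zero_field_stays_zero(self):
        idx, nbr = box_stencil(7)
        out = diffuse(np.zeros(idx.size), nbr, 3e-11)
        assert np.all(out == 0)

    def test_negative_input_rejected(self):
        idx, nbr = box_stencil(5)
        with pytest.raises(ValidationError):
            diffuse(np.full(idx.size, -1.0), nbr, 3e-11)

    def test_mass_conserved_sealed(self):
        """Sealed box: total mass invariant over the full sub-stepped tick."""
        idx, nbr = box_stencil(15)
        vals = point_source(15)
        out = diffuse(vals[idx], nbr, 3e-11, sealed=True)
        assert out.sum() == pytest.approx(1000.0, rel=1e-12)
        assert np.all(out >= 0)

    def test_sink_boundaries_lose_mass(self):
        idx, nbr = box_stencil(9)
        out = diffuse(point_source(9)[idx], nbr, 3e-11, sealed=False)
        assert out.sum() < 1000.0

    def test_symmetry_of_point_source(self):
        """A centered source stays symmetric under the lattice symmetries."""
        n = 11
        idx, nbr = box_stencil(n)
        out = diffuse(point_source(n)[idx], nbr, 3e-11, sealed=True)
        f = out.reshape(n, n, n)
        for axis in range(3):
            assert np.allclose(f, np.flip(f, axis=axis), atol=1e-12)
        assert np.allclose(f, f.transpose(1, 0, 2), atol=1e-12)

    def test_matches_discrete_kernel_oracle(self):
        """Exact product-form oracle: independent sparse-operator power."""
        import scipy.sparse as sp

        n = 15
        idx, nbr = box_stencil(n)
        vals = point_source(n)[idx]
        d = 3e-11
        out = diffuse(vals, nbr, d, sealed=True)
        n_steps = substep_count(d)
        lam = d * params.TICK_SECONDS / (params.PATCH_SIZE_UM * 1e-6) ** 2 / n_steps
        N = idx.size
        rows, cols, data, diag = [], [], [], np.ones(N)
        for a in range(6):
            nb = nbr[:, a]
            inside = nb >= 0
            rows.append(np.flatnonzero(inside))
            cols.append(nb[inside])
            data.append(lam * np.ones(inside.sum()))
            diag[inside] -= lam
        M = sp.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(N, N)) + sp.diags(diag)
        expect = vals.copy()
        for _ in range(n_steps):
            expect = M @ expect
        assert np.allclose(out, expect, rtol=1e-10, atol=1e-13)

    def test_matches_gaussian_heat_kernel(self):
        """Point source in a large sealed box approaches the continuum
        Gaussian at matched D*t/h^2."""
        n = 41
        idx, nbr = box_stencil(n)
        out = diffuse(point_source(n)[idx], nbr, 3e-11, sealed=True)
        f = out.reshape(n, n, n)
        dth2 = 3e-11 * params.TICK_SECONDS / (params.PATCH_SIZE_UM * 1e-6) ** 2
        x = np.arange(n) - n // 2
        g1 = np.exp(-x ** 2 / (4 * dth2))
        G = np.einsum("i,j,k->ijk", g1, g1, g1)
        G *= 1000.0 / G.sum()
        assert np.abs(f - G).max() / G.max() < 0.02

    def test_linearity(self, rng):
        idx, nbr = box_stencil(9)
        f = rng.random(idx.size)
        g = rng.random(idx.size)
        a, b = 2.5, 0.3
        lhs = diffuse(a * f + b * g, nbr, 3e-11)
        rhs = a * diffuse(f, nbr, 3e-11) + b * diffuse(g, nbr, 3e-11)
        assert np.allclose(lhs, rhs, rtol=1e-10)

    def test_explicit_agrees_with_implicit(self):
        """Sub-stepped explicit vs backward Euler at the same step count."""
        n = 15
        idx, nbr = box_stencil(n)
        vals = point_source(n)[idx]
        d = 3e-11
        exp = diffuse(vals, nbr, d, sealed=True)
        imp = diffuse_implicit(vals, nbr, d, sealed=True,
                               n_steps=substep_count(d))
        assert np.abs(exp - imp).max() / exp.max() < 0.08
        assert imp.sum() == pytest.approx(1000.0, rel=1e-9)


class TestReactionTerms:
    def test_production_golden_values(self):
        """Per-cell rates: 1 neutrophil adds 5e-6 TNF and 5e-7 IL-1 U/ml;
        2 monocytes add 1.34e-3 TNF."""
        inc = produce_cytokines({"NEUTROPHIL": np.array([1.0])})
        assert inc["TNFA"][0] == pytest.approx(5e-6)
        assert inc["IL1B"][0] == pytest.approx(5e-7)
        inc = produce_cytokines({"MONOCYTE": np.array([2.0])})
        assert inc["TNFA"][0] == pytest.approx(1.34e-3)
        inc = produce_cytokines({})
        assert np.all(np.asarray(inc["TNFA"]) == 0)

    def test_extended_producers_toggle(self):
        counts = {"M1": np.array([3.0]), "M2": np.array([2.0]),
                  "FOAM": np.array([1.0])}
        on = produce_cytokines(counts, extended_producers=True)
        off = produce_cytokines(counts, extended_producers=False)
        assert on["TNFA"][0] == pytest.approx(4 * 6.7e-4)
        assert on["IL10"][0] == pytest.approx(2 * 3.75e-5)
        assert np.all(np.asarray(off["TNFA"]) == 0)

    def test_il10_clearance_golden_values(self):
        """IL-10 = 10 U/ml removes 9.6 % of IL-1beta and 9.5 % of TNF."""
        tnfa, il1b = il10_clearance(np.array([1.0]), np.array([1.0]),
                                    np.array([10.0]))
        assert il1b[0] == pytest.approx(0.904)
        assert tnfa[0] == pytest.approx(0.905)
        # zero IL-10 leaves both unchanged; huge IL-10 clamps at zero
        t, i = il10_clearance(np.array([2.0]), np.array([3.0]), np.array([0.0]))
        assert t[0] == 2.0 and i[0] == 3.0
        t, i = il10_clearance(np.array([1.0]), np.array([1.0]),
                              np.array([1e4]))
        assert t[0] == 0.0 and i[0] == 0.0

    def test_ldl_wall_concentration(self):
        """C_w at zero shear is 1.15 * C0; the profile decreases on [0, 2] Pa
        under the adopted polynomial reading."""
        assert ldl_wall_concentration(0.0, 1000.0) == pytest.approx(1150.0)
        grid = np.linspace(0.0, 2.0, 201)
        p = ldl_wall_concentration(grid, 1.0)
        assert np.all(np.diff(p) < 0)
        # influx is 70 % of C_w at any shear
        assert np.allclose(ldl_wall_influx(grid, 1000.0),
                           0.7 * ldl_wall_concentration(grid, 1000.0))

    def test_ldl_duplicated_cubic_reading(self):
        a = ldl_wall_concentration(1.0, 1.0, duplicated_cubic=False)
        b = ldl_wall_concentration(1.0, 1.0, duplicated_cubic=True)
        assert a == pytest.approx(b)      # coefficients coincide at x=1
        assert ldl_wall_concentration(2.0, 1.0, duplicated_cubic=True) != \
            pytest.approx(ldl_wall_concentration(2.0, 1.0))

    def test_oxidation(self):
        ldl, ox = oxidize_ldl(np.array([1000.0]), np.array([0.0]))
        assert ldl[0] == pytest.approx(988.0)
        assert ox[0] == pytest.approx(12.0)
        ldl, ox = oxidize_ldl(np.array([0.0]), np.array([5.0]))
        assert ldl[0] == 0.0 and ox[0] == 5.0

    def test_oxidation_geometric_decay(self):
        ldl = np.array([1.0])
        ox = np.array([0.0])
        for _ in range(10):
            ldl, ox = oxidize_ldl(ldl, ox)
        assert ldl[0] == pytest.approx(0.988 ** 10)
        assert ldl[0] + ox[0] == pytest.approx(1.0)


@settings(max_examples=30, deadline=None)
@given(il10=st.floats(0.0, 1000.0), tnfa=st.floats(0.0, 10.0),
       il1b=st.floats(0.0, 10.0))
def test_clearance_never_negative_never_amplifies(il10, tnfa, il1b):
    t, i = il10_clearance(np.array([tnfa]), np.array([il1b]),
                          np.array([il10]))
    assert 0.0 <= t[0] <= tnfa + 1e-12
    assert 0.0 <= i[0] <= il1b + 1e-12


class TestTransportModel:
    def test_tick_accounting_identity(self, small_artery):
        """Per-tick mass balance: d(mass) = production - clearance
        - oxidation transfer - boundary outflux, species by species."""
        model = TransportModel(small_artery)
        counts = {"NEUTROPHIL": np.zeros(small_artery.dims)}
        # a few producing cells mid-wall
        wall = np.argwhere(small_artery.patch_class == 2)
        i, j, k = wall[len(wall) // 2]
        counts["NEUTROPHIL"][i, j, k] = 10
        model.tick(counts)
        n_active = int(model.domain_mask.sum())
        produced = 10 * 5e-6
        mass = model.total_mass()["TNFA"]
        outflux = model.last_boundary_outflux["TNFA"]
        assert mass + outflux == pytest.approx(produced, rel=1e-9)
        assert np.all(model.fields["TNFA"] >= 0)
        # concentration identically zero outside the wall domain
        assert np.all(model.fields["TNFA"][~model.domain_mask] == 0)
        assert n_active > 0

    def test_ldl_influx_applied_at_ec(self, small_artery):
        model = TransportModel(small_artery)
        wss = np.zeros(small_artery.dims)
        ec = small_artery.patch_class == 1
        wss[ec] = 1.4
        model.tick({}, wss_at_ec=wss)
        assert model.total_mass()["LDL"] > 0
        assert model.total_mass()["OXLDL"] > 0

    def test_rebuild_zeroes_outside_domain(self, small_artery):
        model = TransportModel(small_artery)
        model.fields["TNFA"][:] = 1.0
        model.rebuild()
        assert np.all(model.fields["TNFA"][~model.domain_mask] == 0)
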