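"""Restraint potential families: contracts and analytic gradients."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xlinkforge import (DISULFIDE_LORENTZ, DihedralRestraint, LORENTZ_PRESETS,
                        LorentzParams, MDBasedParams, REAGENTS,
                        StatisticalParams, dihedral_penalty, lorentz_energy,
                        lorentz_preset, mdbased_energy, statistical_energy,
                        total_restraint_energy, load_params, save_params,
                        ideal_helix)
from xlinkforge.cg_model import XLGeometry
from xlinkforge.xlink_planner import CrossLink, CrossLinkSet

from conftest import make_chain

DSA_DEFAULTS = LorentzParams(d_l=2.5, d_u=7.0, sigma=5.0, A=8.0)


def random_mdparams(rng, n_terms=2):
    g = lambda n: [[rng.uniform(-2, 2), rng.uniform(0.5, 12),
                    rng.uniform(0.3, 3)] for _ in range(n)]
    dih = [[rng.uniform(-2, 2), rng.uniform(-np.pi, np.pi),
            rng.integers(1, 4)] for _ in range(n_terms)]
    return MDBasedParams(d_xi=rng.uniform(1, 4), d_xj=rng.uniform(1, 4),
                         dist_terms=g(n_terms), angle_terms_i=g(n_terms),
                         angle_terms_j=g(n_terms), dihedral_terms=dih)


def random_geometry(rng):
    return XLGeometry(d_xixj=rng.uniform(1, 20),
                      theta_xi=rng.uniform(0.1, np.pi - 0.1),
                      theta_xj=rng.uniform(0.1, np.pi - 0.1),
                      gamma=rng.uniform(-np.pi, np.pi),
                      d_xi=3.0, d_xj=3.0)


class TestLorentz:
    def test_flat_bottom_dsa_defaults(self):
        e, g = lorentz_energy(5.0, DSA_DEFAULTS)
        assert e == 0.0 and g == 0.0

    def test_boundary_energy_zero(self):
        assert lorentz_energy(DSA_DEFAULTS.d_u, DSA_DEFAULTS)[0] == 0.0
        assert lorentz_energy(DSA_DEFAULTS.d_l, DSA_DEFAULTS)[0] == 0.0

    def test_plateau_at_gross_violation(self):
        e, g = lorentz_energy(1e6, DSA_DEFAULTS)
        assert abs(e - DSA_DEFAULTS.A) < 1e-6 * DSA_DEFAULTS.A
        assert abs(g) < 1e-9

    def test_bounded_and_monotone(self, rng):
        p = LorentzParams(2.5, 7.0, 5.0, 8.0)
        d = np.sort(rng.uniform(0, 60, size=500))
        e, _ = lorentz_energy(d, p)
        assert np.all(e >= 0) and np.all(e < p.A)
        above = d >= p.d_u
        assert np.all(np.diff(e[above]) >= -1e-12)
        inside = (d >= p.d_l) & (d <= p.d_u)
        assert np.all(e[inside] == 0.0)

    def test_symmetric_wall_below_lower_bound(self):
        p = LorentzParams(2.5, 7.0, 5.0, 8.0)
        below, g_below = lorentz_energy(p.d_l - 1.3, p)
        above, g_above = lorentz_energy(p.d_u + 1.3, p)
        assert below == pytest.approx(above)
        assert g_below == pytest.approx(-g_above)

    def test_gradient_matches_finite_difference(self, rng):
        p = LorentzParams(2.5, 7.0, 5.0, 8.0)
        h = 1e-6
        for d in rng.uniform(0.5, 30, size=200):
            if min(abs(d - p.d_l), abs(d - p.d_u)) < 1e-3:
                continue
            _, g = lorentz_energy(d, p)
            fd = (lorentz_energy(d + h, p)[0]
                  - lorentz_energy(d - h, p)[0]) / (2 * h)
            assert g == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="parameter error"):
            LorentzParams(7.0, 2.5, 5.0, 8.0)
        with pytest.raises(ValueError, match="parameter error"):
            LorentzParams(2.5, 7.0, -1.0, 8.0)

    def test_published_presets(self):
        assert set(LORENTZ_PRESETS) == {"LR(5,8)", "LR(15,8)", "LR(5,20)",
                                        "LR(15,20)"}
        p = lorentz_preset("LR(15,20)", "BS3")
        assert (p.sigma, p.A, p.d_l, p.d_u) == (15.0, 20.0, 2.5, 12.0)

    def test_disulfide_parameters(self):
        p = DISULFIDE_LORENTZ
        assert (p.d_l, p.d_u, p.sigma, p.A) == (2.5, 4.5, 5.0, 10.0)


class TestStatistical:
    def test_defaults_echoed(self):
        p = StatisticalParams(b=17.0, c=2.0, sigma=4.0)
        assert p.RT == 0.591 and p.A == 15.0

    def test_gradient_matches_finite_difference(self, rng):
        p = StatisticalParams(b=17.0, c=2.0, sigma=4.0)
        h = 1e-6
        for d in rng.uniform(0.5, 100.0, size=200):
            _, g = statistical_energy(d, p)
            fd = (statistical_energy(d + h, p)[0]
                  - statistical_energy(d - h, p)[0]) / (2 * h)
            assert g == pytest.approx(fd, rel=1e-5)

    def test_linear_in_confidence_weight(self, rng):
        p1 = StatisticalParams(b=15.0, c=-1.0, sigma=3.0, A=15.0)
        p2 = dataclasses.replace(p1, A=30.0)
        for d in rng.uniform(1, 60, size=50):
            assert statistical_energy(d, p2)[0] == pytest.approx(
                2.0 * statistical_energy(d, p1)[0])

    def test_finite_on_working_range(self):
        p = StatisticalParams(b=17.0, c=5.0, sigma=2.0)
        d = np.linspace(0.01, 100.0, 1000)
        e, g = statistical_energy(d, p)
        assert np.isfinite(e).all() and np.isfinite(g).all()

    def test_domain_error(self):
        p = StatisticalParams(b=17.0, c=2.0, sigma=4.0)
        with pytest.raises(ValueError, match="domain error"):
            statistical_energy(0.0, p)


class TestMDBased:
    def test_zero_coefficients_zero_energy(self):
        p = MDBasedParams(3.0, 3.0, [[0, 5, 1]], [[0, 1, 1]], [[0, 1, 1]],
                          [[0, 0, 1]])
        g = XLGeometry(8.0, 1.2, 1.8, 0.5, 3.0, 3.0)
        e, grad = mdbased_energy(g, p)
        assert e == 0.0
        np.testing.assert_array_equal(grad, 0.0)

    def test_additivity_of_components(self, rng):
        from xlinkforge.restraints import mdbased_components
        p = random_mdparams(rng)
        g = random_geometry(rng)
        comps = mdbased_components(g, p)
        assert mdbased_energy(g, p)[0] == pytest.approx(
            sum(comps.values()), abs=1e-12)

    def test_dihedral_periodicity(self, rng):
        p = random_mdparams(rng)
        g = random_geometry(rng)
        g2 = dataclasses.replace(g, gamma=g.gamma + 2 * np.pi)
        assert mdbased_energy(g, p)[0] == pytest.approx(
            mdbased_energy(g2, p)[0], abs=1e-12)

    def test_gradient_matches_finite_difference(self, rng):
        h = 1e-6
        for _ in range(25):
            p = random_mdparams(rng)
            g = random_geometry(rng)
            _, grad = mdbased_energy(g, p)
            for k, fname in enumerate(("d_xixj", "theta_xi", "theta_xj",
                                       "gamma")):
                gp = dataclasses.replace(g, **{fname: getattr(g, fname) + h})
                gm = dataclasses.replace(g, **{fname: getattr(g, fname) - h})
                fd = (mdbased_energy(gp, p)[0]
                      - mdbased_energy(gm, p)[0]) / (2 * h)
                assert grad[k] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_degenerate_gamma_rejected(self, rng):
        p = random_mdparams(rng)
        g = XLGeometry(8.0, 1.2, 1.8, float("nan"), 3.0, 3.0)
        with pytest.raises(ValueError, match="degenerate geometry"):
            mdbased_energy(g, p)

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="parameter error"):
            MDBasedParams(3.0, 3.0, [[1, 5, -1]], [[0, 1, 1]], [[0, 1, 1]],
                          [[0, 0, 1]])
        with pytest.raises(ValueError, match="parameter error"):
            MDBasedParams(3.0, 3.0, [[1, 5, 1]], [[0, 1, 1]], [[0, 1, 1]],
                          [[1, 0, 0.5]])


class TestDihedralPenalty:
    HELICAL = DihedralRestraint(30.0, 70.0, w_dih=50.0)

    def test_flat_inside_window(self):
        assert dihedral_penalty(50.0, self.HELICAL) == (0.0, 0.0)
        assert dihedral_penalty(30.0, self.HELICAL)[0] == 0.0
        assert dihedral_penalty(70.0, self.HELICAL)[0] == 0.0

    def test_quartic_in_radian_excess(self):
        # 10 deg past the upper boundary
        e, g = dihedral_penalty(80.0, self.HELICAL)
        excess = math.radians(10.0)
        assert e == pytest.approx(50.0 * excess ** 4)
        assert g == pytest.approx(4 * 50.0 * excess ** 3)

    def test_360_periodicity(self):
        assert dihedral_penalty(250.0, self.HELICAL)[0] == pytest.approx(
            dihedral_penalty(-110.0, self.HELICAL)[0])

    def test_shorter_path_below_lower_boundary(self):
        e_below, g_below = dihedral_penalty(20.0, self.HELICAL)
        e_above, _ = dihedral_penalty(80.0, self.HELICAL)
        assert e_below == pytest.approx(e_above)   # both 10 deg outside
        assert g_below < 0

    def test_extended_window(self):
        ext = DihedralRestraint(120.0, 240.0)
        assert dihedral_penalty(180.0, ext) == (0.0, 0.0)
        assert dihedral_penalty(250.0, ext)[0] > 0

    @given(gamma=st.floats(-720, 720))
    @settings(max_examples=200, deadline=None)
    def test_periodicity_property(self, gamma):
        e1 = dihedral_penalty(gamma, self.HELICAL)[0]
        e2 = dihedral_penalty(gamma + 360.0, self.HELICAL)[0]
        assert e1 == pytest.approx(e2, abs=1e-9)


class TestTotalRestraintEnergy:
    def test_empty_is_zero(self, helix20):
        total, breakdown = total_restraint_energy(
            helix20, CrossLinkSet(links=[]), ("lorentz", DSA_DEFAULTS))
        assert total == 0.0 and breakdown == []

    def test_satisfied_plus_grossly_violated(self):
        # residues 1-2 satisfied (sc dist ~4), residues 1-3 at ~500 A
        chain = make_chain([
            ([0, 0, 0], [0, 0, 2]), ([4, 0, 0], [4, 0, 2]),
            ([500, 0, 0], [500, 0, 2])])
        links = CrossLinkSet(links=[CrossLink(1, 2, "DSA"),
                                    CrossLink(1, 3, "DSA")])
        total, breakdown = total_restraint_energy(
            chain, links, ("lorentz", DSA_DEFAULTS))
        assert total == pytest.approx(DSA_DEFAULTS.A, rel=1e-6)
        assert breakdown[0]["energy"] == 0.0

    def test_breakdown_sums_to_total(self, helix20, rng):
        links = CrossLinkSet(links=[CrossLink(1, 8, "DSA"),
                                    CrossLink(2, 15, "DSA"),
                                    CrossLink(5, 19, "DSA", 0.5)])
        dih = [(1, DihedralRestraint(120.0, 240.0))]
        total, breakdown = total_restraint_energy(
            helix20, links, ("lorentz", LorentzParams(0.5, 2.0, 3.0, 8.0)),
            dih)
        assert total == pytest.approx(sum(b["energy"] for b in breakdown),
                                      abs=1e-12)
        assert total > 0

    def test_permutation_invariance(self, helix20):
        links = [CrossLink(1, 8, "DSA"), CrossLink(2, 15, "DSA"),
                 CrossLink(5, 19, "DSA")]
        p = ("lorentz", LorentzParams(0.5, 2.0, 3.0, 8.0))
        t1, _ = total_restraint_energy(helix20, CrossLinkSet(links=links), p)
        t2, _ = total_restraint_energy(
            helix20, CrossLinkSet(links=links[::-1]), p)
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_mapping_error(self, helix20):
        links = CrossLinkSet(links=[CrossLink(1, 99, "DSA")])
        with pytest.raises(ValueError, match="mapping error"):
            total_restraint_energy(helix20, links,
                                   ("lorentz", DSA_DEFAULTS))

    def test_per_reagent_potential_dispatch(self, helix20):
        links = CrossLinkSet(links=[CrossLink(1, 8, "DSA"),
                                    CrossLink(2, 15, "BS3")])
        pots = {"DSA": ("lorentz", lorentz_preset("LR(5,8)", "DSA")),
                "BS3": ("statistical",
                        StatisticalParams(b=17.0, c=2.0, sigma=4.0))}
        total, breakdown = total_restraint_energy(helix20, links, pots)
        kinds = {b["kind"] for b in breakdown}
        assert kinds == {"lorentz", "statistical"}


class TestReagentRegistry:
    def test_upper_boundaries(self):
        expect = {"TATA": 4.0, "SDA": 5.0, "ABAS": 6.0, "DSG": 6.0,
                  "DSA": 7.0, "BS3": 12.0, "SS": 4.5}
        for name, du in expect.items():
            assert REAGENTS[name].d_u == du
            assert REAGENTS[name].d_l == 2.5

    def test_specificity(self):
        assert REAGENTS["DSA"].allows("K", "K")
        assert not REAGENTS["DSA"].allows("K", "E")
        assert REAGENTS["SDA"].allows("K", "S")
        assert REAGENTS["SDA"].allows("E", "K")
        assert not REAGENTS["SDA"].allows("K", "K")
        assert REAGENTS["ABAS"].allows("K", "W")
        assert REAGENTS["TATA"].allows("A", "V")
        assert REAGENTS["SS"].allows("C", "C")
        assert not REAGENTS["SS"].allows("C", "K")


def test_params_json_round_trip(tmp_path, rng):
    assignments = {
        "DSA": ("lorentz", lorentz_preset("LR(15,8)", "DSA")),
        "BS3": ("statistical", StatisticalParams(b=17.0, c=2.0, sigma=4.0)),
        "DSG": ("mdbased", random_mdparams(rng)),
    }
    path = tmp_path / "params.json"
    save_params(assignments, path)
    loaded = load_params(path)
    assert set(loaded) == set(assignments)
    kind, p = loaded["DSA"]
    assert kind == "lorentz" and p == assignments["DSA"][1]
    kind, p = loaded["DSG"]
    np.testing.assert_allclose(p.dist_terms, assignments["DSG"][1].dist_terms)
    g = random_geometry(rng)
    assert mdbased_energy(g, p)[0] == pytest.approx(
        mdbased_energy(g, assignments["DSG"][1])[0])
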