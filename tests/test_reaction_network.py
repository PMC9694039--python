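"""Network definition loading, dimensioning and elementary kinetics."""

import textwrap

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hemosim.reaction_network import (
    CompiledNetwork,
    NetworkSchemaError,
    free_site_fraction,
    load_network,
    observable_thrombin,
    tf_reagent_lipid,
)
from hemosim.reaction_network.model import LipidPool


def _write(tmp_path, text):
    p = tmp_path / "net.yaml"
    p.write_text(textwrap.dedent(text))
    return p


class TestLoading:
    def test_full_network_dimensions(self, plasma_network):
        """The packaged chemistry has 59 volume + 19 surface species (78 well-mixed)."""
        assert len(plasma_network.volume_species) == 59
        assert len(plasma_network.surface_species) == 19
        assert plasma_network.n_homogeneous == 78

    def test_minimal_two_species_network(self, tmp_path):
        net = load_network(_write(tmp_path, """
            species:
              - {id: A, initial: 1.0}
              - {id: B}
            reactions:
              - {id: r1, eq: "A -> B", k: 1.0}
        """))
        assert net.n_homogeneous == 2
        assert len(net.reactions) == 1

    def test_undeclared_species_is_schema_error(self, tmp_path):
        with pytest.raises(NetworkSchemaError, match="undeclared species"):
            load_network(_write(tmp_path, """
                species:
                  - {id: A, initial: 1.0}
                reactions:
                  - {id: r1, eq: "A -> C", k: 1.0}
            """))

    def test_negative_constant_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="negative"):
            load_network(_write(tmp_path, """
                species:
                  - {id: A, initial: 1.0}
                  - {id: B}
                reactions:
                  - {id: r1, eq: "A -> B", k: -1.0}
            """))

    def test_every_plasma_reaction_constant_positive(self, plasma_network):
        assert all(r.k >= 0 for r in plasma_network.reactions)
        assert all(r.k > 0 for r in plasma_network.reactions
                   if r.rate == "michaelis")


class TestSmallOps:
    @pytest.mark.parametrize("tf_pm, expected_um", [
        (5.0, 0.025),     # 5000 lipids per TF: 25,000 pM = 0.025 uM
        (0.0, 0.0),
    ])
    def test_tf_reagent_lipid(self, tf_pm, expected_um):
        assert tf_reagent_lipid(tf_pm) == pytest.approx(expected_um)

    def test_tf_reagent_lipid_variant_stoichiometry(self):
        # 8000 lipids per TF at the standard 5 pM dose -> 40 nM = 0.04 uM
        assert tf_reagent_lipid(5.0, lipid_per_tf=8000.0) == pytest.approx(0.04)

    def test_tf_reagent_lipid_rejects_negative(self):
        with pytest.raises(ValueError):
            tf_reagent_lipid(-1.0)

    @pytest.mark.parametrize("occupied_fraction, expected", [
        (0.0, 1.0), (1.0, 0.0), (0.5, 0.5),
    ])
    def test_free_site_fraction(self, occupied_fraction, expected):
        pool = LipidPool(id="p", kind="artificial", total_sites=1000.0)
        occ = {"X@p": occupied_fraction * 1000.0 / 50.0}
        assert free_site_fraction(pool, occ, {"X@p": 50.0}) == pytest.approx(expected)

    def test_free_site_fraction_overflow_is_error(self):
        pool = LipidPool(id="p", kind="artificial", total_sites=100.0)
        with pytest.raises(ValueError, match="exceed"):
            free_site_fraction(pool, {"X@p": 3.0}, {"X@p": 50.0})

    @pytest.mark.parametrize("iia, iia_a2m, expected", [
        (100.0, 50.0, 130.0),
        (0.0, 0.0, 0.0),
        (0.0, 100.0, 60.0),
    ])
    def test_observable_thrombin_weighting(self, iia, iia_a2m, expected):
        assert observable_thrombin(iia, iia_a2m) == pytest.approx(expected)

    def test_observable_thrombin_rejects_negative(self):
        with pytest.raises(ValueError):
            observable_thrombin(-1.0, 0.0)


class TestKinetics:
    def test_reversible_binding_reaches_equilibrium_kd(self, mini_network):
        """Steady state of A + B <-> AB matches the closed-form Kd = koff/kon.

        Analytic solution: with totals a0, b0 and Kd, the equilibrium
        complex is the smaller root of
        c^2 - (a0 + b0 + Kd) c + a0 b0 = 0.
        """
        cn = CompiledNetwork(mini_network)
        rhs = cn.homogeneous_rhs(np.zeros(0))
        y0 = np.array([100.0, 50.0, 0.0])
        sol = solve_ivp(rhs, (0, 5e4), y0, method="BDF", rtol=1e-10, atol=1e-12)
        ab = sol.y[2, -1]
        a0, b0, kd = 100.0, 50.0, 10.0
        s = a0 + b0 + kd
        ab_exact = (s - np.sqrt(s**2 - 4 * a0 * b0)) / 2
        assert ab == pytest.approx(ab_exact, rel=1e-3)

    def test_mass_conservation_along_trajectory(self, mini_network):
        cn = CompiledNetwork(mini_network)
        rhs = cn.homogeneous_rhs(np.zeros(0))
        sol = solve_ivp(rhs, (0, 1e4), np.array([100.0, 50.0, 0.0]),
                        method="BDF", rtol=1e-8, atol=1e-10)
        a_tot = sol.y[0] + sol.y[2]
        b_tot = sol.y[1] + sol.y[2]
        assert np.allclose(a_tot, 100.0, rtol=1e-6)
        assert np.allclose(b_tot, 50.0, rtol=1e-6)
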