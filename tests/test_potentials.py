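"""Force-field tier, pair interactions, and the external-engine adapter."""

import numpy as np
import pytest

from framonc.engine import (
    EngineAdapterSpec,
    EngineExitError,
    EngineParseError,
    ExternalEngineBackend,
    external_engine_evaluate,
)
from framonc.potentials import (
    FFParameters,
    ForceFieldBackend,
    Fragment,
    OverlapError,
    ZeroBackend,
    dsf_coulomb_energy,
    ff_configuration_energy,
    fragment_from_molecules,
    lj_pair_energy,
    pair_interaction_energy,
)
from framonc.system import (
    Box,
    Configuration,
    MoleculeInstance,
    instance_coordinates,
    minimum_image_displacement,
    random_unit_quaternion,
)
from framonc.units import COULOMB_K
from conftest import make_lj_dimer


class TestLennardJones:
    def test_zero_at_sigma(self):
        assert lj_pair_energy(3.15, 3.15, 0.636) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_depth(self):
        sigma, eps = 3.15, 0.636
        assert lj_pair_energy(2 ** (1 / 6) * sigma, sigma, eps) == pytest.approx(
            -eps, rel=1e-12
        )

    def test_closed_form_at_three_sigma(self):
        sigma, eps = 3.15, 0.636
        r = 3 * sigma
        expected = 4 * eps * ((sigma / r) ** 12 - (sigma / r) ** 6)
        assert lj_pair_energy(r, sigma, eps) == pytest.approx(expected, rel=1e-14)

    def test_overlap_rejected(self):
        with pytest.raises(OverlapError):
            lj_pair_energy(0.0, 3.0, 1.0)


class TestDSFCoulomb:
    def test_zero_charge_gives_zero(self):
        assert dsf_coulomb_energy(2.0, 0.0, 0.5, 0.2, 9.0) == 0.0

    def test_vanishes_at_cutoff(self):
        assert dsf_coulomb_energy(9.0, 0.4, -0.4, 0.2, 9.0) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_first_derivative_continuous_at_cutoff(self):
        rc, h = 9.0, 1e-6
        slope_inside = (
            dsf_coulomb_energy(rc - h, 0.4, -0.4, 0.2, rc)
            - dsf_coulomb_energy(rc - 2 * h, 0.4, -0.4, 0.2, rc)
        ) / h
        assert slope_inside == pytest.approx(0.0, abs=1e-4)

    def test_undamped_limit_matches_plain_coulomb_minus_shifts(self):
        # independent closed form of the shifted-force construction at alpha=0
        q_a, q_b, rc = 0.5, -0.3, 12.0
        for r in (1.0, 2.5, 5.0):
            plain = COULOMB_K * q_a * q_b / r
            shift = COULOMB_K * q_a * q_b / rc
            force_term = COULOMB_K * q_a * q_b / rc ** 2 * (r - rc)
            expected = plain - shift + force_term
            assert dsf_coulomb_energy(r, q_a, q_b, 0.0, rc) == pytest.approx(
                expected, rel=1e-10
            )

    def test_beyond_cutoff_is_zero_by_contract(self):
        assert dsf_coulomb_energy(10.0, 0.4, -0.4, 0.2, 9.0) == 0.0


def naive_ff_energy(config, templates, params):
    """O(N^2 * sites^2) double-loop oracle over explicit site pairs."""
    mols = config.molecules
    r_cut = params.effective_r_cut(config.box)
    coords = [instance_coordinates(m, templates) for m in mols]
    sites = [templates[m.template_id].sites for m in mols]
    e = 0.0
    for i in range(len(mols) - 1):
        for j in range(i + 1, len(mols)):
            for a, sa in enumerate(sites[i]):
                for b, sb in enumerate(sites[j]):
                    d = minimum_image_displacement(
                        coords[i][a], coords[j][b], config.box
                    )
                    r = float(np.linalg.norm(d))
                    if r > r_cut:
                        continue
                    if params.combining_rule == "lorentz_berthelot":
                        sig = 0.5 * (sa.lj_sigma + sb.lj_sigma)
                    else:
                        sig = np.sqrt(sa.lj_sigma * sb.lj_sigma)
                    eps = np.sqrt(sa.lj_epsilon * sb.lj_epsilon)
                    if eps > 0:
                        e += lj_pair_energy(r, sig, eps)
                    if sa.charge * sb.charge != 0:
                        e += dsf_coulomb_energy(
                            r, sa.charge, sb.charge, params.coulomb_damping, r_cut
                        )
    return e


class TestConfigurationEnergy:
    def test_single_molecule_has_no_intermolecular_energy(self, water_box_30):
        _, templates = water_box_30
        name = next(iter(templates))
        config = Configuration(
            Box([20, 20, 20]),
            [MoleculeInstance(name, np.full(3, 10.0), np.array([1.0, 0, 0, 0]))],
        )
        assert ff_configuration_energy(config, templates) == 0.0

    def test_lj_dimer_at_minimum(self, lj_templates):
        config = make_lj_dimer(2 ** (1 / 6) * 3.0, lj_templates)
        params = FFParameters(r_cut=20.0)
        assert ff_configuration_energy(config, lj_templates, params) == pytest.approx(
            -1.0, rel=1e-10
        )

    @pytest.mark.parametrize("combining_rule", ["lorentz_berthelot", "geometric"])
    def test_matches_double_loop_oracle(self, water_box_30, combining_rule):
        config, templates = water_box_30
        params = FFParameters(combining_rule=combining_rule, r_cut=4.5)
        fast = ff_configuration_energy(config, templates, params)
        slow = naive_ff_energy(config, templates, params)
        assert fast == pytest.approx(slow, rel=1e-9)

    def test_rigid_translation_invariance(self, water_box_30):
        config, templates = water_box_30
        params = FFParameters(r_cut=4.5)
        e0 = ff_configuration_energy(config, templates, params)
        shifted = config.copy()
        for m in shifted.molecules:
            m.com_position = m.com_position + np.array([1.234, -0.77, 3.21])
        e1 = ff_configuration_energy(shifted, templates, params)
        assert abs(e1 - e0) < 1e-8

    def test_two_noninteracting_halves_are_extensive(self, lj_templates):
        # two particles separated beyond the cutoff contribute zero
        params = FFParameters(r_cut=5.0)
        config = make_lj_dimer(20.0, lj_templates, edge=60.0)
        assert ff_configuration_energy(config, lj_templates, params) == 0.0

    def test_overlap_detected(self, lj_templates):
        config = make_lj_dimer(0.05, lj_templates)
        with pytest.raises(OverlapError):
            ff_configuration_energy(config, lj_templates, FFParameters(r_cut=10.0))

    def test_tail_correction_is_negative_for_attractive_fluid(self, lj_templates):
        config = make_lj_dimer(4.0, lj_templates, edge=12.0)
        e_plain = ff_configuration_energy(
            config, lj_templates, FFParameters(r_cut=5.0)
        )
        e_tail = ff_configuration_energy(
            config, lj_templates, FFParameters(r_cut=5.0, tail_correction=True)
        )
        assert e_tail < e_plain

    def test_r_cut_larger_than_half_box_rejected(self, lj_templates):
        config = make_lj_dimer(3.0, lj_templates, edge=8.0)
        with pytest.raises(ValueError, match="half the smallest box edge"):
            ff_configuration_energy(config, lj_templates, FFParameters(r_cut=5.0))


class TestPairInteraction:
    def test_zero_backend_gives_zero(self, water_box_30):
        config, templates = water_box_30
        e = pair_interaction_energy(
            ZeroBackend(), config.molecules[0], config.molecules[1], templates,
            config.box,
        )
        assert e == 0.0

    def test_lj_dimer_interaction_is_minus_epsilon(self, lj_templates):
        config = make_lj_dimer(2 ** (1 / 6) * 3.0, lj_templates)
        backend = ForceFieldBackend(FFParameters(r_cut=20.0))
        e = pair_interaction_energy(
            backend, config.molecules[0], config.molecules[1], lj_templates,
            config.box,
        )
        assert e == pytest.approx(-1.0, rel=1e-10)

    def test_symmetric_under_swap(self, water_box_30, ff_backends):
        config, templates = water_box_30
        backend, _ = ff_backends
        a, b = config.molecules[0], config.molecules[1]
        e_ab = pair_interaction_energy(backend, a, b, templates, config.box)
        e_ba = pair_interaction_energy(backend, b, a, templates, config.box)
        assert e_ab == e_ba

    def test_equals_cross_terms_of_configuration_energy(self, water_box_30):
        """For a rigid-molecule FF the dimer interaction is exactly the
        intermolecular cross-term sum of the two-molecule configuration."""
        config, templates = water_box_30
        params = FFParameters(r_cut=4.5)
        backend = ForceFieldBackend(params)
        a, b = config.molecules[2], config.molecules[3]
        # a big box so the minimum-image dimer equals the free-space dimer
        sub = Configuration(Box([60, 60, 60]), [a.copy(), b.copy()])
        shift = np.full(3, 30.0) - a.com_position
        for m in sub.molecules:
            m.com_position = m.com_position + shift
        e_cross = ff_configuration_energy(sub, templates, params)
        e_int = pair_interaction_energy(
            backend, sub.molecules[0], sub.molecules[1], templates, sub.box
        )
        assert e_int == pytest.approx(e_cross, rel=1e-9, abs=1e-12)


class TestExternalEngine:
    def test_constant_mock_and_cache_contract(self, water_box_30, tmp_path):
        config, templates = water_box_30
        frag = fragment_from_molecules([config.molecules[0]], templates)
        spec = EngineAdapterSpec(
            command_template="echo 'ENERGY = -42.5'",
            workdir=str(tmp_path),
        )
        assert external_engine_evaluate(spec, frag) == -42.5
        assert spec.dispatch_count == 1
        assert external_engine_evaluate(spec, frag) == -42.5
        assert spec.dispatch_count == 1  # served from cache

    def test_nonzero_exit_raises_engine_failure_naming_fragment(
        self, water_box_30, tmp_path
    ):
        config, templates = water_box_30
        frag = fragment_from_molecules([config.molecules[0]], templates)
        spec = EngineAdapterSpec(command_template="false", workdir=str(tmp_path))
        with pytest.raises(EngineExitError, match="H2O1"):
            external_engine_evaluate(spec, frag)

    def test_unparseable_output_raises(self, water_box_30, tmp_path):
        config, templates = water_box_30
        frag = fragment_from_molecules([config.molecules[0]], templates)
        spec = EngineAdapterSpec(command_template="echo nothing", workdir=str(tmp_path))
        with pytest.raises(EngineParseError):
            external_engine_evaluate(spec, frag)

    def test_external_lj_agrees_with_builtin(self, lj_templates, tmp_path):
        """Round trip through a shell command that evaluates the 12-6 form
        on the exported XYZ, compared against the in-process backend."""
        config = make_lj_dimer(3.7, lj_templates)
        script = tmp_path / "lj_engine.py"
        script.write_text(
            "import sys, math\n"
            "lines = open(sys.argv[1]).read().splitlines()\n"
            "if int(lines[0]) < 2:\n"
            "    print('ENERGY = 0.0'); sys.exit()\n"
            "a = [float(x) for x in lines[2].split()[1:4]]\n"
            "b = [float(x) for x in lines[3].split()[1:4]]\n"
            "r = math.dist(a, b)\n"
            "sig, eps = 3.0, 1.0\n"
            "print('ENERGY =', 4*eps*((sig/r)**12 - (sig/r)**6))\n"
        )
        spec = EngineAdapterSpec(
            command_template=f"python {script} {{xyz}}", workdir=str(tmp_path)
        )
        backend = ExternalEngineBackend(spec)
        e_ext = pair_interaction_energy(
            backend, config.molecules[0], config.molecules[1], lj_templates,
            config.box,
        )
        e_builtin = pair_interaction_energy(
            ForceFieldBackend(FFParameters(r_cut=20.0)),
            config.molecules[0], config.molecules[1], lj_templates, config.box,
        )
        assert e_ext == pytest.approx(e_builtin, abs=1e-9)
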