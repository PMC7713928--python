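import numpy as np
import pytest

import preyview as pv
from preyview.rnl import (
    NoiseModel,
    QuantumCatchTable,
    RnlError,
    bootstrap_coldist,
    receptor_noise,
)
from preyview.spectra import Spectrum
from preyview.synthetic import make_population


def flat(value, kind):
    wl = pv.DEFAULT_GRID.wavelengths
    return Spectrum(wl, np.full(wl.size, float(value)), kind)


class TestQuantumCatch:
    def test_neutral_patch_under_flat_light(self):
        s = pv.govardovskii_template(539)
        q = pv.quantum_catch(flat(1.0, "reflectance"), flat(1.0, "irradiance_photons"), s)
        assert q == pytest.approx(pv.integrate(s))

    def test_linear_in_illuminant(self):
        s = pv.govardovskii_template(520)
        r = flat(0.5, "reflectance")
        q1 = pv.quantum_catch(r, flat(1.0, "irradiance_photons"), s)
        q2 = pv.quantum_catch(r, flat(2.0, "irradiance_photons"), s)
        assert q2 == pytest.approx(2 * q1)

    def test_matches_fine_grid_product_oracle(self):
        wl = pv.DEFAULT_GRID.wavelengths
        refl = Spectrum(wl, 0.9 * np.exp(-(((wl - 550) / 30.0) ** 2)), "reflectance")
        illum = flat(1.0, "irradiance_photons")
        sens = pv.govardovskii_template(539)
        q = pv.quantum_catch(refl, illum, sens)
        # brute-force product integral on a 0.1 nm midpoint grid
        fine = np.arange(300.05, 700.0, 0.1)
        rf = np.interp(fine, wl, refl.values)
        sf = np.interp(fine, wl, sens.values)
        oracle = (rf * sf).sum() * 0.1
        assert q == pytest.approx(oracle, rel=1e-3)

    def test_black_patch_floored_positive(self):
        q = pv.quantum_catch(
            flat(0.0, "reflectance"),
            flat(1.0, "irradiance_photons"),
            pv.govardovskii_template(520),
        )
        assert q > 0


class TestVonKries:
    def test_background_equal_stimulus_gives_ones(self):
        q = np.array([2.0, 3.0])
        assert np.allclose(pv.von_kries(q, q), 1.0)

    def test_shared_background_cancels_in_ds(self):
        noise = NoiseModel(e=np.array([0.1, 0.1]), e_achromatic=0.1)
        qa, qb = np.array([2.0, 3.0]), np.array([1.5, 4.0])
        bg = np.array([0.7, 1.3])
        raw = pv.chromatic_distance(qa, qb, noise)
        adapted = pv.chromatic_distance(pv.von_kries(qa, bg), pv.von_kries(qb, bg), noise)
        assert adapted == pytest.approx(raw, rel=1e-12)

    def test_nonpositive_background_rejected(self):
        with pytest.raises(RnlError):
            pv.von_kries(np.array([1.0]), np.array([0.0]))


class TestReceptorNoise:
    def test_equal_abundances_give_uniform_noise(self, dichromat):
        noise = receptor_noise(dichromat)
        assert np.allclose(noise.e, 0.1)
        assert noise.e_achromatic == pytest.approx(0.1)

    def test_abundance_ratio_closed_form(self):
        from preyview.receptors import ReceptorChannel, VisualSystem

        system = VisualSystem(
            channels=(
                ReceptorChannel("s", 450, relative_abundance=1.0, weber_fraction=0.5),
                ReceptorChannel("l", 550, relative_abundance=2.0, weber_fraction=0.1),
            ),
        )
        noise = receptor_noise(system)
        # reference is the longest-wavelength channel (eta=2, omega=0.1)
        assert noise.e[1] == pytest.approx(0.1)
        assert noise.e[0] == pytest.approx(0.1 * np.sqrt(2.0))

    def test_scaling_all_abundances_is_neutral(self):
        from preyview.receptors import ReceptorChannel, VisualSystem

        def build(scale):
            return VisualSystem(
                channels=(
                    ReceptorChannel("a", 450, relative_abundance=1.0 * scale),
                    ReceptorChannel("b", 550, relative_abundance=3.0 * scale),
                ),
            )

        assert np.allclose(receptor_noise(build(1)).e, receptor_noise(build(7)).e)


class TestChromaticDistance:
    def test_identical_catches_give_zero(self):
        noise = NoiseModel(e=np.array([0.1, 0.1]), e_achromatic=0.1)
        q = np.array([2.0, 5.0])
        assert pv.chromatic_distance(q, q, noise) == 0.0

    def test_dichromat_closed_form(self):
        noise = NoiseModel(e=np.array([0.1, 0.1]), e_achromatic=0.1)
        qa = np.array([np.e**0.1, 1.0])
        qb = np.array([1.0, 1.0])
        assert pv.chromatic_distance(qa, qb, noise) == pytest.approx(
            0.1 / np.sqrt(0.02), rel=1e-12
        )

    def test_trichromat_degenerates_to_dichromat_as_e3_grows(self):
        rng = np.random.default_rng(5)
        qa, qb = rng.uniform(0.5, 2.0, 3), rng.uniform(0.5, 2.0, 3)
        noise3 = NoiseModel(e=np.array([0.1, 0.12, 1e6]), e_achromatic=0.1)
        noise2 = NoiseModel(e=np.array([0.1, 0.12]), e_achromatic=0.1)
        d3 = pv.chromatic_distance(qa, qb, noise3)
        d2 = pv.chromatic_distance(qa[:2], qb[:2], noise2)
        assert d3 == pytest.approx(d2, rel=1e-6)

    def test_monochromat_undefined(self):
        noise = NoiseModel(e=np.array([0.1]), e_achromatic=0.1)
        with pytest.raises(RnlError, match="monochromat"):
            pv.chromatic_distance(np.array([1.0]), np.array([2.0]), noise)

    def test_symmetry_and_illuminant_scale_invariance(self):
        rng = np.random.default_rng(11)
        noise = NoiseModel(e=np.array([0.1, 0.08, 0.12]), e_achromatic=0.1)
        qa, qb = rng.uniform(0.1, 5, 3), rng.uniform(0.1, 5, 3)
        d = pv.chromatic_distance(qa, qb, noise)
        assert pv.chromatic_distance(qb, qa, noise) == pytest.approx(d)
        assert pv.chromatic_distance(7.3 * qa, 7.3 * qb, noise) == pytest.approx(
            d, rel=1e-12
        )

    def test_triangle_inequality_dichromat(self):
        rng = np.random.default_rng(2)
        noise = NoiseModel(e=np.array([0.1, 0.1]), e_achromatic=0.1)
        for _ in range(50):
            qa, qb, qc = rng.uniform(0.1, 5, (3, 2))
            dab = pv.chromatic_distance(qa, qb, noise)
            dbc = pv.chromatic_distance(qb, qc, noise)
            dac = pv.chromatic_distance(qa, qc, noise)
            assert dac <= dab + dbc + 1e-12


class TestAchromaticDistance:
    def test_equal_luminance_zero(self, dichromat):
        noise = receptor_noise(dichromat)
        q = np.array([2.0, 3.0])
        assert pv.achromatic_distance(q, q, dichromat, noise) == 0.0

    def test_closed_form(self, dichromat):
        noise = receptor_noise(dichromat)
        qa = np.array([np.e**0.1, np.e**0.1])
        qb = np.array([1.0, 1.0])
        assert pv.achromatic_distance(qa, qb, dichromat, noise) == pytest.approx(
            1.0, rel=1e-12
        )

    def test_symmetric(self, monochromat):
        noise = receptor_noise(monochromat)
        qa, qb = np.array([2.0]), np.array([3.0])
        assert pv.achromatic_distance(qa, qb, monochromat, noise) == pytest.approx(
            pv.achromatic_distance(qb, qa, monochromat, noise)
        )


def _table_from_catches(catches_by_group, system):
    import pandas as pd

    rows = []
    for g, mat in catches_by_group.items():
        for i, q in enumerate(mat):
            row = {"species": g, "individual": f"{g}{i}", "patch": 1}
            row.update({f"Q_{n}": v for n, v in zip(system.channel_names, q)})
            rows.append(row)
    return QuantumCatchTable(pd.DataFrame(rows), system)


class TestBootstrapColdist:
    def test_identical_groups_near_zero(self, dichromat):
        rng = np.random.default_rng(0)
        mat = rng.uniform(1.0, 1.02, (8, 2))
        table = _table_from_catches({"a": mat, "b": mat}, dichromat)
        res = bootstrap_coldist(table, "a", "b", 1, n_boot=500, seed=1)
        assert res.mean_ds < 0.05
        assert res.ds_ci[0] < 0.02

    def test_degenerate_variance_recovers_exact_separation(self, dichromat):
        # groups built so the geometric-mean dS is exactly 3.0 with zero
        # individual variation -> mean 3.0, CI width 0
        e = receptor_noise(dichromat).e
        delta = 3.0 * np.hypot(e[0], e[1])
        qa = np.tile([1.0, 1.0], (5, 1))
        qb = np.tile([np.exp(delta), 1.0], (5, 1))
        table = _table_from_catches({"a": qa, "b": qb}, dichromat)
        res = bootstrap_coldist(table, "a", "b", 1, n_boot=300, seed=0)
        assert res.mean_ds == pytest.approx(3.0, rel=1e-12)
        assert res.ds_ci[1] - res.ds_ci[0] == pytest.approx(0.0, abs=1e-12)

    def test_seed_determinism(self, trichromat):
        rng = np.random.default_rng(9)
        mats = {
            "a": rng.uniform(0.5, 2, (6, 3)),
            "b": rng.uniform(0.5, 2, (6, 3)),
        }
        table = _table_from_catches(mats, trichromat)
        r1 = bootstrap_coldist(table, "a", "b", 1, n_boot=400, seed=1)
        r2 = bootstrap_coldist(table, "a", "b", 1, n_boot=400, seed=1)
        r3 = bootstrap_coldist(table, "a", "b", 1, n_boot=400, seed=2)
        assert r1.ds_ci == r2.ds_ci
        assert r1.ds_ci != r3.ds_ci

    def test_small_group_rejected(self, dichromat):
        table = _table_from_catches(
            {"a": [[1.0, 1.0]], "b": [[1.0, 1.0], [1.1, 1.0]]}, dichromat
        )
        with pytest.raises(RnlError, match="'a'"):
            bootstrap_coldist(table, "a", "b", 1, n_boot=300, seed=0)

    def test_monochromat_reports_achromatic_only(self, monochromat):
        rng = np.random.default_rng(4)
        table = _table_from_catches(
            {"a": rng.uniform(1, 2, (5, 1)), "b": rng.uniform(2, 4, (5, 1))},
            monochromat,
        )
        res = bootstrap_coldist(table, "a", "b", 1, n_boot=300, seed=0)
        assert np.isnan(res.mean_ds)
        assert res.mean_dl > 0

    def test_discriminable_flag_follows_ci_lower_bound(self):
        from preyview.rnl import ColdistResult

        above = ColdistResult("a", "b", 1, 2.0, (1.2, 3.0), 0.5, (0.1, 0.9), 300)
        below = ColdistResult("a", "b", 1, 2.0, (0.8, 3.5), 0.5, (0.1, 0.9), 300)
        assert above.discriminable(1.0)
        assert not below.discriminable(1.0)


def test_catch_table_from_populations_positive_and_labelled(
    trichromat, illuminant_5m
):
    from preyview.synthetic import default_study_species

    spec = default_study_species()[0]
    pops = {spec.label: make_population(spec, 3)}
    table = QuantumCatchTable.from_populations(pops, illuminant_5m, trichromat)
    assert table.species == [spec.label]
    assert table.patches == list(range(1, 8))
    assert (table.data[table.channel_columns] > 0).all().all()
    assert len(table.data) == spec.n_individuals * 7
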