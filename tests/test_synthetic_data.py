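import numpy as np
import pytest

from nirpls.pls_core import fit_plsr, predict
from nirpls.spectral_io import canonical_grid
from nirpls.synthetic_data import (
    ANCHOR_CAL_PAIRS,
    VALIDATION_LEVELS,
    MixtureDesign,
    NoiseModel,
    build_design,
    default_component_library,
    synthesize,
)


@pytest.fixture(scope="module")
def library():
    return default_component_library()


class TestComponentLibrary:
    def test_four_components(self, library):
        assert sorted(c.name for c in library) == ["An", "Excipient", "Hemi", "Mono"]

    def test_anhydrate_has_no_water_band(self, library, grid):
        an = next(c for c in library if c.name == "An")
        window = np.abs(grid.values - 5099.0) <= 50.0
        assert np.all(np.abs(an.spectrum(grid)[window]) < 1e-8)

    def test_hemihydrate_hydroxyl_peaks(self, library):
        hemi = next(c for c in library if c.name == "Hemi")
        centers = {p[0] for p in hemi.peaks}
        assert {6913.0, 6811.0} <= centers

    def test_hydrates_share_water_band_at_distinct_intensity(self, library):
        amp = {
            c.name: {p[0]: p[2] for p in c.peaks}.get(5099.0, 0.0) for c in library
        }
        assert amp["Mono"] > amp["Hemi"] > 0.0

    def test_all_peaks_inside_canonical_grid(self, library, grid):
        lo, hi = grid.values[-1], grid.values[0]
        for comp in library:
            for center, sigma, _ in comp.peaks:
                assert lo <= center <= hi
                assert sigma > 0


class TestBuildDesign:
    def test_default_counts(self):
        design = build_design()
        frame = design.table.frame
        assert (frame["role"] == "calibration").sum() == 41
        assert (frame["role"] == "validation").sum() == 6
        assert design.replicates == 3

    def test_validation_levels_matched_pairs(self):
        frame = build_design().table.frame
        val = frame[frame["role"] == "validation"]
        np.testing.assert_allclose(val["an_cfz"], VALIDATION_LEVELS)
        np.testing.assert_allclose(val["mono_cfz"], VALIDATION_LEVELS)

    def test_anchor_pairs_present(self):
        frame = build_design().table.frame
        cal = frame[frame["role"] == "calibration"]
        pairs = set(zip(cal["an_cfz"].round(6), cal["mono_cfz"].round(6)))
        for pair in ANCHOR_CAL_PAIRS:
            assert pair in pairs

    def test_impurities_within_range(self):
        frame = build_design().table.frame
        assert frame["an_cfz"].between(0, 10).all()
        assert frame["mono_cfz"].between(0, 10).all()
        assert (frame["an_cfz"] + frame["mono_cfz"] <= 10 + 1e-9).all()

    def test_infeasible_impurity_max_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            build_design(impurity_max=40.0)

    def test_layout_seedable(self):
        a = build_design(seed=1).table.frame
        b = build_design(seed=1).table.frame
        c = build_design(seed=2).table.frame
        assert a.equals(b)
        assert not a.equals(c)


class TestSynthesize:
    def test_same_seed_bit_identical(self, library, grid):
        design = build_design(seed=3)
        s1, _ = synthesize(design, library, NoiseModel(seed=5), grid)
        s2, _ = synthesize(design, library, NoiseModel(seed=5), grid)
        assert np.array_equal(s1.absorbance, s2.absorbance)

    def test_zero_concentration_zero_noise_is_flat(self, library, grid):
        import pandas as pd

        from nirpls.spectral_io import ConcentrationTable

        table = ConcentrationTable(
            pd.DataFrame(
                [
                    {
                        "sample_id": "blank", "an_cfz": 0.0, "mono_cfz": 0.0,
                        "hemi_cfz": 0.0, "excipients": 100.0, "role": "calibration",
                    }
                ]
            )
        )
        lib = [c for c in library if c.name != "Excipient"] + [
            type(library[0])("Excipient", ())
        ]
        spectra, _ = synthesize(
            MixtureDesign(table, 1), lib, NoiseModel.noiseless(), grid
        )
        np.testing.assert_allclose(spectra.absorbance, 0.0, atol=1e-15)

    def test_linearity_in_concentration_at_zero_noise(self, library, grid):
        base = build_design(seed=0).table.frame.iloc[:1].copy()
        base.loc[:, ["an_cfz", "mono_cfz", "hemi_cfz", "excipients"]] = [
            [2.0, 0.0, 100.0 / 3.0 - 2.0, 200.0 / 3.0]
        ]
        doubled = base.copy()
        doubled.loc[:, ["an_cfz", "hemi_cfz"]] = [[4.0, 100.0 / 3.0 - 4.0]]
        from nirpls.spectral_io import ConcentrationTable

        noise = NoiseModel.noiseless()
        s_base, _ = synthesize(MixtureDesign(ConcentrationTable(base), 1), library, noise, grid)
        s_dbl, _ = synthesize(MixtureDesign(ConcentrationTable(doubled), 1), library, noise, grid)
        an = next(c for c in library if c.name == "An").spectrum(grid)
        hemi = next(c for c in library if c.name == "Hemi").spectrum(grid)
        np.testing.assert_allclose(
            s_dbl.absorbance[0] - s_base.absorbance[0], 2.0 * an - 2.0 * hemi,
            atol=1e-12,
        )

    def test_noiseless_spectra_fit_exactly_by_pls(self, noiseless_dataset):
        """At zero noise the spectra are an exact linear map of the two
        independently varying impurity concentrations."""
        from nirpls.spectral_io import average_replicates

        spectra, conc = noiseless_dataset
        averaged = average_replicates(spectra)
        cal = averaged.subset_samples(conc.role_ids("calibration"))
        Y = conc.responses(cal.sample_ids)
        model = fit_plsr(cal.absorbance, Y, 2)
        resid = Y - predict(model, cal.absorbance)
        assert np.max(np.abs(resid)) < 1e-8

    def test_additive_noise_degrades_rmsecv_in_expectation(self, grid):
        """More measurement noise means worse cross-validated error for a
        fixed model, averaged over seeds."""
        from nirpls.intervals import extract_bands, partition
        from nirpls.pls_core import cross_validate_rmsecv
        from nirpls.spectral_io import average_replicates

        design = build_design(n_cal=20, seed=4, replicates=1)
        scheme = partition(grid, 50)
        bands = (17, 18, 26)
        avgs = {sd: [] for sd in (5e-4, 5e-3)}
        for seed in range(20):
            for sd in avgs:
                noise = NoiseModel(additive_sd=sd, gain_sd=0.0, offset_sd=0.0,
                                   baseline_scale=0.0, seed=seed)
                spectra, conc = synthesize(design, noise=noise, grid=grid)
                cal = average_replicates(spectra).subset_samples(
                    conc.role_ids("calibration")
                )
                X = extract_bands(cal.absorbance, scheme, bands)
                _, avg = cross_validate_rmsecv(
                    X, conc.responses(cal.sample_ids), 2
                )
                avgs[sd].append(avg)
        assert np.mean(avgs[5e-3]) > np.mean(avgs[5e-4])
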