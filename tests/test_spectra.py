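"""Spectrum containers, CSV round-trips, windows and replicate summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xrfquant.errors import (
    EmptyWindowError,
    FormatError,
    GridError,
    ValidationError,
)
from xrfquant.simulate import (
    DetectorModel,
    MatrixProfile,
    expected_spectrum,
    sample_spectrum,
)
from xrfquant.spectra import (
    EnergyGrid,
    FeatureTable,
    RegionSpec,
    Spectrum,
    Standard,
    assemble_dataset,
    extract_features,
    load_spectra,
    load_standards,
    save_spectra,
    save_standards,
    subtract_background,
    summarize_replicates,
)


def _spec(totals, background, start=10.0, step=0.01, **kw):
    grid = EnergyGrid(start, step, len(totals))
    return Spectrum(grid=grid, total_counts=np.asarray(totals, float),
                    background_counts=np.asarray(background, float), **kw)


class TestGridAndTypes:
    def test_grid_energies_strictly_increasing(self):
        g = EnergyGrid(9.5, 0.01, 401)
        e = g.energies
        assert len(e) == 401
        assert np.all(np.diff(e) > 0)
        assert e[0] == pytest.approx(9.5)
        assert e[-1] == pytest.approx(13.5)

    @pytest.mark.parametrize("step,n", [(0.0, 10), (-0.01, 10), (0.01, 0)])
    def test_invalid_grid_rejected(self, step, n):
        with pytest.raises(GridError):
            EnergyGrid(10.0, step, n)

    def test_negative_raw_counts_rejected(self):
        with pytest.raises(ValidationError):
            _spec([-1.0, 2.0], [0.0, 0.0])

    def test_length_mismatch_rejected(self):
        grid = EnergyGrid(10.0, 0.01, 3)
        with pytest.raises(ValidationError):
            Spectrum(grid=grid, total_counts=np.zeros(2),
                     background_counts=np.zeros(3))

    def test_standard_rejects_mixed_grids(self):
        s1 = _spec([1, 2], [0, 0])
        s2 = _spec([1, 2], [0, 0], start=11.0)
        with pytest.raises(GridError):
            Standard("S", 1.0, 1.0, [s1, s2])

    def test_regionspec_rejects_overlap_and_inversion(self):
        with pytest.raises(ValidationError):
            RegionSpec([(10.7, 10.35)])
        with pytest.raises(ValidationError):
            RegionSpec([(10.0, 11.0), (10.5, 12.0)])


class TestIO:
    def test_three_row_csv_parses_single_spectrum(self, tmp_path):
        p = tmp_path / "s.csv"
        pd.DataFrame({
            "standard_id": "A", "pellet_id": "P1", "repeat_id": "R1",
            "energy_keV": [10.35, 10.36, 10.37],
            "total_counts": [5, 6, 7], "background_counts": [1, 1, 1],
            "live_time_s": 120.0,
        }).to_csv(p, index=False)
        (s,) = load_spectra(p)
        assert s.grid.step_keV == pytest.approx(0.01)
        assert s.grid.n_channels == 3
        assert s.standard_id == "A"

    def test_negative_count_in_file_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        pd.DataFrame({
            "standard_id": "A", "pellet_id": "P1", "repeat_id": "R1",
            "energy_keV": [10.0, 10.01], "total_counts": [5, -1],
            "background_counts": [1, 1], "live_time_s": 120.0,
        }).to_csv(p, index=False)
        with pytest.raises(ValidationError):
            load_spectra(p)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "s.csv"
        pd.DataFrame({"energy_keV": [1.0], "total_counts": [1]}).to_csv(
            p, index=False)
        with pytest.raises(FormatError):
            load_spectra(p)

    def test_nonuniform_step_is_grid_error(self, tmp_path):
        p = tmp_path / "s.csv"
        pd.DataFrame({
            "standard_id": "A", "pellet_id": "P1", "repeat_id": "R1",
            "energy_keV": [10.0, 10.01, 10.03], "total_counts": [1, 1, 1],
            "background_counts": [0, 0, 0], "live_time_s": 120.0,
        }).to_csv(p, index=False)
        with pytest.raises(GridError):
            load_spectra(p)

    def test_simulated_spectrum_roundtrips_exactly(self, tmp_path, detector):
        m = MatrixProfile(intrinsic_as=100.0, intrinsic_pb=10.0)
        exp = expected_spectrum(300.0, 150.0, m, detector,
                                standard_id="S", pellet_id="P1",
                                repeat_id="R1")
        s = sample_spectrum(exp, seed=3)
        p = tmp_path / "rt.csv"
        save_spectra([s], p)
        (back,) = load_spectra(p)
        assert np.array_equal(back.total_counts, s.total_counts)
        assert np.array_equal(back.background_counts, s.background_counts)
        assert back.grid.isclose(s.grid)
        assert (back.standard_id, back.pellet_id, back.repeat_id) == \
            ("S", "P1", "R1")
        assert back.live_time_s == s.live_time_s

    def test_standards_table_roundtrip_with_roles(self, tmp_path, detector):
        m = MatrixProfile(intrinsic_as=50.0, intrinsic_pb=5.0)
        spectra = []
        stds = []
        for i, conc in enumerate([100.0, 200.0]):
            s = sample_spectrum(
                expected_spectrum(conc, 5.0, m, detector,
                                  standard_id=f"S{i}", pellet_id="P1",
                                  repeat_id="R1"), seed=i)
            spectra.append(s)
            stds.append(Standard(f"S{i}", conc, 5.0, [s]))
        save_spectra(spectra, tmp_path / "sp.csv")
        save_standards(stds, tmp_path / "st.csv", role="train")
        back = load_standards(tmp_path / "sp.csv", tmp_path / "st.csv",
                              role="train")
        assert [b.standard_id for b in back] == ["S0", "S1"]
        assert back[0].as_conc == 100.0
        assert back[0].n_replicates == 1


class TestBackgroundSubtraction:
    def test_net_counts_arithmetic(self):
        s = _spec([100, 50], [40, 50])
        net = subtract_background(s)
        assert np.array_equal(net.total_counts, [60, 0])
        # background retained for audit
        assert np.array_equal(net.background_counts, [40, 50])

    def test_totals_equal_background_gives_zero(self):
        s = _spec([7, 7], [7, 7])
        assert np.array_equal(subtract_background(s).total_counts, [0, 0])

    def test_net_counts_not_clamped(self):
        s = _spec([10, 5], [12, 5])
        assert np.array_equal(subtract_background(s).total_counts, [-2, 0])


class TestFeatureExtraction:
    def test_published_windows_give_82_features(self, regions):
        s = _spec(np.ones(400), np.zeros(400), start=10.0, step=0.01)
        v = extract_features(s, regions)
        assert len(v) == 36 + 46

    def test_empty_window_raises(self):
        s = _spec(np.ones(100), np.zeros(100), start=10.0, step=0.01)
        with pytest.raises(EmptyWindowError):
            extract_features(s, RegionSpec([(10.355, 10.356)]))

    def test_full_grid_window_is_identity(self, small_spectrum):
        net = subtract_background(small_spectrum)
        full = RegionSpec([(net.grid.energies[0], net.grid.energies[-1])])
        assert np.array_equal(extract_features(net, full), net.total_counts)

    @given(a=st.floats(-5, 5), b=st.floats(-5, 5), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_extraction_is_linear(self, a, b, seed):
        regions = RegionSpec([(10.35, 10.70), (12.40, 12.85)])
        rng = np.random.default_rng(seed)
        grid = EnergyGrid(10.0, 0.01, 300)
        n1 = rng.normal(size=300)
        n2 = rng.normal(size=300)

        def feats(net):
            s = Spectrum(grid=grid, total_counts=net,
                         background_counts=np.zeros(300), is_net=True)
            return extract_features(s, regions)

        lhs = feats(a * n1 + b * n2)
        rhs = a * feats(n1) + b * feats(n2)
        assert np.allclose(lhs, rhs, atol=1e-9)


class TestDatasetAssembly:
    def _standards(self, n_std, n_spec, detector):
        m = MatrixProfile(intrinsic_as=50.0, intrinsic_pb=5.0)
        out = []
        for i in range(n_std):
            spectra = [
                sample_spectrum(
                    expected_spectrum(100.0 + i, 5.0, m, detector,
                                      standard_id=f"S{i}",
                                      pellet_id=f"P{j // 3 + 1}",
                                      repeat_id=f"R{j % 3 + 1}"),
                    seed=i * 100 + j)
                for j in range(n_spec)]
            out.append(Standard(f"S{i}", 100.0 + i, 5.0, spectra))
        return out

    @pytest.mark.parametrize("n_std,n_spec", [(4, 9), (1, 1), (3, 2)])
    def test_row_count_equals_total_spectra(self, n_std, n_spec, detector,
                                            regions):
        ft = assemble_dataset(self._standards(n_std, n_spec, detector),
                              regions)
        assert ft.n_rows == n_std * n_spec
        assert ft.n_features == 82

    def test_targets_constant_within_group(self, detector, regions):
        ft = assemble_dataset(self._standards(3, 4, detector), regions)
        for sid in np.unique(ft.groups):
            assert len(np.unique(ft.y[ft.groups == sid, 0])) == 1

    def test_permuting_standards_permutes_rows(self, detector, regions):
        stds = self._standards(3, 2, detector)
        ft1 = assemble_dataset(stds, regions)
        ft2 = assemble_dataset(stds[::-1], regions)
        order = [np.where(ft2.groups == g)[0][i % 2]
                 for i, g in enumerate(ft1.groups)]
        assert np.array_equal(ft1.X, ft2.X[order])


class TestReplicateSummary:
    @pytest.mark.parametrize("values,mean,sd", [
        ([1, 1, 1], 1.0, 0.0),
        ([0, 0, 0, 0, 0, 0, 0, 0, 0, 10], 1.0, 3.1622776601683795),
        ([5], 5.0, 0.0),
    ])
    def test_mean_and_sample_sd(self, values, mean, sd):
        got = summarize_replicates(values)
        assert got[0] == pytest.approx(mean)
        assert got[1] == pytest.approx(sd)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize_replicates([])
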