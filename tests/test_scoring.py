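"""Spectral accuracy and candidate ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specacc import (
    Formula,
    PeakShapeModel,
    ProfileSpectrum,
    SimulationConfig,
    Species,
    enumerate_candidates,
    extract_window,
    ion_formula_mz,
    rank_candidates,
    simulate_spectrum,
    spectral_accuracy,
    summary_string,
)
from specacc.scoring import ProfileWindow, parse_report_tsv, report


def window_from_arrays(mz, intensity, mono=None):
    mono = mono if mono is not None else mz[0] + 0.5
    return ProfileWindow(mono, -0.5, 3.5, np.asarray(mz, float), np.asarray(intensity, float))


class TestExtractWindow:
    def test_default_window_spans_m_to_m3_and_catches_interference(self):
        config = SimulationConfig(
            species=(
                Species(Formula.parse("C14H27NO3Na+"), 100.0),
                Species(283.0140, 30.0),  # interference 2.83 Da above mono
            ),
            grid_range=(270.0, 295.0),
        )
        spec = simulate_spectrum(config)
        win = extract_window(spec, 280.1883, (-0.5, 3.5))
        assert win.mz[0] == pytest.approx(279.6883, abs=0.02)
        assert win.mz[-1] == pytest.approx(283.6883, abs=0.02)
        at_interference = np.interp(283.0140, win.mz, win.intensity)
        assert at_interference > 10.0

    def test_narrowed_window_excludes_interference(self):
        config = SimulationConfig(
            species=(
                Species(Formula.parse("C14H27NO3Na+"), 100.0),
                Species(283.0140, 30.0),
            ),
            grid_range=(270.0, 295.0),
        )
        spec = simulate_spectrum(config)
        win = extract_window(spec, 280.1883, (-0.5, 2.5))
        assert win.mz[-1] < 283.0
        assert not win.is_empty

    def test_all_zero_window_object(self):
        grid = np.arange(150.0, 350.0, 0.01)
        spec = ProfileSpectrum(grid, np.zeros_like(grid), {})
        win = extract_window(spec, 280.0)
        assert win.is_empty

    def test_window_outside_spectrum_errors(self):
        grid = np.arange(150.0, 160.0, 0.01)
        spec = ProfileSpectrum(grid, np.ones_like(grid), {})
        with pytest.raises(ValueError):
            extract_window(spec, 300.0)

    def test_invalid_window_orientation(self):
        grid = np.arange(150.0, 350.0, 0.01)
        spec = ProfileSpectrum(grid, np.ones_like(grid), {})
        with pytest.raises(ValueError, match="start < 0 < end"):
            extract_window(spec, 200.0, (0.5, 3.5))

    def test_constant_baseline_is_removed(self, gaussian_spectrum):
        spec = gaussian_spectrum([(280.1883, 100.0)], baseline=5.0)
        win = extract_window(spec, 280.1883)
        # far from the peak the baseline-subtracted window is ~0
        far = np.abs(win.mz - 280.1883) > 1.5
        assert np.median(win.intensity[far]) < 0.5


class TestSpectralAccuracy:
    def test_perfect_fit_scores_100(self, gaussian_spectrum):
        spec = gaussian_spectrum([(280.1883, 100.0), (281.19, 16.0)])
        win = extract_window(spec, 280.1883)
        theo = ProfileSpectrum(win.mz, win.intensity + 1e-30, {})
        assert spectral_accuracy(win, theo) == pytest.approx(100.0, abs=1e-6)

    def test_disjoint_supports_score_0(self):
        mz = np.arange(279.7, 283.7, 0.01)
        o = np.where(np.abs(mz - 280.2) < 0.2, 50.0, 0.0)
        t = np.where(np.abs(mz - 282.8) < 0.2, 50.0, 0.0)
        win = window_from_arrays(mz, o, mono=280.2)
        assert spectral_accuracy(win, ProfileSpectrum(mz, t, {})) == 0.0

    def test_added_interference_strictly_lowers_sa(self, gaussian_spectrum):
        clean = gaussian_spectrum([(280.1883, 100.0), (281.1917, 16.0)])
        dirty = gaussian_spectrum(
            [(280.1883, 100.0), (281.1917, 16.0), (283.0140, 25.0)]
        )
        theo_win = extract_window(clean, 280.1883)
        theo = ProfileSpectrum(theo_win.mz, theo_win.intensity + 1e-30, {})
        sa_clean = spectral_accuracy(extract_window(clean, 280.1883), theo)
        sa_dirty = spectral_accuracy(extract_window(dirty, 280.1883), theo)
        assert sa_dirty < sa_clean

    def test_all_zero_observed_is_undefined_not_zero(self):
        mz = np.arange(279.7, 283.7, 0.01)
        win = window_from_arrays(mz, np.zeros_like(mz))
        theo = ProfileSpectrum(mz, np.ones_like(mz), {})
        assert spectral_accuracy(win, theo) is None

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.01, 1e4), st.floats(0.01, 1e4))
    def test_scale_invariance(self, s1, s2):
        rng = np.random.default_rng(3)
        mz = np.arange(279.7, 283.7, 0.01)
        o = np.abs(rng.normal(10, 3, mz.size))
        t = np.abs(rng.normal(10, 3, mz.size))
        base = spectral_accuracy(window_from_arrays(mz, o), ProfileSpectrum(mz, t, {}))
        scaled = spectral_accuracy(
            window_from_arrays(mz, o * s1), ProfileSpectrum(mz, t * s2, {})
        )
        assert scaled == pytest.approx(base, abs=1e-6)

    def test_zero_intensity_padding_changes_nothing(self):
        mz = np.arange(279.7, 283.7, 0.01)
        rng = np.random.default_rng(5)
        o = np.abs(rng.normal(10, 3, mz.size))
        t = np.abs(rng.normal(10, 3, mz.size))
        base = spectral_accuracy(window_from_arrays(mz, o), ProfileSpectrum(mz, t, {}))
        mz_pad = np.concatenate([mz, np.arange(290.0, 291.0, 0.01)])
        o_pad = np.concatenate([o, np.zeros(100)])
        t_pad = np.concatenate([t, np.zeros(100)])
        padded = spectral_accuracy(
            window_from_arrays(mz_pad, o_pad), ProfileSpectrum(mz_pad, t_pad, {})
        )
        assert padded == pytest.approx(base, abs=1e-9)

    def test_sa_degrades_monotonically_with_noise(self, qqq_shape):
        """Monte-Carlo, fixed seed: more additive noise, lower mean SA."""
        ion = Formula.parse("C13H20NO+")
        mean_sas = []
        for sigma in (0.0, 1.0, 3.0, 8.0):
            sas = []
            for rep in range(8):
                config = SimulationConfig(
                    species=(Species(ion, 100.0),),
                    noise_sigma=sigma,
                    seed=1000 + rep,
                    grid_range=(200.0, 212.0),
                )
                spec = simulate_spectrum(config)
                win = extract_window(spec, 206.1539)
                theo = np.zeros_like(win.mz)
                from specacc.isotopes import isotope_pattern

                for m, a in isotope_pattern(ion).peaks:
                    theo += qqq_shape.evaluate(win.mz, m, a)
                sas.append(
                    spectral_accuracy(win, ProfileSpectrum(win.mz, theo, {}))
                )
            mean_sas.append(np.mean(sas))
        assert all(a > b for a, b in zip(mean_sas, mean_sas[1:]))


class TestRankCandidates:
    def test_true_formula_ranks_first_on_clean_spectrum(self, qqq_shape):
        ion = Formula.parse("C13H20NO+")
        config = SimulationConfig(
            species=(Species(ion, 100.0),), grid_range=(200.0, 212.0)
        )
        spec = simulate_spectrum(config)
        cands = enumerate_candidates(206.1539)
        assert len(cands) == 6
        ranked = rank_candidates(spec, cands, qqq_shape)
        assert ranked[0].formula == ion
        assert summary_string(ranked, ion.hill()) == "1/6"
        assert [c.rank for c in ranked] == list(range(1, 7))

    def test_generating_formula_attains_maximal_sa_for_all_six_ions(self, qqq_shape):
        from conftest import ANALYTE_IONS

        for label, (text, exact) in ANALYTE_IONS.items():
            ion = Formula.parse(text)
            spec = simulate_spectrum(
                SimulationConfig(
                    species=(Species(ion, 100.0),),
                    grid_range=(exact - 6.0, exact + 8.0),
                )
            )
            ranked = rank_candidates(spec, enumerate_candidates(exact), qqq_shape)
            assert ranked[0].formula == ion, f"compound {label}"

    def test_interference_narrowing_improves_sa_and_rank(self, qqq_shape):
        ion = Formula.parse("C14H27NO3Na+")
        config = SimulationConfig(
            species=(Species(ion, 100.0), Species(283.0140, 40.0)),
            grid_range=(270.0, 295.0),
        )
        spec = simulate_spectrum(config)
        cands = enumerate_candidates(280.1883)
        wide = rank_candidates(spec, cands, qqq_shape, (-0.5, 3.5))
        narrow = rank_candidates(spec, cands, qqq_shape, (-0.5, 2.5))
        sa_wide = next(c.sa for c in wide if c.formula == ion)
        sa_narrow = next(c.sa for c in narrow if c.formula == ion)
        rank_wide = next(c.rank for c in wide if c.formula == ion)
        rank_narrow = next(c.rank for c in narrow if c.formula == ion)
        assert sa_narrow > sa_wide
        assert rank_narrow <= rank_wide

    def test_single_candidate_is_rank_1_regardless_of_sa(self, qqq_shape):
        ion = Formula.parse("C13H20NO+")
        cons_ion = enumerate_candidates(
            ion_formula_mz(ion),
            __import__("specacc").SearchConstraints(
                elements=(("C", 13, 13), ("H", 20, 20), ("N", 1, 1), ("O", 1, 1)),
                tolerance_mda=0.5,
            ),
        )
        grid = np.arange(200.0, 212.0, 0.01)
        rng = np.random.default_rng(9)
        spec = ProfileSpectrum(grid, np.abs(rng.normal(5, 1, grid.size)), {})
        ranked = rank_candidates(spec, cons_ion, qqq_shape)
        assert len(ranked) == 1 and ranked[0].rank == 1

    def test_empty_candidate_set_errors(self, qqq_shape, gaussian_spectrum):
        from specacc.search import CandidateSet, SearchConstraints

        spec = gaussian_spectrum([(206.15, 100.0)])
        with pytest.raises(ValueError):
            rank_candidates(spec, CandidateSet(206.15, SearchConstraints()), qqq_shape)


class TestReport:
    def _ranked(self, qqq_shape):
        ion = Formula.parse("C13H20NO+")
        spec = simulate_spectrum(
            SimulationConfig(species=(Species(ion, 100.0),), grid_range=(200.0, 212.0))
        )
        return rank_candidates(spec, enumerate_candidates(206.1539), qqq_shape)

    def test_summary_string_formats_rank_over_total(self, qqq_shape):
        ranked = self._ranked(qqq_shape)
        assert summary_string(ranked, "C13H20NO+") == "1/6"
        with pytest.raises(ValueError):
            summary_string(ranked, "C99H99+")

    def test_tsv_round_trip(self, tmp_path, qqq_shape):
        ranked = self._ranked(qqq_shape)
        p = tmp_path / "ranked.tsv"
        report(ranked, p, fmt="tsv")
        rows = parse_report_tsv(p.read_text())
        assert len(rows) == len(ranked)
        for row, c in zip(rows, ranked):
            assert row["rank"] == c.rank
            assert row["formula"] == c.formula.hill()
            assert row["sa"] == pytest.approx(c.sa, abs=0.05)

    def test_empty_list_gives_header_only(self):
        text = report([], fmt="tsv")
        assert text.strip() == "rank\tformula\texact_mz\tdelta_m_mda\trdbe\tsa"
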