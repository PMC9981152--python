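"""LN Gabor population, divisive surround, noise model, archetypes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from figground.geometry import CanvasGeometry
from figground.population import (ArchetypeSpec, GaborParams, GaborPopulation,
                                  NoiseModel, OrientationEnergyBank,
                                  ResponseMatrix, SurroundParams, add_noise,
                                  archetype_response, gabor_image, ln_response,
                                  sample_population, simulate_session,
                                  surround_modulate, _region_masks)
from figground.session import (PositionGrid, build_figure_map_session,
                               canonical_condition_specs)
from figground.stimuli import MotionSpec, StimulusMovie, condition_spec, \
    render_trial_movie


class TestSamplePopulation:
    def test_parameter_ranges(self):
        pop = sample_population(25_000, seed=0)
        p = pop.params
        assert len(pop) == 25_000
        assert p.sigma.between(2.0, 7.0).all()
        assert (1.0 / p.wavelength).between(0.05, 0.3).all()
        assert p.theta.between(0, np.pi).all()
        assert p.omega.between(0, np.pi).all()
        assert (p.gamma == 1.0).all()

    def test_seed_determinism(self):
        a = sample_population(500, seed=3)
        b = sample_population(500, seed=3)
        assert a.params.equals(b.params)

    def test_theta_is_uniform(self):
        """KS statistic of theta against U(0, pi) below 0.01 at n = 1e5."""
        pop = sample_population(100_000, seed=1)
        d = stats.kstest(pop.params.theta / np.pi, "uniform").statistic
        assert d < 0.01


class TestLNResponse:
    def test_gabor_peak_at_center(self, canvas):
        g = gabor_image(GaborParams(theta=0.3, sigma=4.0, wavelength=10.0,
                                    omega=0.0), canvas)
        row, col = canvas.pixel_of(0.0, 0.0)
        assert g[int(row), int(col)] == pytest.approx(1.0, abs=0.05)

    def test_uniform_gray_gives_zero(self, canvas):
        frames = np.full((3, *canvas.shape), 0.5, dtype=np.float32)
        movie = StimulusMovie(frames, 56.0, np.zeros(3), np.zeros(3),
                              np.zeros(3, int), np.zeros(3, int), None, canvas)
        params = GaborParams(theta=0.5, sigma=3.0, wavelength=8.0)
        assert ln_response(params, movie) == 0.0

    def test_matched_grating_maximizes_response(self, small_canvas):
        """A full-field grating matched in orientation, frequency and phase
        drives the filter harder than any probe in a brute-force sweep."""
        from figground.textures import TextureSpec, make_texture
        params = GaborParams(theta=0.0, sigma=4.0, wavelength=10.0, omega=0.0)

        def response_to(ori_deg, freq, phase):
            img = make_texture(TextureSpec("grating", orientation_deg=ori_deg,
                                           spatial_freq_cpd=freq, phase=phase),
                               small_canvas).astype(np.float32)
            movie = StimulusMovie(img[None], 56.0, np.zeros(1), np.zeros(1),
                                  np.zeros(1, int), np.zeros(1, int), None,
                                  small_canvas)
            return ln_response(params, movie)

        # theta=0 Gabor varies along azimuth; a 0-deg grating at the filter
        # frequency and cosine phase is the matched stimulus
        matched = response_to(0.0, 0.1, 0.0)
        sweep = [response_to(o, f, p)
                 for o in (0.0, 45.0, 90.0, 135.0)
                 for f in (0.05, 0.1, 0.2)
                 for p in (0.0, np.pi / 2, np.pi)]
        assert matched == pytest.approx(max(sweep))
        assert matched > 0


class TestSurround:
    def test_modulation_algebra_and_nan_passthrough(self, canvas):
        pop = sample_population(20, center_extent_deg=(-3, 3, -3, 3),
                                seed=5, canvas=canvas)
        sur = SurroundParams()
        movie = render_trial_movie(condition_spec("Iso", 1), canvas)
        frame = movie.frames[-1].astype(float)
        ff = np.ones(20)
        mod, rho = surround_modulate(ff, frame, pop, sur)
        expected = ff / (1.0 + sur.beta * np.where(np.isnan(rho), 0.0, rho))
        assert np.allclose(mod, expected)
        # uniform gray: zero-variance energies, rho undefined, rate unchanged
        mod_flat, rho_flat = surround_modulate(ff, np.full(canvas.shape, 0.5),
                                               pop, sur)
        assert np.all(np.isnan(rho_flat))
        assert np.allclose(mod_flat, ff)

    def test_rho_sign_iso_positive_cross_negative(self, canvas):
        """Cells whose surround annulus reaches beyond the 27-deg figure see
        matched orientation content for Iso (rho > 0, suppression) and
        orthogonal content for Cross (rho < 0, facilitation)."""
        # sigma >= 5 so the 2-5 sigma annulus extends past the figure border
        params = pd.DataFrame({
            "theta": np.linspace(0, np.pi, 12, endpoint=False),
            "sigma": 6.0, "wavelength": 12.0, "gamma": 1.0, "omega": 0.0,
            "x0": 0.0, "y0": 0.0})
        pop = GaborPopulation(params, canvas)
        sur = SurroundParams()
        bank = OrientationEnergyBank(canvas, sur.n_cell_types, sur.seed)
        masks = _region_masks(pop, sur)
        rho = {}
        for cond in ("Cross", "Iso"):
            vals = []
            for var in (1, 2):
                m = render_trial_movie(condition_spec(cond, var), canvas)
                frame = m.frames[int(np.argmax(np.abs(m.relative_disp_deg())))]
                from figground.population import surround_rho
                vals.append(surround_rho(frame.astype(float), pop, sur,
                                         bank, masks))
            rho[cond] = np.concatenate(vals)
        assert np.nanmean(rho["Iso"]) > 0.5
        assert np.nanmean(rho["Cross"]) < 0.0

    def test_invalid_surround_params(self):
        with pytest.raises(ValueError):
            SurroundParams(beta=1.0)
        with pytest.raises(ValueError):
            SurroundParams(inner_radius_sigma=5, outer_radius_sigma=2)


class TestNoiseModel:
    def _matrix(self, values, conditions):
        n, t = values.shape
        trials = pd.DataFrame({"condition": conditions,
                               "variant": 1,
                               "az_bin": 1, "el_bin": 1,
                               "onset_s": np.arange(t) * 0.25,
                               "motion_phase": 0.0,
                               "trial": np.arange(t)})
        return ResponseMatrix(values, pd.DataFrame(index=range(n)), trials)

    def test_zero_factor_is_identity(self):
        rm = self._matrix(np.random.default_rng(0).uniform(0, 5, (4, 40)),
                          ["Cross"] * 40)
        out = add_noise(rm, NoiseModel(0.0), seed=1)
        assert np.array_equal(out.responses, rm.responses)

    def test_outputs_rectified(self):
        rm = self._matrix(np.full((5, 200), 0.1), ["Cross"] * 200)
        out = add_noise(rm, NoiseModel(5.0), seed=2)
        assert (out.responses >= 0).all()

    def test_noise_variance_matches_mean_scaled_law(self):
        """Added-noise variance is noise_factor * popmean within 5% (checked
        at a mean high enough that rectification never clips)."""
        mean = 1000.0
        rm = self._matrix(np.full((100, 1000), mean), ["Cross"] * 1000)
        out = add_noise(rm, NoiseModel(2.0), seed=3)
        noise = out.responses - mean
        assert noise.var() == pytest.approx(2.0 * mean, rel=0.05)
        assert abs(noise.mean()) < 1.0

    def test_popmean_scope_is_per_condition(self):
        vals = np.concatenate([np.full((1, 500), 10000.0),
                               np.full((1, 500), 100.0)], axis=1)
        rm = self._matrix(np.repeat(vals, 20, axis=0),
                          ["Cross"] * 500 + ["Nat"] * 500)
        out = add_noise(rm, NoiseModel(1.0), seed=4)
        noise = out.responses - rm.responses
        var_cross = noise[:, :500].var()
        var_nat = noise[:, 500:].var()
        assert var_cross == pytest.approx(10000.0, rel=0.1)
        assert var_nat == pytest.approx(100.0, rel=0.1)


class TestArchetypes:
    def test_figure_cell_rule(self):
        cell = ArchetypeSpec("figure_cell", rf_center=(0.0, 0.0), rf_size=3.0)
        assert archetype_response(cell, (0.0, 0.0), 27.0) == 1.0
        assert archetype_response(cell, (40.0, 0.0), 27.0) == 0.0
        # touching at the dilated boundary counts
        assert archetype_response(cell, (13.5 + 3.0, 0.0), 27.0) == 1.0
        assert archetype_response(cell, (13.5 + 3.1, 0.0), 27.0) == 0.0

    def test_border_cell_prefers_side(self):
        cell = ArchetypeSpec("border_cell", rf_center=(0.0, 0.0), rf_size=2.0,
                             preferred_border_orientation="vertical",
                             preferred_side="left")
        # figure on the left: its right edge (at center + 13.5) crosses the RF
        assert archetype_response(cell, (-13.5, 0.0), 27.0) == 1.0
        # figure on the right: its right edge is far away
        assert archetype_response(cell, (13.5, 0.0), 27.0) == 0.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ArchetypeSpec("edge_cell")

    def test_figure_cell_map_is_dilated_square(self, canvas):
        """The figure map of a figure cell is the figure square dilated by
        the RF disc, computed against a closed-form geometry oracle."""
        grid = PositionGrid(repeats_per_position=1)
        session = build_figure_map_session(
            grid, canonical_condition_specs(("Cross",), (1,)), seed=0,
            canvas=canvas)
        cell = ArchetypeSpec("figure_cell", rf_center=(0.0, 0.0), rf_size=4.0)
        rm = simulate_session([cell], session)
        from figground.figure_maps import build_figure_map
        fmap = build_figure_map(rm.responses[0], rm.trials, grid, "Cross", 1)
        half = 27.0 / 2.0
        for el_bin in range(1, 9):
            for az_bin in range(1, 17):
                dx = max(abs(grid.azimuth_of_bin(az_bin)) - half, 0.0)
                dy = max(abs(grid.elevation_of_bin(el_bin)) - half, 0.0)
                expected = 1.0 if np.hypot(dx, dy) <= 4.0 else 0.0
                assert fmap.values[el_bin - 1, az_bin - 1] == expected


class TestSimulateSession:
    def test_duplicate_trials_identical_when_noiseless(self, canvas):
        grid = PositionGrid(n_azimuth=2, n_elevation=2, azimuth_span_deg=3.0,
                            elevation_span_deg=3.0, repeats_per_position=3)
        session = build_figure_map_session(
            grid, canonical_condition_specs(("Cross",), (1,)), seed=1,
            canvas=canvas, continuous_motion_phase=False)
        pop = sample_population(5, center_extent_deg=(-2, 2, -2, 2),
                                seed=2, canvas=canvas)
        rm = simulate_session(pop, session)
        df = pd.DataFrame(rm.responses.T)
        df["key"] = rm.trials[["az_bin", "el_bin"]].astype(str).agg("-".join,
                                                                    axis=1)
        assert (df.groupby("key").nunique() == 1).all().all()

    def test_trial_count_and_determinism(self, canvas):
        grid = PositionGrid(n_azimuth=4, n_elevation=2, azimuth_span_deg=9.0,
                            elevation_span_deg=3.0, repeats_per_position=2)
        session = build_figure_map_session(
            grid, canonical_condition_specs(("Cross", "Nat")), seed=3,
            canvas=canvas)
        pop = sample_population(4, center_extent_deg=(-4, 4, -1, 1),
                                seed=4, canvas=canvas)
        a = simulate_session(pop, session, noise=NoiseModel(1.0), seed=5)
        b = simulate_session(pop, session, noise=NoiseModel(1.0), seed=5)
        # 4 condition-variants x 8 positions x 2 repeats
        assert a.responses.shape == (4, 4 * 8 * 2)
        assert np.array_equal(a.responses, b.responses)
        assert (a.responses >= 0).all()
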