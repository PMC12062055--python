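import numpy as np
import pytest

from conftest import max_eig_discrepancy, random_panel
from epidmd import dmd
from epidmd.errors import (
    InsufficientDataError,
    NoSteadyModeError,
    RankError,
    ValidationError,
)
from epidmd.io_panel import IncidencePanel
from epidmd.synthetic import GeneratorConfig, generate_panel


class TestBuildSnapshots:
    def test_shift_by_one(self):
        panel = IncidencePanel(["00001"], [2000, 2001, 2002, 2003],
                               np.array([[1.0, 2.0, 3.0, 4.0]]))
        snaps = dmd.build_snapshots(panel)
        np.testing.assert_array_equal(snaps.X1, [[1, 2, 3]])
        np.testing.assert_array_equal(snaps.X2, [[2, 3, 4]])
        assert snaps.m == 4

    def test_twenty_training_years_give_nineteen_columns(self):
        rng = np.random.default_rng(0)
        panel = random_panel(rng, 5, 22)
        snaps = dmd.build_snapshots(panel, (2000, 2019))
        assert snaps.X1.shape[1] == snaps.X2.shape[1] == 19
        assert snaps.m == 20

    def test_single_snapshot_errors(self):
        panel = IncidencePanel(["00001"], [2000], np.array([[1.0]]))
        with pytest.raises(InsufficientDataError):
            dmd.build_snapshots(panel)

    def test_shift_consistency_enforced(self):
        with pytest.raises(ValidationError):
            dmd.SnapshotPair(
                X1=np.array([[1.0, 2.0]]), X2=np.array([[5.0, 9.0]]),
                counties=["00001"], years=[2000, 2001, 2002],
            )


class TestFit:
    def test_constant_panel_gives_unit_eigenvalue(self):
        panel = IncidencePanel(
            ["00001", "00002"], [2000, 2001, 2002],
            np.array([[3.0, 3.0, 3.0], [7.0, 7.0, 7.0]]),
        )
        snaps = dmd.build_snapshots(panel)
        model = dmd.fit(snaps, 1)
        np.testing.assert_allclose(model.eigenvalues, [1.0 + 0j], atol=1e-12)
        np.testing.assert_allclose(dmd.predict(model, 1), snaps.snapshot(1), atol=1e-10)

    def test_scalar_geometric_decay(self, scalar_decay_panel):
        model = dmd.fit(dmd.build_snapshots(scalar_decay_panel), 1)
        np.testing.assert_allclose(model.eigenvalues, [0.9 + 0j], atol=1e-12)
        # unit-norm mode with amplitude absorbing the scale: phi * b = 100
        np.testing.assert_allclose(model.Phi[:, 0] * model.amplitudes[0],
                                   [100.0 + 0j], atol=1e-9)
        np.testing.assert_allclose(dmd.predict(model, 5), [65.61], atol=1e-9)

    def test_svd_factor_invariants(self, small_noise_free):
        (panel, _), cfg = small_noise_free
        model = dmd.fit(dmd.build_snapshots(panel), cfg.r_true)
        r = model.r
        np.testing.assert_allclose(model.U.T @ model.U, np.eye(r), atol=1e-10)
        np.testing.assert_allclose(model.V.T @ model.V, np.eye(r), atol=1e-10)
        assert np.all(np.diff(model.S) <= 0) and np.all(model.S > 0)
        lhs = model.A_tilde @ model.W
        rhs = model.W * model.eigenvalues
        assert np.abs(lhs - rhs).max() < 1e-8 * np.abs(model.A_tilde).max()

    def test_eigenvalue_ordering_contract(self):
        rng = np.random.default_rng(7)
        model = dmd.fit(dmd.build_snapshots(random_panel(rng, 8, 9)), "full")
        mags = np.abs(model.eigenvalues)
        assert np.all(np.diff(mags) <= 1e-12)

    def test_full_rank_matches_pseudoinverse_oracle(self):
        """DMD spectrum == nonzero spectrum of the dense operator X2 pinv(X1)."""
        rng = np.random.default_rng(21)
        for _ in range(25):
            n, m = int(rng.integers(2, 9)), int(rng.integers(3, 11))
            snaps = dmd.build_snapshots(random_panel(rng, n, m))
            model = dmd.fit(snaps, "full")
            dense = snaps.X2 @ np.linalg.pinv(snaps.X1)
            ev = np.linalg.eigvals(dense)
            ev = ev[np.argsort(-np.abs(ev))][: model.r]
            assert max_eig_discrepancy(model.eigenvalues, ev) < 1e-8

    def test_rank_beyond_numerical_rank_reports_it(self, small_noise_free):
        (panel, _), cfg = small_noise_free
        snaps = dmd.build_snapshots(panel)
        with pytest.raises(RankError) as err:
            dmd.fit(snaps, cfg.r_true + 1)
        assert err.value.numerical_rank == cfg.r_true

    def test_zero_matrix_is_degenerate(self):
        from epidmd.errors import DegenerateInputError
        snaps = dmd.SnapshotPair(np.zeros((3, 2)), np.zeros((3, 2)),
                                 ["00001", "00002", "00003"], [2000, 2001, 2002])
        with pytest.raises(DegenerateInputError):
            dmd.fit(snaps, 1)

    def test_row_permutation_equivariance(self, small_noise_free):
        (panel, _), cfg = small_noise_free
        rng = np.random.default_rng(0)
        perm = rng.permutation(panel.n_counties)
        permuted = IncidencePanel(
            counties=[panel.counties[i] for i in perm],
            years=list(panel.years), values=panel.values[perm],
        )
        m1 = dmd.fit(dmd.build_snapshots(panel), cfg.r_true)
        m2 = dmd.fit(dmd.build_snapshots(permuted), cfg.r_true)
        assert max_eig_discrepancy(m1.eigenvalues, m2.eigenvalues) < 1e-9
        # mode magnitudes permute with the rows (phases may rotate)
        np.testing.assert_allclose(
            np.abs(m2.Phi), np.abs(m1.Phi[perm]), atol=1e-8
        )


class TestPredict:
    def test_in_sample_reconstruction_exact_for_linear_system(self, small_noise_free):
        (panel, _), cfg = small_noise_free
        snaps = dmd.build_snapshots(panel)
        model = dmd.fit(snaps, "full")
        scale = np.abs(panel.values).max()
        for k in range(1, snaps.m + 1):
            err = np.abs(dmd.predict(model, k) - snaps.snapshot(k)).max()
            assert err < 1e-6 * scale

    def test_decaying_spectrum_prediction_vanishes(self, small_noise_free):
        """|lambda|max < 1 forces ||predict(k)|| -> 0; the step at which it
        drops below 1e-6 of the initial state is bounded by |lambda|max^(k-1)
        computed from the fitted spectrum itself."""
        (panel, _), cfg = small_noise_free
        model = dmd.fit(dmd.build_snapshots(panel), cfg.r_true)
        lam_max = np.abs(model.eigenvalues).max()
        assert lam_max < 1.0
        n1 = np.linalg.norm(dmd.predict(model, 1))
        # smallest k with lam_max^(k-1) * amplitude headroom below 1e-6
        headroom = np.sum(np.abs(model.amplitudes)) / n1
        k = 1 + int(np.ceil(np.log(1e-6 / headroom) / np.log(lam_max)))
        assert np.linalg.norm(dmd.predict(model, k)) < 1e-6 * n1
        assert np.linalg.norm(dmd.predict(model, 200)) < np.linalg.norm(
            dmd.predict(model, 100)
        )

    def test_real_output_guarantee_conjugate_closed(self, small_noise_free):
        (panel, _), cfg = small_noise_free
        model = dmd.fit(dmd.build_snapshots(panel), cfg.r_true)
        coeff = model.amplitudes * model.eigenvalues ** 9
        raw = model.Phi @ coeff
        assert np.abs(raw.imag).max() < 1e-8 * np.linalg.norm(raw)

    def test_step_index_domain(self, scalar_decay_panel):
        model = dmd.fit(dmd.build_snapshots(scalar_decay_panel), 1)
        with pytest.raises(ValidationError):
            dmd.predict(model, 0)


class TestRankSweep:
    def test_energy_ratio_frobenius_arithmetic(self):
        # snapshots x1=[4,0], x2=[0,3], x3=[4,0]: X1 has singular values {4, 3}
        snaps = dmd.SnapshotPair(
            X1=np.array([[4.0, 0.0], [0.0, 3.0]]),
            X2=np.array([[0.0, 4.0], [3.0, 0.0]]),
            counties=["00001", "00002"], years=[2000, 2001, 2002],
        )
        table = dmd.rank_sweep(snaps, holdout=np.array([1.0, 1.0]), ranks=[1, 2])
        np.testing.assert_allclose(table["energy_ratio"], [16 / 25, 1.0], atol=1e-12)

    def test_exact_low_rank_case(self, small_noise_free):
        (panel, _), cfg = small_noise_free
        train = panel.restrict_years(panel.years[0], panel.years[-2])
        snaps = dmd.build_snapshots(train)
        holdout = panel.column(panel.years[-1])
        table = dmd.rank_sweep(snaps, holdout, ranks=[1, 2, 3])
        scale = np.abs(holdout).max()
        assert table.loc[table["rank"] == 3, "rmse"].item() < 1e-6 * scale
        assert table.loc[table["rank"] == 3, "energy_ratio"].item() > 1 - 1e-10
        assert table["energy_ratio"].is_monotonic_increasing

    def test_noisy_energy_curve_strictly_increasing(self):
        cfg = GeneratorConfig(n_counties=80, n_years=12, n_blocks=8, noise_sd=2.0, seed=3)
        panel, _ = generate_panel(cfg)
        train = panel.restrict_years(2000, 2010)
        snaps = dmd.build_snapshots(train)
        table = dmd.rank_sweep(snaps, panel.column(2011))
        er = table["energy_ratio"].to_numpy()
        assert np.all(np.diff(er) > 0)
        # independent cumulative-sum oracle
        s = np.linalg.svd(snaps.X1, compute_uv=False)
        oracle = np.cumsum(s**2) / np.sum(s**2)
        np.testing.assert_allclose(er, oracle[: len(er)], atol=1e-12)
        assert np.all(np.isfinite(table["rmse"]))


class TestEigenSpectrum:
    def test_decaying_real_eigenvalue_row(self, scalar_decay_panel):
        model = dmd.fit(dmd.build_snapshots(scalar_decay_panel), 1)
        row = dmd.eigen_spectrum(model).iloc[0]
        assert row["magnitude"] == pytest.approx(0.9, abs=1e-12)
        assert row["frequency"] == pytest.approx(0.0, abs=1e-12)
        assert row["growth"] == pytest.approx(np.log(0.9), abs=1e-10)
        assert bool(row["inside_unit_circle"])

    def test_unit_circle_boundary_not_inside(self):
        """The boundary |lambda| = 1 is flagged as not inside (strict test)."""
        panel = IncidencePanel(["00001"], [2000, 2001, 2002],
                               np.array([[5.0, 5.0, 5.0]]))
        model = dmd.fit(dmd.build_snapshots(panel), 1)
        model.eigenvalues = np.array([1.0 + 0j])  # exact boundary value
        row = dmd.eigen_spectrum(model).iloc[0]
        assert row["growth"] == pytest.approx(0.0, abs=1e-12)
        assert not bool(row["inside_unit_circle"])

    def test_all_inside_when_truth_decays(self, small_noise_free):
        (panel, truth), cfg = small_noise_free
        model = dmd.fit(dmd.build_snapshots(panel), cfg.r_true)
        spec = dmd.eigen_spectrum(model)
        assert np.abs(truth.eigenvalues).max() < 1.0
        assert spec["inside_unit_circle"].all()


class TestDominantModeTable:
    def test_high_block_outranks_all_other_counties(self, small_noise_free):
        (panel, truth), cfg = small_noise_free
        model = dmd.fit(dmd.build_snapshots(panel), cfg.r_true)
        table = dmd.dominant_mode_table(model, panel)
        in_high = table["fips"].str.startswith(cfg.high_block).to_numpy()
        assert in_high.any() and (~in_high).any()
        assert table["magnitude"][in_high].min() > table["magnitude"][~in_high].max()
        assert abs(table.attrs["eigenvalue"].imag) < 1e-8

    def test_scalar_model_unit_magnitude(self, scalar_decay_panel):
        model = dmd.fit(dmd.build_snapshots(scalar_decay_panel), 1)
        table = dmd.dominant_mode_table(model, scalar_decay_panel)
        np.testing.assert_allclose(table["magnitude"], [1.0], atol=1e-12)

    def test_pure_oscillation_has_no_steady_mode(self):
        # conjugate pair only: cos/sin evolution, no zero-frequency eigenvalue
        rng = np.random.default_rng(2)
        lam = 0.9 * np.exp(0.7j)
        phi = rng.standard_normal(6) + 1j * rng.standard_normal(6)
        states = np.column_stack(
            [(phi * lam**k + np.conj(phi) * np.conj(lam) ** k).real
             for k in range(8)]
        )
        snaps = dmd.SnapshotPair(states[:, :-1], states[:, 1:],
                                 [f"{i + 1:05d}" for i in range(6)],
                                 list(range(2000, 2008)))
        model = dmd.fit(snaps, 2)
        assert np.abs(np.angle(model.eigenvalues)).min() > 0.5
        with pytest.raises(NoSteadyModeError):
            dmd.dominant_mode_table(model)
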