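"""Synthetic generators: determinism, generative structure, oracle agreement."""

import numpy as np
import pandas as pd
import pytest

import dropqs as dq
from dropqs.errors import InvalidInputError


def measured_fraction(droplets: pd.DataFrame) -> float:
    """Ground-truth percent positive cells from a droplet table."""
    return 100.0 * droplets["n_positive"].sum() / droplets["n_cells"].sum()


def cluster_se(droplets: pd.DataFrame) -> float:
    k = droplets["n_cells"].to_numpy(dtype=float)
    pos = droplets["n_positive"].to_numpy(dtype=float)
    p = pos.sum() / k.sum()
    return 100.0 * np.sqrt(np.sum((pos - p * k) ** 2)) / k.sum()


class TestDeterminism:
    def test_same_seed_identical_event_tables(self, config):
        e1 = dq.generate_single_cell_events(config, n_cells=2000, seed=9)
        e2 = dq.generate_single_cell_events(config, n_cells=2000, seed=9)
        pd.testing.assert_frame_equal(e1, e2)

    def test_same_seed_byte_identical_files(self, config, tmp_path):
        cfg = dq.GeneratorConfig(n_droplets=500)
        for name in ("x", "y"):
            droplets, events = dq.generate_multicell_dataset(cfg, seed=13)
            dq.write_table(droplets, tmp_path / f"{name}_droplets.csv", "droplets")
            dq.write_table(events, tmp_path / f"{name}_events.csv", "events")
        assert (tmp_path / "x_droplets.csv").read_bytes() == (tmp_path / "y_droplets.csv").read_bytes()
        assert (tmp_path / "x_events.csv").read_bytes() == (tmp_path / "y_events.csv").read_bytes()

    def test_csv_round_trip_preserves_values(self, config, tmp_path):
        events = dq.generate_single_cell_events(config, n_cells=500, seed=2)
        dq.write_table(events, tmp_path / "events.csv", "events")
        back = dq.read_table(tmp_path / "events.csv")
        assert dq.validate_frame(back, "events") == []
        np.testing.assert_allclose(back["il10_signal"], events["il10_signal"], rtol=1e-9)
        assert (back["true_producer"] == events["true_producer"]).all()


class TestSingleCellEvents:
    def test_degenerate_producer_fractions(self):
        none = dq.generate_single_cell_events(
            dq.GeneratorConfig(producer_fraction=0.0), n_cells=500, seed=1
        )
        assert not none["true_producer"].any()
        all_prod = dq.generate_single_cell_events(
            dq.GeneratorConfig(producer_fraction=1.0), n_cells=500, seed=1
        )
        assert all_prod["true_producer"].all()

    def test_bimodal_separation_around_gate(self, config):
        events = dq.generate_single_cell_events(config, n_cells=20_000, seed=5)
        gate = config.positivity_gate_mfi
        producers = events[events.true_producer]
        others = events[~events.true_producer]
        assert (producers["il10_signal"] > gate).mean() > 0.99
        assert (others["il10_signal"] < gate).mean() > 0.99

    def test_tnfa_signal_positive_for_all_cells(self, config):
        events = dq.generate_single_cell_events(config, n_cells=5000, seed=6)
        assert (events["tnfa_signal"] > config.positivity_gate_mfi).mean() > 0.99

    def test_unstimulated_control_has_no_producers(self, config):
        control = dq.generate_single_cell_events(config, n_cells=2000, seed=7, stimulated=False)
        assert not control["true_producer"].any()
        assert (control["il10_signal"] < config.positivity_gate_mfi).mean() > 0.99


class TestMulticellDataset:
    def test_ground_truth_fraction_matches_exact_model(self):
        cfg = dq.GeneratorConfig(n_droplets=20_000)
        droplets, _ = dq.generate_multicell_dataset(cfg, seed=23)
        for a in cfg.occupancy_means:
            sub = droplets[droplets["condition"] == f"a={a:g}"]
            exact = dq.fraction_positive_exact(
                dq.SharingParams(a=a, b=cfg.producer_fraction)
            ).fraction_positive
            assert abs(measured_fraction(sub) - exact) < 4 * cluster_se(sub)

    def test_single_cell_regime_fraction_approaches_b(self):
        # occupied droplets almost always hold one cell, so fraction -> b;
        # the occupancy must be genuinely small: cell-weighted (size-biased)
        # sampling inflates multi-cell droplets even at a = 0.3
        cfg = dq.GeneratorConfig(occupancy_means=(0.05,), n_droplets=200_000)
        droplets, _ = dq.generate_multicell_dataset(cfg, seed=24)
        frac = measured_fraction(droplets)
        exact = dq.fraction_positive_exact(dq.SharingParams(a=0.05, b=0.1)).fraction_positive
        assert abs(frac - exact) < 4 * cluster_se(droplets)
        assert abs(frac - 10.0) < 1.5

    def test_events_consistent_with_droplet_table(self):
        cfg = dq.GeneratorConfig(n_droplets=1000, occupancy_means=(4.0,))
        droplets, events = dq.generate_multicell_dataset(cfg, seed=25)
        assert len(events) == droplets["n_cells"].sum()
        by_droplet = events.groupby("droplet_id")["true_producer"].sum()
        merged = droplets.set_index("droplet_id").join(by_droplet, how="left").fillna(0)
        np.testing.assert_array_equal(
            merged["true_producer"].to_numpy(dtype=int),
            merged["n_producers"].to_numpy(dtype=int),
        )
        pos_cells = events.groupby("droplet_id")["true_positive"].sum()
        merged2 = droplets.set_index("droplet_id").join(pos_cells, how="left").fillna(0)
        np.testing.assert_array_equal(
            merged2["true_positive"].to_numpy(dtype=int),
            merged2["n_positive"].to_numpy(dtype=int),
        )


class TestTitrationStandards:
    def test_noiseless_standards_exactly_on_curve(self, noiseless_config):
        std = dq.generate_titration_standards(noiseless_config, seed=0, cytokines=("IL-10",))
        expected = dq.true_forward(noiseless_config, std["concentration_pg_ml"].to_numpy())
        np.testing.assert_allclose(std["mfi"], expected, rtol=1e-12)

    def test_fit_on_noiseless_standards_reproduces_forward_map(self, noiseless_config):
        std = dq.generate_titration_standards(noiseless_config, seed=0, cytokines=("IL-10",))
        curve = dq.fit_titration(std)
        lo, hi = curve.valid_range
        conc = np.geomspace(lo, hi, 200)
        np.testing.assert_allclose(
            curve.forward(conc), dq.true_forward(noiseless_config, conc), rtol=1e-3
        )

    def test_noisy_standards_remain_monotone(self, config):
        std = dq.generate_titration_standards(config, seed=1)
        assert dq.validate_frame(std, "standards") == []


class TestDensityTimecourse:
    def test_shutoff_times_strictly_decrease_with_density(self, config):
        table = dq.generate_density_timecourse(config, seed=41)
        for donor in ("D1", "D4"):
            shutoffs = []
            for density in config.densities_e6:
                grp = table[
                    (table.donor == donor)
                    & (table.cytokine == "IL-10")
                    & (table.condition == f"{density:g}e6/mL")
                ]
                course = dq.TimeCourse(
                    donor, f"{density:g}e6/mL",
                    grp["timepoint_h"].to_numpy(), grp["amount_pg_per_1e5_cells"].to_numpy(),
                )
                shutoffs.append(dq.shutoff_time(course))
            assert all(s1 > s2 for s1, s2 in zip(shutoffs, shutoffs[1:]))

    def test_higher_density_has_lower_final_amount(self, config):
        table = dq.generate_density_timecourse(config, seed=42)
        finals = [
            table[
                (table.donor == "D2")
                & (table.cytokine == "IL-10")
                & (table.condition == f"{d:g}e6/mL")
                & (table.timepoint_h == 24.0)
            ]["amount_pg_per_1e5_cells"].iloc[0]
            for d in config.densities_e6
        ]
        assert all(f1 > f2 for f1, f2 in zip(finals, finals[1:]))

    def test_tnfa_clearance_only_at_two_highest_densities(self, config):
        table = dq.generate_density_timecourse(config, seed=43)
        n_dens = len(config.densities_e6)
        for i, density in enumerate(config.densities_e6):
            for donor in table.donor.unique():
                grp = table[
                    (table.donor == donor)
                    & (table.cytokine == "TNFa")
                    & (table.condition == f"{density:g}e6/mL")
                ]
                course = dq.TimeCourse(
                    donor, f"{density:g}e6/mL",
                    grp["timepoint_h"].to_numpy(), grp["amount_pg_per_1e5_cells"].to_numpy(),
                    cytokine="TNFa",
                )
                flagged = dq.interval_rates(course)["clearance"].any()
                assert flagged == (i >= n_dens - config.n_decay_densities)

    def test_degenerate_config_identical_normalized_courses(self):
        # near-identical shutoffs (tau tracks shutoff) and no decay: the
        # normalized courses collapse onto one shape regardless of density
        table = dq.generate_density_timecourse(
            dq.GeneratorConfig(
                il10_shutoff_h=(24.0, 23.999, 23.998, 23.997),
                tnfa_shutoff_h=(24.0, 23.999, 23.998, 23.997),
                n_decay_densities=0,
            ),
            seed=44,
        )
        courses = []
        for density in (2.5, 5.0, 10.0, 15.0):
            grp = table[
                (table.donor == "D1")
                & (table.cytokine == "IL-10")
                & (table.condition == f"{density:g}e6/mL")
            ]
            course = dq.normalize_to_max(
                dq.TimeCourse(
                    "D1", "x",
                    grp["timepoint_h"].to_numpy(), grp["amount_pg_per_1e5_cells"].to_numpy(),
                )
            )
            courses.append(course.amounts)
        for c in courses[1:]:
            np.testing.assert_allclose(c, courses[0], rtol=1e-3)

    def test_invalid_shutoff_ordering_rejected(self):
        with pytest.raises(InvalidInputError):
            dq.GeneratorConfig(il10_shutoff_h=(2.0, 4.0, 8.0, 24.0))
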