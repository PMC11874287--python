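"""The synthetic-tissue generator: masks, point patterns, cohorts."""

import math

import numpy as np
import pandas as pd
import pytest

from spatialtme import (
    ParameterError,
    Scenario,
    build_expansion_graph,
    default_scenarios,
    generate_cells,
    generate_cohort,
    generate_mask,
    permutation_interaction_test,
)
from spatialtme.simulate import (
    generate_survival_times,
    read_cohort,
    write_cohort,
)


def uniform_scenario(intensities, **kw):
    return Scenario(name="custom", stroma_fraction=0.0, intensities=intensities, **kw)


class TestMask:
    def test_zero_fraction_uniform_parenchyma(self):
        mask = generate_mask(200, 200, 0.0, seed=0)
        assert np.all(mask.labels == 1)

    def test_one_fraction_uniform_stroma(self):
        mask = generate_mask(200, 200, 1.0, seed=0)
        assert np.all(mask.labels == 2)

    def test_target_fraction_hit(self):
        mask = generate_mask(1000, 1000, 0.3, seed=1)
        frac = float((mask.labels == 2).mean())
        assert 0.28 <= frac <= 0.32

    def test_deterministic_per_seed(self):
        m1 = generate_mask(300, 300, 0.4, seed=7)
        m2 = generate_mask(300, 300, 0.4, seed=7)
        np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_too_small_rejected(self):
        with pytest.raises(ParameterError):
            generate_mask(50, 50, 0.3)


class TestCells:
    def test_zero_intensity_zero_cells(self):
        mask = generate_mask(200, 200, 0.0, seed=0)
        scen = uniform_scenario({("CD8 T-cell", "parenchyma"): 0.0})
        table = generate_cells(mask, scen, seed=0)
        assert len(table) == 0

    def test_poisson_count_envelope(self):
        # intensity 300/mm^2 on a 1 mm^2 single-compartment mask
        mask = generate_mask(1000, 1000, 0.0, seed=0)
        scen = uniform_scenario({("CD8 T-cell", "parenchyma"): 300.0})
        table = generate_cells(mask, scen, seed=42)
        assert abs(len(table) - 300) <= 3 * math.sqrt(300)

    def test_realised_density_unbiased(self):
        # mean realised density over replicates within 2 SE of the intensity
        mask = generate_mask(400, 400, 0.0, seed=0)
        rate, area = 250.0, 0.16
        counts = [
            len(generate_cells(mask, uniform_scenario({("B cell", "parenchyma"): rate}),
                               seed=s))
            for s in range(60)
        ]
        dens = np.array(counts) / area
        se = math.sqrt(rate / area) / math.sqrt(len(counts))
        assert abs(dens.mean() - rate) <= 2 * se

    def test_cells_confined_to_their_compartment(self):
        mask = generate_mask(300, 300, 0.5, seed=3)
        scen = Scenario(
            name="c", stroma_fraction=0.5,
            intensities={("CD8 T-cell", "stroma"): 400.0},
        )
        table = generate_cells(mask, scen, seed=4)
        ij = np.floor(table.cells[["y", "x"]].to_numpy()).astype(int)
        assert np.all(mask.labels[ij[:, 0], ij[:, 1]] == 2)

    def test_intensity_cap(self):
        mask = generate_mask(1000, 1000, 0.0, seed=0)
        scen = uniform_scenario({("CD8 T-cell", "parenchyma"): 1e9})
        with pytest.raises(ParameterError, match="cap"):
            generate_cells(mask, scen, seed=0)

    def test_deterministic_per_seed(self):
        mask = generate_mask(300, 300, 0.3, seed=0)
        scen = default_scenarios()["enriched"]
        t1 = generate_cells(mask, scen, seed=5)
        t2 = generate_cells(mask, scen, seed=5)
        pd.testing.assert_frame_equal(t1.cells, t2.cells)


class TestCoClustering:
    # tumour-cell background matters: the permutation null spreads subset
    # labels over all cells, so a realistic label pool is part of the design
    _BACKGROUND = {("Tumour cell", "parenchyma"): 600.0}

    def _roi(self, planted: bool, seed: int):
        mask = generate_mask(500, 500, 0.0, seed=seed)
        if planted:
            scen = uniform_scenario(
                {**self._BACKGROUND, ("CD8 T-cell", "parenchyma"): 120.0},
                co_cluster=[("CD8 T-cell", "Macrophage", 8.0, 2.0)],
            )
        else:
            scen = uniform_scenario(
                {
                    **self._BACKGROUND,
                    ("CD8 T-cell", "parenchyma"): 120.0,
                    ("Macrophage", "parenchyma"): 240.0,
                }
            )
        return generate_cells(mask, scen, seed=seed)

    def test_planted_pairs_called_interaction(self):
        calls = []
        for seed in range(15):
            table = self._roi(True, seed)
            cells = table.cells
            g = build_expansion_graph(cells)
            rec = permutation_interaction_test(
                g, cells, [("CD8 T-cell", "Macrophage")], n_perm=200, seed=seed
            )
            calls.append(rec["call"].iloc[0] == "interaction")
        assert np.mean(calls) >= 0.9

    def test_unplanted_false_positive_rate_near_tail(self):
        calls = []
        for seed in range(40):
            table = self._roi(False, seed)
            cells = table.cells
            g = build_expansion_graph(cells)
            rec = permutation_interaction_test(
                g, cells, [("CD8 T-cell", "Macrophage")], n_perm=200, seed=seed
            )
            calls.append(rec["call"].iloc[0] == "interaction")
        # ~5% nominal; binomial 99% envelope for n=40
        assert np.mean(calls) <= 0.15

    def test_planting_raises_score_pairwise(self):
        higher = 0
        for seed in range(12):
            on = self._roi(True, seed)
            off = self._roi(False, seed + 500)
            from spatialtme import interaction_score

            s_on = interaction_score(
                build_expansion_graph(on.cells), on.cells, "CD8 T-cell", "Macrophage"
            )
            s_off = interaction_score(
                build_expansion_graph(off.cells), off.cells, "CD8 T-cell", "Macrophage"
            )
            higher += (s_on > s_off) or math.isnan(s_off)
        assert higher >= 0.9 * 12


class TestSurvival:
    def test_exponential_median_recovered(self):
        # average the empirical median over replicates (a single n=200 draw
        # has SE ~0.67 months and would fail a 15% band for 1 seed in 6)
        medians = [
            float(np.median(
                generate_survival_times(
                    200, median=6.6, censor_rate=0.0,
                    rng=np.random.default_rng(s),
                )["time"]
            ))
            for s in range(10)
        ]
        assert abs(np.mean(medians) - 6.6) / 6.6 <= 0.15

    def test_censor_rate_realised(self):
        rng = np.random.default_rng(4)
        df = generate_survival_times(2000, median=6.0, censor_rate=0.3, rng=rng)
        assert abs((~df["event"]).mean() - 0.3) < 0.05


class TestCohort:
    def test_homogeneous_cohort_truth_labels(self):
        bundle = generate_cohort(
            {"depleted": 2, "enriched": 2}, rois_per_patient=2,
            heterogeneity_rate=0.0, seed=0, roi_size_um=300,
        )
        per_patient = bundle.truth.groupby("patient_id")["scenario"].nunique()
        assert (per_patient == 1).all()
        assert len(bundle.survival) == 4
        assert len(bundle.masks) == 8

    def test_heterogeneity_rate_one_forces_mixed_rois(self):
        bundle = generate_cohort(
            {"enriched": 3}, rois_per_patient=2,
            heterogeneity_rate=1.0, seed=1, roi_size_um=300,
        )
        per_patient = bundle.truth.groupby("patient_id")["scenario"].nunique()
        assert (per_patient == 2).all()
        assert bundle.truth["heterogeneous"].all()

    def test_round_trip_through_disk(self, tmp_path):
        bundle = generate_cohort(
            {"compartmentalised": 2}, rois_per_patient=1, seed=2, roi_size_um=300
        )
        write_cohort(bundle, tmp_path)
        back = read_cohort(tmp_path)
        pd.testing.assert_frame_equal(
            back.table.cells[bundle.table.cells.columns], bundle.table.cells
        )
        assert set(back.masks) == set(bundle.masks)
        for roi_id in bundle.masks:
            np.testing.assert_array_equal(
                back.masks[roi_id].labels, bundle.masks[roi_id].labels
            )
        pd.testing.assert_frame_equal(back.survival, bundle.survival)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ParameterError, match="unknown scenario"):
            generate_cohort({"nonexistent": 1})
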