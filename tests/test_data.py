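"""Cell-table I/O, normalization, gating and truncation."""

import numpy as np
import pandas as pd
import pytest

from cytoinfo import fcs
from cytoinfo.data import (
    ChannelDataset,
    gate_extreme_expressers,
    load_cells,
    normalize_experiment,
    truncate_heterogeneity,
    write_cells,
)
from cytoinfo.exceptions import (
    DegenerateDataError,
    EmptyDataError,
    FormatError,
    ParameterError,
    SchemaError,
)
from cytoinfo.simulate import SimulationConfig, simulate_dataset, write_fixture

from conftest import make_cells


class TestLoadCells:
    def test_csv_passthrough_with_channel_map(self, tmp_path):
        p = tmp_path / "cells.csv"
        pd.DataFrame(
            {"STAT3": [1.0, 2.0, 3.0], "pSTAT3": [4.0, 5.0, 6.0], "dose": [0.0, 5.0, 25.0]}
        ).to_csv(p, index=False)
        cells = load_cells(p, channel_map={"STAT3": "expression", "pSTAT3": "response"})
        assert len(cells) == 3
        assert list(cells["dose"]) == [0.0, 5.0, 25.0]
        assert cells.attrs["n_dropped"] == 0

    def test_nan_rows_dropped_and_counted(self, tmp_path):
        p = tmp_path / "cells.csv"
        pd.DataFrame(
            {"expression": [1.0, 2.0, 3.0], "response": [4.0, np.nan, 6.0]}
        ).to_csv(p, index=False)
        cells = load_cells(p)
        assert len(cells) == 2
        assert cells.attrs["n_dropped"] == 1

    def test_missing_mapped_channel_is_schema_error(self, tmp_path):
        p = tmp_path / "cells.csv"
        pd.DataFrame({"a": [1.0], "b": [2.0]}).to_csv(p, index=False)
        with pytest.raises(SchemaError):
            load_cells(p, channel_map={"missing": "expression", "b": "response"})

    def test_all_nan_is_empty_data_error(self, tmp_path):
        p = tmp_path / "cells.csv"
        pd.DataFrame({"expression": [np.nan], "response": [1.0]}).to_csv(p, index=False)
        with pytest.raises(EmptyDataError):
            load_cells(p)

    def test_unknown_format_is_format_error(self, tmp_path):
        p = tmp_path / "cells.xyz"
        p.write_text("hello")
        with pytest.raises(FormatError):
            load_cells(p)

    def test_csv_round_trip_exact(self, tmp_path, small_synthetic):
        cells, _ = small_synthetic
        sub = cells.head(200)
        p = tmp_path / "rt.csv"
        write_cells(sub, p)
        back = load_cells(p)
        pd.testing.assert_frame_equal(
            back[list(sub.columns)].reset_index(drop=True), sub.reset_index(drop=True)
        )


class TestFCSRoundTrip:
    def test_fixture_round_trips_to_float_precision(self, tmp_path):
        cfg = SimulationConfig(n_cells=1000, n_replicates=1, doses=(25.0,), seed=3)
        cells, _ = simulate_dataset(cfg)
        p = tmp_path / "fixture.fcs"
        write_fixture(cells, p, format="fcs")
        back = load_cells(p, channel_map={"STAT3": "expression", "pSTAT3": "response"})
        assert len(back) == 1000
        np.testing.assert_allclose(
            back["expression"], cells["expression"], rtol=1e-6
        )
        np.testing.assert_allclose(back["response"], cells["response"], rtol=1e-6)
        # sidecar metadata survives
        assert back["dose"].iloc[0] == 25.0
        assert back["line"].iloc[0] == "MEF"

    def test_reader_rejects_non_fcs(self, tmp_path):
        p = tmp_path / "bogus.fcs"
        p.write_bytes(b"not an fcs file" * 10)
        with pytest.raises(FormatError):
            fcs.read_fcs(p)

    def test_writer_refuses_empty(self, tmp_path):
        with pytest.raises(EmptyDataError):
            fcs.write_fcs(tmp_path / "e.fcs", np.empty((0, 2)), ["a", "b"])


class TestNormalizeExperiment:
    def _cells_with_dose_means(self, means, replicate="r1"):
        frames = [
            make_cells(np.full(50, 10.0), np.full(50, m), dose=float(i), replicate=replicate)
            for i, m in enumerate(means, start=1)
        ]
        return pd.concat(frames, ignore_index=True)

    @pytest.mark.parametrize(
        "means, expected",
        [((50.0, 80.0, 100.0), (50.0, 80.0, 100.0)), ((40.0, 200.0), (20.0, 100.0)), ((7.0,), (100.0,))],
    )
    def test_max_mean_scaled_to_100(self, means, expected):
        out = normalize_experiment(self._cells_with_dose_means(means))
        got = out.groupby("dose")["response"].mean().to_numpy()
        np.testing.assert_allclose(np.sort(got), np.sort(expected))

    def test_replicates_normalized_independently(self):
        cells = pd.concat(
            [
                self._cells_with_dose_means((50.0, 100.0), replicate="r1"),
                self._cells_with_dose_means((10.0, 40.0), replicate="r2"),
            ],
            ignore_index=True,
        )
        out = normalize_experiment(cells)
        for rep in ("r1", "r2"):
            top = out[out["replicate"] == rep].groupby("dose")["response"].mean().max()
            assert top == pytest.approx(100.0)

    def test_idempotent(self, small_synthetic):
        cells, _ = small_synthetic
        once = normalize_experiment(cells)
        twice = normalize_experiment(once)
        np.testing.assert_allclose(twice["response"], once["response"], rtol=1e-12)
        np.testing.assert_allclose(twice["expression"], once["expression"], rtol=1e-12)

    def test_raw_values_retained(self, small_synthetic):
        cells, _ = small_synthetic
        out = normalize_experiment(cells)
        np.testing.assert_allclose(out["response_raw"], cells["response"])

    def test_all_zero_response_is_degenerate(self):
        cells = make_cells([1.0] * 50, [0.0] * 50)
        with pytest.raises(DegenerateDataError):
            normalize_experiment(cells)


class TestGateExtremeExpressers:
    def test_ten_percent_of_10000(self):
        cells = make_cells(np.arange(1.0, 10001.0), np.ones(10000))
        res = gate_extreme_expressers(cells, 0.10)
        assert len(res.low_subset) == 1000
        assert len(res.high_subset) == 1000

    def test_half_fraction_partitions_everything(self):
        cells = make_cells(np.arange(1.0, 11.0), np.ones(10))
        res = gate_extreme_expressers(cells, 0.5)
        assert len(res.low_subset) + len(res.high_subset) == 10
        combined = set(res.low_subset["expression"]) | set(res.high_subset["expression"])
        assert combined == set(cells["expression"])

    def test_five_percent_of_1_to_100(self):
        cells = make_cells(np.arange(1.0, 101.0), np.ones(100))
        res = gate_extreme_expressers(cells, 0.05)
        assert sorted(res.low_subset["expression"]) == [1.0, 2.0, 3.0, 4.0, 5.0]
        assert sorted(res.high_subset["expression"]) == [96.0, 97.0, 98.0, 99.0, 100.0]

    def test_supports_do_not_overlap(self, small_synthetic):
        cells, _ = small_synthetic
        res = gate_extreme_expressers(cells, 0.10)
        assert res.low_subset["expression"].max() <= res.high_subset["expression"].min()
        # disjoint row sets by construction
        assert len(res.low_subset) + len(res.high_subset) == 2 * round(0.10 * len(cells))

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 0.6, 1.0])
    def test_fraction_out_of_range(self, fraction):
        cells = make_cells(np.arange(1.0, 101.0), np.ones(100))
        with pytest.raises(ParameterError):
            gate_extreme_expressers(cells, fraction)


class TestTruncateHeterogeneity:
    def test_counts_match_quantile_definition(self, rng):
        cells = make_cells(rng.lognormal(0, 0.5, 10000), np.ones(10000))
        assert len(truncate_heterogeneity(cells, 0.90)) == 9000
        assert len(truncate_heterogeneity(cells, 0.15)) == 1500

    def test_identity_at_residual_one(self, small_synthetic):
        cells, _ = small_synthetic
        out = truncate_heterogeneity(cells, 1.0)
        pd.testing.assert_frame_equal(out, cells)

    def test_preserves_relative_order(self, rng):
        expr = rng.lognormal(0, 0.5, 1000)
        cells = make_cells(expr, np.arange(1000.0))
        out = truncate_heterogeneity(cells, 0.5)
        # retained rows keep their original relative order (stable subset)
        assert (np.diff(out["response"].to_numpy()) > 0).all()

    def test_cv_decreases_monotonically(self, rng):
        expr = rng.lognormal(0, 0.5, 20000)
        cells = make_cells(expr, np.ones(20000))
        cvs = []
        for residual in (1.0, 0.9, 0.7, 0.5, 0.3, 0.15):
            sub = truncate_heterogeneity(cells, residual)
            e = sub["expression"]
            cvs.append(e.std() / e.mean())
        assert all(a > b for a, b in zip(cvs, cvs[1:]))

    def test_mean_window_variant(self):
        cells = make_cells(np.linspace(50.0, 150.0, 1001), np.ones(1001))
        out = truncate_heterogeneity(cells, 0.15, method="mean_window")
        mu = cells["expression"].mean()
        assert out["expression"].between(mu * 0.925, mu * 1.075).all()

    def test_residual_out_of_range(self):
        cells = make_cells(np.arange(1.0, 101.0), np.ones(100))
        with pytest.raises(ParameterError):
            truncate_heterogeneity(cells, 0.0)
        with pytest.raises(ParameterError):
            truncate_heterogeneity(cells, 1.5)


class TestChannelDataset:
    def test_levels_partition_cells(self, small_synthetic):
        cells, _ = small_synthetic
        ds = ChannelDataset.from_cells(cells, replicate="r1")
        assert ds.counts.sum() == len(ds.cells)
        assert len(ds.input_levels) == 12

    def test_single_level_rejected_for_capacity(self):
        cells = make_cells(np.arange(1.0, 101.0), np.ones(100), dose=5.0)
        ds = ChannelDataset.from_cells(cells)
        with pytest.raises(ParameterError):
            ds.require_channel()
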