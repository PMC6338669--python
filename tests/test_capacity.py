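"""Channel-capacity estimators against closed forms and each other."""

import numpy as np
import pytest

from cytoinfo.capacity import (
    DiscreteChannel,
    DiscreteChannelCapacity,
    LogisticCapacity,
    blahut_arimoto,
    build_discrete_channel,
    capacity_basic,
    capacity_var,
    estimate_cc_classifier,
    truncation_capacity_sweep,
)
from cytoinfo.data import ChannelDataset
from cytoinfo.exceptions import ParameterError
from cytoinfo.simulate import SimulationConfig, make_reference_channel, simulate_dataset

from conftest import make_cells


def binary_entropy(p):
    return -p * np.log2(p) - (1 - p) * np.log2(1 - p)


class TestBlahutArimoto:
    @pytest.mark.parametrize("p", [0.05, 0.11, 0.2, 0.5])
    def test_bsc_closed_form(self, p):
        channel = make_reference_channel("bsc", {"p": p})
        res = blahut_arimoto(channel)
        expected = 1.0 - binary_entropy(p) if p not in (0.0, 1.0) else 1.0
        assert res.cc_bits == pytest.approx(expected, abs=1e-6)
        np.testing.assert_allclose(res.optimal_input, [0.5, 0.5], atol=1e-6)

    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_identity_channel(self, k):
        res = blahut_arimoto(make_reference_channel("identity", {"k": k}))
        assert res.cc_bits == pytest.approx(np.log2(k), abs=1e-9)
        assert res.distinguishable_states == pytest.approx(k, rel=1e-6)

    def test_erasure_channel_closed_form(self):
        # binary erasure channel capacity = 1 - p
        res = blahut_arimoto(make_reference_channel("erasure", {"p": 0.3}))
        assert res.cc_bits == pytest.approx(0.7, abs=1e-6)

    def test_identical_rows_zero_capacity(self):
        res = blahut_arimoto(np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert res.cc_bits == 0.0

    def test_capacity_bounded_by_log_inputs(self, rng):
        t = rng.dirichlet(np.ones(6), size=4)
        res = blahut_arimoto(t)
        assert 0.0 <= res.cc_bits <= np.log2(4) + 1e-12
        assert res.optimal_input.sum() == pytest.approx(1.0, abs=1e-9)
        assert (res.optimal_input >= 0).all()

    def test_invariance_under_permutation(self, rng):
        t = rng.dirichlet(np.ones(8), size=5)
        base = blahut_arimoto(t).cc_bits
        perm_out = blahut_arimoto(t[:, rng.permutation(8)]).cc_bits
        perm_in = blahut_arimoto(t[rng.permutation(5), :]).cc_bits
        assert base == pytest.approx(perm_out, abs=1e-9)
        assert base == pytest.approx(perm_in, abs=1e-9)

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ParameterError):
            blahut_arimoto(np.array([[0.5, 0.4], [0.5, 0.5]]))


class TestBuildDiscreteChannel:
    def test_separable_doses_give_near_identity(self):
        import pandas as pd

        cells = pd.concat(
            [
                make_cells(np.ones(500), np.linspace(0, 1, 500), dose=0.0),
                make_cells(np.ones(500), np.linspace(10, 11, 500), dose=50.0),
            ],
            ignore_index=True,
        )
        ds = ChannelDataset.from_cells(cells)
        ch = build_discrete_channel(ds, bins=2)
        assert ch.transition[0, 0] > 0.99
        assert ch.transition[1, 1] > 0.99

    def test_identical_distributions_give_equal_rows(self, rng):
        import pandas as pd

        draws = rng.normal(100.0, 10.0, 2000)
        cells = pd.concat(
            [
                make_cells(np.ones(1000), draws[:1000], dose=1.0),
                make_cells(np.ones(1000), draws[1000:], dose=10.0),
            ],
            ignore_index=True,
        )
        ch = build_discrete_channel(ChannelDataset.from_cells(cells), bins=10)
        np.testing.assert_allclose(ch.transition[0], ch.transition[1], atol=0.12)

    def test_12_dose_channel_shape(self, small_synthetic):
        cells, _ = small_synthetic
        ds = ChannelDataset.from_cells(cells, replicate="r1")
        ch = build_discrete_channel(ds, bins=20)
        assert ch.transition.shape == (12, 20)
        np.testing.assert_allclose(ch.transition.sum(axis=1), 1.0, atol=1e-12)


class TestLogisticCapacity:
    def test_well_separated_binary_channel(self, rng):
        X = np.concatenate([rng.normal(-5, 1, 2000), rng.normal(5, 1, 2000)])[:, None]
        y = np.repeat([0, 1], 2000)
        est = LogisticCapacity().fit(X, y)
        assert est.capacity_bits_ == pytest.approx(1.0, abs=0.02)
        assert est.converged_

    def test_common_distribution_zero_capacity(self, rng):
        X = rng.normal(0, 1, 4000)[:, None]
        y = np.repeat([0, 1], 2000)
        est = LogisticCapacity().fit(X, y)
        assert est.capacity_bits_ <= 0.05

    def test_single_level_rejected(self, rng):
        with pytest.raises(ParameterError):
            LogisticCapacity().fit(rng.normal(size=100)[:, None], np.zeros(100))

    def test_bootstrap_spread_available(self, rng):
        X = np.concatenate([rng.normal(-2, 1, 500), rng.normal(2, 1, 500)])[:, None]
        y = np.repeat([0, 1], 500)
        est = LogisticCapacity(n_boot=8).fit(X, y)
        assert np.isfinite(est.bootstrap_sd_)
        assert est.bootstrap_sd_ < 0.2

    def test_agrees_with_discretized_ba(self, rng):
        # 1-D synthetic channel: overlapping Gaussian responses per level
        means = [0.0, 1.0, 2.0, 4.0]
        X = np.concatenate([rng.normal(m, 1.0, 2500) for m in means])[:, None]
        y = np.repeat(np.arange(4), 2500)
        clf = LogisticCapacity().fit(X, y).capacity_bits_
        ba = DiscreteChannelCapacity(bins=20).fit(X, y).capacity_bits_
        assert clf == pytest.approx(ba, abs=0.1)


class TestCapacityOnCells:
    def test_noiseless_deterministic_channel_hits_log2_k(self):
        import pandas as pd

        frames = [
            make_cells(np.ones(300), np.full(300, float(i + 1)), dose=float(i + 1))
            for i in range(12)
        ]
        ds = ChannelDataset.from_cells(pd.concat(frames, ignore_index=True))
        res = capacity_basic(ds, estimator="ba", bins=24, alpha=1e-6)
        assert res.cc_bits == pytest.approx(np.log2(12), abs=0.05)

    def test_classifier_wrapper_matches_estimator(self, small_synthetic):
        cells, _ = small_synthetic
        ds = ChannelDataset.from_cells(cells, replicate="r1")
        est = estimate_cc_classifier(ds, seed=0)
        assert est.estimator == "classifier"
        assert est.cc_bits == pytest.approx(capacity_basic(ds).cc_bits, abs=1e-9)
        assert est.optimal_input.sum() == pytest.approx(1.0, abs=1e-9)

    def test_var_at_least_basic(self, small_synthetic):
        cells, _ = small_synthetic
        ds = ChannelDataset.from_cells(cells, replicate="r1")
        cb = capacity_basic(ds)
        cv = capacity_var(ds)
        assert cv.cc_bits >= cb.cc_bits - 0.02

    def test_uninformative_covariate_changes_nothing(self, rng):
        import pandas as pd

        # expression independent of response at every dose
        frames = [
            make_cells(
                rng.lognormal(4, 0.5, 1500),
                rng.normal(20.0 * (i + 1), 10.0, 1500).clip(0),
                dose=float(i + 1),
            )
            for i in range(4)
        ]
        ds = ChannelDataset.from_cells(pd.concat(frames, ignore_index=True))
        cb = capacity_basic(ds)
        cv = capacity_var(ds)
        assert cv.cc_bits - cb.cc_bits <= 0.05

    def test_more_noise_never_helps(self):
        caps = []
        for sigma_b in (10.0, 80.0):
            cells, _ = simulate_dataset(
                SimulationConfig(n_cells=800, n_replicates=1, sigma_b=sigma_b, seed=11)
            )
            ds = ChannelDataset.from_cells(cells)
            caps.append(capacity_basic(ds).cc_bits)
        assert caps[1] <= caps[0] + 0.05

    def test_sweep_identity_row(self, small_synthetic):
        cells, _ = small_synthetic
        one = cells[cells["replicate"] == "r1"]
        sw = truncation_capacity_sweep(one, (1.0,), per_replicate=False)
        assert len(sw) == 1
        ds = ChannelDataset.from_cells(one)
        direct = capacity_basic(ds)
        assert sw["capacity_basic"].iloc[0] == pytest.approx(direct.cc_bits, abs=1e-9)

    def test_sweep_skips_undersized_strata(self):
        cells, _ = simulate_dataset(
            SimulationConfig(n_cells=120, n_replicates=1, seed=5)
        )
        with pytest.warns(UserWarning, match="skipped"):
            sw = truncation_capacity_sweep(cells, (0.15,), min_cells_per_level=50)
        assert sw["skipped"].all()


class TestDiscreteChannelValidation:
    def test_reference_channels_are_valid(self):
        for kind, params in (("bsc", {"p": 0.11}), ("identity", {"k": 4}), ("erasure", {"p": 0.1})):
            ch = make_reference_channel(kind, params)
            assert isinstance(ch, DiscreteChannel)
            np.testing.assert_allclose(ch.transition.sum(axis=1), 1.0, atol=1e-12)

    def test_gaussian_pair_correlation(self):
        x, y = make_reference_channel("gaussian_pair", {"rho": 0.9}, n=5000, seed=42)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.9, abs=0.02)
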