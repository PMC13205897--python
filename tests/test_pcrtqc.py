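"""Pre-classified monitor: mining, mapping, clustering, grouping, filtering."""

import numpy as np
import pandas as pd
import pytest

from pbrtqc import biasinject, bench, pcrtqc, presets


def _tiny_panel(support_b=1.0, support_c=1.0, support_d=0.0, n=40):
    frame = pd.DataFrame(
        {
            "barcode": [f"x{i}" for i in range(n)],
            "value": np.linspace(1, 2, n),
            "B": np.linspace(1, 2, n),
            "C": np.linspace(1, 2, n),
            "D": np.linspace(1, 2, n),
        }
    )
    for col, sup in (("B", support_b), ("C", support_c), ("D", support_d)):
        k = int(n * (1 - sup))
        if k:
            frame.loc[frame.index[:k], col] = np.nan
    return frame


class TestCompanionMining:
    def test_recovers_co_ordered_companions(self, cea_panel):
        comps = pcrtqc.mine_companions(cea_panel.frame, "CEA")
        assert set(comps) == set(presets.load_companions()["CEA"])

    def test_equal_support_ties_break_lexicographically(self):
        comps = pcrtqc.mine_companions(_tiny_panel(1.0, 1.0, 1.0), "A")
        assert comps == ["B", "C"]

    def test_never_co_ordered_analyte_excluded(self):
        frame = _tiny_panel(1.0, 0.5, 0.0)
        comps = pcrtqc.mine_companions(frame, "A")
        assert "D" not in comps and comps == ["B", "C"]

    def test_too_few_candidates_rejected(self):
        frame = _tiny_panel(1.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="fewer than 2"):
            pcrtqc.mine_companions(frame, "A")


@pytest.fixture(scope="module")
def mapping():
    rng = np.random.default_rng(5)
    frame = pd.DataFrame(
        {
            "barcode": [f"m{i}" for i in range(2000)],
            "T": rng.lognormal(0.5, 0.6, 2000),
            "B": rng.lognormal(1.0, 0.4, 2000),
            "C": rng.lognormal(2.0, 0.5, 2000),
        }
    )
    return frame, pcrtqc.fit_mapping(frame, ["T", "B", "C"])


class TestMapping:
    def test_median_value_maps_to_negative_ln_median_over_iqr(self, mapping):
        frame, m = mapping
        row = pd.DataFrame(
            {"T": [m.medians[0]], "B": [m.medians[1]], "C": [m.medians[2]]}
        )
        coords = m.transform(row)[0]
        expect = [-lm / iq for lm, iq in zip(m.ln_medians, m.ln_iqrs)]
        assert coords == pytest.approx(expect)
        # ln-median of MOM values is ~0, so coords sit near the origin
        assert np.all(np.abs(coords) < 0.05)

    def test_doubling_shifts_coordinate_by_ln2_over_iqr(self, mapping):
        frame, m = mapping
        row = frame.head(1)
        base = m.transform(row)[0]
        doubled = row.copy()
        doubled["T"] = doubled["T"] * 2
        shifted = m.transform(doubled)[0]
        assert shifted[0] - base[0] == pytest.approx(np.log(2) / m.ln_iqrs[0])
        assert shifted[1:] == pytest.approx(base[1:])

    def test_non_positive_values_rejected(self, mapping):
        _, m = mapping
        row = pd.DataFrame({"T": [-1.0], "B": [1.0], "C": [1.0]})
        with pytest.raises(ValueError, match="non-positive"):
            m.transform(row)


class TestClustering:
    def test_two_blobs_recovered(self, rng):
        a = rng.normal(0.0, 0.5, size=(1500, 3))
        b = rng.normal(4.0, 0.5, size=(1500, 3))
        coords = np.vstack([a, b])
        truth = np.repeat([0, 1], 1500)
        labels = pcrtqc.cluster_optics(coords, seed=0)
        assert labels.max() == 1
        agree = max(np.mean(labels == truth), np.mean(labels == 1 - truth))
        assert agree >= 0.95

    def test_uniform_cloud_collapses_to_one_group(self, rng):
        coords = rng.uniform(0, 1, size=(2000, 3))
        labels = pcrtqc.cluster_optics(coords, seed=0)
        assert set(labels) == {0}

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError, match="need >="):
            pcrtqc.cluster_optics(rng.normal(size=(30, 3)), min_samples=50)

    def test_every_point_labeled(self, rng):
        a = rng.normal(0.0, 0.7, size=(1000, 3))
        b = rng.normal(4.0, 0.7, size=(1000, 3))
        labels = pcrtqc.cluster_optics(np.vstack([a, b]), seed=0)
        assert len(labels) == 2000 and np.all(labels >= 0)


class TestGroupClassifier:
    def test_separable_blobs_pass_accuracy_gate(self, rng):
        a = rng.normal(0.0, 0.5, size=(800, 3))
        b = rng.normal(4.0, 0.5, size=(800, 3))
        coords = np.vstack([a, b])
        labels = np.repeat([0, 1], 800)
        clf, acc = pcrtqc.train_group_classifier(coords, labels, seed=0)
        assert acc >= 0.90

    def test_single_group_trivial_classifier(self, rng):
        coords = rng.normal(size=(100, 3))
        clf, acc = pcrtqc.train_group_classifier(coords, np.zeros(100, dtype=int))
        assert acc == 1.0
        assert np.all(clf.predict(coords) == 0)

    def test_permuted_labels_fail_gate(self, rng):
        coords = rng.normal(size=(1000, 3))
        labels = rng.integers(0, 2, 1000)  # labels carry no structure
        with pytest.raises(pcrtqc.ClassifierGateError, match="accuracy"):
            pcrtqc.train_group_classifier(coords, labels, seed=0)


class TestBayesFallback:
    def test_likelihood_dominates_with_equal_priors(self):
        gid = pcrtqc.bayes_assign(
            9.0, np.array([0.5, 0.5]), np.array([0.0, 10.0]), np.array([1.0, 1.0])
        )
        assert gid == 1

    def test_exact_tie_goes_to_lower_group(self):
        gid = pcrtqc.bayes_assign(
            5.0, np.array([0.5, 0.5]), np.array([0.0, 10.0]), np.array([1.0, 1.0])
        )
        assert gid == 0

    def test_strong_prior_overrides_likelihood(self):
        # x at the minority mean but within 2 SD of the majority: the
        # posterior ratio is prior-driven; verify against the closed form
        priors = np.array([0.99, 0.01])
        mus = np.array([0.0, 1.5])
        sds = np.array([1.0, 1.0])
        x = 1.5
        post = np.log(priors) - 0.5 * (x - mus) ** 2
        assert pcrtqc.bayes_assign(x, priors, mus, sds) == int(np.argmax(post)) == 0


class TestFilterChain:
    def _constant_gp(self):
        return pcrtqc.GroupParams(
            group_id=0, boxcox_lambda=1.0, shift=0.0, zmean=5.0, zsd=1.0,
            wavelet_threshold=0.0, lower=-1, upper=1, prior=1.0,
            density_mu=0.0, density_sd=1.0, clamp_lo=0.0, clamp_hi=100.0,
        )

    def test_constant_series_passes_through_to_constant(self):
        out = pcrtqc.group_filter_chain(np.full(300, 5.0), self._constant_gp())
        # Box-Cox(lambda=1) maps 5 -> 4; z-score vs mean 5 gives -1
        assert np.allclose(out, out[0])

    def test_white_noise_variance_reduced(self, rng):
        x = rng.lognormal(1.0, 0.4, 4000)
        denoised, _ = pcrtqc._wavelet_denoise(x)
        assert denoised.var() < x.var()

    def test_step_change_tracked_within_filter_window(self, rng):
        gp = self._constant_gp()
        x = np.full(2000, 5.0) + rng.normal(0, 0.01, 2000)
        x[1000:] += 2.0
        out = pcrtqc.group_filter_chain(x, gp)
        half = 0.5 * (out[:900].mean() + out[1100:].mean())
        crossing = 1000 + np.argmax(out[1000:] > half)
        assert crossing - 1000 <= pcrtqc.MEAN_FILTER_WINDOW


@pytest.fixture(scope="module")
def pcr_model(cea_panel_splits):
    tr, va, _ = cea_panel_splits
    return pcrtqc.fit_pcrtqc(tr, va, seed=0)


class TestEndToEnd:
    def test_far_controlled_on_error_free_stream(self, cea_panel_splits, pcr_model):
        _, _, te = cea_panel_splits
        bias = biasinject.BiasSpec("PE", 0)
        reps = biasinject.sample_replicates(
            te, bias, n_reps=5, window=2000, seed=5, margin=400
        )
        fars = [bench.far(pcrtqc.run_pcrtqc(f, pcr_model)) for f, _ in reps]
        assert np.mean(fars) <= 0.002

    def test_gross_positive_shift_alarms_every_replicate(self, cea_panel_splits, pcr_model):
        _, _, te = cea_panel_splits
        bias = biasinject.BiasSpec("PE", 2)
        reps = biasinject.sample_replicates(
            te, bias, n_reps=5, window=2000, seed=5, margin=400
        )
        for frame, record in reps:
            cs = pcrtqc.run_pcrtqc(frame, pcr_model)
            assert bench.nped(cs, record.bias_start_index) is not bench.NOT_DETECTED

    def test_every_sample_routed_exactly_once(self, cea_panel_splits, pcr_model):
        _, _, te = cea_panel_splits
        routes = pcrtqc._route(te.frame.head(1000), pcr_model)
        assert routes.shape == (1000,)
        assert set(np.unique(routes)) <= set(pcr_model.groups)

    def test_single_group_model_matches_unpartitioned_chain(self, cea_panel_splits):
        """Degenerate one-group model: alarms equal running the filter
        chain on the whole stream with that group's parameters."""
        tr, _, te = cea_panel_splits
        vals = tr.frame["value"].to_numpy(float)
        gp = pcrtqc._fit_group_params(
            0, vals, prior=1.0, fb_mu=0.0, fb_sd=1.0,
            clamp=(tr.spec.range_lo, tr.spec.range_hi),
        )
        model = pcrtqc.PCRTQCModel(
            target="CEA",
            companions=("AFP", "CA19-9"),
            mapping=pcrtqc.fit_mapping(
                tr.frame.rename(columns={"value": "CEA"}).dropna(
                    subset=["AFP", "CA19-9"]
                ),
                ["CEA", "AFP", "CA19-9"],
            ),
            classifier=pcrtqc._ConstantClassifier(0),
            classifier_accuracy=1.0,
            groups={0: gp},
            fallback_lambda=0.0,
            fallback_shift=0.0,
        )
        window = te.frame.head(1500)
        cs = pcrtqc.run_pcrtqc(window, model)
        direct = pcrtqc.group_filter_chain(
            window["value"].to_numpy(float), gp, prepend=gp.training_tail
        )
        assert np.array_equal(cs.statistic, direct)
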