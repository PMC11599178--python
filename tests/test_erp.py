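"""Preprocessing, window amplitudes, RM-ANOVA and FDR correlations."""

import numpy as np
import pandas as pd
import pytest

from normnet import erp, montage, synth
from normnet.errors import ParameterError, NormnetError
from oracles import bh_stepup_oracle


def _toy_epochs(data, srate=500.0, channels=None, conditions=None,
                epoch_start=-200.0):
    data = np.asarray(data, dtype=float)
    n_tr, n_ch, _ = data.shape
    if channels is None:
        channels = tuple(f"C{i}" for i in range(n_ch))
    if conditions is None:
        conditions = np.resize(np.array(["peer_feedback", "non_feedback"],
                                        dtype=object), n_tr)
    return montage.EpochSet(amplitudes=data, srate=srate,
                            epoch_start_ms=epoch_start,
                            conditions=conditions, channels=channels,
                            subject_id="t")


class TestPreprocess:
    def test_50hz_attenuated_10hz_preserved(self):
        srate, n = 500.0, 1001
        t = np.arange(n) / srate
        sig50 = np.sin(2 * np.pi * 50 * t)
        sig10 = np.sin(2 * np.pi * 10 * t)
        # antiphase channel pairs keep the average reference at zero so
        # only the filter acts
        data = np.stack([sig50, -sig50, sig10, -sig10])[None].repeat(2, 0)
        out = np.asarray(erp.preprocess(_toy_epochs(data)).amplitudes)
        mid = slice(200, 800)   # avoid filter edges
        assert out[0, 0, mid].std() < 0.1 * sig50[mid].std()
        assert out[0, 2, mid].std() > 0.85 * sig10[mid].std()

    def test_average_reference_identity(self, small_epochs, layout):
        out = erp.preprocess(small_epochs, layout)
        idx = layout.retained_indices()
        means = np.asarray(out.amplitudes)[:, idx, :].mean(axis=1)
        assert np.abs(means).max() < 1e-9
        # idempotence
        again = np.asarray(out.amplitudes) - \
            np.asarray(out.amplitudes)[:, idx, :].mean(1, keepdims=True)
        assert np.allclose(again, out.amplitudes)

    def test_dc_offset_removed(self):
        ep = _toy_epochs(np.full((2, 2, 1001), 10.0))
        out = np.asarray(erp.preprocess(ep).amplitudes)
        assert np.abs(out[:, :, 300:700]).max() < 0.5

    def test_band_above_nyquist_rejected(self, small_epochs):
        with pytest.raises(ParameterError):
            erp.preprocess(small_epochs, h_freq=200.0)


class TestBaseline:
    def test_constant_trace_zeroed(self):
        ep = _toy_epochs(np.full((2, 2, 601), 5.0))
        out = erp.baseline_correct(ep)
        assert np.allclose(out.amplitudes, 0.0)

    def test_baseline_window_mean_is_zero(self, small_epochs):
        out = erp.baseline_correct(small_epochs)
        idx = out.window_slice(-200.0, 0.0)
        means = np.asarray(out.amplitudes)[:, :, idx].mean(axis=-1)
        assert np.abs(means).max() < 1e-6

    def test_per_trial_independence(self):
        data = np.zeros((2, 1, 601))
        data[0] += 3.0
        data[1] += -7.0
        out = erp.baseline_correct(_toy_epochs(data))
        assert np.allclose(out.amplitudes, 0.0)


class TestArtifactRejection:
    def test_threshold_boundary(self):
        data = np.zeros((2, 2, 601))
        data[0, 0, 100] = 80.0
        data[1, 1, 50] = 74.9
        clean, rejected = erp.reject_artifacts(_toy_epochs(data))
        assert rejected == [0]
        assert clean.n_trials == 1

    def test_recovers_injected_contamination(self, layout):
        spec = synth.EffectSpec(noise_rms=5.0)
        sess = synth.generate_session(40, seed=61, subject="x")
        ep = synth.generate_eeg(sess, layout, spec, srate=250.0, seed=62)
        dirty, truth = synth.inject_artifacts(ep, fraction=0.1,
                                              amplitude=100.0, seed=63,
                                              layout=layout)
        _, rejected = erp.reject_artifacts(dirty, layout=layout)
        assert rejected == truth

    def test_all_rejected_is_error(self):
        data = np.full((3, 1, 601), 100.0)
        with pytest.raises(NormnetError):
            erp.reject_artifacts(_toy_epochs(data))


class TestWindowRegionMeans:
    def test_linearity_under_scaling(self, small_epochs, layout):
        from dataclasses import replace
        t1 = erp.window_region_means(small_epochs, layout)
        doubled = replace(small_epochs,
                          amplitudes=np.asarray(small_epochs.amplitudes) * 2)
        t2 = erp.window_region_means(doubled, layout)
        assert np.allclose(t2["amplitude"], 2 * t1["amplitude"])

    def test_single_trial_equals_trial_means(self, layout):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((2, 64, 301))
        ep = montage.EpochSet(
            amplitudes=data, srate=250.0, epoch_start_ms=-200.0,
            conditions=np.array(["peer_feedback", "non_feedback"],
                                dtype=object),
            channels=montage.default_layout().names, subject_id="x")
        tab = erp.window_region_means(ep, layout)
        row = tab[(tab.condition == "peer_feedback") &
                  (tab.region == "medial central") & (tab.component == "P3")]
        idx = ep.window_slice(300.0, 500.0)
        chans = [list(ep.channels).index(c)
                 for c in layout.regions["medial central"]]
        expected = data[0][np.ix_(chans, idx)].mean()
        assert row["amplitude"].iloc[0] == pytest.approx(expected)


def _make_cell_table(rng, n=12, effects=None, noise=0.5):
    """Synthesize a subject × condition × region table with known effects."""
    effects = effects or {}
    rows = []
    for s in range(n):
        subj_offset = rng.normal(0, 1)
        for cond in ("peer_feedback", "non_feedback"):
            for hemi in ("left", "medial", "right"):
                for lobe in ("frontal", "central", "parietal"):
                    mu = subj_offset
                    if cond == "peer_feedback":
                        mu += effects.get("S", 0.0)
                        mu += effects.get(("S", lobe), 0.0)
                        mu += effects.get(("S", hemi), 0.0)
                    rows.append({
                        "subject": f"s{s:02d}", "condition": cond,
                        "region": f"{hemi} {lobe}", "component": "N2",
                        "amplitude": mu + rng.normal(0, noise)})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_two_level_factor_forces_epsilon_one(self, rng):
        tab = _make_cell_table(rng)
        res = erp.rm_anova(tab, "N2")
        assert res.loc["S", "eps"] == 1.0
        assert res.loc["S", "p_gg"] == pytest.approx(res.loc["S", "p_unc"])

    def test_matches_statsmodels_anovarm(self, rng):
        from statsmodels.stats.anova import AnovaRM
        tab = _make_cell_table(rng, effects={"S": 0.4, ("S", "parietal"): 0.5})
        sub = tab.copy()
        sub[["hemisphere", "lobe"]] = [r.split() for r in sub["region"]]
        aov = AnovaRM(sub, depvar="amplitude", subject="subject",
                      within=["condition", "hemisphere", "lobe"],
                      aggregate_func="mean").fit()
        res = erp.rm_anova(tab, "N2")
        sm = aov.anova_table
        assert res.loc["S", "F"] == pytest.approx(
            sm.loc["condition", "F Value"], rel=1e-6)
        assert res.loc["S x H", "F"] == pytest.approx(
            sm.loc["condition:hemisphere", "F Value"], rel=1e-6)
        assert res.loc["S x R", "F"] == pytest.approx(
            sm.loc["condition:lobe", "F Value"], rel=1e-6)
        assert res.loc["S x R x H", "F"] == pytest.approx(
            sm.loc["condition:hemisphere:lobe", "F Value"], rel=1e-6)

    def test_epsilon_matches_pingouin(self, rng):
        import pingouin as pg
        tab = _make_cell_table(rng, effects={("S", "parietal"): 0.8})
        sub = tab.copy()
        sub[["hemisphere", "lobe"]] = [r.split() for r in sub["region"]]
        # S x R effect: epsilon of the interaction contrast covariance
        piv = sub.pivot_table(index="subject",
                              columns=["condition", "lobe"],
                              values="amplitude")
        eps_pg = pg.epsilon(piv, correction="gg")
        res = erp.rm_anova(tab, "N2")
        # pingouin's epsilon on the 2x3 (condition, lobe) table corresponds
        # to the S x R contrast space here
        assert res.loc["S x R", "eps"] == pytest.approx(eps_pg, abs=0.05)

    def test_interaction_detected_where_injected(self, rng):
        hits_sr, hits_sh = 0, 0
        reps = 30
        for _ in range(reps):
            tab = _make_cell_table(rng, n=14,
                                   effects={("S", "parietal"): 0.8},
                                   noise=0.5)
            res = erp.rm_anova(tab, "N2")
            hits_sr += res.loc["S x R", "p_gg"] < 0.05
            hits_sh += res.loc["S x H", "p_gg"] < 0.05
        assert hits_sr / reps >= 0.9       # injected interaction found
        assert hits_sh / reps <= 0.2       # absent interaction mostly quiet

    def test_type_one_error_calibrated(self, rng):
        hits = 0
        reps = 60
        for _ in range(reps):
            tab = _make_cell_table(rng, n=10, noise=1.0)
            res = erp.rm_anova(tab, "N2")
            hits += res.loc["S", "p_gg"] < 0.05
        assert hits / reps <= 0.12

    def test_incomplete_design_rejected(self, rng):
        tab = _make_cell_table(rng)
        with pytest.raises(ParameterError):
            erp.rm_anova(tab.iloc[:-5], "N2")


class TestSimpleEffects:
    def test_reports_lobe_level_feedback_effect(self, rng):
        tab = _make_cell_table(rng, n=16, effects={("S", "parietal"): 1.0},
                               noise=0.3)
        res = erp.simple_effects(tab, "N2")
        assert res.loc["parietal", "p"] < 0.01
        assert res.loc["parietal", "F"] > res.loc["frontal", "F"]


class TestFDR:
    def test_worked_example_all_adjust_to_004(self):
        adj = erp.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            m = int(rng.integers(1, 30))
            p = rng.random(m)
            assert np.allclose(erp.bh_adjust(p), bh_stepup_oracle(p))


class TestCentralityCorrelations:
    def _diffs(self, rng, n=20):
        rows = []
        for s in range(n):
            for region in ("left frontal", "medial frontal"):
                for comp in ("N2", "LPP"):
                    rows.append({"subject": f"s{s:02d}", "region": region,
                                 "component": comp,
                                 "diff": rng.normal(0, 1)})
        return pd.DataFrame(rows)

    def test_recovers_linked_metric(self, rng):
        n = 24
        cent = pd.DataFrame({"betweenness": rng.normal(10, 3, n)},
                            index=[f"s{s:02d}" for s in range(n)])
        diffs = self._diffs(rng, n)
        link = diffs["subject"].map(cent["betweenness"])
        diffs.loc[(diffs.region == "left frontal") &
                  (diffs.component == "LPP"), "diff"] += \
            0.5 * link[(diffs.region == "left frontal") &
                       (diffs.component == "LPP")]
        out = erp.centrality_correlations(diffs, cent)
        row = out[(out.component == "LPP") & (out.region == "left frontal")]
        assert row["r"].iloc[0] > 0.5

    def test_zero_variance_flagged_and_excluded(self, rng):
        cent = pd.DataFrame({"in_degree": np.full(10, 3.0)},
                            index=[f"s{s:02d}" for s in range(10)])
        out = erp.centrality_correlations(self._diffs(rng, 10), cent)
        assert out["undefined"].all()
        assert out["p_fdr"].isna().all()

    def test_family_definitions(self, rng):
        cent = pd.DataFrame({"a": rng.normal(size=12),
                             "b": rng.normal(size=12)},
                            index=[f"s{s:02d}" for s in range(12)])
        diffs = self._diffs(rng, 12)
        by_comp = erp.centrality_correlations(diffs, cent,
                                              family="component")
        by_metric = erp.centrality_correlations(diffs, cent, family="metric")
        # same raw p, possibly different adjusted p
        assert np.allclose(by_comp["p"], by_metric["p"])
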