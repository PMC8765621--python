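import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.anova import AnovaRM

import facefreq as ff
from facefreq.erp import component_anova, default_component_specs, mixed_anova_cells


class TestConditionAverage:
    def test_identical_trials_average_equals_any_trial(self, make_epochs):
        wave = np.arange(10.0)
        data = np.tile(wave, (8, 2, 1))
        ep = make_epochs(data)
        avgs = ff.condition_average(ep)
        for cond in ff.CONDITIONS:
            np.testing.assert_array_equal(avgs[cond], data[0])

    def test_opposite_trials_cancel(self, make_epochs):
        data = np.zeros((8, 2, 5))
        data[0::4] = 1.0   # first AA trial
        data[4::4] = -1.0  # second AA trial
        ep = make_epochs(data)
        avgs, counts = ff.condition_average(ep, return_counts=True)
        np.testing.assert_allclose(avgs["AA"], 0.0)
        assert counts["AA"] == 2

    def test_rejected_trials_excluded_and_empty_condition_errors(self, make_epochs):
        data = np.ones((4, 2, 5))
        ep = make_epochs(data)
        # reject both AA trials -> AA empty
        aa = np.flatnonzero(ep.condition == "AA")
        for i in aa:
            ep.rejected_trials[int(i)] = "amplitude"
        with pytest.raises(ValueError):
            ff.condition_average(ep)

    def test_noisy_average_close_to_template(self, make_epochs):
        rng = np.random.default_rng(0)
        template = np.sin(np.linspace(0, 3, 50))
        n = 58
        data = template[None, None, :] + rng.normal(0, 2.0, size=(4 * n, 2, 50))
        ep = make_epochs(data)
        avgs = ff.condition_average(ep)
        sem = 2.0 / np.sqrt(n)
        assert np.all(np.abs(avgs["HH"] - template) < 4 * sem)


class TestComponentAmplitude:
    def make_avg(self, layout, trace):
        avg = np.zeros((layout.n_channels, trace.size))
        avg[:] = trace
        return avg

    def test_constructed_gaussian_peak_recovered(self, layout64):
        times = np.arange(-500.0, 1500.0, 4.0)
        trace = 5.0 * np.exp(-0.5 * ((times - 120.0) / 15.0) ** 2)
        spec = default_component_specs()[0]  # P1: max in 100-150
        amps = ff.component_amplitude(self.make_avg(layout64, trace), times,
                                      layout64, spec)
        assert amps["left"] == pytest.approx(5.0, abs=1e-9)
        assert amps["right"] == pytest.approx(5.0, abs=1e-9)

    def test_negative_deflection_minimum(self, layout64):
        times = np.arange(-500.0, 1500.0, 4.0)
        trace = -4.0 * np.exp(-0.5 * ((times - 180.0) / 10.0) ** 2)
        spec = default_component_specs()[1]  # N170: min in 160-200
        amps = ff.component_amplitude(self.make_avg(layout64, trace), times,
                                      layout64, spec)
        assert amps["left"] == pytest.approx(-4.0, abs=1e-9)

    def test_ramp_mean_amplitude(self, layout64):
        times = np.arange(-500.0, 1500.0, 4.0)
        trace = np.where((times >= 250) & (times <= 350),
                         (times - 250) / 100.0 * 2.0, 0.0)
        spec = default_component_specs()[2]  # N250: mean in 250-350
        amps = ff.component_amplitude(self.make_avg(layout64, trace), times,
                                      layout64, spec)
        assert amps["right"] == pytest.approx(1.0, abs=0.05)

    def test_measure_ordering_invariant(self, layout64):
        rng = np.random.default_rng(1)
        times = np.arange(-500.0, 1500.0, 4.0)
        avg = rng.normal(size=(layout64.n_channels, times.size))
        base = default_component_specs()[1]
        vals = {}
        for measure in ("max", "mean", "min"):
            spec = ff.ComponentSpec("x", measure, base.window_ms, base.electrodes)
            vals[measure] = ff.component_amplitude(avg, times, layout64, spec)
        for hemi in ("left", "right"):
            assert vals["max"][hemi] >= vals["mean"][hemi] >= vals["min"][hemi]

    def test_window_outside_epoch_errors(self, layout64):
        times = np.arange(0.0, 100.0, 4.0)
        spec = ff.ComponentSpec("x", "max", (500.0, 600.0),
                                {"left": ["E35"], "right": ["E39"]})
        with pytest.raises(ValueError):
            ff.component_amplitude(np.zeros((64, times.size)), times,
                                   layout64, spec)


def balanced_table(n_per_group=4, effects=None, noise=0.0, seed=0):
    """Small condition x hemisphere x group amplitude table."""
    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    for gi, group in enumerate(("pTD", "pASD")):
        for s in range(n_per_group):
            pid = f"{group}{s:02d}"
            subj_off = rng.normal(0, effects.get("subject_sd", 0.0))
            for ci, cond in enumerate(ff.CONDITIONS):
                for hi, hemi in enumerate(("left", "right")):
                    val = (effects.get("condition", 0.0) * ci
                           + effects.get("hemisphere", 0.0) * hi
                           + effects.get("group", 0.0) * gi
                           + effects.get("interaction_cg", 0.0) * ci * gi
                           + subj_off + rng.normal(0, noise))
                    rows.append(dict(participant=pid, group=group,
                                     condition=cond, hemisphere=hemi,
                                     component="LPP", amplitude=val))
    return pd.DataFrame(rows)


class TestComponentAnova:
    def test_identical_amplitudes_give_zero_f(self):
        tab = balanced_table()
        aov = component_anova(tab, "LPP").set_index("effect")
        for eff in ("condition", "laterality", "group",
                    "group:condition", "condition:laterality"):
            assert aov.loc[eff, "F"] == pytest.approx(0.0, abs=1e-9)

    def test_planted_condition_effect_detected_group_null(self):
        tab = balanced_table(n_per_group=6,
                             effects={"condition": 2.0, "subject_sd": 0.5},
                             noise=0.3, seed=2)
        aov = component_anova(tab, "LPP").set_index("effect")
        assert aov.loc["condition", "p"] < 1e-6
        assert aov.loc["group", "p"] > 0.05

    def test_f_invariant_to_constant_shift(self):
        tab = balanced_table(n_per_group=5, effects={"condition": 1.0},
                             noise=1.0, seed=3)
        aov1 = component_anova(tab, "LPP")
        tab2 = tab.assign(amplitude=tab["amplitude"] + 100.0)
        aov2 = component_anova(tab2, "LPP")
        np.testing.assert_allclose(aov1["F"], aov2["F"], rtol=1e-9)

    def test_matches_anovarm_for_single_group(self):
        # within-only oracle: statsmodels AnovaRM on one group must agree
        # with the contrast-score implementation exactly
        tab = balanced_table(n_per_group=8, effects={"condition": 0.5,
                                                     "hemisphere": 0.8},
                             noise=1.0, seed=4)
        tab = tab[tab.group == "pTD"]
        aov = mixed_anova_cells(
            tab.pivot_table(index="participant",
                            columns=["condition", "hemisphere"],
                            values="amplitude")
            [[(c, h) for c in ff.CONDITIONS for h in ("left", "right")]]
            .to_numpy(),
            np.array(["pTD"] * 8),
            within_shapes=(4, 2), within_names=("condition", "laterality"))
        rm = AnovaRM(tab, "amplitude", "participant",
                     within=["condition", "hemisphere"]).fit().anova_table
        got = aov.set_index("effect")
        assert got.loc["condition", "F"] == pytest.approx(
            rm.loc["condition", "F Value"], rel=1e-8)
        assert got.loc["laterality", "F"] == pytest.approx(
            rm.loc["hemisphere", "F Value"], rel=1e-8)
        assert got.loc["condition:laterality", "F"] == pytest.approx(
            rm.loc["condition:hemisphere", "F Value"], rel=1e-8)

    def test_matches_pingouin_mixed_anova_collapsed(self):
        # two-factor oracle: collapse hemispheres, compare condition x
        # group against pingouin's mixed ANOVA (balanced groups)
        import pingouin as pg
        tab = balanced_table(n_per_group=7,
                             effects={"condition": 0.7, "interaction_cg": 0.4,
                                      "subject_sd": 0.6},
                             noise=0.8, seed=5)
        collapsed = (tab.groupby(["participant", "group", "condition"],
                                 observed=True)["amplitude"].mean()
                     .reset_index())
        cells = collapsed.pivot_table(index=["participant", "group"],
                                      columns="condition",
                                      values="amplitude")[list(ff.CONDITIONS)]
        groups = np.array([g for _, g in cells.index])
        aov = mixed_anova_cells(cells.to_numpy(), groups, within_shapes=(4,),
                                within_names=("condition",)).set_index("effect")
        ref = pg.mixed_anova(collapsed, dv="amplitude", within="condition",
                             subject="participant", between="group",
                             effsize="ng2").set_index("Source")
        assert aov.loc["condition", "F"] == pytest.approx(
            ref.loc["condition", "F"], rel=1e-6)
        assert aov.loc["group", "F"] == pytest.approx(
            ref.loc["group", "F"], rel=1e-6)
        assert aov.loc["group:condition", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6)
        assert aov.loc["condition", "ges"] == pytest.approx(
            ref.loc["condition", "ng2"], rel=1e-6)

    def test_brute_force_ss_oracle_balanced(self):
        # hand-rolled sums of squares for the balanced split-plot design
        rng = np.random.default_rng(6)
        n, k = 5, 2  # per group, groups
        y = rng.normal(size=(k * n, 4, 2))  # subjects x cond x hemi
        groups = np.repeat(["pTD", "pASD"], n)
        aov = mixed_anova_cells(y.reshape(k * n, 8), groups,
                                within_shapes=(4, 2),
                                within_names=("condition", "laterality"))

        N = k * n
        grand = y.mean()
        subj_m = y.mean(axis=(1, 2))           # subject means
        grp_m = np.array([y[groups == g].mean() for g in ("pTD", "pASD")])
        cond_m = y.mean(axis=(0, 2))
        hemi_m = y.mean(axis=(0, 1))
        # between stratum
        ss_group = 8 * n * ((grp_m - grand) ** 2).sum()
        ss_subj = 8 * ((subj_m - np.repeat(grp_m, n)) ** 2).sum()
        f_group = (ss_group / (k - 1)) / (ss_subj / (N - k))
        # condition stratum
        ss_cond = N * 2 * ((cond_m - grand) ** 2).sum()
        cg_m = np.stack([y[groups == g].mean(axis=(0, 2))
                         for g in ("pTD", "pASD")])
        ss_cg = 2 * n * ((cg_m - cond_m[None] - grp_m[:, None] + grand) ** 2).sum()
        subj_cond = y.mean(axis=2)  # subject x cond
        ss_cs = 2 * ((subj_cond - subj_m[:, None] - cg_m[np.repeat([0, 1], n)]
                      + np.repeat(grp_m, n)[:, None]) ** 2).sum()
        f_cond = (ss_cond / 3) / (ss_cs / (3 * (N - k)))
        f_cg = (ss_cg / 3) / (ss_cs / (3 * (N - k)))

        got = aov.set_index("effect")
        assert got.loc["group", "F"] == pytest.approx(f_group, rel=1e-8)
        assert got.loc["condition", "F"] == pytest.approx(f_cond, rel=1e-8)
        assert got.loc["group:condition", "F"] == pytest.approx(f_cg, rel=1e-8)
        # hemisphere stratum (1 df)
        ss_hemi = N * 4 * ((hemi_m - grand) ** 2).sum()
        subj_hemi = y.mean(axis=1)
        gh_m = np.stack([y[groups == g].mean(axis=(0, 1))
                         for g in ("pTD", "pASD")])
        ss_gh = 4 * n * ((gh_m - hemi_m[None] - grp_m[:, None] + grand) ** 2).sum()
        ss_hs = 4 * ((subj_hemi - subj_m[:, None] - gh_m[np.repeat([0, 1], n)]
                      + np.repeat(grp_m, n)[:, None]) ** 2).sum()
        f_hemi = (ss_hemi / 1) / (ss_hs / (N - k))
        assert got.loc["laterality", "F"] == pytest.approx(f_hemi, rel=1e-8)
        assert got.loc["group:laterality", "F"] == pytest.approx(
            (ss_gh / 1) / (ss_hs / (N - k)), rel=1e-8)

    def test_gg_correction_never_smaller_p(self):
        tab = balanced_table(n_per_group=6, effects={"condition": 0.6,
                                                     "subject_sd": 0.4},
                             noise=0.7, seed=7)
        aov = component_anova(tab, "LPP").set_index("effect")
        eps = aov.loc["condition", "eps_gg"]
        assert eps <= 1.0
        assert aov.loc["condition", "p_gg"] >= aov.loc["condition", "p"]

    def test_missing_cells_raise(self):
        tab = balanced_table()
        tab = tab[~((tab.participant == "pTD00") & (tab.condition == "AA"))]
        with pytest.raises(ValueError):
            component_anova(tab, "LPP")


def test_component_table_from_cohort(small_cohort):
    sub = {p: small_cohort.epochs[p] for p in small_cohort.participants()[:4]}
    tab = ff.component_table(sub, small_cohort.layout)
    assert set(tab["component"]) == {"P1", "N170", "N250"}
    # 4 participants x 4 conditions x 2 hemispheres x 3 components
    assert len(tab) == 4 * 4 * 2 * 3
    assert np.isfinite(tab["amplitude"]).all()
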