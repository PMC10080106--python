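"""Synthetic-data generator: determinism, composition law, condition effects."""

import numpy as np
import pandas as pd
import pytest

import cytoscreen as cs
from cytoscreen.simulate import DEFAULT_LADDER, MarkerExpr


def tiny_tree():
    nodes = [
        cs.PopulationNode("pos_pop", None, 0.3, {"M1": MarkerExpr.single(5000.0)}),
        cs.PopulationNode("neg_pop", None, 0.7, {}),
    ]
    return cs.PopulationTree(nodes, markers=["M1", "M2"], name="tiny")


class TestGenerateDonorEvents:
    def test_same_seed_is_byte_identical(self):
        tree = tiny_tree()
        donor = cs.DonorSpec("D", seed=99)
        a = cs.generate_donor_events(tree, donor, 2000)
        b = cs.generate_donor_events(tree, donor, 2000)
        assert a.data.equals(b.data)
        assert a.labels.equals(b.labels)

    def test_label_fractions_follow_multinomial_law(self, pbmc_populations):
        n = 200_000
        donor = cs.DonorSpec("D", composition_jitter=0.0, seed=1)
        em = cs.generate_donor_events(
            pbmc_populations, donor, n,
            debris_fraction=0.0, doublet_fraction=0.0, dead_fraction=0.0,
        )
        fractions = pbmc_populations.leaf_fractions()
        counts = em.labels.value_counts()
        for leaf, p in fractions.items():
            se = np.sqrt(p * (1 - p) / n)
            observed = counts.get(leaf, 0) / n
            assert abs(observed - p) <= 3 * se, leaf

    def test_zero_qc_fractions_mean_no_qc_labels(self):
        em = cs.generate_donor_events(
            tiny_tree(), cs.DonorSpec("D", seed=0), 5000,
            debris_fraction=0.0, doublet_fraction=0.0, dead_fraction=0.0,
        )
        assert not em.labels.isin(cs.QC_LABELS).any()

    def test_overfull_composition_rejected(self):
        nodes = [
            cs.PopulationNode("a", None, 0.7, {}),
            cs.PopulationNode("b", None, 0.5, {}),
        ]
        with pytest.raises(ValueError, match="summing"):
            cs.PopulationTree(nodes, markers=["M1"])

    def test_doublets_break_scatter_ratio(self):
        em = cs.generate_donor_events(
            tiny_tree(), cs.DonorSpec("D", seed=2), 20_000,
            debris_fraction=0.0, doublet_fraction=0.3, dead_fraction=0.0,
        )
        ratio = em.data["FSC-H"] / em.data["FSC-A"]
        doublets = em.labels == "doublet"
        assert (ratio[doublets] < 0.75).all()
        assert (ratio[~doublets] >= 0.75).mean() > 0.99


class TestApplyCondition:
    def test_identity_factor_changes_nothing(self, pbmc_populations):
        effect = cs.ConditionEffect("null", {("t_cells", "CD69"): 1.0})
        new = cs.apply_condition(pbmc_populations, effect)
        for leaf in pbmc_populations.leaves():
            a = pbmc_populations.resolved_expression(leaf)["CD69"]
            b = new.resolved_expression(leaf)["CD69"]
            assert a.median() == pytest.approx(b.median())

    def test_effect_is_local_and_exact(self, pbmc_populations):
        effect = cs.ConditionEffect("k2", {("mono_classical", "CD69"): 2.0})
        new = cs.apply_condition(pbmc_populations, effect)
        for leaf in pbmc_populations.leaves():
            before = pbmc_populations.resolved_expression(leaf)["CD69"].median()
            after = new.resolved_expression(leaf)["CD69"].median()
            if leaf == "mono_classical":
                assert after == pytest.approx(2.0 * before)
            else:
                assert after == pytest.approx(before)
        # composition untouched
        assert new.leaf_fractions() == pytest.approx(
            pbmc_populations.leaf_fractions()
        )

    def test_ground_truth_fd_is_k_minus_one(self):
        effect = cs.ConditionEffect("x", {("a", "M"): 1.5})
        assert effect.ground_truth_fd()[("a", "M")] == pytest.approx(0.5)

    def test_unknown_population_or_marker_raises(self, pbmc_populations):
        with pytest.raises(KeyError, match="population"):
            cs.apply_condition(
                pbmc_populations, cs.ConditionEffect("e", {("nope", "CD69"): 2.0})
            )
        with pytest.raises(KeyError, match="marker"):
            cs.apply_condition(
                pbmc_populations, cs.ConditionEffect("e", {("t_cells", "XYZ"): 2.0})
            )

    def test_median_commutes_with_asinh(self):
        # the monotone-transform invariance the MFI reporting relies on
        rng = np.random.default_rng(0)
        x = MarkerExpr.single(5000.0).sample(100_001, rng)
        med_raw = np.median(x)
        med_back = 150.0 * np.sinh(np.median(np.arcsinh(x / 150.0)))
        assert med_back == pytest.approx(med_raw, rel=1e-12)


class TestSpectralSynthesis:
    def test_noiseless_mix_unmixes_exactly(self, pbmc_populations):
        panel = cs.load_panel("pbmc_panel")
        em = cs.generate_donor_events(
            pbmc_populations, cs.DonorSpec("D", seed=4), 500,
            debris_fraction=0.0, doublet_fraction=0.0, dead_fraction=0.0,
        )
        raw = cs.synthesize_spectral_raw(em, panel, noise_sd=0.0)
        det_cols = [c for c in raw.channels if c.startswith("D")]
        order = [cs.events.VIABILITY_CHANNEL] + pbmc_populations.markers
        sigs = []
        for m in order:
            ch = (
                panel.channels[3]
                if m == cs.events.VIABILITY_CHANNEL
                else panel.channel_for_marker(m)
            )
            sigs.append(ch.signature)
        res = cs.unmix(raw.data[det_cols].to_numpy(), sigs)
        truth = em.data[order].to_numpy()
        assert np.abs(res.abundances - truth).max() <= 1e-6 * truth.max()

    def test_marker_missing_from_panel_raises(self):
        panel = cs.load_panel("tcell_panel")
        em = cs.generate_donor_events(tiny_tree(), cs.DonorSpec("D", seed=0), 100)
        with pytest.raises(KeyError, match="M1"):
            cs.synthesize_spectral_raw(em, panel)

    def test_unmixing_error_grows_with_noise(self, pbmc_populations):
        panel = cs.load_panel("pbmc_panel")
        em = cs.generate_donor_events(
            pbmc_populations, cs.DonorSpec("D", seed=4), 1000,
            debris_fraction=0.0, doublet_fraction=0.0, dead_fraction=0.0,
        )
        det = None
        errs = []
        order = [cs.events.VIABILITY_CHANNEL] + pbmc_populations.markers
        sigs = [
            panel.channels[3] if m == cs.events.VIABILITY_CHANNEL
            else panel.channel_for_marker(m)
            for m in order
        ]
        sigs = [c.signature for c in sigs]
        truth = em.data[order].to_numpy()
        for mult in (1, 2, 4):
            raw = cs.synthesize_spectral_raw(em, panel, noise_sd=5.0 * mult, seed=9)
            det = [c for c in raw.channels if c.startswith("D")]
            res = cs.unmix(raw.data[det].to_numpy(), sigs)
            errs.append(float(np.sqrt(np.mean((res.abundances - truth) ** 2))))
        assert errs[0] < errs[1] < errs[2]


class TestTitrationSeries:
    def test_saturation_limit(self):
        # c = 1e6 * K: binding is saturated, positive median ~ MFI_max + bg
        huge = tuple(1e6 / 2**i for i in range(3))
        series = cs.generate_titration_series(
            "R", concentrations=huge, n_events=20_000, seed=0,
            background_slope=0.0,
        )
        c, em = series[0]
        pos = em.data["R"][em.labels == "positive"]
        assert np.median(pos) == pytest.approx(20_000.0 + 100.0, rel=0.01)

    def test_half_saturation_point(self):
        series = cs.generate_titration_series(
            "R", concentrations=(4.0, 2.0, 1.0), n_events=50_000, seed=1,
            half_saturation=1.0, background_slope=0.0,
        )
        c, em = series[-1]
        assert c == 1.0
        pos = em.data["R"][em.labels == "positive"]
        assert np.median(pos) == pytest.approx(20_000.0 / 2 + 100.0, rel=0.02)

    def test_stain_index_unimodal_over_default_ladder(self):
        series = cs.generate_titration_series("R", seed=5)
        result = cs.titration_curve(cs.TitrationSeries.from_event_series(series))
        si = result.table["stain_index"].to_numpy()
        peak = int(np.argmax(si))
        assert all(np.diff(si[: peak + 1]) > 0) or peak == 0
        assert all(np.diff(si[peak:]) < 0) or peak == len(si) - 1

    def test_invalid_ladders_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cs.generate_titration_series("R", concentrations=(2.0, 1.0, -0.5))
        with pytest.raises(ValueError, match="decreasing"):
            cs.generate_titration_series("R", concentrations=(1.0, 2.0))
        with pytest.raises(ValueError, match="2-fold"):
            cs.generate_titration_series("R", concentrations=(9.0, 3.0))

    def test_default_ladder_is_a_2fold_chain(self):
        assert all(
            a / b == pytest.approx(2.0) for a, b in zip(DEFAULT_LADDER, DEFAULT_LADDER[1:])
        )


class TestCohort:
    def test_metadata_has_one_row_per_donor_condition(self, tcell_populations):
        effect = cs.load_effect("ra_effect")
        samples, meta = cs.generate_cohort(
            tcell_populations, effect, donors_per_group=2, n_events=500,
            seed=3, conditions=("unstim", "pha"),
        )
        assert len(meta) == 2 * 2 * 2
        assert set(meta["sample_id"]) == set(samples)

    def test_null_cohort_groups_differ_only_by_noise(self, tcell_populations):
        null = cs.ConditionEffect("null")
        samples, meta = cs.generate_cohort(
            tcell_populations, null, donors_per_group=4, n_events=8000,
            seed=6, composition_jitter=0.0,
        )
        t_frac = {
            sid: (em.labels.isin(
                set(tcell_populations.descendant_leaves("cd3_t"))
            )).mean()
            for sid, em in samples.items()
        }
        meta = meta.set_index("sample_id")
        by_group = pd.Series(t_frac).groupby(meta["group"]).mean()
        assert abs(by_group.iloc[0] - by_group.iloc[1]) < 0.01

    def test_cohort_is_seed_deterministic(self, tcell_populations):
        effect = cs.load_effect("ra_effect")
        a, _ = cs.generate_cohort(tcell_populations, effect, 2, 300, seed=12)
        b, _ = cs.generate_cohort(tcell_populations, effect, 2, 300, seed=12)
        for sid in a:
            assert a[sid].data.equals(b[sid].data)


class TestTruthReadouts:
    def test_truth_mfi_matches_log_location(self):
        tree = tiny_tree()
        em = cs.generate_donor_events(
            tree, cs.DonorSpec("D", seed=13), 30_000,
            debris_fraction=0.0, doublet_fraction=0.0, dead_fraction=0.0,
        )
        t = cs.truth_subset_mfi(em, tree, ["pos_pop"], ["M1"])
        assert t.loc[0, "mfi"] == pytest.approx(5000.0, rel=0.03)

    def test_small_subsets_reported_missing(self):
        tree = tiny_tree()
        em = cs.generate_donor_events(tree, cs.DonorSpec("D", seed=13), 30)
        t = cs.truth_subset_mfi(em, tree, ["pos_pop"], ["M1"], min_events=20)
        assert np.isnan(t.loc[0, "mfi"])
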