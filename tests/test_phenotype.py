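import numpy as np
import pandas as pd
import pytest

from foamquant.phenotype import (
    RULE_FEATURES,
    ClassifierThresholds,
    StatsTable,
    classify_phenotype,
    compute_stats,
    fold_changes,
    reversibility,
    simulate_null_type1,
)


def _records(groups):
    """groups: {(compound, conc, recovery): {well: (experiment, [values])}}"""
    rows = []
    for (compound, conc, rec), wells in groups.items():
        for well, (exp, vals) in wells.items():
            for i, v in enumerate(vals):
                rows.append(
                    {
                        "well": well, "experiment": exp, "compound": compound,
                        "concentration_uM": conc, "recovery_h": rec, "cell_id": i,
                        "cell_area": v,
                    }
                )
    return pd.DataFrame(rows)


class TestComputeStats:
    def test_identical_groups_are_not_significant(self):
        vals = {"W%d" % i: (i, [100.0 + 10 * i]) for i in range(3)}
        tvals = {"T%d" % i: (i, [100.0 + 10 * i]) for i in range(3)}
        rec = _records({("untreated", 0.0, 0): vals, ("drug", 1.0, 0): tvals})
        st = compute_stats(rec, features=["cell_area"])
        row = st.pairwise.iloc[0]
        assert row["t"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_adj"] == pytest.approx(1.0)
        assert not row["significant"]
        cond_f = st.anova.loc[st.anova["effect"].str.contains("condition"), "F"]
        assert cond_f.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_deficient_design_names_the_cell(self):
        rec = _records(
            {
                ("untreated", 0.0, 0): {"W0": (1, [1.0]), "W1": (2, [2.0])},
                ("drug", 1.0, 0): {"T0": (1, [1.0])},
            }
        )
        with pytest.raises(ValueError, match="drug_1 R0"):
            compute_stats(rec, features=["cell_area"])

    def test_strong_effect_is_detected(self):
        base = {"W%d" % i: (i, [600.0 + i]) for i in range(3)}
        small = {"T%d" % i: (i, [72.0 + i]) for i in range(3)}
        rec = _records({("untreated", 0.0, 0): base, ("staurosporine", 1.0, 0): small})
        st = compute_stats(rec, features=["cell_area"])
        assert st.is_significant("cell_area", "staurosporine", 1.0, 0)

    def test_bonferroni_adjustment_multiplies_by_family_size(self):
        groups = {("untreated", 0.0, r): {f"U{r}{i}": (i, [10.0, 11.0, 12.0 + i]) for i in range(3)}
                  for r in (0, 24)}
        groups.update(
            {("drug", 1.0, r): {f"D{r}{i}": (i, [10.5, 11.5, 12.0 + i]) for i in range(3)}
             for r in (0, 24)}
        )
        st = compute_stats(_records(groups), features=["cell_area"])
        m = len(st.pairwise)
        assert m == 2  # one contrast per time point
        np.testing.assert_allclose(
            st.pairwise["p_adj"], np.minimum(1.0, st.pairwise["p_raw"] * m)
        )
        assert (st.pairwise["p_adj"] >= st.pairwise["p_raw"]).all()


def _summary(rows):
    recs = []
    for (compound, conc, rec), feats in rows.items():
        row = {"compound": compound, "concentration_uM": conc, "recovery_h": rec}
        for f, v in feats.items():
            row[f + "_mean"] = v
            row[f + "_sem"] = 0.1
        recs.append(row)
    return pd.DataFrame(recs)


_BASE = {"cell_area": 600.0, "n_vacuoles": 72.0,
         "vacuole_area_fraction": 0.29, "phospholipid_total": 1.0e6}


class TestFoldChanges:
    def test_equal_means_fold_one_direction_none(self):
        s = _summary({("untreated", 0.0, 0): _BASE, ("drug", 1.0, 0): dict(_BASE)})
        f = fold_changes(s).set_index("feature")
        assert (f["fold"] == 1.0).all()
        assert (f["direction"] == "none").all()

    def test_times_fewer_phrasing(self):
        t = dict(_BASE, n_vacuoles=27.7)
        s = _summary({("untreated", 0.0, 0): _BASE, ("amiodarone", 10.0, 0): t})
        row = fold_changes(s).set_index("feature").loc["n_vacuoles"]
        assert row["direction"] == "down"
        assert row["fold_magnitude"] == pytest.approx(72.0 / 27.7)
        assert row["fold_magnitude"] == pytest.approx(2.6, rel=0.01)

    def test_times_higher_phospholipid(self):
        t = dict(_BASE, phospholipid_total=2.9e6)
        s = _summary({("untreated", 0.0, 0): _BASE, ("amiodarone", 10.0, 0): t})
        row = fold_changes(s).set_index("feature").loc["phospholipid_total"]
        assert row["direction"] == "up"
        assert row["fold"] == pytest.approx(2.9)

    def test_zero_baseline_is_flagged(self):
        b = dict(_BASE, phospholipid_total=0.0)
        s = _summary({("untreated", 0.0, 0): b, ("drug", 1.0, 0): _BASE})
        row = fold_changes(s).set_index("feature").loc["phospholipid_total"]
        assert row["undefined_baseline"]
        assert np.isnan(row["fold"])

    def test_missing_baseline_time_point_is_an_error(self):
        s = _summary({("untreated", 0.0, 0): _BASE, ("drug", 1.0, 24): _BASE})
        with pytest.raises(ValueError, match="recovery_h=24"):
            fold_changes(s)


def _stats_stub(significant: dict) -> StatsTable:
    """significant: {(feature, compound, conc, recovery): bool}"""
    rows = [
        {
            "feature": f, "compound": c, "concentration_uM": conc, "recovery_h": r,
            "t": 5.0 if sig else 0.1, "p_raw": 0.001 if sig else 0.8,
            "p_adj": 0.004 if sig else 1.0, "significant": sig,
        }
        for (f, c, conc, r), sig in significant.items()
    ]
    return StatsTable(anova=pd.DataFrame(), pairwise=pd.DataFrame(rows))


def _sig_map(compound, conc, recovery, flags):
    return {(f, compound, conc, recovery): flags.get(f, False) for f in RULE_FEATURES}


class TestClassifier:
    def test_staurosporine_signature_is_pro_apoptotic(self):
        t = {"cell_area": 72.0, "n_vacuoles": 9.0, "vacuole_area_fraction": 0.098,
             "phospholipid_total": 1.2e5}
        s = _summary({("untreated", 0.0, 0): _BASE, ("staurosporine", 1.0, 0): t})
        folds = fold_changes(s)
        stats = _stats_stub(_sig_map("staurosporine", 1.0, 0, {
            "cell_area": True, "n_vacuoles": True,
            "vacuole_area_fraction": True, "phospholipid_total": True}))
        call = classify_phenotype(folds, stats, "staurosporine", 1.0)
        assert call.label == "pro_apoptotic"
        assert call.rule_trace

    def test_amiodarone_signature_is_phospholipidosis(self):
        t = dict(_BASE, n_vacuoles=27.7, phospholipid_total=2.9e6)
        s = _summary({("untreated", 0.0, 0): _BASE, ("amiodarone", 10.0, 0): t})
        folds = fold_changes(s)
        stats = _stats_stub(_sig_map("amiodarone", 10.0, 0, {
            "n_vacuoles": True, "phospholipid_total": True}))
        call = classify_phenotype(folds, stats, "amiodarone", 10.0)
        assert call.label == "phospholipidosis"

    def test_phospholipid_only_elevation_is_lipid_accumulating(self):
        t = dict(_BASE, phospholipid_total=2.6e6)
        s = _summary({("untreated", 0.0, 24): _BASE, ("fluticasone", 50.0, 24): t})
        folds = fold_changes(s)
        stats = _stats_stub(_sig_map("fluticasone", 50.0, 24, {"phospholipid_total": True}))
        call = classify_phenotype(folds, stats, "fluticasone", 50.0)
        assert call.label == "lipid_accumulating"
        assert call.decided_at_recovery_h == 24

    def test_no_change_is_normal_with_empty_trace(self):
        s = _summary({("untreated", 0.0, 0): _BASE, ("salbutamol", 10.0, 0): dict(_BASE)})
        folds = fold_changes(s)
        stats = _stats_stub(_sig_map("salbutamol", 10.0, 0, {}))
        call = classify_phenotype(folds, stats, "salbutamol", 10.0)
        assert call.label == "normal"
        assert call.rule_trace == []

    def test_classifier_is_deterministic(self):
        t = dict(_BASE, n_vacuoles=27.7, phospholipid_total=2.9e6)
        s = _summary({("untreated", 0.0, 0): _BASE, ("amiodarone", 10.0, 0): t})
        folds = fold_changes(s)
        stats = _stats_stub(_sig_map("amiodarone", 10.0, 0, {
            "n_vacuoles": True, "phospholipid_total": True}))
        a = classify_phenotype(folds, stats, "amiodarone", 10.0)
        b = classify_phenotype(folds, stats, "amiodarone", 10.0)
        assert (a.label, a.rule_trace) == (b.label, b.rule_trace)

    def test_missing_feature_is_an_error(self):
        s = _summary({("untreated", 0.0, 0): _BASE, ("drug", 1.0, 0): _BASE})
        folds = fold_changes(s)
        folds = folds[folds["feature"] != "cell_area"]
        stats = _stats_stub(_sig_map("drug", 1.0, 0, {}))
        with pytest.raises(ValueError, match="cell_area"):
            classify_phenotype(folds, stats, "drug", 1.0)


def _rev_inputs(acute, recovered, base0=None, base48=None, acute_sig=True, recov_sig=False):
    base0 = base0 or _BASE
    base48 = base48 or base0
    s = _summary(
        {
            ("untreated", 0.0, 0): base0,
            ("untreated", 0.0, 48): base48,
            ("drug", 1.0, 0): acute,
            ("drug", 1.0, 48): recovered,
        }
    )
    sig = {}
    sig.update({(f, "drug", 1.0, 0): acute_sig for f in RULE_FEATURES})
    sig.update({(f, "drug", 1.0, 48): recov_sig for f in RULE_FEATURES})
    return s, _stats_stub(sig)


class TestReversibility:
    def test_full_recovery_is_reversible(self):
        acute = dict(_BASE, n_vacuoles=27.7)
        s, st = _rev_inputs(acute, dict(_BASE))
        rev = reversibility(s, st, "drug", 1.0).set_index("feature")
        row = rev.loc["n_vacuoles"]
        assert row["recovery_index"] == pytest.approx(1.0)
        assert row["verdict"] == "reversible"

    def test_no_recovery_is_irreversible(self):
        acute = dict(_BASE, n_vacuoles=9.0)
        s, st = _rev_inputs(acute, acute, recov_sig=True)
        rev = reversibility(s, st, "drug", 1.0).set_index("feature")
        row = rev.loc["n_vacuoles"]
        assert row["recovery_index"] == pytest.approx(0.0)
        assert row["verdict"] == "irreversible"

    def test_unaffected_feature_is_not_applicable(self):
        s, st = _rev_inputs(dict(_BASE), dict(_BASE), acute_sig=False)
        rev = reversibility(s, st, "drug", 1.0).set_index("feature")
        assert (rev["verdict"] == "not_applicable").all()
        assert rev.attrs["overall"] == "not_applicable"

    def test_recovery_index_is_affine_invariant(self):
        acute = dict(_BASE, n_vacuoles=20.0)
        recov = dict(_BASE, n_vacuoles=60.0)
        s, st = _rev_inputs(acute, recov)
        r1 = reversibility(s, st, "drug", 1.0).set_index("feature")
        # rescale the feature: x -> 3x + 5 everywhere
        s2 = s.copy()
        s2["n_vacuoles_mean"] = 3 * s2["n_vacuoles_mean"] + 5
        r2 = reversibility(s2, st, "drug", 1.0).set_index("feature")
        assert r1.loc["n_vacuoles", "recovery_index"] == pytest.approx(
            r2.loc["n_vacuoles", "recovery_index"]
        )

    def test_missing_time_point_is_an_error(self):
        acute = dict(_BASE, n_vacuoles=20.0)
        s, st = _rev_inputs(acute, acute)
        s = s[s["recovery_h"] != 48]
        with pytest.raises(ValueError, match="recovery_h=48"):
            reversibility(s, st, "drug", 1.0)


def test_null_type1_error_is_near_nominal():
    rate = simulate_null_type1(n_sims=400, n_wells=5, rng_seed=7)
    assert rate < 0.09  # ~2x nominal as a loose sanity bound at 400 sims
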