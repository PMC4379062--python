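import numpy as np
import pandas as pd
import pytest

from serumqc.classification import (
    SUM_RATIOS,
    QualityLabel,
    TreeModel,
    TreeNode,
    apply_to_heldout,
    build_feature_table,
    compute_sum_ratios,
    fit_tree,
    label_samples,
    label_series,
    misclassification_rate,
    order_tree_candidates,
    rank_variables,
    robustness_scan,
    split_participants,
    transition_band,
)
from serumqc.qc import apply_qc
from serumqc.simulate import GeneratorConfig


# ---------------------------------------------------------------------------
# sum ratios and features


def test_sum_ratios_hand_computed(fixture_dataset):
    filt, _ = apply_qc(fixture_dataset, cv_max=np.inf, frac_min=0.0)
    sums = compute_sum_ratios(filt)
    # participant 1 reference: lyso 20 / (220 + 12) PC, AA (600+100) / AC 5
    assert sums.loc["1-ref", "tLyso/tPC"] == pytest.approx(20 / 232)
    assert sums.loc["1-ref", "tLyso/tPCaa"] == pytest.approx(20 / 220)
    assert sums.loc["1-ref", "tLyso/tPCae"] == pytest.approx(20 / 12)
    assert sums.loc["1-ref", "tAA/tAC"] == pytest.approx(700 / 5)
    # rt 36 h: lyso x2.4, PC(34:2) x0.75 -> ratio rises
    assert sums.loc["1-rt-36h", "tLyso/tPC"] == pytest.approx(48 / (165 + 12))


def test_sum_ratios_scale_invariant(fixture_dataset):
    filt, _ = apply_qc(fixture_dataset, cv_max=np.inf, frac_min=0.0)
    doubled = filt.values * 2.0
    from serumqc.dataset import ConcentrationDataset

    ds2 = ConcentrationDataset(filt.panel, filt.annotations, doubled)
    pd.testing.assert_frame_equal(compute_sum_ratios(filt), compute_sum_ratios(ds2))


def test_sum_ratio_requires_all_classes(study_qc):
    filt, _ = study_qc
    no_lyso = filt.subset_metabolites(
        [m for m in filt.panel.ids if filt.panel.class_of(m) != "lyso_pc"]
    )
    with pytest.raises(ValueError):
        compute_sum_ratios(no_lyso)


def test_feature_table_shape(study_qc):
    filt, _ = study_qc
    pairs = [("Gln", "Ser"), ("lysoPC(18:0)", "PC(34:2)")]
    feats = build_feature_table(filt, pairs)
    assert list(feats.columns) == ["Gln/Ser", "lysoPC(18:0)/PC(34:2)", *SUM_RATIOS]
    assert feats.loc["1-ref", "Gln/Ser"] == pytest.approx(
        filt.values.loc["1-ref", "Gln"] / filt.values.loc["1-ref", "Ser"]
    )


# ---------------------------------------------------------------------------
# labels and split


def test_label_counts_on_training_participants(study_qc):
    filt, _ = study_qc
    train, _ = split_participants(filt.participants())
    tr = filt.subset_participants(train)
    non_stringent = label_series(label_samples(tr, "non_stringent")).value_counts()
    assert non_stringent["good"] == 48 and non_stringent["bad"] == 24
    stringent = label_series(label_samples(tr, "stringent")).value_counts()
    assert stringent["good"] == 12 and stringent["bad"] == 12


def test_wet_ice_unlabeled_under_both_schemes(study):
    for scheme in ("stringent", "non_stringent"):
        lab = {l.sample_id: l.label for l in label_samples(study, scheme)}
        for a in study.annotations:
            if a.role == "handling" and a.temperature == "wet_ice":
                assert lab[a.sample_id] == "unlabeled"


def test_unknown_scheme_rejected(study):
    with pytest.raises(ValueError):
        label_samples(study, "lenient")


class TestSplit:
    def test_default_split(self):
        parts = [str(i) for i in range(1, 20)]
        train, test = split_participants(parts)
        assert len(train) == 12 and len(test) == 7
        assert set(train) | set(test) == set(parts)
        assert not set(train) & set(test)

    def test_seeded_split_reproducible(self):
        parts = [str(i) for i in range(1, 20)]
        a = split_participants(parts, seed=3)
        b = split_participants(parts, seed=3)
        assert a == b
        assert len(a[0]) == 12

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="both"):
            split_participants(["1", "2", "3"], train_ids=["1", "2"], test_ids=["2", "3"])

    def test_uncovered_participant_rejected(self):
        with pytest.raises(ValueError, match="neither"):
            split_participants(["1", "2", "3"], train_ids=["1"], test_ids=["2"])


# ---------------------------------------------------------------------------
# tree model mechanics


@pytest.fixture
def printed_rule_tree():
    """The published-style rule: tLyso/tPC >= 0.12 and Gln/Ser <= 4.71 -> bad."""
    return TreeModel(
        [
            TreeNode(feature="tLyso/tPC", threshold=0.12, left=1, right=2),
            TreeNode(label="good"),
            TreeNode(feature="Gln/Ser", threshold=4.71, left=3, right=4),
            TreeNode(label="bad"),
            TreeNode(label="good"),
        ]
    )


@pytest.mark.parametrize(
    "tlyso, glnser, expected",
    [
        (0.15, 4.0, "bad"),
        (0.10, 6.0, "good"),
        (0.15, 6.0, "good"),   # high lysoPC ratio alone is not enough
        (0.10, 4.0, "good"),
    ],
)
def test_rule_application(printed_rule_tree, tlyso, glnser, expected):
    feats = pd.DataFrame({"tLyso/tPC": [tlyso], "Gln/Ser": [glnser]}, index=["s"])
    assert printed_rule_tree.predict(feats)["s"] == expected


def test_rule_text_and_json_roundtrip(printed_rule_tree):
    text = printed_rule_tree.rule_text()
    assert "tLyso/tPC >= 0.12" in text and "Gln/Ser <= 4.71" in text
    assert text.endswith("-> bad")
    back = TreeModel.from_json(printed_rule_tree.to_json())
    assert back == printed_rule_tree


def test_missing_feature_is_unclassifiable(printed_rule_tree):
    feats = pd.DataFrame(
        {"tLyso/tPC": [0.2, 0.2], "Gln/Ser": [np.nan, 4.0]}, index=["a", "b"]
    )
    pred = printed_rule_tree.predict(feats)
    assert pred["a"] is None and pred["b"] == "bad"
    labels = [QualityLabel("a", "bad", "non_stringent"), QualityLabel("b", "bad", "non_stringent")]
    rate, errors, n = misclassification_rate(pred, labels)
    assert (rate, errors, n) == (0.0, 0, 1)  # the unclassifiable sample is excluded


def test_misclassification_rate_worked_values():
    labels = [QualityLabel(f"s{i}", "good", "non_stringent") for i in range(72)]
    pred = pd.Series(["good"] * 69 + ["bad"] * 3, index=[f"s{i}" for i in range(72)])
    rate, errors, n = misclassification_rate(pred, labels)
    assert errors == 3 and n == 72
    assert rate == pytest.approx(0.042, abs=5e-4)


def test_fit_tree_on_separable_data():
    """CART places a single split at the midpoint of the empty margin."""
    x = [1.0, 2.0, 3.0, 4.0, 5.0, 11.0, 12.0, 13.0, 14.0, 15.0]
    feats = pd.DataFrame({"v": x}, index=[f"s{i}" for i in range(10)])
    labels = [
        QualityLabel(f"s{i}", "good" if i < 5 else "bad", "non_stringent")
        for i in range(10)
    ]
    tree = fit_tree(feats, labels, min_samples_leaf=5)
    assert tree.splits == [("v", 8.0)]
    pred = tree.predict(feats)
    assert (pred == label_series(labels)).all()


def test_fit_tree_requires_both_classes():
    feats = pd.DataFrame({"v": [1.0, 2.0]}, index=["a", "b"])
    labels = [QualityLabel(i, "good", "non_stringent") for i in ("a", "b")]
    with pytest.raises(ValueError):
        fit_tree(feats, labels)


def test_tie_break_prefers_earlier_column():
    """Two equally separating variables: the first-listed one is used."""
    x = [1.0] * 6 + [10.0] * 6
    feats = pd.DataFrame(
        {"second": x, "first": x}, index=[f"s{i}" for i in range(12)]
    )[["first", "second"]]
    labels = [
        QualityLabel(f"s{i}", "good" if i < 6 else "bad", "non_stringent")
        for i in range(12)
    ]
    tree = fit_tree(feats, labels, min_samples_leaf=5)
    assert tree.splits[0][0] == "first"


def test_order_tree_candidates_puts_sums_first():
    cands = ["Gln/Ser", "tLyso/tPC", "a/b", "tAA/tAC"]
    assert order_tree_candidates(cands) == ["tLyso/tPC", "tAA/tAC", "Gln/Ser", "a/b"]


def test_pruning_removes_noise_splits():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(0, 1, 30), rng.normal(6, 1, 30)])
    noise = rng.normal(size=60)
    feats = pd.DataFrame({"signal": x, "noise": noise}, index=[f"s{i}" for i in range(60)])
    labels = [
        QualityLabel(f"s{i}", "good" if i < 30 else "bad", "non_stringent")
        for i in range(60)
    ]
    tree = fit_tree(feats, labels, min_samples_leaf=2, ccp_alpha=0.01)
    assert [v for v, _ in tree.splits] == ["signal"]


# ---------------------------------------------------------------------------
# random-forest ranking


def test_ranking_deterministic(classifier_inputs):
    feats = classifier_inputs["features"]
    tr = classifier_inputs["train"]
    f_tr = feats.loc[tr.sample_ids]
    labels = label_samples(tr, "stringent")
    a = rank_variables(f_tr, labels, n_iter=3, n_trees=51, seed=9)
    b = rank_variables(f_tr, labels, n_iter=3, n_trees=51, seed=9)
    assert a.ranking == b.ranking
    pd.testing.assert_series_equal(a.importance, b.importance)


def test_pure_noise_variable_never_ranks_first(classifier_inputs):
    feats = classifier_inputs["features"]
    tr = classifier_inputs["train"]
    f_tr = feats.loc[tr.sample_ids].copy()
    labels = label_samples(tr, "stringent")
    rng = np.random.default_rng(123)
    for run in range(5):
        f_tr["noise_var"] = rng.normal(size=len(f_tr))
        rank = rank_variables(f_tr, labels, n_iter=5, n_trees=101, seed=run)
        assert rank.ranking[0] != "noise_var"


def test_degenerate_labels_rejected(classifier_inputs):
    feats = classifier_inputs["features"]
    tr = classifier_inputs["train"]
    labels = [QualityLabel(s, "good", "stringent") for s in tr.sample_ids]
    with pytest.raises(ValueError):
        rank_variables(feats.loc[tr.sample_ids], labels, n_iter=1, n_trees=11)


def test_lyso_family_dominates_ranking(classifier_inputs):
    """The degradation-process variables fill the top of the ranking.

    Dozens of lysoPC/PC variables separate the stringent classes almost
    perfectly, so the exact order among them is close to exchangeable;
    the family-level pattern is what the ranking must deliver.
    """
    top10 = classifier_inputs["rank"].top(10)
    lyso_family = [v for v in top10 if "lysoPC" in v or v.startswith("tLyso")]
    assert len(lyso_family) >= 6
    # the best lysoPC/PC sum ratio sits in the upper fifth of the ranking
    imp = classifier_inputs["rank"].importance
    best_sum_rank = min(
        imp.index.get_loc(v) for v in ("tLyso/tPC", "tLyso/tPCaa", "tLyso/tPCae")
    )
    assert best_sum_rank < len(imp) / 5


def test_importance_averaging_reduces_rank_variance(classifier_inputs):
    """More forest repetitions stabilise a variable's rank."""
    feats = classifier_inputs["features"]
    tr = classifier_inputs["train"]
    cols = list(feats.columns[:20]) + list(SUM_RATIOS)
    f_tr = feats.loc[tr.sample_ids, sorted(set(cols), key=cols.index)]
    labels = label_samples(tr, "stringent")
    values = {5: [], 50: []}
    for n_iter in values:
        for seed in range(8):
            r = rank_variables(f_tr, labels, n_iter=n_iter, n_trees=35, seed=seed)
            values[n_iter].append(r.importance["tLyso/tPC"])
    # averaging over more forests shrinks the sampling noise of the
    # importance estimate (ranks among near-exchangeable variables do not
    # converge, the values do)
    assert np.std(values[50]) < np.std(values[5])


# ---------------------------------------------------------------------------
# end-to-end on the default study


@pytest.fixture(scope="module")
def fitted(classifier_inputs):
    feats = classifier_inputs["features"]
    tr, te = classifier_inputs["train"], classifier_inputs["test"]
    top10 = classifier_inputs["top10"]
    lab_tr = label_samples(tr, "non_stringent")
    lab_te = label_samples(te, "non_stringent")
    tree = fit_tree(feats.loc[tr.sample_ids, top10], lab_tr)
    return tree, lab_tr, lab_te


def test_end_to_end_performance(classifier_inputs, fitted):
    tree, lab_tr, lab_te = fitted
    feats = classifier_inputs["features"]
    tr, te = classifier_inputs["train"], classifier_inputs["test"]
    top10 = classifier_inputs["top10"]
    rate_tr, _, n_tr = misclassification_rate(
        tree.predict(feats.loc[tr.sample_ids, top10]), lab_tr
    )
    rate_te, _, n_te = misclassification_rate(
        tree.predict(feats.loc[te.sample_ids, top10]), lab_te
    )
    assert n_tr == 72 and n_te == 42
    assert rate_tr <= 0.05 and rate_te <= 0.05


def test_recovered_cutoffs_inside_transition_bands(classifier_inputs, fitted):
    tree, _, _ = fitted
    cfg = GeneratorConfig(seed=1)
    assert tree.splits, "tree must have at least one split"
    for var, cut in tree.splits:
        lo, hi = transition_band(cfg, var)
        assert lo <= cut <= hi, (var, cut, lo, hi)


def test_heldout_conditions(classifier_inputs, fitted):
    tree, _, _ = fitted
    feats = classifier_inputs["features"]
    filt = classifier_inputs["filtered"]
    table = apply_to_heldout(tree, feats, filt)
    assert set(table["temperature"]) == {"wet_ice", "rt"}
    wet = table[table.temperature == "wet_ice"]
    # wet-ice samples are (almost) entirely classified good
    assert wet.n_good.sum() / (wet.n_good.sum() + wet.n_bad.sum()) >= 0.9
    assert (wet.frac_good >= 0.8).all()
    rt12 = table[(table.temperature == "rt") & (table.delay_h == 12)]
    assert rt12.iloc[0]["n_bad"] > 0  # degradation already visible at 12 h


def test_heldout_empty_without_unlabeled(classifier_inputs, fitted):
    tree, _, _ = fitted
    filt = classifier_inputs["filtered"]
    only_labeled = filt.subset_roles(["reference"])
    feats = build_feature_table(only_labeled, [])
    table = apply_to_heldout(tree, feats, only_labeled)
    assert len(table) == 0


def test_prediction_invariant_under_common_rescaling(classifier_inputs, fitted):
    tree, _, _ = fitted
    feats = classifier_inputs["features"]
    filt = classifier_inputs["filtered"]
    from serumqc.dataset import ConcentrationDataset

    scaled = ConcentrationDataset(filt.panel, filt.annotations, filt.values * 3.0)
    pairs = [tuple(c.split("/")) for c in feats.columns if c not in SUM_RATIOS]
    feats2 = build_feature_table(scaled, pairs)
    pd.testing.assert_series_equal(
        tree.predict(feats[tree.variables]), tree.predict(feats2[tree.variables])
    )


class TestRobustnessScan:
    def test_full_subset_matches_direct_fit(self, classifier_inputs, fitted):
        tree, lab_tr, lab_te = fitted
        feats = classifier_inputs["features"]
        tr, te = classifier_inputs["train"], classifier_inputs["test"]
        top10 = classifier_inputs["top10"]
        table = robustness_scan(
            feats.loc[tr.sample_ids], lab_tr, feats.loc[te.sample_ids], lab_te,
            [top10],
        )
        assert table.iloc[0]["rule"] == tree.rule_text()

    def test_both_family_subsets_perform(self, classifier_inputs, fitted):
        tree, lab_tr, lab_te = fitted
        feats = classifier_inputs["features"]
        tr, te = classifier_inputs["train"], classifier_inputs["test"]
        top10 = classifier_inputs["top10"]
        full = robustness_scan(
            feats.loc[tr.sample_ids], lab_tr, feats.loc[te.sample_ids], lab_te, [top10]
        ).iloc[0]
        lyso = [v for v in top10 if "lysoPC" in v or v.startswith("tLyso")]
        amino = ["Gln/Ser"] if "Gln/Ser" in feats.columns else []
        subset = [lyso[0]] + amino
        table = robustness_scan(
            feats.loc[tr.sample_ids], lab_tr, feats.loc[te.sample_ids], lab_te, [subset]
        )
        # similar performance: within a doubled rate plus one extra sample
        assert table.iloc[0]["test_rate"] <= 2 * full["test_rate"] + 1 / 42 + 1e-9

    def test_empty_subset_rejected(self, classifier_inputs, fitted):
        _, lab_tr, lab_te = fitted
        feats = classifier_inputs["features"]
        tr, te = classifier_inputs["train"], classifier_inputs["test"]
        with pytest.raises(ValueError):
            robustness_scan(
                feats.loc[tr.sample_ids], lab_tr, feats.loc[te.sample_ids], lab_te, [[]]
            )
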