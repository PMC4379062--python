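import numpy as np
import pytest
from hypothesis import given, strategies as st

from serumqc.qc import apply_qc
from serumqc.ratios import (
    enumerate_pairs,
    fit_ratio_model,
    fit_ratio_screen,
    pgain_threshold,
    ratio_alpha,
    screen_ratios,
    single_reference,
)
from serumqc.simulate import GeneratorConfig, generate_study


def test_pair_enumeration_counts():
    assert len(enumerate_pairs([f"m{i}" for i in range(127)])) == 8001
    assert enumerate_pairs(["a", "b"]) == [("a", "b")]
    assert len(enumerate_pairs(list("abcde"))) == 10
    assert enumerate_pairs(["x"]) == []


@given(st.integers(min_value=2, max_value=40))
def test_pair_count_formula(k):
    mets = [f"m{i:02d}" for i in range(k)]
    pairs = enumerate_pairs(mets)
    assert len(pairs) == k * (k - 1) // 2
    assert all(a < b for a, b in pairs)  # ordered, no self-pairs
    assert len(set(pairs)) == len(pairs)


def test_self_ratio_rejected(fixture_dataset):
    with pytest.raises(ValueError):
        fit_ratio_model(fixture_dataset, ("Gln", "Gln"))


@pytest.mark.parametrize(
    "n_pairs, n_terms, alpha, gain",
    [
        (8001, 3, 0.05 / 24003, 240030.0),
        (8001, 1, 0.05 / 8001, 80010.0),
        (435, 3, 0.05 / 1305, 13050.0),
    ],
)
def test_screen_thresholds(n_pairs, n_terms, alpha, gain):
    assert ratio_alpha(n_pairs, n_terms) == pytest.approx(alpha)
    assert pgain_threshold(n_pairs, n_terms) == gain


@pytest.fixture(scope="module")
def six_metabolite_run(study_qc):
    """Ratio screen over a 6-metabolite subset of the default study."""
    filt, _ = study_qc
    mets = ["Gln", "Ser", "Gly", "lysoPC(18:0)", "PC(34:2)", "PC(O-34:1)"]
    singles = single_reference(filt, mets)
    results = fit_ratio_screen(filt, mets, singles=singles)
    return filt, mets, singles, results


def test_pgain_equals_brute_force(six_metabolite_run):
    """Pipeline p-gains equal an independent recomputation, exactly."""
    filt, mets, singles, results = six_metabolite_run
    assert len(results) == 15
    for r in results:
        a, b = r.pair
        for term, p_ratio, pgain in r.terms():
            expected = min(singles.p_term[term][a], singles.p_term[term][b]) / p_ratio
            assert pgain == expected, (r.pair, term)


def test_pgain_against_statsmodels(six_metabolite_run):
    """One pair cross-checked against a statsmodels mixed-model refit."""
    from statsmodels.regression.mixed_linear_model import MixedLM

    from serumqc.association import TEMP_CENTER, TEMPERATURE_SCORE, TIME_CENTER_H

    filt, _, singles, results = six_metabolite_run
    # a cross-class pair with clearly positive donor variance, so the
    # reference fit is away from the boundary
    r = next(x for x in results if x.pair == ("PC(O-34:1)", "lysoPC(18:0)"))
    anns = [a for a in filt.annotations if a.role == "handling"]
    ids = [a.sample_id for a in anns]
    t = np.array([a.delay_h for a in anns], dtype=float) - TIME_CENTER_H
    s = np.array([TEMPERATURE_SCORE[a.temperature] for a in anns]) - TEMP_CENTER
    X = np.column_stack([np.ones_like(t), t, s])
    groups = np.array([a.participant for a in anns])
    y = np.log(filt.values.loc[ids, "PC(O-34:1)"]) - np.log(
        filt.values.loc[ids, "lysoPC(18:0)"]
    )
    ref = MixedLM(y.to_numpy(), X, groups).fit(reml=False)
    assert r.p_temp == pytest.approx(ref.pvalues[2], rel=1e-3)
    assert r.beta_temp == pytest.approx(ref.fe_params[2], rel=1e-3)


def test_symmetry_under_pair_swap(six_metabolite_run):
    filt, _, singles, _ = six_metabolite_run
    ab = fit_ratio_model(filt, ("Gln", "Ser"))
    ba = fit_ratio_model(filt, ("Ser", "Gln"))
    assert ab.p_temp == pytest.approx(ba.p_temp, rel=1e-12)
    assert ab.p_time == pytest.approx(ba.p_time, rel=1e-12)
    assert ab.p_overall == pytest.approx(ba.p_overall, rel=1e-12)
    assert ab.pgain_temp == pytest.approx(ba.pgain_temp, rel=1e-12)
    assert ab.beta_temp == pytest.approx(-ba.beta_temp, rel=1e-10)


def test_scale_invariance(study_qc):
    """Rescaling one metabolite moves only the intercept of the ratio model."""
    filt, _ = study_qc
    scaled = filt.values.copy()
    scaled["Ser"] = scaled["Ser"] * 10.0
    from serumqc.dataset import ConcentrationDataset

    ds2 = ConcentrationDataset(filt.panel, filt.annotations, scaled)
    base = fit_ratio_model(filt, ("Gln", "Ser"))
    shifted = fit_ratio_model(ds2, ("Gln", "Ser"))
    assert shifted.p_temp == pytest.approx(base.p_temp, rel=1e-6)
    assert shifted.p_overall == pytest.approx(base.p_overall, rel=1e-6)


def test_pgain_unity_when_ratio_matches_single():
    # by definition: ratio p equal to the smaller single p gives p-gain 1
    from serumqc.ratios import RatioResult, SingleReference
    import pandas as pd

    r = RatioResult(pair=("a", "b"), p_temp=1e-4)
    singles = SingleReference(
        p_term={
            "time": pd.Series({"a": 1.0, "b": 1.0}),
            "temp": pd.Series({"a": 1e-4, "b": 0.5}),
            "overall": pd.Series({"a": 1.0, "b": 1.0}),
        }
    )
    gain = min(singles.p_term["temp"]["a"], singles.p_term["temp"]["b"]) / r.p_temp
    assert gain == 1.0


def test_opposite_slope_pair_gains():
    """Opposite implanted trends are the p-gain mechanism.

    The overall (likelihood-ratio) p-gain carries the signal; the
    term-wise p-gains fluctuate because the raw-scale single models are
    themselves extremely significant for these metabolites.
    """
    hits = 0
    reps = 15
    for rep in range(reps):
        ds = generate_study(GeneratorConfig(seed=1300 + rep))
        filt, _ = apply_qc(ds)
        r = fit_ratio_model(filt, ("PC(34:2)", "lysoPC(16:0)"))
        hits += (r.pgain_overall or 0) > 10
    assert hits >= 0.9 * reps


def test_null_study_passes_nothing():
    cfg = GeneratorConfig(seed=77, profiles=[])
    ds = generate_study(cfg)
    filt, _ = apply_qc(ds)
    mets = filt.panel.ids[:30]
    results = screen_ratios(fit_ratio_screen(filt, mets))
    assert sum(bool(r.passed_screen) for r in results) == 0


def test_interaction_switch_runs(study_qc):
    filt, _ = study_qc
    r = fit_ratio_model(filt, ("Gln", "Ser"), include_interaction=True)
    assert r.converged and 0 < r.p_overall <= 1


def test_default_screen_is_selective(ratio_screen):
    n_pass = sum(bool(r.passed_screen) for r in ratio_screen)
    assert len(ratio_screen) == 8001
    assert 0 < n_pass < 1000  # a small fraction of all pairs
    # every passing pair had to clear both bars on the same term
    a = ratio_alpha(8001, 3)
    g = pgain_threshold(8001, 3)
    for r in ratio_screen:
        if r.passed_screen:
            assert any(
                p is not None and pg is not None and p < a and pg > g
                for _, p, pg in r.terms()
            )


def test_missing_cells_drop_rows(fixture_dataset):
    filt, _ = apply_qc(fixture_dataset, cv_max=np.inf, frac_min=0.0)
    r = fit_ratio_model(filt, ("PC(O-34:1)", "PC(34:2)"))
    assert r.n_dropped == 1  # the one missing fixture cell
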