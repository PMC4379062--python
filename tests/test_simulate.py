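from collections import Counter

import numpy as np
import pandas as pd
import pytest

from serumqc.classification import expected_feature
from serumqc.simulate import (
    COUPLING_POOL,
    LYSO_RISERS,
    DegradationProfile,
    GeneratorConfig,
    default_profiles,
    generate_study,
    generate_worked_fixture,
)


def test_design_counts(study):
    assert study.values.shape == (279, 163)
    roles = Counter(a.role for a in study.annotations)
    assert roles == {
        "reference": 19, "handling": 171, "ftc": 57, "pool": 20, "zero": 12,
    }
    per_participant = Counter(
        a.participant for a in study.annotations if a.role != "pool" and a.role != "zero"
    )
    assert all(n == 13 for n in per_participant.values())
    plates = {a.plate for a in study.annotations}
    assert len(plates) == 4


def test_determinism():
    a = generate_study(GeneratorConfig(seed=7))
    b = generate_study(GeneratorConfig(seed=7))
    pd.testing.assert_frame_equal(a.values, b.values)
    c = generate_study(GeneratorConfig(seed=8))
    assert not a.values.equals(c.values)


def test_null_config_has_no_condition_effects():
    cfg = GeneratorConfig(seed=3, profiles=[])
    ds = generate_study(cfg)
    sheet = ds.sheet.set_index("sample_id")
    logs = np.log(ds.values)
    handling = sheet[sheet.role == "handling"]
    # per metabolite, condition means differ only by donor/noise; compare
    # rt-36h against dry-ice-12h group means across all metabolites
    rt = logs.loc[handling[(handling.temperature == "rt") & (handling.delay_h == 36)].index]
    dry = logs.loc[handling[(handling.temperature == "dry_ice") & (handling.delay_h == 12)].index]
    diff = rt.mean() - dry.mean()
    assert np.abs(diff.mean()) < 0.02
    # per-metabolite Monte-Carlo error: sqrt(2)*sigma/sqrt(19), up to ~0.07
    # for trace species; the largest of 163 such draws stays within ~5 SE
    assert np.abs(diff).max() < 0.35


def test_profiles_dry_ice_and_lyso18_2_are_null():
    for prof in default_profiles():
        assert prof.log_shift("dry_ice", 36) == 0.0
    lyso182 = [p for p in default_profiles() if p.target == "lysoPC(18:2)"]
    assert len(lyso182) == 1 and lyso182[0].rt_slope == 0.0


def test_wet_ice_attenuated_and_delayed():
    cfg = GeneratorConfig(seed=0)
    for m in LYSO_RISERS:
        rt = cfg.expected_log_shift(m, "rt", 36)
        wet24 = cfg.expected_log_shift(m, "wet_ice", 24)
        wet36 = cfg.expected_log_shift(m, "wet_ice", 36)
        assert wet24 == 0.0  # onset after 24 h
        assert 0 < wet36 < 0.5 * rt


def test_implanted_sum_ratio_trajectory_crosses_cutoff_scale():
    cfg = GeneratorConfig(seed=0)
    r = {t: expected_feature(cfg, "tLyso/tPC", "rt", t) for t in (0, 12, 24, 36)}
    assert r[0] < r[12] < r[24] < r[36]
    assert r[12] < 0.12 < r[24]  # crossing inside the 12-24 h window
    g = {t: expected_feature(cfg, "Gln/Ser", "rt", t) for t in (0, 12, 24)}
    assert g[0] > g[12] > 4.71 > g[24]


def test_sum_ratio_expectation_matches_simulation():
    """Closed-form tLyso/tPC expectation agrees with the simulated mean."""
    cfg = GeneratorConfig(seed=0)
    expected = expected_feature(cfg, "tLyso/tPC", "rt", 36)
    baseline = expected_feature(cfg, "tLyso/tPC", "dry_ice", 0)
    vals_rt, vals_ref = [], []
    for rep in range(200):
        ds = generate_study(GeneratorConfig(seed=10_000 + rep, n_participants=2))
        sheet = ds.sheet.set_index("sample_id")
        lyso = ds.panel.ids_of_class("lyso_pc")
        pcs = ds.panel.ids_of_class("pc_aa", "pc_ae")
        ratio = ds.values[lyso].sum(axis=1) / ds.values[pcs].sum(axis=1)
        rt_ids = sheet[(sheet.temperature == "rt") & (sheet.delay_h == 36)].index
        ref_ids = sheet[sheet.role == "reference"].index
        vals_rt.extend(ratio[rt_ids])
        vals_ref.extend(ratio[ref_ids])
    # direction and rough magnitude; the closed form ignores QC-failing
    # species and rate-jitter convexity, so allow a generous band
    assert np.mean(vals_rt) > np.mean(vals_ref)
    assert abs(np.mean(vals_rt) - expected) / expected < 0.15
    assert abs(np.mean(vals_ref) - baseline) / baseline < 0.1


def test_coupling_conserves_choline_lipid_mass():
    """Total lysoPC + coupled diacyl-PC mass is condition-invariant."""
    risers = list(LYSO_RISERS)
    pool = list(COUPLING_POOL)
    totals = {"ref": [], "rt36": []}
    for rep in range(200):
        ds = generate_study(GeneratorConfig(seed=20_000 + rep, n_participants=2))
        sheet = ds.sheet.set_index("sample_id")
        mass = ds.values[risers].sum(axis=1) + ds.values[pool].sum(axis=1)
        totals["ref"].extend(mass[sheet[sheet.role == "reference"].index])
        totals["rt36"].extend(
            mass[sheet[(sheet.temperature == "rt") & (sheet.delay_h == 36)].index]
        )
    ref = np.array(totals["ref"])
    rt = np.array(totals["rt36"])
    se = np.sqrt(ref.var() / len(ref) + rt.var() / len(rt))
    assert abs(ref.mean() - rt.mean()) < 3 * se


def test_zero_and_pool_samples(study):
    sheet = study.sheet.set_index("sample_id")
    zeros = study.values.loc[sheet[sheet.role == "zero"].index]
    pools = study.values.loc[sheet[sheet.role == "pool"].index]
    cfg = GeneratorConfig(seed=1)
    implanted_fail = set(cfg.qc_fail_lod) | set(cfg.qc_fail_cv)
    for m in study.panel.ids:
        if m in implanted_fail:
            continue
        # blanks sit far below serum levels ...
        assert zeros[m].mean() < 0.05 * cfg.baseline[m]
        # ... and pools are tight
        assert pools[m].std(ddof=1) / pools[m].mean() < 0.25


def test_donors_dominate_pca(study):
    """First two principal components cluster by donor, not by condition."""
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    subj = study.subset_roles(["reference", "handling", "ftc"])
    X = np.log(subj.values.to_numpy(dtype=float))
    X = (X - X.mean(0)) / X.std(0)
    pcs = PCA(n_components=2, random_state=0).fit_transform(X)
    donors = [a.participant for a in subj.annotations]
    condition = [
        f"{a.temperature}-{a.delay_h}" if a.role == "handling" else a.role
        for a in subj.annotations
    ]
    assert silhouette_score(pcs, donors) > silhouette_score(pcs, condition)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(sd_noise=0.0)
    with pytest.raises(ValueError):
        GeneratorConfig(n_participants=0)
    with pytest.raises(ValueError):
        DegradationProfile("Gln", 0.01, wet_attenuation=1.5)
    with pytest.raises(ValueError):
        GeneratorConfig(profiles=[DegradationProfile("NotAMetabolite", 0.01)])


class TestWorkedFixture:
    def test_identical_across_calls(self):
        a, b = generate_worked_fixture(), generate_worked_fixture()
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_valid_and_complete(self, fixture_dataset):
        roles = {a.role for a in fixture_dataset.annotations}
        assert roles == {"reference", "handling", "ftc", "pool", "zero"}
        assert fixture_dataset.values.shape == (33, 6)

    def test_constructed_qc_failures(self, fixture_dataset):
        vals = fixture_dataset.values
        sheet = fixture_dataset.sheet.set_index("sample_id")
        pools = vals.loc[sheet[sheet.role == "pool"].index]
        cv = pools["PC(O-34:1)"].std(ddof=1) / pools["PC(O-34:1)"].mean()
        assert cv > 0.25  # noisy-pool metabolite
        zeros = vals.loc[sheet[sheet.role == "zero"].index]
        lod = 3 * zeros["C2"].mean()
        assert (vals["C2"].dropna() > lod).mean() < 0.5  # below-LOD metabolite
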