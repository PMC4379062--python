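"""Seeded replication experiments over the synthetic study.

Each function runs one self-contained replicate - generate a study, push it
through the relevant pipeline stages, and reduce the outcome to a small
dictionary - so that calibration properties (type-I control, signal
recovery, end-to-end classifier performance) can be estimated by repeating
over seeds.
"""

from __future__ import annotations

import numpy as np

from . import association, classification, qc, ratios
from .simulate import (
    COUPLING_POOL,
    LYSO_RISERS,
    GeneratorConfig,
    generate_study,
)

#: metabolites implanted with a strong handling response (glutamine's drift
#: is deliberately sub-threshold and is not part of this set)
IMPLANTED_SET = frozenset(
    set(LYSO_RISERS)
    | set(COUPLING_POOL)
    | {"Arg", "Gly", "Orn", "Phe", "Ser", "xLeu", "C10:2", "PC(O-34:1)"}
)


def signal_replicate(seed: int) -> dict:
    """QC + single-metabolite handling screen of one default study."""
    ds = generate_study(GeneratorConfig(seed=seed))
    filt, report = qc.apply_qc(ds)
    results = association.fit_handling_screen(filt, filt.panel.ids)
    _, summary = association.screen_metabolites(results, "handling")
    significant = set(summary["metabolite"]) if len(summary) else set()
    return {
        "n_retained": report.n_passed,
        "significant": significant,
        "implanted_recovered": IMPLANTED_SET <= significant,
        "no_flat_significant": significant <= (IMPLANTED_SET | {"Gln"}),
    }


def null_replicate(seed: int, n_metabolites: int = 30) -> dict:
    """All-null study at reduced panel width: familywise error + ratio screen."""
    full = GeneratorConfig(seed=seed, profiles=[])
    keep = [
        m
        for m in full.panel.ids
        if m not in set(full.qc_fail_lod) | set(full.qc_fail_cv)
    ][:n_metabolites]
    cfg = GeneratorConfig(
        seed=seed, profiles=[], panel=full.panel.subset(keep)
    )
    ds = generate_study(cfg)
    filt, _ = qc.apply_qc(ds)
    mets = filt.panel.ids
    results = association.fit_handling_screen(filt, mets)
    alpha = association.bonferroni_alpha(len(mets), "handling")
    any_significant = any(
        r.converged
        and min(p for p in (r.p_time, r.p_temp, r.p_interaction) if p is not None)
        < alpha
        for r in results
    )
    rr = ratios.screen_ratios(ratios.fit_ratio_screen(filt, mets))
    return {
        "n_metabolites": len(mets),
        "familywise_error": bool(any_significant),
        "n_pairs_passing": sum(bool(r.passed_screen) for r in rr),
    }


def classifier_replicate(
    seed: int,
    n_iter: int = 20,
    n_trees: int = 501,
    m_try: int = 80,
    top_k: int = 10,
) -> dict:
    """Full two-stage classifier on one default study (reduced-scale RF)."""
    cfg = GeneratorConfig(seed=seed)
    ds = generate_study(cfg)
    filt, report = qc.apply_qc(ds)
    singles = ratios.single_reference(filt, filt.panel.ids)
    rr = ratios.screen_ratios(
        ratios.fit_ratio_screen(filt, filt.panel.ids, singles=singles)
    )
    passing = [r.pair for r in rr if r.passed_screen]
    feats = classification.build_feature_table(filt, passing)
    train, test = classification.split_participants(filt.participants())
    tr = filt.subset_participants(train)
    te = filt.subset_participants(test)
    f_tr, f_te = feats.loc[tr.sample_ids], feats.loc[te.sample_ids]
    rank = classification.rank_variables(
        f_tr,
        classification.label_samples(tr, "stringent"),
        n_iter=n_iter,
        n_trees=n_trees,
        m_try=m_try,
        seed=seed,
    )
    top = classification.order_tree_candidates(rank.top(top_k))
    lab_tr = classification.label_samples(tr, "non_stringent")
    lab_te = classification.label_samples(te, "non_stringent")
    tree = classification.fit_tree(f_tr[top], lab_tr)
    rate_tr, err_tr, n_tr = classification.misclassification_rate(
        tree.predict(f_tr[top]), lab_tr
    )
    rate_te, err_te, n_te = classification.misclassification_rate(
        tree.predict(f_te[top]), lab_te
    )
    held = classification.apply_to_heldout(tree, feats, filt)
    wet = held[held.temperature == "wet_ice"]
    rt12 = held[(held.temperature == "rt") & (held.delay_h == 12)]
    cut_ok = all(
        classification.transition_band(cfg, var)[0]
        <= cut
        <= classification.transition_band(cfg, var)[1]
        for var, cut in tree.splits
    )
    return {
        "n_retained": report.n_passed,
        "n_passing_pairs": len(passing),
        "n_variables": feats.shape[1],
        "top_variables": top,
        "tree_splits": tree.splits,
        "rule": tree.rule_text(),
        "train_rate": rate_tr,
        "train_errors": err_tr,
        "test_rate": rate_te,
        "test_errors": err_te,
        "n_test_labelled": n_te,
        "wet_all_good": bool((wet["frac_good"] == 1.0).all()) and len(wet) == 3,
        "wet_frac_good": float(
            wet["n_good"].sum() / max(wet["n_good"].sum() + wet["n_bad"].sum(), 1)
        ),
        "frac_rt12_good": float(rt12["frac_good"].iloc[0]) if len(rt12) else np.nan,
        "cutoffs_in_band": bool(cut_ok),
    }
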