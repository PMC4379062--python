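"""End-to-end orchestration: simulate -> qc -> screens -> ratios -> classifier.

A :class:`RunConfig` (flat keyed YAML, unknown keys rejected) drives all
stages; every artifact is written as CSV (trees as JSON) together with a
human-readable markdown report.  All randomness flows from one master seed,
so a run is reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import association, classification, qc, ratios
from .dataset import read_dataset, write_dataset
from .panel import build_p150_panel
from .simulate import GeneratorConfig, generate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    # either simulate ...
    simulate: bool = True
    n_participants: int = 19
    # ... or read user data
    concentration_table: Optional[str] = None
    sample_sheet: Optional[str] = None
    # qc
    cv_max: float = 0.25
    frac_min: float = 0.5
    # classifier
    train_ids: Optional[list[str]] = None
    test_ids: Optional[list[str]] = None
    n_iter: int = 20
    n_trees: int = 501
    m_try: int = 80
    top_k: int = 10
    min_samples_leaf: int = 5
    ccp_alpha: float = 0.01

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.cv_max <= 0 or not 0 <= self.frac_min <= 1:
            raise ValueError("invalid QC thresholds")
        if min(self.n_iter, self.n_trees, self.m_try, self.top_k) <= 0:
            raise ValueError("classifier settings must be positive")
        if not self.simulate and not (self.concentration_table and self.sample_sheet):
            raise ValueError("user-data mode needs concentration_table and sample_sheet")


@dataclass
class StageRecord:
    stage: str
    counts: dict
    warnings: list[str] = field(default_factory=list)


@dataclass
class RunReport:
    config: RunConfig
    stages: list[StageRecord]

    def counts(self, stage: str) -> dict:
        for s in self.stages:
            if s.stage == stage:
                return s.counts
        raise KeyError(stage)

    def check_consistency(self) -> None:
        """Cross-stage count identities; violations are hard failures."""
        m = self.counts("qc")["n_retained"]
        n_pairs = self.counts("ratios")["n_pairs"]
        if n_pairs != m * (m - 1) // 2:
            raise AssertionError("ratio pair count inconsistent with retained metabolites")
        lab = self.counts("classify")
        if lab["n_train_good"] + lab["n_train_bad"] != 6 * lab["n_train_participants"]:
            raise AssertionError("non-stringent training label count inconsistent")

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": dataclasses.asdict(self.config),
                "stages": [dataclasses.asdict(s) for s in self.stages],
            },
            indent=2,
            default=str,
        )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and write artifacts under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[StageRecord] = []

    # -- data ---------------------------------------------------------------
    if config.simulate:
        gen = GeneratorConfig(n_participants=config.n_participants, seed=config.seed)
        ds = generate_study(gen)
        write_dataset(ds, out / "concentrations.csv", out / "samples.csv")
    else:
        ds = read_dataset(
            config.concentration_table, config.sample_sheet, build_p150_panel()
        )
    stages.append(
        StageRecord(
            "data",
            {
                "n_samples": len(ds.values),
                "n_metabolites": len(ds.panel),
                "n_participants": len(ds.participants()),
            },
        )
    )

    # -- qc -----------------------------------------------------------------
    filt, report = qc.apply_qc(ds, cv_max=config.cv_max, frac_min=config.frac_min)
    report.to_csv(out / "qc_report.csv")
    stages.append(
        StageRecord(
            "qc",
            {
                "n_retained": report.n_passed,
                "n_failed_cv": int(report.table["fail_reasons"].str.contains("cv").sum()),
                "n_failed_lod": int(report.table["fail_reasons"].str.contains("lod").sum()),
            },
        )
    )
    mets = filt.panel.ids
    M = len(mets)

    # -- single-metabolite screens ------------------------------------------
    handl = association.fit_handling_screen(filt, mets)
    dec_h, tiers = association.screen_metabolites(handl, "handling")
    association.results_table(handl, filt.panel).to_csv(
        out / "handling_models.csv", index=False
    )
    tiers.to_csv(out / "handling_significant.csv", index=False)
    ftc = association.fit_ftc_screen(filt, mets)
    dec_f, ftc_sig = association.screen_metabolites(ftc, "ftc")
    association.results_table(ftc, filt.panel).to_csv(out / "ftc_models.csv", index=False)
    stages.append(
        StageRecord(
            "association",
            {
                "alpha_handling": association.bonferroni_alpha(M, "handling"),
                "alpha_ftc": association.bonferroni_alpha(M, "ftc"),
                "n_temp_significant": len(tiers),
                "n_ftc_significant": len(ftc_sig),
                "tiers": tiers["tier"].value_counts().to_dict() if len(tiers) else {},
            },
        )
    )

    # -- ratio screens -------------------------------------------------------
    rr = ratios.screen_ratios(ratios.fit_ratio_screen(filt, mets))
    ratios.ratio_table(rr).to_csv(out / "ratio_models.csv", index=False)
    passing = [r.pair for r in rr if r.passed_screen]
    rr_ftc = ratios.screen_ratios(ratios.fit_ratio_screen(filt, mets, scheme="ftc"))
    n_pass_ftc = sum(bool(r.passed_screen) for r in rr_ftc)
    stages.append(
        StageRecord(
            "ratios",
            {
                "n_pairs": len(rr),
                "alpha_ratio": ratios.ratio_alpha(len(rr), 3),
                "pgain_threshold": ratios.pgain_threshold(len(rr), 3),
                "n_passing": len(passing),
                "n_pairs_ftc": len(rr_ftc),
                "pgain_threshold_ftc": ratios.pgain_threshold(len(rr_ftc), 1),
                "n_passing_ftc": n_pass_ftc,
            },
        )
    )

    # -- classifier ----------------------------------------------------------
    feats = classification.build_feature_table(filt, passing)
    train, test = classification.split_participants(
        filt.participants(), config.train_ids, config.test_ids
    )
    tr, te = filt.subset_participants(train), filt.subset_participants(test)
    f_tr, f_te = feats.loc[tr.sample_ids], feats.loc[te.sample_ids]
    rank = classification.rank_variables(
        f_tr,
        classification.label_samples(tr, "stringent"),
        n_iter=config.n_iter,
        n_trees=config.n_trees,
        m_try=config.m_try,
        seed=config.seed,
    )
    rank.importance.to_csv(out / "importance.csv", header=["mean_decrease_accuracy"])
    top = classification.order_tree_candidates(rank.top(config.top_k))
    lab_tr = classification.label_samples(tr, "non_stringent")
    lab_te = classification.label_samples(te, "non_stringent")
    tree = classification.fit_tree(
        f_tr[top], lab_tr,
        min_samples_leaf=config.min_samples_leaf,
        ccp_alpha=config.ccp_alpha,
    )
    (out / "tree.json").write_text(tree.to_json())
    rate_tr, err_tr, n_tr = classification.misclassification_rate(
        tree.predict(f_tr[top]), lab_tr
    )
    rate_te, err_te, n_te = classification.misclassification_rate(
        tree.predict(f_te[top]), lab_te
    )
    held = classification.apply_to_heldout(tree, feats, filt)
    held.to_csv(out / "heldout_conditions.csv", index=False)
    pred = tree.predict(feats[tree.variables] if tree.variables else feats)
    pred.to_frame().to_csv(out / "classifications.csv", index_label="sample_id")
    # rule robustness across variable choices (one tree per subset)
    subsets: list[list[str]] = [list(top), list(top[:5])]
    subsets += [[v] for v in top[:3]]
    amino_ids = set(filt.panel.ids_of_class("amino_acid"))
    lyso_vars = [v for v in top if "lysoPC" in v or v.startswith("tLyso")]
    amino_vars = [
        v for v in top
        if v not in classification.SUM_RATIOS
        and all(part in amino_ids for part in v.split("/"))
    ]
    if lyso_vars and amino_vars:
        subsets.append([lyso_vars[0], amino_vars[0]])
    robust = classification.robustness_scan(
        f_tr, lab_tr, f_te, lab_te, subsets,
        min_samples_leaf=config.min_samples_leaf, ccp_alpha=config.ccp_alpha,
    )
    robust.to_csv(out / "robustness.csv", index=False)
    lab_count = classification.label_series(lab_tr).value_counts().to_dict()
    stages.append(
        StageRecord(
            "classify",
            {
                "n_variables": feats.shape[1],
                "n_train_participants": len(train),
                "n_test_participants": len(test),
                "n_train_good": int(lab_count.get("good", 0)),
                "n_train_bad": int(lab_count.get("bad", 0)),
                "top_variables": top,
                "rule": tree.rule_text(),
                "train_rate": rate_tr,
                "train_errors": err_tr,
                "n_train_labelled": n_tr,
                "test_rate": rate_te,
                "test_errors": err_te,
                "n_test_labelled": n_te,
                "heldout": held.to_dict("records"),
            },
        )
    )

    report_obj = RunReport(config=config, stages=stages)
    report_obj.check_consistency()
    (out / "report.json").write_text(report_obj.to_json())
    (out / "report.md").write_text(make_report(report_obj))
    return report_obj


def make_report(report: RunReport) -> str:
    """Plain-markdown run summary mirroring the analysis narrative."""
    d = report.counts("data")
    q = report.counts("qc")
    a = report.counts("association")
    r = report.counts("ratios")
    c = report.counts("classify")
    lines = [
        "# Serum pre-analytical quality run report",
        "",
        f"- samples: {d['n_samples']} ({d['n_participants']} participants), "
        f"metabolites measured: {d['n_metabolites']}",
        "",
        "## Quality control",
        f"- retained {q['n_retained']} metabolites "
        f"(failed CV: {q['n_failed_cv']}, failed LOD: {q['n_failed_lod']})",
        "",
        "## Single-metabolite screens",
        f"- handling screen alpha {a['alpha_handling']:.3g}: "
        f"{a['n_temp_significant']} metabolites temperature-significant "
        f"(tiers: {a['tiers']})",
        f"- freeze-thaw screen alpha {a['alpha_ftc']:.3g}: "
        f"{a['n_ftc_significant']} significant",
        "",
        "## Ratio screen",
        f"- {r['n_pairs']} pairs; alpha {r['alpha_ratio']:.3g}, "
        f"p-gain threshold {r['pgain_threshold']:.0f}: {r['n_passing']} passing",
        f"- freeze-thaw ratios: {r['n_passing_ftc']} of {r['n_pairs_ftc']} passed "
        f"(p-gain threshold {r['pgain_threshold_ftc']:.0f})",
        "",
        "## Classifier",
        f"- candidate variables: {c['n_variables']} "
        f"({c['n_train_good']} good / {c['n_train_bad']} bad training labels, "
        f"{c['n_train_participants']}/{c['n_test_participants']} participant split)",
        f"- top variables: {', '.join(c['top_variables'])}",
        f"- rule: {c['rule']}",
        f"- misclassification: training {c['train_rate']:.3f} "
        f"({c['train_errors']}/{c['n_train_labelled']}), "
        f"test {c['test_rate']:.3f} ({c['test_errors']}/{c['n_test_labelled']})",
        "",
        "## Held-out handling conditions",
    ]
    for row in c["heldout"]:
        lines.append(
            f"- {row['temperature']} {row['delay_h']} h: "
            f"{row['n_good']} good / {row['n_bad']} bad "
            f"({100 * row['frac_good']:.0f}% good)"
        )
    if not c["heldout"]:
        lines.append("- none")
    lines.append("")
    return "\n".join(lines)
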