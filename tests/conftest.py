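import numpy as np
import pytest

from serumqc.classification import (
    build_feature_table,
    label_samples,
    order_tree_candidates,
    rank_variables,
    split_participants,
)
from serumqc.qc import apply_qc
from serumqc.ratios import fit_ratio_screen, screen_ratios, single_reference
from serumqc.simulate import GeneratorConfig, generate_study, generate_worked_fixture

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def fixture_dataset():
    """Tiny hand-written 2-participant, 6-metabolite dataset."""
    return generate_worked_fixture()


@pytest.fixture(scope="session")
def study():
    """One default synthetic study (seed 1)."""
    return generate_study(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def study_qc(study):
    """(filtered dataset, QC report) for the default study."""
    return apply_qc(study)


@pytest.fixture(scope="session")
def ratio_screen(study_qc):
    """Screened all-pairs ratio results for the default study."""
    filt, _ = study_qc
    singles = single_reference(filt, filt.panel.ids)
    return screen_ratios(fit_ratio_screen(filt, filt.panel.ids, singles=singles))


@pytest.fixture(scope="session")
def classifier_inputs(study_qc, ratio_screen):
    """Feature table, split datasets and RF ranking for the default study.

    Shared across classification tests; the ranking uses the reduced-scale
    forest settings.
    """
    filt, _ = study_qc
    passing = [r.pair for r in ratio_screen if r.passed_screen]
    feats = build_feature_table(filt, passing)
    train, test = split_participants(filt.participants())
    tr = filt.subset_participants(train)
    te = filt.subset_participants(test)
    rank = rank_variables(
        feats.loc[tr.sample_ids],
        label_samples(tr, "stringent"),
        n_iter=20,
        n_trees=501,
        seed=1,
    )
    top = order_tree_candidates(rank.top(10))
    return {
        "filtered": filt,
        "features": feats,
        "train": tr,
        "test": te,
        "rank": rank,
        "top10": top,
    }
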