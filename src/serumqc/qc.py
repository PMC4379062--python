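"""Kit-level quality control of the measured metabolites.

Two criteria, applied per metabolite:

1. the coefficient of variation over the pooled-serum replicates must be
   *smaller than* 25% (strict), and
2. at least 50% of all measured concentrations must lie *strictly above*
   the limit of detection, defined as 3 x the mean of the blank (zero)
   samples.

Metabolites failing either criterion are dropped; pool and zero rows are
then removed from the filtered dataset, which is what the downstream
statistics operate on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ConcentrationDataset

LOD_FACTOR = 3.0


class QCError(ValueError):
    pass


@dataclass
class QCReport:
    """Per-metabolite QC statistics and pass/fail decisions."""

    table: pd.DataFrame  # index metabolite; lod, pool_cv, frac_above_lod, passed, fail_reasons
    cv_max: float
    frac_min: float

    @property
    def passed_ids(self) -> list[str]:
        return self.table.index[self.table["passed"]].tolist()

    @property
    def n_passed(self) -> int:
        return int(self.table["passed"].sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="metabolite")


def compute_lod(dataset: ConcentrationDataset) -> pd.Series:
    """Limit of detection per metabolite: 3 x mean of the zero samples.

    Missing cells are excluded from the mean; a metabolite whose zero
    measurements are all missing gets an undefined (NaN) LOD.
    """
    zero_ids = [a.sample_id for a in dataset.annotations if a.role == "zero"]
    if not zero_ids:
        raise QCError("dataset contains no zero samples")
    lod = LOD_FACTOR * dataset.values.loc[zero_ids].mean(axis=0, skipna=True)
    lod.name = "lod"
    return lod


def compute_pool_cv(dataset: ConcentrationDataset) -> pd.Series:
    """Coefficient of variation over the pool samples (sample SD / mean).

    Undefined (NaN) when the pool mean is zero; treated as a failure by
    :func:`apply_qc`.
    """
    pool_ids = [a.sample_id for a in dataset.annotations if a.role == "pool"]
    if len(pool_ids) < 2:
        raise QCError("need at least two pool samples to estimate a CV")
    pools = dataset.values.loc[pool_ids]
    mean = pools.mean(axis=0, skipna=True)
    sd = pools.std(axis=0, ddof=1, skipna=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    cv[mean == 0] = np.nan
    cv.name = "pool_cv"
    return cv


def apply_qc(
    dataset: ConcentrationDataset,
    cv_max: float = 0.25,
    frac_min: float = 0.5,
    subject_only_lod_frac: bool = False,
) -> tuple[ConcentrationDataset, QCReport]:
    """Filter the panel to metabolites passing both QC criteria.

    Parameters
    ----------
    cv_max : float
        Pool-CV bound; the comparison is strict (``cv < cv_max``).
    frac_min : float
        Minimum fraction of measured concentrations strictly above the LOD;
        the comparison is inclusive (``frac >= frac_min``).
    subject_only_lod_frac : bool
        When True, the above-LOD fraction is computed over subject samples
        only instead of every measured sample (subject, pool and zero).

    Returns
    -------
    (filtered, report)
        ``filtered`` keeps only passing metabolites and drops the pool and
        zero rows; ``report`` holds the per-metabolite statistics.
    """
    lod = compute_lod(dataset)
    cv = compute_pool_cv(dataset)

    if subject_only_lod_frac:
        ids = [
            a.sample_id
            for a in dataset.annotations
            if a.role in ("reference", "handling", "ftc")
        ]
        vals = dataset.values.loc[ids]
    else:
        vals = dataset.values
    above = vals.gt(lod, axis=1)
    measured = vals.notna().sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = above.sum(axis=0) / measured
    frac[measured == 0] = np.nan
    # undefined LOD -> no cell can be shown to exceed it
    frac[lod.isna()] = 0.0
    frac.name = "frac_above_lod"

    cv_ok = cv.notna() & (cv < cv_max)
    lod_ok = frac.notna() & (frac >= frac_min)
    passed = cv_ok & lod_ok
    reasons = pd.Series(
        [
            ";".join(r for r, bad in (("cv", not c), ("lod", not l)) if bad)
            for c, l in zip(cv_ok, lod_ok)
        ],
        index=dataset.values.columns,
        name="fail_reasons",
    )
    table = pd.concat([lod, cv, frac], axis=1)
    table["passed"] = passed
    table["fail_reasons"] = reasons
    report = QCReport(table=table, cv_max=cv_max, frac_min=frac_min)

    filtered = dataset.subset_metabolites(report.passed_ids).subset_roles(
        ("reference", "handling", "ftc")
    )
    return filtered, report
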