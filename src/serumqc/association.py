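"""Single-metabolite mixed-effects screening.

Handling screen: for each metabolite, concentration (uM, raw scale) is
regressed on storage delay (hours), storage temperature and their
interaction, with a random intercept per study participant.  Temperature
enters as an ordered score (dry ice = 0, wet ice = 1, room temperature = 2),
matching a single reported temperature coefficient; a two-dummy factor
coding is available for sensitivity analysis.  Reference aliquots (delay 0)
carry no storage temperature and are excluded.

Freeze-thaw screen: concentration regressed on the total number of thaws
(1..4) over reference + freeze-thaw aliquots.

Both screens are Bonferroni-controlled: alpha / (3 M) for the handling
screen (three coefficients per model) and alpha / M for the freeze-thaw
screen, with M the number of QC-retained metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import ConcentrationDataset
from .lmm import LMMFit, fit_random_intercept

TEMPERATURE_SCORE = {"dry_ice": 0.0, "wet_ice": 1.0, "rt": 2.0}

#: design midpoints of the storage delays {12, 24, 36} h and the
#: temperature score {0, 1, 2}
TIME_CENTER_H = 24.0
TEMP_CENTER = 1.0

Scheme = Literal["handling", "ftc"]


@dataclass
class ModelResult:
    """Fixed-effect estimates and Wald p-values for one metabolite."""

    metabolite: str
    scheme: Scheme
    p_time: Optional[float] = None
    p_temp: Optional[float] = None
    p_interaction: Optional[float] = None
    p_ftc: Optional[float] = None
    beta_time: Optional[float] = None
    beta_temp: Optional[float] = None
    beta_interaction: Optional[float] = None
    beta_ftc: Optional[float] = None
    loglik: Optional[float] = None
    converged: bool = True

    def direction(self, alpha: float = 0.05) -> str:
        """Sign of the temperature-associated trend, if significant."""
        if self.scheme == "handling":
            p, beta = self.p_temp, self.beta_temp
        else:
            p, beta = self.p_ftc, self.beta_ftc
        if p is None or beta is None or not np.isfinite(p) or p >= alpha:
            return "none"
        return "+" if beta > 0 else "-"


@dataclass
class SignificanceDecision:
    metabolite: str
    significant_terms: tuple[str, ...]
    alpha_adj: float
    direction: str


def _handling_design(
    dataset: ConcentrationDataset, temperature_coding: str = "score"
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    anns = [a for a in dataset.annotations if a.role == "handling"]
    if len({a.participant for a in anns}) < 2:
        raise ValueError("handling screen needs handling samples from >= 2 participants")
    ids = [a.sample_id for a in anns]
    t = np.array([float(a.delay_h) for a in anns])
    # centring both predictors makes the marginal coefficients the average
    # trends over the design rather than extrapolations to delay zero /
    # dry ice, where the implanted effects vanish by construction
    tc = t - TIME_CENTER_H
    groups = np.array([a.participant for a in anns])
    if temperature_coding == "score":
        s = np.array([TEMPERATURE_SCORE[a.temperature] for a in anns])
        sc = s - TEMP_CENTER
        X = np.column_stack([np.ones_like(t), tc, sc, tc * sc])
        names = ["intercept", "time", "temp", "interaction"]
    elif temperature_coding == "factor":
        wet = np.array([1.0 if a.temperature == "wet_ice" else 0.0 for a in anns])
        rt = np.array([1.0 if a.temperature == "rt" else 0.0 for a in anns])
        X = np.column_stack([np.ones_like(t), tc, wet, rt, tc * wet, tc * rt])
        names = ["intercept", "time", "temp_wet", "temp_rt", "int_wet", "int_rt"]
    else:
        raise ValueError(f"unknown temperature coding {temperature_coding!r}")
    return X, groups, ids, names


def _ftc_design(dataset: ConcentrationDataset) -> tuple[np.ndarray, np.ndarray, list[str]]:
    anns = [a for a in dataset.annotations if a.role in ("reference", "ftc")]
    thaws = np.array([float(a.thaw_count) for a in anns])
    if len(anns) == 0 or thaws.min() == thaws.max():
        raise ValueError("freeze-thaw screen needs reference and freeze-thaw samples")
    X = np.column_stack([np.ones_like(thaws), thaws])
    groups = np.array([a.participant for a in anns])
    ids = [a.sample_id for a in anns]
    return X, groups, ids


def _fit_matrix(
    dataset: ConcentrationDataset,
    metabolites: Sequence[str],
    X: np.ndarray,
    groups: np.ndarray,
    ids: list[str],
) -> tuple[LMMFit, np.ndarray]:
    """Fit all complete-data metabolites in one vectorized call.

    Metabolites with missing cells are fitted individually on their
    complete rows.  Returns the fit of the complete block plus an index
    array mapping metabolites to block columns (-1 = fitted separately).
    """
    Y = dataset.values.loc[ids, list(metabolites)].to_numpy(dtype=float)
    complete = ~np.isnan(Y).any(axis=0)
    fit = fit_random_intercept(Y[:, complete], X, groups) if complete.any() else None
    col = np.full(len(metabolites), -1)
    col[complete] = np.arange(complete.sum())
    return fit, col


def fit_handling_screen(
    dataset: ConcentrationDataset,
    metabolites: Optional[Sequence[str]] = None,
    temperature_coding: str = "score",
) -> list[ModelResult]:
    """Fit the handling model for every (retained) metabolite."""
    mets = list(metabolites) if metabolites is not None else dataset.panel.ids
    X, groups, ids, names = _handling_design(dataset, temperature_coding)
    results: list[ModelResult] = []
    fit, col = _fit_matrix(dataset, mets, X, groups, ids)
    for j, m in enumerate(mets):
        if col[j] >= 0:
            results.append(_handling_result(m, fit, int(col[j]), names))
        else:
            y = dataset.values.loc[ids, m].to_numpy(dtype=float)
            keep = ~np.isnan(y)
            if keep.sum() < X.shape[1] + 2 or np.nanstd(y) == 0:
                results.append(ModelResult(m, "handling", converged=False))
                continue
            f1 = fit_random_intercept(y[keep], X[keep], groups[keep])
            results.append(_handling_result(m, f1, 0, names))
    return results


def _handling_result(m: str, fit: LMMFit, j: int, names: list[str]) -> ModelResult:
    if not fit.converged[j]:
        # degenerate (e.g. zero-variance) outcome: coefficients are still
        # well defined, p-values are not
        beta = fit.beta[:, j]
        kw = {}
        if np.all(np.isfinite(beta)) and "temp" in names:
            kw = dict(
                beta_time=float(beta[names.index("time")]),
                beta_temp=float(beta[names.index("temp")]),
                beta_interaction=float(beta[names.index("interaction")]),
            )
        return ModelResult(m, "handling", converged=False, **kw)
    get = lambda nm: names.index(nm)
    if "temp" in names:  # score coding
        return ModelResult(
            m, "handling",
            p_time=float(fit.wald_p[get("time"), j]),
            p_temp=float(fit.wald_p[get("temp"), j]),
            p_interaction=float(fit.wald_p[get("interaction"), j]),
            beta_time=float(fit.beta[get("time"), j]),
            beta_temp=float(fit.beta[get("temp"), j]),
            beta_interaction=float(fit.beta[get("interaction"), j]),
            loglik=float(fit.loglik[j]),
        )
    # factor coding: joint two-df Wald chi-square per term
    from scipy import stats

    def joint(t1: str, t2: str) -> tuple[float, float]:
        z = np.array([fit.beta[get(t1), j] / fit.se[get(t1), j],
                      fit.beta[get(t2), j] / fit.se[get(t2), j]])
        return float(stats.chi2.sf(np.sum(z**2), 2)), float(
            fit.beta[get(t2), j]
        )
    p_temp, b_temp = joint("temp_wet", "temp_rt")
    p_int, b_int = joint("int_wet", "int_rt")
    return ModelResult(
        m, "handling",
        p_time=float(fit.wald_p[get("time"), j]),
        p_temp=p_temp, p_interaction=p_int,
        beta_time=float(fit.beta[get("time"), j]),
        beta_temp=b_temp, beta_interaction=b_int,
        loglik=float(fit.loglik[j]),
    )


def fit_handling_model(dataset: ConcentrationDataset, metabolite: str, **kw) -> ModelResult:
    """Handling-screen fit for a single metabolite."""
    return fit_handling_screen(dataset, [metabolite], **kw)[0]


def fit_ftc_screen(
    dataset: ConcentrationDataset, metabolites: Optional[Sequence[str]] = None
) -> list[ModelResult]:
    """Fit the freeze-thaw model for every (retained) metabolite."""
    mets = list(metabolites) if metabolites is not None else dataset.panel.ids
    X, groups, ids = _ftc_design(dataset)
    fit, col = _fit_matrix(dataset, mets, X, groups, ids)
    results = []
    for j, m in enumerate(mets):
        if col[j] >= 0:
            f, jj = fit, int(col[j])
        else:
            y = dataset.values.loc[ids, m].to_numpy(dtype=float)
            keep = ~np.isnan(y)
            if keep.sum() < 4 or np.nanstd(y) == 0:
                results.append(ModelResult(m, "ftc", converged=False))
                continue
            f, jj = fit_random_intercept(y[keep], X[keep], groups[keep]), 0
        if not f.converged[jj]:
            beta = f.beta[1, jj]
            results.append(
                ModelResult(
                    m, "ftc", converged=False,
                    beta_ftc=float(beta) if np.isfinite(beta) else None,
                )
            )
            continue
        results.append(
            ModelResult(
                m, "ftc",
                p_ftc=float(f.wald_p[1, jj]),
                beta_ftc=float(f.beta[1, jj]),
                loglik=float(f.loglik[jj]),
            )
        )
    return results


def fit_ftc_model(dataset: ConcentrationDataset, metabolite: str) -> ModelResult:
    return fit_ftc_screen(dataset, [metabolite])[0]


# ---------------------------------------------------------------------------


def bonferroni_alpha(n_models: int, scheme: Scheme = "handling", alpha: float = 0.05) -> float:
    """Adjusted per-test threshold: alpha/(3 M) for handling, alpha/M for ftc."""
    n_terms = 3 if scheme == "handling" else 1
    return alpha / (n_terms * n_models)


def screen_metabolites(
    results: Sequence[ModelResult], scheme: Scheme = "handling", alpha: float = 0.05
) -> tuple[list[SignificanceDecision], pd.DataFrame]:
    """Bonferroni screen + tiered summary of the model results.

    The summary tiers mirror the reporting convention for the handling
    screen: metabolites significant for temperature only, for temperature
    and the interaction, or for time, temperature and the interaction.
    """
    results = [r for r in results if r.converged]
    M = len(results)
    decisions: list[SignificanceDecision] = []
    rows = []
    if M == 0:
        cols = ["metabolite", "p_time", "p_temp", "p_interaction", "tier", "direction"]
        return decisions, pd.DataFrame(columns=cols)
    a = bonferroni_alpha(M, scheme, alpha)
    for r in results:
        if scheme == "handling":
            terms = tuple(
                t
                for t, p in (
                    ("time", r.p_time),
                    ("temp", r.p_temp),
                    ("interaction", r.p_interaction),
                )
                if p is not None and p < a
            )
        else:
            terms = ("ftc",) if (r.p_ftc is not None and r.p_ftc < a) else ()
        direction = r.direction(a)
        decisions.append(SignificanceDecision(r.metabolite, terms, a, direction))
        if scheme == "handling" and "temp" in terms:
            if "time" in terms and "interaction" in terms:
                tier = "time+temp+interaction"
            elif "interaction" in terms:
                tier = "temp+interaction"
            else:
                tier = "temp"
            rows.append(
                {
                    "metabolite": r.metabolite,
                    "p_time": r.p_time,
                    "p_temp": r.p_temp,
                    "p_interaction": r.p_interaction,
                    "tier": tier,
                    "direction": direction,
                }
            )
        elif scheme == "ftc" and terms:
            rows.append(
                {"metabolite": r.metabolite, "p_ftc": r.p_ftc, "tier": "ftc",
                 "direction": direction}
            )
    summary = pd.DataFrame(rows)
    return decisions, summary


def results_table(results: Sequence[ModelResult], panel=None) -> pd.DataFrame:
    """Flat per-metabolite results table (CSV-friendly)."""
    rows = []
    for r in results:
        row = {"metabolite": r.metabolite, "converged": r.converged}
        if panel is not None and r.metabolite in panel:
            met = panel[r.metabolite]
            row["full_name"] = met.full_name
            row["mclass"] = met.mclass
        if r.scheme == "handling":
            row.update(
                p_time=r.p_time, p_temp=r.p_temp, p_interaction=r.p_interaction,
                beta_time=r.beta_time, beta_temp=r.beta_temp,
                beta_interaction=r.beta_interaction,
            )
        else:
            row.update(p_ftc=r.p_ftc, beta_ftc=r.beta_ftc)
        rows.append(row)
    return pd.DataFrame(rows)
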