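"""All-pairs metabolite-ratio models and the p-gain screen.

For every unordered pair of retained metabolites the outcome
``log c1 - log c2`` is regressed on storage delay and temperature (no
interaction) with a participant random intercept; an 'overall' p-value
comes from the likelihood-ratio test of the fitted model against the
intercept(+random intercept) null.  The p-gain of a term is the smaller of
the two single-metabolite p-values for that term divided by the ratio
model's p-value; large p-gains flag pairs that carry information beyond
either metabolite alone, the signature of a shared degradation process.

Screen thresholds scale with the number of pairs K(K-1)/2 and tested terms:
p < alpha/(n_terms * n_pairs) together with p-gain > 10 * n_terms * n_pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .association import TEMPERATURE_SCORE, TEMP_CENTER, TIME_CENTER_H
from .dataset import ConcentrationDataset
from .lmm import fit_random_intercept, likelihood_ratio_p

Scheme = Literal["handling", "ftc"]


def enumerate_pairs(metabolites: Sequence[str]) -> list[tuple[str, str]]:
    """All K(K-1)/2 unordered pairs in lexicographic order."""
    return list(itertools.combinations(sorted(metabolites), 2))


def ratio_alpha(n_pairs: int, n_terms: int = 3, alpha: float = 0.05) -> float:
    return alpha / (n_terms * n_pairs)


def pgain_threshold(n_pairs: int, n_terms: int = 3) -> float:
    return 10.0 * n_terms * n_pairs


@dataclass
class RatioResult:
    """Ratio-model p-values and p-gains for one metabolite pair."""

    pair: tuple[str, str]
    scheme: Scheme = "handling"
    p_time: Optional[float] = None
    p_temp: Optional[float] = None
    p_ftc: Optional[float] = None
    p_overall: Optional[float] = None
    pgain_time: Optional[float] = None
    pgain_temp: Optional[float] = None
    pgain_ftc: Optional[float] = None
    pgain_overall: Optional[float] = None
    beta_time: Optional[float] = None
    beta_temp: Optional[float] = None
    beta_ftc: Optional[float] = None
    passed_screen: Optional[bool] = None
    converged: bool = True
    n_dropped: int = 0

    def terms(self) -> list[tuple[str, Optional[float], Optional[float]]]:
        if self.scheme == "handling":
            return [
                ("time", self.p_time, self.pgain_time),
                ("temp", self.p_temp, self.pgain_temp),
                ("overall", self.p_overall, self.pgain_overall),
            ]
        return [
            ("ftc", self.p_ftc, self.pgain_ftc),
            ("overall", self.p_overall, self.pgain_overall),
        ]


@dataclass
class SingleReference:
    """Single-metabolite p-values entering the p-gain denominator's rival."""

    p_term: dict[str, pd.Series]  # term -> per-metabolite p (raw-scale fits)


def _design(dataset: ConcentrationDataset, scheme: Scheme):
    if scheme == "handling":
        anns = [a for a in dataset.annotations if a.role == "handling"]
        t = np.array([float(a.delay_h) for a in anns]) - TIME_CENTER_H
        s = np.array([TEMPERATURE_SCORE[a.temperature] for a in anns]) - TEMP_CENTER
        X = np.column_stack([np.ones_like(t), t, s])
        terms = {"time": 1, "temp": 2}
    else:
        anns = [a for a in dataset.annotations if a.role in ("reference", "ftc")]
        th = np.array([float(a.thaw_count) for a in anns])
        X = np.column_stack([np.ones_like(th), th])
        terms = {"ftc": 1}
    groups = np.array([a.participant for a in anns])
    ids = [a.sample_id for a in anns]
    return X, groups, ids, terms


def single_reference(
    dataset: ConcentrationDataset,
    metabolites: Sequence[str],
    scheme: Scheme = "handling",
) -> SingleReference:
    """Per-metabolite single-model p-values used by the p-gain.

    Term p-values come from the single-metabolite screen (raw
    concentrations; for handling this is the time+temperature+interaction
    model).  The single 'overall' p is the likelihood-ratio test of the
    raw-concentration time+temperature model (no interaction) against the
    intercept null, mirroring the ratio model's overall test.
    """
    from .association import fit_ftc_screen, fit_handling_screen

    mets = list(metabolites)
    X, groups, ids, terms = _design(dataset, scheme)
    p_term: dict[str, pd.Series] = {}
    if scheme == "handling":
        singles = fit_handling_screen(dataset, mets)
        p_term["time"] = pd.Series(
            [r.p_time if r.converged else np.nan for r in singles], index=mets
        )
        p_term["temp"] = pd.Series(
            [r.p_temp if r.converged else np.nan for r in singles], index=mets
        )
    else:
        singles = fit_ftc_screen(dataset, mets)
        p_term["ftc"] = pd.Series(
            [r.p_ftc if r.converged else np.nan for r in singles], index=mets
        )
    # overall: LRT of the no-interaction raw model against the null
    Y = dataset.values.loc[ids, mets].to_numpy(dtype=float)
    complete = ~np.isnan(Y).any(axis=0)
    p_over = np.full(len(mets), np.nan)
    if complete.any():
        f1 = fit_random_intercept(Y[:, complete], X, groups)
        f0 = fit_random_intercept(Y[:, complete], X[:, :1], groups)
        p_over[complete] = likelihood_ratio_p(
            f1.loglik, f0.loglik, X.shape[1] - 1
        )
    for j in np.flatnonzero(~complete):
        y = Y[:, j]
        keep = ~np.isnan(y)
        if keep.sum() < X.shape[1] + 2 or np.nanstd(y) == 0:
            continue
        f1 = fit_random_intercept(y[keep], X[keep], groups[keep])
        f0 = fit_random_intercept(y[keep], X[keep][:, :1], groups[keep])
        p_over[j] = likelihood_ratio_p(f1.loglik, f0.loglik, X.shape[1] - 1)[0]
    p_term["overall"] = pd.Series(p_over, index=mets)
    return SingleReference(p_term=p_term)


def fit_ratio_screen(
    dataset: ConcentrationDataset,
    metabolites: Optional[Sequence[str]] = None,
    scheme: Scheme = "handling",
    include_interaction: bool = False,
    singles: Optional[SingleReference] = None,
) -> list[RatioResult]:
    """Fit every pairwise log-ratio model and attach p-gains.

    Rows where either metabolite is missing or non-positive are dropped for
    that pair.  Pairs sharing the complete-data design are fitted in one
    vectorized pass.
    """
    mets = list(metabolites) if metabolites is not None else dataset.panel.ids
    pairs = enumerate_pairs(mets)
    if not pairs:
        return []
    X, groups, ids, term_cols = _design(dataset, scheme)
    if include_interaction and scheme == "handling":
        X = np.column_stack([X, X[:, 1] * X[:, 2]])
    df_overall = X.shape[1] - 1
    if singles is None:
        singles = single_reference(dataset, mets, scheme)

    V = dataset.values.loc[ids, mets].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.where(V > 0, np.log(V), np.nan)
    ok_col = ~np.isnan(L).any(axis=0)
    col = {m: i for i, m in enumerate(mets)}

    results: list[RatioResult] = []
    idx_complete = [
        k for k, (a, b) in enumerate(pairs) if ok_col[col[a]] and ok_col[col[b]]
    ]
    if idx_complete:
        i1 = np.array([col[pairs[k][0]] for k in idx_complete])
        i2 = np.array([col[pairs[k][1]] for k in idx_complete])
        Y = L[:, i1] - L[:, i2]
        f1 = fit_random_intercept(Y, X, groups)
        f0 = fit_random_intercept(Y, X[:, :1], groups)
        p_over = likelihood_ratio_p(f1.loglik, f0.loglik, df_overall)
    res_by_pair: dict[int, RatioResult] = {}
    for pos, k in enumerate(idx_complete):
        a, b = pairs[k]
        r = RatioResult(pair=(a, b), scheme=scheme, converged=bool(f1.converged[pos]))
        if r.converged:
            for term, ci in term_cols.items():
                setattr(r, f"p_{term}", float(f1.wald_p[ci, pos]))
                setattr(r, f"beta_{term}", float(f1.beta[ci, pos]))
            r.p_overall = float(p_over[pos])
        res_by_pair[k] = r
    for k, (a, b) in enumerate(pairs):
        if k in res_by_pair:
            continue
        y = L[:, col[a]] - L[:, col[b]]
        keep = ~np.isnan(y)
        r = RatioResult(pair=(a, b), scheme=scheme, n_dropped=int((~keep).sum()))
        if keep.sum() < X.shape[1] + 2 or np.nanstd(y[keep]) == 0:
            r.converged = False
        else:
            g1 = fit_random_intercept(y[keep], X[keep], groups[keep])
            g0 = fit_random_intercept(y[keep], X[keep][:, :1], groups[keep])
            r.converged = bool(g1.converged[0])
            if r.converged:
                for term, ci in term_cols.items():
                    setattr(r, f"p_{term}", float(g1.wald_p[ci, 0]))
                    setattr(r, f"beta_{term}", float(g1.beta[ci, 0]))
                r.p_overall = float(
                    likelihood_ratio_p(g1.loglik, g0.loglik, df_overall)[0]
                )
        res_by_pair[k] = r

    for k, (a, b) in enumerate(pairs):
        r = res_by_pair[k]
        if r.converged:
            for term, p_r, _ in r.terms():
                p1 = singles.p_term[term].get(a, np.nan)
                p2 = singles.p_term[term].get(b, np.nan)
                if p_r is not None and np.isfinite(p1) and np.isfinite(p2) and p_r > 0:
                    setattr(r, f"pgain_{term}", float(min(p1, p2) / p_r))
        results.append(r)
    return results


def fit_ratio_model(
    dataset: ConcentrationDataset,
    pair: tuple[str, str],
    scheme: Scheme = "handling",
    include_interaction: bool = False,
    singles: Optional[SingleReference] = None,
) -> RatioResult:
    """Single-pair ratio fit, honouring the given pair orientation.

    Swapping the pair flips every coefficient's sign but leaves p-values
    and p-gains unchanged.
    """
    a, b = pair
    if a == b:
        raise ValueError("ratio of a metabolite with itself is undefined")
    X, groups, ids, term_cols = _design(dataset, scheme)
    if include_interaction and scheme == "handling":
        X = np.column_stack([X, X[:, 1] * X[:, 2]])
    if singles is None:
        singles = single_reference(dataset, [a, b], scheme)
    V = dataset.values.loc[ids, [a, b]].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.where(V > 0, np.log(V), np.nan)
    y = L[:, 0] - L[:, 1]
    keep = ~np.isnan(y)
    r = RatioResult(pair=(a, b), scheme=scheme, n_dropped=int((~keep).sum()))
    if keep.sum() < X.shape[1] + 2 or np.nanstd(y[keep]) == 0:
        r.converged = False
        return r
    f1 = fit_random_intercept(y[keep], X[keep], groups[keep])
    f0 = fit_random_intercept(y[keep], X[keep][:, :1], groups[keep])
    r.converged = bool(f1.converged[0])
    if r.converged:
        for term, ci in term_cols.items():
            setattr(r, f"p_{term}", float(f1.wald_p[ci, 0]))
            setattr(r, f"beta_{term}", float(f1.beta[ci, 0]))
        r.p_overall = float(
            likelihood_ratio_p(f1.loglik, f0.loglik, X.shape[1] - 1)[0]
        )
        for term, p_r, _ in r.terms():
            p1 = singles.p_term[term].get(a, np.nan)
            p2 = singles.p_term[term].get(b, np.nan)
            if p_r is not None and np.isfinite(p1) and np.isfinite(p2) and p_r > 0:
                setattr(r, f"pgain_{term}", float(min(p1, p2) / p_r))
    return r


def screen_ratios(
    results: Sequence[RatioResult],
    n_pairs: Optional[int] = None,
    n_terms: Optional[int] = None,
    alpha: float = 0.05,
) -> list[RatioResult]:
    """Set ``passed_screen`` on every result.

    A pair passes when *some* term (time, temperature or overall for the
    handling scheme; freeze-thaw or overall for the ftc scheme) has
    ``p < alpha/(n_terms * n_pairs)`` and simultaneously
    ``p-gain > 10 * n_terms * n_pairs``.
    """
    results = list(results)
    if n_pairs is None:
        n_pairs = len(results)
    if n_terms is None:
        n_terms = 3 if (results and results[0].scheme == "handling") else 1
    a = ratio_alpha(n_pairs, n_terms, alpha)
    g = pgain_threshold(n_pairs, n_terms)
    for r in results:
        if not r.converged:
            r.passed_screen = False
            continue
        r.passed_screen = any(
            p is not None and pg is not None and p < a and pg > g
            for _, p, pg in r.terms()
        )
    return results


def ratio_table(results: Sequence[RatioResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "metabolite_1": r.pair[0],
                "metabolite_2": r.pair[1],
                "p_time": r.p_time,
                "p_temp": r.p_temp,
                "p_ftc": r.p_ftc,
                "p_overall": r.p_overall,
                "pgain_time": r.pgain_time,
                "pgain_temp": r.pgain_temp,
                "pgain_ftc": r.pgain_ftc,
                "pgain_overall": r.pgain_overall,
                "passed_screen": r.passed_screen,
                "converged": r.converged,
            }
        )
    return pd.DataFrame(rows)
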