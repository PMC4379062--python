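"""Intrinsic sample-quality classification.

Two-stage procedure on the training participants:

1. *Variable ranking.*  Candidate variables are the screened single
   metabolite ratios plus four sum ratios (tLyso/tPC, tLyso/tPCaa,
   tLyso/tPCae, tAA/tAC).  Under the stringent quality labels (good =
   immediately frozen reference, bad = 36 h room temperature) repeated
   Random-Forest runs are averaged; importance is the unscaled permutation
   importance (mean decrease in out-of-bag classification accuracy).

2. *Rule construction.*  A CART classification tree (Gini impurity,
   cost-complexity pruning) is grown on the top-ranked variables under the
   non-stringent labels (good = reference + dry ice, bad = 24/36 h room
   temperature), yielding an explicit cut-off rule such as
   ``tLyso/tPC >= 0.12 and Gln/Ser <= 4.71 -> bad``.

The fitted rule is evaluated on the held-out test participants and applied
to the unlabelled handling conditions (wet ice, 12 h room temperature).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .dataset import ConcentrationDataset

logger = logging.getLogger(__name__)

LabelScheme = Literal["stringent", "non_stringent"]

SUM_RATIOS = ("tLyso/tPC", "tLyso/tPCaa", "tLyso/tPCae", "tAA/tAC")

#: participant split as used throughout: 12 training / 7 test donors
DEFAULT_TRAIN_IDS = ("1", "4", "5", "7", "9", "11", "12", "14", "15", "16", "18", "19")
DEFAULT_TEST_IDS = ("2", "3", "6", "8", "10", "13", "17")


# ---------------------------------------------------------------------------
# labels and features


@dataclass(frozen=True)
class QualityLabel:
    sample_id: str
    label: str  # good / bad / unlabeled
    scheme: LabelScheme


def label_samples(
    dataset: ConcentrationDataset, scheme: LabelScheme
) -> list[QualityLabel]:
    """Assign good/bad/unlabeled quality labels per sample.

    stringent      good = reference; bad = room temperature, 36 h.
    non_stringent  good = reference or any dry-ice delay;
                   bad = room temperature, 24 or 36 h.
    """
    if scheme not in ("stringent", "non_stringent"):
        raise ValueError(f"unknown labelling scheme {scheme!r}")
    out = []
    for a in dataset.annotations:
        label = "unlabeled"
        if scheme == "stringent":
            if a.role == "reference":
                label = "good"
            elif a.role == "handling" and a.temperature == "rt" and a.delay_h == 36:
                label = "bad"
        else:
            if a.role == "reference" or (
                a.role == "handling" and a.temperature == "dry_ice"
            ):
                label = "good"
            elif a.role == "handling" and a.temperature == "rt" and a.delay_h >= 24:
                label = "bad"
        out.append(QualityLabel(a.sample_id, label, scheme))
    return out


def label_series(labels: Sequence[QualityLabel]) -> pd.Series:
    return pd.Series(
        {l.sample_id: l.label for l in labels}, name=labels[0].scheme if labels else "label"
    )


def compute_sum_ratios(
    dataset: ConcentrationDataset, include_free_carnitine: bool = True
) -> pd.DataFrame:
    """The four class-level sum ratios, per sample.

    Sums run over the QC-retained metabolites of each class (missing cells
    are excluded from a sum).  ``tAA/tAC`` divides total amino acids by
    total acylcarnitines, including free carnitine in the denominator
    unless disabled.  A zero or empty denominator yields a missing feature
    for that sample.
    """
    panel = dataset.panel
    lyso = panel.ids_of_class("lyso_pc")
    pc_aa = panel.ids_of_class("pc_aa")
    pc_ae = panel.ids_of_class("pc_ae")
    aa = panel.ids_of_class("amino_acid")
    ac = panel.ids_of_class("acylcarnitine")
    if include_free_carnitine:
        ac = ac + panel.ids_of_class("carnitine")
    needed = {
        "tLyso/tPC": (lyso, pc_aa + pc_ae),
        "tLyso/tPCaa": (lyso, pc_aa),
        "tLyso/tPCae": (lyso, pc_ae),
        "tAA/tAC": (aa, ac),
    }
    out = {}
    for name, (num_ids, den_ids) in needed.items():
        if not num_ids or not den_ids:
            raise ValueError(f"no retained metabolites for both sides of {name}")
        num = dataset.values[num_ids].sum(axis=1, min_count=1)
        den = dataset.values[den_ids].sum(axis=1, min_count=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = num / den
        ratio[den <= 0] = np.nan
        n_bad = int(ratio.isna().sum())
        if n_bad:
            logger.warning("%s undefined for %d samples", name, n_bad)
        out[name] = ratio
    return pd.DataFrame(out)


def build_feature_table(
    dataset: ConcentrationDataset,
    pairs: Sequence[tuple[str, str]],
    include_free_carnitine: bool = True,
) -> pd.DataFrame:
    """Candidate classifier variables: screened pair ratios + 4 sum ratios.

    Pair features are plain concentration ratios named ``"a/b"``.
    """
    cols = {}
    for a, b in pairs:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = dataset.values[a] / dataset.values[b]
        r[dataset.values[b] <= 0] = np.nan
        cols[f"{a}/{b}"] = r
    feats = pd.DataFrame(cols, index=dataset.values.index)
    sums = compute_sum_ratios(dataset, include_free_carnitine)
    return pd.concat([feats, sums], axis=1)


def split_participants(
    participants: Sequence[str],
    train_ids: Optional[Sequence[str]] = None,
    test_ids: Optional[Sequence[str]] = None,
    seed: Optional[int] = None,
    n_train: int = 12,
) -> tuple[list[str], list[str]]:
    """Partition participants into training and test sets.

    With no explicit ids, the default 12/7 split is used when it covers the
    participant list; otherwise (or with ``seed`` given) a seeded random
    split of ``n_train`` participants is drawn.
    """
    parts = list(participants)
    if train_ids is None and test_ids is None:
        if seed is None and set(DEFAULT_TRAIN_IDS + DEFAULT_TEST_IDS) == set(parts):
            return list(DEFAULT_TRAIN_IDS), list(DEFAULT_TEST_IDS)
        rng = np.random.default_rng(seed)
        train = sorted(rng.choice(parts, size=min(n_train, len(parts)), replace=False))
        test = [p for p in parts if p not in set(train)]
        return list(train), test
    train, test = list(train_ids or []), list(test_ids or [])
    overlap = set(train) & set(test)
    if overlap:
        raise ValueError(f"participants in both sets: {sorted(overlap)}")
    missing = set(parts) - set(train) - set(test)
    if missing:
        raise ValueError(f"participants in neither set: {sorted(missing)}")
    unknown = (set(train) | set(test)) - set(parts)
    if unknown:
        raise ValueError(f"unknown participants: {sorted(unknown)}")
    return train, test


# ---------------------------------------------------------------------------
# stage 1: repeated Random-Forest importance


@dataclass
class ImportanceRanking:
    """Mean decrease in OOB accuracy per variable, averaged over forests."""

    importance: pd.Series  # sorted descending; ties broken by variable id
    n_iter: int
    n_trees: int
    m_try: int

    @property
    def ranking(self) -> list[str]:
        return self.importance.index.tolist()

    def top(self, k: int = 10) -> list[str]:
        return self.ranking[:k]


def _forest_importance(
    X: np.ndarray, y: np.ndarray, n_trees: int, m_try: int, rng: np.random.Generator
) -> np.ndarray:
    """Unscaled permutation importance of one bagged forest.

    For each tree, out-of-bag rows are predicted once with the original
    values and once per *used* variable with that column permuted (permuting
    a variable the tree never splits on cannot change its predictions, so
    those contribute exactly zero and are skipped); the importance of a
    variable is the mean decrease in OOB accuracy.
    """
    n, p = X.shape
    imp = np.zeros(p)
    used = 0
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        if oob.size == 0:
            continue
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=m_try,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        feats = np.unique(tree.tree_.feature)
        feats = feats[feats >= 0]
        used += 1
        if feats.size == 0:
            continue
        Xo = X[oob]
        k = Xo.shape[0]
        q = feats.size
        perm = rng.permuted(Xo[:, feats], axis=0)  # per-column permutations
        stacked = np.tile(Xo, (q + 1, 1))
        rows = np.arange(q * k)
        cols = np.repeat(feats, k)
        stacked[k + rows, cols] = perm.T.ravel()
        pred = tree.predict(np.ascontiguousarray(stacked), check_input=False)
        correct = (pred == y[np.tile(oob, q + 1)]).reshape(q + 1, k)
        base = correct[0].mean()
        imp[feats] += base - correct[1:].mean(axis=1)
    return imp / max(used, 1)


def rank_variables(
    features: pd.DataFrame,
    labels: Sequence[QualityLabel],
    n_iter: int = 20,
    n_trees: int = 501,
    m_try: int = 80,
    seed: int = 0,
) -> ImportanceRanking:
    """Average permutation importance over ``n_iter`` independent forests.

    ``features`` should already be restricted to the intended (training)
    samples; only rows with a good/bad label are used.  Deterministic given
    ``seed``; final ties are broken lexicographically by variable id.
    """
    lab = label_series(list(labels)).reindex(features.index)
    mask = lab.isin(["good", "bad"]).to_numpy()
    sub = features.loc[mask]
    if sub.isna().any().any():
        bad_cols = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"labelled samples have missing features: {bad_cols[:5]}")
    y = (lab[mask] == "bad").to_numpy().astype(np.int8)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least two labelled samples per class")
    X = np.ascontiguousarray(sub.to_numpy(dtype=np.float32))
    m_try_eff = min(m_try, X.shape[1])
    master = np.random.default_rng(seed)
    total = np.zeros(X.shape[1])
    for child in master.spawn(n_iter):
        total += _forest_importance(X, y, n_trees, m_try_eff, child)
    imp = pd.Series(total / n_iter, index=features.columns)
    order = sorted(imp.index, key=lambda v: (-imp[v], v))
    return ImportanceRanking(imp.loc[order], n_iter, n_trees, m_try_eff)


# ---------------------------------------------------------------------------
# stage 2: CART rule


@dataclass
class TreeNode:
    feature: Optional[str] = None  # None for leaves
    threshold: Optional[float] = None
    left: Optional[int] = None   # child where feature value <= threshold
    right: Optional[int] = None
    label: Optional[str] = None  # leaf label


@dataclass
class TreeModel:
    """Explicit CART rule: ordered splits ending in good/bad leaves."""

    nodes: list[TreeNode]

    @property
    def splits(self) -> list[tuple[str, float]]:
        """(variable, threshold) for every internal node, in node order."""
        return [
            (n.feature, float(n.threshold)) for n in self.nodes if n.feature is not None
        ]

    @property
    def variables(self) -> list[str]:
        seen: dict[str, None] = {}
        for v, _ in self.splits:
            seen.setdefault(v, None)
        return list(seen)

    def predict_row(self, row) -> Optional[str]:
        i = 0
        while True:
            node = self.nodes[i]
            if node.feature is None:
                return node.label
            x = row.get(node.feature, np.nan)
            if pd.isna(x):
                return None
            i = node.left if x <= node.threshold else node.right

    def predict(self, features: pd.DataFrame) -> pd.Series:
        """Label per sample; missing required features give ``None``."""
        return pd.Series(
            [self.predict_row(row) for _, row in features.iterrows()],
            index=features.index,
            dtype=object,
            name="predicted",
        )

    def rule_text(self) -> str:
        """The 'bad' region as printed conjunctions of half-open cuts."""
        clauses = []

        def walk(i: int, conds: list[str]) -> None:
            node = self.nodes[i]
            if node.feature is None:
                if node.label == "bad":
                    clauses.append(" and ".join(conds) if conds else "always")
                return
            walk(node.left, conds + [f"{node.feature} <= {node.threshold:.4g}"])
            walk(node.right, conds + [f"{node.feature} >= {node.threshold:.4g}"])

        walk(0, [])
        if not clauses:
            return "no sample is classified bad"
        return " OR ".join(f"({c})" for c in clauses) + " -> bad"

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "feature": n.feature,
                    "threshold": n.threshold,
                    "left": n.left,
                    "right": n.right,
                    "label": n.label,
                }
                for n in self.nodes
            ],
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TreeModel":
        return cls([TreeNode(**d) for d in json.loads(text)])


def order_tree_candidates(variables: Sequence[str]) -> list[str]:
    """Candidate order handed to the tree: sum ratios first.

    CART gain ties resolve to the earliest column, so among equally
    separating candidates the aggregate (sum-ratio) process markers are
    preferred over individual species ratios; within each group the
    importance order is preserved.
    """
    sums = [v for v in variables if v in SUM_RATIOS]
    rest = [v for v in variables if v not in SUM_RATIOS]
    return sums + rest


def _gini(n_bad: int, n: int) -> float:
    if n == 0:
        return 0.0
    p = n_bad / n
    return 2.0 * p * (1.0 - p)


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best (feature, threshold, impurity decrease) with deterministic ties.

    Equal-gain splits resolve to the earliest feature column (callers pass
    columns in importance order) and then the smallest threshold.
    """
    n = len(y)
    parent = _gini(int(y.sum()), n) * n
    best = None  # (gain, col, thr)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        cum_bad = np.cumsum(ys)
        total_bad = cum_bad[-1]
        for i in range(min_leaf - 1, n - min_leaf):
            if xs[i] == xs[i + 1]:
                continue
            nl = i + 1
            nr = n - nl
            cost = _gini(int(cum_bad[i]), nl) * nl + _gini(
                int(total_bad - cum_bad[i]), nr
            ) * nr
            gain = parent - cost
            thr = 0.5 * (xs[i] + xs[i + 1])
            if best is None or gain > best[0] + 1e-12:
                best = (gain, j, thr)
    return best


def fit_tree(
    features: pd.DataFrame,
    labels: Sequence[QualityLabel],
    min_samples_leaf: int = 5,
    ccp_alpha: float = 0.01,
) -> TreeModel:
    """Grow and prune a CART tree on the labelled samples of ``features``.

    ``features`` should be restricted to the selected top variables (in
    importance order - equal-gain splits prefer the higher-ranked variable)
    and the training samples.  Gini impurity, thresholds at CART midpoints
    between neighbouring training values, minimum leaf size
    ``min_samples_leaf``, then weakest-link cost-complexity pruning with
    penalty ``ccp_alpha`` per split.  Leaf label ties go to 'good' (a
    sample is only called bad on a majority).
    """
    lab = label_series(list(labels)).reindex(features.index)
    mask = lab.isin(["good", "bad"]).to_numpy()
    sub = features.loc[mask]
    if sub.shape[1] == 0:
        raise ValueError("no candidate variables given")
    if sub.isna().any().any():
        raise ValueError("labelled samples have missing features")
    y = (lab[mask] == "bad").to_numpy()
    if y.all() or not y.any():
        raise ValueError("both quality classes must be present to fit a tree")
    X = sub.to_numpy(dtype=float)
    n_total = len(y)
    cols = list(features.columns)

    nodes: list[TreeNode] = []

    def leaf_label(yy: np.ndarray) -> str:
        return "bad" if yy.sum() * 2 > len(yy) else "good"

    def grow(idx: np.ndarray) -> int:
        yy = y[idx]
        node_id = len(nodes)
        nodes.append(TreeNode(label=leaf_label(yy)))
        if yy.all() or not yy.any() or len(idx) < 2 * min_samples_leaf:
            return node_id
        best = _best_split(X[idx], yy, min_samples_leaf)
        if best is None or best[0] <= 0:
            return node_id
        _, j, thr = best
        go_left = X[idx, j] <= thr
        node = nodes[node_id]
        node.feature, node.threshold, node.label = cols[j], float(thr), None
        node.left = grow(idx[go_left])
        node.right = grow(idx[~go_left])
        return node_id

    def risk(i: int, idx: np.ndarray) -> tuple[float, int]:
        """(misclassification risk of subtree, leaf count); prunes in place."""
        node = nodes[i]
        yy = y[idx]
        own_risk = min(yy.sum(), len(yy) - yy.sum()) / n_total
        if node.feature is None:
            return own_risk, 1
        go_left = X[idx, cols.index(node.feature)] <= node.threshold
        rl, nl = risk(node.left, idx[go_left])
        rr, nr = risk(node.right, idx[~go_left])
        sub_risk, leaves = rl + rr, nl + nr
        # weakest-link: collapse when the split no longer pays its penalty
        if own_risk - sub_risk <= ccp_alpha * (leaves - 1):
            node.feature = node.threshold = node.left = node.right = None
            node.label = leaf_label(yy)
            return own_risk, 1
        return sub_risk, leaves

    root_idx = np.arange(n_total)
    grow(root_idx)
    risk(0, root_idx)
    # drop orphaned nodes after pruning, re-indexing children
    keep: list[int] = []

    def collect(i: int) -> None:
        keep.append(i)
        node = nodes[i]
        if node.feature is not None:
            collect(node.left)
            collect(node.right)

    collect(0)
    remap = {old: new for new, old in enumerate(keep)}
    pruned = []
    for old in keep:
        node = nodes[old]
        pruned.append(
            TreeNode(
                feature=node.feature,
                threshold=node.threshold,
                left=remap.get(node.left),
                right=remap.get(node.right),
                label=node.label,
            )
        )
    return TreeModel(pruned)


# ---------------------------------------------------------------------------
# implanted-feature expectations (for judging recovered cut-offs)


def expected_feature(config, feature: str, temperature: str = "dry_ice",
                     delay_h: float = 0.0) -> float:
    """Expected value of a classifier feature under one handling condition.

    Works for the four sum ratios and for ``"a/b"`` pair ratios; sums run
    over the metabolites not implanted to fail QC.  Uses the generator's
    closed-form expectations at the median degradation rate.
    """
    failed = set(config.qc_fail_lod) | set(config.qc_fail_cv)
    panel = config.panel

    def total(ids):
        return sum(
            config.expected_concentration(m, temperature, delay_h)
            for m in ids
            if m not in failed
        )

    lyso = panel.ids_of_class("lyso_pc")
    if feature == "tLyso/tPC":
        return total(lyso) / total(panel.ids_of_class("pc_aa", "pc_ae"))
    if feature == "tLyso/tPCaa":
        return total(lyso) / total(panel.ids_of_class("pc_aa"))
    if feature == "tLyso/tPCae":
        return total(lyso) / total(panel.ids_of_class("pc_ae"))
    if feature == "tAA/tAC":
        return total(panel.ids_of_class("amino_acid")) / total(
            panel.ids_of_class("acylcarnitine", "carnitine")
        )
    a, b = feature.split("/")
    return config.expected_concentration(a, temperature, delay_h) / (
        config.expected_concentration(b, temperature, delay_h)
    )


def transition_band(config, feature: str) -> tuple[float, float]:
    """Interval a cut-off on ``feature`` may occupy to separate good
    conditions from manifestly degraded ones.

    The training design contains no states between the good cluster
    (reference, dry ice, and the near-null wet-ice conditions) and the
    first 'bad' condition (24 h at room temperature), so any boundary
    between the extreme good-state expectation and the 24 h RT expectation
    is a faithful recovery of the implanted transition.
    """
    good_conditions = [("dry_ice", 0.0)] + [
        (t, d) for t in ("dry_ice", "wet_ice") for d in (12.0, 24.0, 36.0)
    ]
    good_vals = [expected_feature(config, feature, t, d) for t, d in good_conditions]
    onset = expected_feature(config, feature, "rt", 24.0)
    if onset >= max(good_vals):
        return max(good_vals), onset
    return onset, min(good_vals)


# ---------------------------------------------------------------------------
# evaluation


def misclassification_rate(
    predictions: pd.Series, labels: Sequence[QualityLabel]
) -> tuple[float, int, int]:
    """(rate, n_errors, n_evaluated) over labelled, classifiable samples.

    Samples without a prediction (missing features) are excluded and
    counted via a logged warning.
    """
    lab = label_series(list(labels))
    lab = lab[lab.isin(["good", "bad"])]
    pred = predictions.reindex(lab.index)
    usable = pred.notna()
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning("%d labelled samples were unclassifiable", n_dropped)
    n = int(usable.sum())
    if n == 0:
        return np.nan, 0, 0
    errors = int((pred[usable] != lab[usable]).sum())
    return errors / n, errors, n


def apply_to_heldout(
    tree: TreeModel, features: pd.DataFrame, dataset: ConcentrationDataset
) -> pd.DataFrame:
    """Classify the conditions left unlabelled by the non-stringent scheme.

    Returns one row per (temperature, delay) condition among unlabelled
    handling samples (wet ice at any delay, room temperature at 12 h) with
    good/bad counts and the fraction classified good.
    """
    lab = label_series(label_samples(dataset, "non_stringent"))
    rows = []
    by_cond: dict[tuple[str, int], list[str]] = {}
    for a in dataset.annotations:
        if a.role == "handling" and lab.get(a.sample_id) == "unlabeled":
            by_cond.setdefault((a.temperature, a.delay_h), []).append(a.sample_id)
    for (temp, delay), ids in sorted(by_cond.items()):
        pred = tree.predict(features.loc[ids])
        n_good = int((pred == "good").sum())
        n_bad = int((pred == "bad").sum())
        rows.append(
            {
                "temperature": temp,
                "delay_h": delay,
                "n_good": n_good,
                "n_bad": n_bad,
                "n_unclassifiable": int(pred.isna().sum()),
                "frac_good": n_good / max(n_good + n_bad, 1),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["temperature", "delay_h", "n_good", "n_bad", "n_unclassifiable", "frac_good"],
    )


def robustness_scan(
    features_train: pd.DataFrame,
    labels_train: Sequence[QualityLabel],
    features_test: pd.DataFrame,
    labels_test: Sequence[QualityLabel],
    variable_subsets: Sequence[Sequence[str]],
    **tree_kw,
) -> pd.DataFrame:
    """Refit the CART rule on subsets of the top variables.

    One tree per subset; reports training and test misclassification rates
    so that rule stability across variable choices can be judged.
    """
    rows = []
    for subset in variable_subsets:
        subset = list(subset)
        if not subset:
            raise ValueError("variable subset must not be empty")
        tree = fit_tree(features_train[subset], labels_train, **tree_kw)
        rate_tr, err_tr, n_tr = misclassification_rate(
            tree.predict(features_train[subset]), labels_train
        )
        rate_te, err_te, n_te = misclassification_rate(
            tree.predict(features_test[subset]), labels_test
        )
        rows.append(
            {
                "variables": " + ".join(subset),
                "n_variables": len(subset),
                "train_rate": rate_tr,
                "train_errors": err_tr,
                "test_rate": rate_te,
                "test_errors": err_te,
                "rule": tree.rule_text(),
            }
        )
    return pd.DataFrame(rows)
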