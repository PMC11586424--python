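"""Multi-layer feature table and predictive modelling of treatment response.

For every ROI three variable sets are assembled: per-type cell ratios,
per-type cell densities (cells/mm^2), and pairwise interaction intensities
among the non-tumor types (C(6,2) = 15 pairs on the 7-type clinical panel,
for 29 features in total).  Response and survival-class labels are modelled
by L1-regularized logistic regression over repeated stratified 75/25
splits — standardization and regularization-strength selection happen
inside the training fold only — and all-relevant features are identified
with a shadow-feature (Boruta-style) random-forest procedure.

Splits are grouped by patient by default so no patient contributes ROIs to
both train and test; an ROI-level mode (``groups=None``) reproduces plain
row splitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .cellmap_io import CellMap
from .interactions import InteractionMatrix
from .panels import Panel


def assemble_features(
    cell_map: CellMap,
    matrix: InteractionMatrix,
    panel: Optional[Panel] = None,
) -> pd.DataFrame:
    """Per-ROI feature table: type ratios, densities, non-tumor interactions.

    Columns: ``{type}_ratio`` and ``{type}_density`` for every panel type,
    and ``{A}|{B}_inter`` for every unordered pair of non-tumor types; plus
    a ``patient_id`` column.  No missing values remain after assembly
    (absent types yield zero ratios/densities/intensities).
    """
    panel = panel or cell_map.panel
    rois = list(cell_map.roi_ids)
    type_list = list(panel.types)

    counts = (
        cell_map.cells.groupby(["roi_id", "cell_type"], sort=False, observed=True)
        .size().unstack(fill_value=0)
        .reindex(index=rois, columns=type_list, fill_value=0)
    )
    totals = cell_map.cells.groupby("roi_id", sort=False).size().reindex(rois)
    ratios = counts.div(totals, axis=0)
    areas = pd.Series({r: cell_map.roi_area_mm2(r) for r in rois})
    if (areas <= 0).any():
        raise ValueError("every ROI needs a positive area")
    densities = counts.div(areas, axis=0)

    pairs = list(combinations(panel.non_tumor_types, 2))
    inter = matrix.pair_table(pairs).reindex(rois)
    if inter.isna().any().any():
        raise ValueError("interaction matrix does not cover all ROIs")

    out = pd.concat(
        [
            ratios.add_suffix("_ratio"),
            densities.add_suffix("_density"),
            inter.add_suffix("_inter"),
        ],
        axis=1,
    )
    out.insert(0, "patient_id", cell_map.roi_patient().reindex(rois))
    return out


FEATURE_SUFFIXES = ("_ratio", "_density", "_inter")


def feature_columns(table: pd.DataFrame) -> List[str]:
    return [c for c in table.columns if c.endswith(FEATURE_SUFFIXES)]


@dataclass
class ModelResult:
    """Repeated-split classifier performance."""

    auc_values: np.ndarray           # one AUC per repeat, held-out only
    coefficients: pd.DataFrame       # repeats x features, training-fold fit
    chosen_C: np.ndarray             # inverse regularization per repeat
    seed: int
    split_fraction: float

    @property
    def mean_auc(self) -> float:
        return float(self.auc_values.mean())


def _stratified_split(
    ids: np.ndarray,
    labels: np.ndarray,
    train_fraction: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Class-stratified random split of ``ids``; both classes in both halves."""
    train_idx: List[int] = []
    test_idx: List[int] = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        perm = rng.permutation(members)
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return ids[np.sort(train_idx)], ids[np.sort(test_idx)]


def _lasso_path_fit(
    X_train: np.ndarray,
    y_train: np.ndarray,
    rng: np.random.Generator,
    Cs: int = 20,
    cv: int = 5,
) -> Tuple[LogisticRegression, float]:
    """L1 logistic regression with C chosen by internal CV + 1-SE rule.

    Candidate strengths are log-spaced; the strongest regularization whose
    cross-validated AUC is within one standard error of the best is chosen
    (standard LASSO practice).
    """
    C_grid = np.logspace(-2, 2, Cs)
    n_splits = min(cv, int(np.bincount(y_train).min()))
    means = np.full(Cs, -np.inf)
    ses = np.zeros(Cs)
    if n_splits >= 2:
        skf = StratifiedKFold(
            n_splits=n_splits, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        folds = list(skf.split(X_train, y_train))
        for i, C in enumerate(C_grid):
            aucs = []
            for tr, va in folds:
                clf = LogisticRegression(
                    solver="liblinear", l1_ratio=1.0, C=C, max_iter=2000
                )
                clf.fit(X_train[tr], y_train[tr])
                if len(np.unique(y_train[va])) < 2:
                    continue
                aucs.append(
                    roc_auc_score(y_train[va], clf.decision_function(X_train[va]))
                )
            if aucs:
                means[i] = np.mean(aucs)
                ses[i] = np.std(aucs) / np.sqrt(len(aucs))
    if np.isfinite(means).any():
        best = int(np.argmax(means))
        floor = means[best] - ses[best]
        chosen = int(np.flatnonzero(means >= floor)[0])  # smallest C qualifying
    else:
        chosen = Cs // 2
    C = float(C_grid[chosen])
    final = LogisticRegression(
        solver="liblinear", l1_ratio=1.0, C=C, max_iter=2000
    )
    final.fit(X_train, y_train)
    return final, C


def fit_response_model(
    features: pd.DataFrame,
    labels: Sequence,
    groups: Optional[Sequence] = None,
    split_fraction: float = 0.75,
    n_repeats: int = 100,
    seed: int = 0,
    Cs: int = 20,
    cv: int = 5,
) -> ModelResult:
    """Repeated train/test evaluation of an L1-logistic response classifier.

    Each repeat draws a stratified split (at the patient level when
    ``groups`` gives a patient id per row, so no patient spans train and
    test), standardizes features on the training rows only, selects the
    regularization strength by internal cross-validation, and scores AUC on
    the held-out rows.  A split that leaves a class empty is redrawn with a
    fresh sub-seed (logged via ``warnings``).
    """
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels).astype(int)
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 rows per class")
    feature_names = list(features.columns)
    root = np.random.SeedSequence(seed)

    aucs, coefs, chosen = [], [], []
    for rep_seq in root.spawn(n_repeats):
        rng = np.random.default_rng(rep_seq)
        for attempt in range(20):
            if groups is not None:
                g = np.asarray(groups)
                uniq = pd.unique(g)
                g_labels = np.array([y[g == u][0] for u in uniq])
                tr_g, te_g = _stratified_split(uniq, g_labels, split_fraction, rng)
                tr_mask = np.isin(g, tr_g)
                te_mask = np.isin(g, te_g)
            else:
                idx = np.arange(len(y))
                tr_i, te_i = _stratified_split(idx, y, split_fraction, rng)
                tr_mask = np.zeros(len(y), bool)
                tr_mask[tr_i] = True
                te_mask = ~tr_mask
            ok = (
                len(np.unique(y[tr_mask])) == 2
                and len(np.unique(y[te_mask])) == 2
            )
            if ok:
                break
            warnings.warn(f"degenerate split redrawn (attempt {attempt + 1})")
        scaler = StandardScaler().fit(X[tr_mask])
        X_tr = scaler.transform(X[tr_mask])
        X_te = scaler.transform(X[te_mask])
        clf, C = _lasso_path_fit(X_tr, y[tr_mask], rng, Cs=Cs, cv=cv)
        aucs.append(roc_auc_score(y[te_mask], clf.decision_function(X_te)))
        coefs.append(clf.coef_.ravel())
        chosen.append(C)

    return ModelResult(
        auc_values=np.asarray(aucs),
        coefficients=pd.DataFrame(coefs, columns=feature_names),
        chosen_C=np.asarray(chosen),
        seed=seed,
        split_fraction=split_fraction,
    )


# ---------------------------------------------------------------------------
# Boruta all-relevant feature selection
# ---------------------------------------------------------------------------

@dataclass
class BorutaResult:
    """Shadow-feature selection outcome.

    ``decision`` holds "confirmed" / "rejected" / "tentative" per feature;
    ``hits`` counts iterations where a feature's importance beat the best
    shadow; ``pvalue`` is the two-sided binomial p at the final iteration
    tested; ``importance_history`` stacks per-iteration importances with the
    shadow maximum in column ``shadow_max``.
    """

    decision: pd.Series
    hits: pd.Series
    n_iter: pd.Series               # iteration at which each decision fell
    pvalue: pd.Series
    importance_history: pd.DataFrame


def boruta_select(
    features: pd.DataFrame,
    labels: Sequence,
    alpha: float = 0.01,
    max_iter: int = 30,
    seed: int = 0,
    n_estimators: int = 500,
    importance: str = "impurity",
) -> BorutaResult:
    """All-relevant selection by comparison against permuted shadow features.

    Each iteration appends a per-column permuted "shadow" copy of every
    still-undecided feature, fits a random-forest classifier, and records a
    hit for each real feature whose importance exceeds the maximum shadow
    importance.  A two-sided binomial test on the hit count (p = 0.5)
    confirms features hitting significantly more than half the time and
    rejects those hitting significantly less; rejected features leave the
    forest.  Features still undecided after ``max_iter`` are tentative.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if importance not in ("impurity", "permutation"):
        raise ValueError("importance must be 'impurity' or 'permutation'")
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are degenerate (single class)")
    X = features.to_numpy(dtype=float)
    names = list(features.columns)
    p = len(names)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    decision = pd.Series("tentative", index=names)
    hits = pd.Series(0, index=names)
    n_iter = pd.Series(max_iter, index=names)
    pvalues = pd.Series(1.0, index=names)
    history = []

    active = np.arange(p)
    for it in range(1, max_iter + 1):
        Xa = X[:, active]
        shadows = np.column_stack([rng.permutation(col) for col in Xa.T])
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(np.hstack([Xa, shadows]), y)
        if importance == "impurity":
            imp = forest.feature_importances_
        else:
            from sklearn.inspection import permutation_importance

            imp = permutation_importance(
                forest, np.hstack([Xa, shadows]), y, n_repeats=5,
                random_state=int(rng.integers(2**31 - 1)),
            ).importances_mean
        real_imp = imp[: len(active)]
        shadow_max = imp[len(active):].max()
        row = dict.fromkeys(names, np.nan)
        for a, v in zip(active, real_imp):
            row[names[a]] = v
        row["shadow_max"] = shadow_max
        history.append(row)

        hit_now = real_imp > shadow_max
        for a, h in zip(active, hit_now):
            hits.iloc[a] += int(h)

        still = []
        for a in active:
            test = binomtest(int(hits.iloc[a]), it, 0.5)
            pvalues.iloc[a] = test.pvalue
            if test.pvalue < alpha and hits.iloc[a] > it / 2:
                decision.iloc[a] = "confirmed"
                n_iter.iloc[a] = min(n_iter.iloc[a], it)
            elif test.pvalue < alpha and hits.iloc[a] < it / 2:
                if decision.iloc[a] != "rejected":
                    decision.iloc[a] = "rejected"
                    n_iter.iloc[a] = it
            else:
                still.append(a)
        # confirmed features stay in the forest; rejected ones leave
        active = np.array(
            [a for a in active if decision.iloc[a] != "rejected"], dtype=int
        )
        if not len(active):
            break

    return BorutaResult(
        decision=decision,
        hits=hits,
        n_iter=n_iter,
        pvalue=pvalues,
        importance_history=pd.DataFrame(history),
    )


def fit_survival_class_model(
    features: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[bool],
    cutoff: float,
    groups: Optional[Sequence] = None,
    **model_kwargs,
) -> ModelResult:
    """Classify long vs short survivors at ``cutoff`` (months) and model.

    A row is "long" when its time is at or beyond the cutoff (censored or
    not — the patient verifiably survived past it) and "short" when an
    event occurred before the cutoff.  Rows censored before the cutoff are
    uninformative and are excluded (logged).  Delegates the classification
    task to :func:`fit_response_model`.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    long_cls = t >= cutoff
    excluded = (~e) & (t < cutoff)
    if excluded.any():
        warnings.warn(
            f"excluding {int(excluded.sum())} rows censored before the cutoff"
        )
    keep = ~excluded
    y = long_cls[keep].astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("one survival class is empty after dichotomization")
    sub_groups = None if groups is None else np.asarray(groups)[keep]
    return fit_response_model(
        features.loc[keep], y, groups=sub_groups, **model_kwargs
    )
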