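"""Nearest-neighbor classification on KDA scores, repeated stratified CV,
classification metrics, the DeLong paired-AUC test, and greedy parameter search.

The evaluation protocol: per subject, build the hybrid network for a given
(k, μ, threshold); vectorize the upper triangle; within each training fold
fit the non-negative elastic net to select edges and the kernel Fisher
discriminant to obtain a 1-D score; classify held-out subjects by the
nearest training score. Stratified 10-fold cross-validation is repeated
(default 20 times) and every metric is reported as mean ± std across
repeats. No held-out subject ever enters a fitting step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm as normal_dist
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .features import fit_kda, fit_nonneg_elastic_net, kda_transform, vectorize_network
from .networks import hybrid_network, pearson_network, second_order_network, threshold_network

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CVPlan",
    "PipelineParams",
    "SearchGrid",
    "nn_classify",
    "compute_metrics",
    "rank_auc",
    "delong_compare",
    "delong_compare_reports",
    "cohort_feature_matrix",
    "run_repeated_cv",
    "greedy_grid_search",
]

POSITIVE = "patient"  # positive class throughout
METRIC_NAMES = ("ACC", "SEN", "SPE", "PPV", "NPV", "F1", "BAC", "AUC")


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN with patient as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """Mean ± std of each metric across CV repeats; per-repeat values retained."""

    mean: dict
    std: dict
    per_repeat: list  # list of dicts, one per repeat

    def __getitem__(self, key):
        return self.mean[key]

    def as_row(self) -> dict:
        row = {}
        for name in METRIC_NAMES:
            row[name] = 100.0 * self.mean[name]
            row[f"{name}_std"] = 100.0 * self.std[name]
        return row


@dataclass
class CVPlan:
    n_folds: int = 10
    n_repeats: int = 20
    stratified: bool = True
    seed: int = 0


@dataclass
class PipelineParams:
    """Parameters of the full network → selection → projection pipeline."""

    k: int = 15
    mu: float = 0.5
    threshold: float = 0.0
    lam1: float = 0.01
    lam2: float = 0.01
    penalty_cv: bool = False  # select lam1/lam2 by inner 5-fold CV per training fold
    gamma: float | None = None  # None -> median heuristic
    epsilon: float | None = None


@dataclass
class SearchGrid:
    k_values: tuple = (5, 10, 15, 20, 25, 30, 35, 40, 45)
    mu_values: tuple = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    threshold_values: tuple = (0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4)

    def __post_init__(self):
        if not (self.k_values and self.mu_values and self.threshold_values):
            raise ValueError("search grid axes must be non-empty")


# ---------------------------------------------------------------- classification

def nn_classify(train_scores, train_labels, test_scores) -> np.ndarray:
    """1-nearest-neighbor on scalar scores; ties go to the smaller train index."""
    train_scores = np.asarray(train_scores, dtype=float)
    test_scores = np.atleast_1d(np.asarray(test_scores, dtype=float))
    if train_scores.size == 0:
        raise ValueError("empty training set")
    train_labels = np.asarray(train_labels)
    diffs = np.abs(test_scores[:, None] - train_scores[None, :])
    nearest = np.argmin(diffs, axis=1)  # argmin returns the first (smallest index) minimum
    return train_labels[nearest]


def rank_auc(scores, labels) -> float:
    """AUC from average ranks of the pooled scores (exact Mann–Whitney statistic).

    AUC = (Σ_{i∈patients} rank_i − N_pat(N_pat+1)/2) / (N_pat·N_nor), with
    ascending average ranks so tied scores receive half credit.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == POSITIVE
    n_pat = int(pos.sum())
    n_nor = int((~pos).sum())
    if n_pat == 0 or n_nor == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores, method="average")
    return float((ranks[pos].sum() - n_pat * (n_pat + 1) / 2.0) / (n_pat * n_nor))


def _safe_ratio(num, den, name):
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN", stacklevel=3)
        return float("nan")
    return num / den


def compute_metrics(counts: ConfusionCounts, scores=None, labels=None) -> dict:
    """All eight metrics from confusion counts (+ AUC when scores are given).

    Undefined ratios are NaN with a warning, never silently zero.
    """
    acc = _safe_ratio(counts.TP + counts.TN, counts.total, "ACC")
    sen = _safe_ratio(counts.TP, counts.TP + counts.FN, "SEN")
    spe = _safe_ratio(counts.TN, counts.TN + counts.FP, "SPE")
    ppv = _safe_ratio(counts.TP, counts.TP + counts.FP, "PPV")
    npv = _safe_ratio(counts.TN, counts.FN + counts.TN, "NPV")
    if np.isnan(sen) or np.isnan(ppv) or (sen + ppv) == 0:
        warnings.warn("F1 undefined; reported as NaN", stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2.0 * sen * ppv / (sen + ppv)
    bac = (sen + spe) / 2.0
    out = {"ACC": acc, "SEN": sen, "SPE": spe, "PPV": ppv, "NPV": npv,
           "F1": f1, "BAC": bac}
    if scores is not None and labels is not None:
        out["AUC"] = rank_auc(scores, labels)
    return out


# ---------------------------------------------------------------- DeLong test

def _placements(scores, pos_mask):
    """DeLong placement values V10 (per patient) and V01 (per control)."""
    x = np.asarray(scores[pos_mask], dtype=float)
    y = np.asarray(scores[~pos_mask], dtype=float)
    psi = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    return psi.mean(axis=1), 1.0 - psi.mean(axis=0), psi.mean()


def delong_compare(scores_A, scores_B, labels) -> tuple:
    """DeLong's paired comparison of two correlated AUCs on the same subjects.

    Returns (p_value, auc_A, auc_B). Variance of the AUC difference comes
    from the empirical covariance of the placement values; z is compared to
    a standard normal, two-sided.
    """
    labels = np.asarray(labels)
    pos = labels == POSITIVE
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValueError("DeLong comparison needs both classes present")
    scores_A = np.asarray(scores_A, dtype=float)
    scores_B = np.asarray(scores_B, dtype=float)
    if scores_A.shape != labels.shape or scores_B.shape != labels.shape:
        raise ValueError("scores must be paired on identical subjects")

    v10_a, v01_a, auc_a = _placements(scores_A, pos)
    v10_b, v01_b, auc_b = _placements(scores_B, pos)
    m, n = len(v10_a), len(v01_a)

    def cov(u, v):
        if len(u) < 2:
            return 0.0
        return float(np.cov(u, v, ddof=1)[0, 1])

    var = (
        (cov(v10_a, v10_a) + cov(v10_b, v10_b) - 2 * cov(v10_a, v10_b)) / m
        + (cov(v01_a, v01_a) + cov(v01_b, v01_b) - 2 * cov(v01_a, v01_b)) / n
    )
    diff = auc_a - auc_b
    if var <= 0:
        if diff == 0:
            return 1.0, auc_a, auc_b
        raise ValueError("zero DeLong variance estimate with unequal AUCs")
    z = diff / np.sqrt(var)
    p = float(2.0 * normal_dist.sf(abs(z)))
    return p, auc_a, auc_b


# ---------------------------------------------------------------- repeated CV

def delong_compare_reports(rep_a: "MetricsReport", rep_b: "MetricsReport",
                           labels) -> float:
    """Median DeLong p across repeats for two pipelines evaluated on the
    same cohort with the same CV plan (paired pooled out-of-fold scores)."""
    if len(rep_a.per_repeat) != len(rep_b.per_repeat):
        raise ValueError("reports have different repeat counts")
    ps = [
        delong_compare(ma["_scores"], mb["_scores"], labels)[0]
        for ma, mb in zip(rep_a.per_repeat, rep_b.per_repeat)
    ]
    return float(np.median(ps))


def cohort_feature_matrix(cohort, params: PipelineParams):
    """Per-subject hybrid-network edge features (subjects × edges) and ±1-free labels.

    Network construction is strictly per subject (no group information), so
    precomputing it outside the CV loop cannot leak labels.
    """
    feats = []
    labels = []
    for s in cohort:
        X = s.values
        c1 = pearson_network(X)
        c2 = second_order_network(X, params.k)
        c = hybrid_network(c1, c2, params.mu)
        if params.threshold > 0:
            c = threshold_network(c, params.threshold)
        feats.append(vectorize_network(c))
        labels.append(s.label)
    return np.array(feats), np.array(labels)


_PENALTY_GRID = tuple(float(v) for v in np.logspace(-3, 0, 4))


def _fit_fold(F_tr, y_tr, params: PipelineParams, rng_seed: int):
    lam1, lam2 = params.lam1, params.lam2
    if params.penalty_cv:
        lam1, lam2 = select_penalties(F_tr, y_tr, seed=rng_seed,
                                      gamma=params.gamma, epsilon=params.epsilon)
    target = np.where(y_tr == POSITIVE, 1.0, -1.0)
    enet = fit_nonneg_elastic_net(F_tr, target, lam1, lam2)
    sel = enet.selected_edges
    if sel.size == 0:
        warnings.warn("elastic net selected no edges; falling back to all edges",
                      stacklevel=2)
        sel = np.arange(F_tr.shape[1])
    kda = fit_kda(F_tr[:, sel], y_tr, gamma=params.gamma, epsilon=params.epsilon)
    return sel, kda


def select_penalties(F, y, grid=_PENALTY_GRID, n_folds: int = 5, seed: int = 0,
                     gamma=None, epsilon=None) -> tuple:
    """Inner stratified CV over a log grid of (λ1, λ2), maximizing accuracy.

    Used on training partitions only; ties resolve to the smallest penalties.
    """
    y = np.asarray(y)
    best = (grid[0], grid[0])
    best_acc = -1.0
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    for lam1 in grid:
        for lam2 in grid:
            correct = 0
            total = 0
            for tr, te in splits:
                target = np.where(y[tr] == POSITIVE, 1.0, -1.0)
                enet = fit_nonneg_elastic_net(F[tr], target, lam1, lam2)
                sel = enet.selected_edges
                if sel.size == 0:
                    sel = np.arange(F.shape[1])
                kda = fit_kda(F[tr][:, sel], y[tr], gamma=gamma, epsilon=epsilon)
                s_tr = kda_transform(kda, F[tr][:, sel])
                s_te = kda_transform(kda, F[te][:, sel])
                pred = nn_classify(s_tr, y[tr], s_te)
                correct += int(np.sum(pred == y[te]))
                total += len(te)
            acc = correct / total
            if acc > best_acc:
                best_acc = acc
                best = (lam1, lam2)
    return best


def run_repeated_cv(cohort, params: PipelineParams, plan: CVPlan) -> MetricsReport:
    """Repeated stratified k-fold CV of the full pipeline.

    Per repeat, out-of-fold predictions and scores are pooled and the eight
    metrics computed once; the report aggregates mean ± std across repeats.
    Entirely reproducible from ``plan.seed``.
    """
    F, y = cohort_feature_matrix(cohort, params)
    return _repeated_cv_features(F, y, params, plan)


def _repeated_cv_features(F, y, params: PipelineParams, plan: CVPlan) -> MetricsReport:
    y = np.asarray(y)
    for cls in np.unique(y):
        if np.sum(y == cls) < plan.n_folds:
            warnings.warn(
                f"class {cls!r} has fewer subjects than folds; stratification degraded",
                stacklevel=2,
            )
    ss = np.random.SeedSequence(plan.seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(plan.n_repeats)]
    per_repeat = []
    for rep_seed in repeat_seeds:
        if plan.stratified:
            splitter = StratifiedKFold(n_splits=plan.n_folds, shuffle=True,
                                       random_state=rep_seed)
            splits = splitter.split(np.zeros(len(y)), y)
        else:
            from sklearn.model_selection import KFold

            splits = KFold(n_splits=plan.n_folds, shuffle=True,
                           random_state=rep_seed).split(np.zeros(len(y)))
        pred = np.empty(len(y), dtype=y.dtype)
        score = np.empty(len(y))
        for tr, te in splits:
            sel, kda = _fit_fold(F[tr], y[tr], params, rep_seed)
            s_tr = kda_transform(kda, F[tr][:, sel])
            s_te = kda_transform(kda, F[te][:, sel])
            pred[te] = nn_classify(s_tr, y[tr], s_te)
            # affine calibration from training class means only: makes scores
            # comparable across folds when pooled for the repeat-level AUC
            m_pos = s_tr[y[tr] == POSITIVE].mean()
            m_neg = s_tr[y[tr] != POSITIVE].mean()
            mid, gap = (m_pos + m_neg) / 2.0, abs(m_pos - m_neg)
            score[te] = (s_te - mid) / gap if gap > 0 else s_te - mid
        counts = ConfusionCounts(
            TP=int(np.sum((pred == POSITIVE) & (y == POSITIVE))),
            TN=int(np.sum((pred != POSITIVE) & (y != POSITIVE))),
            FP=int(np.sum((pred == POSITIVE) & (y != POSITIVE))),
            FN=int(np.sum((pred != POSITIVE) & (y == POSITIVE))),
        )
        metrics = compute_metrics(counts, scores=score, labels=y)
        metrics["_scores"] = score.copy()
        per_repeat.append(metrics)
    mean = {}
    std = {}
    for name in METRIC_NAMES:
        vals = np.array([m[name] for m in per_repeat])
        mean[name] = float(np.nanmean(vals))
        std[name] = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0
    return MetricsReport(mean, std, per_repeat)


def greedy_grid_search(cohort, grid: SearchGrid, plan: CVPlan,
                       params: PipelineParams | None = None):
    """Coordinate-wise greedy search over (k, μ, threshold).

    Optimizes k first (μ = 0.5, t = 0), then μ at the best k, then the
    threshold at the best (k, μ); each candidate is scored by repeated-CV
    mean accuracy under ``plan``. Ties resolve to the smaller parameter
    value. Returns ((k, mu, threshold), MetricsReport of the winner).
    """
    base = params or PipelineParams()
    n = next(iter(cohort)).values.shape[0]
    k_values = [k for k in grid.k_values if 1 <= k <= n - 1]
    if not k_values:
        raise ValueError(f"no legal k in grid for n={n} regions")

    def score(p: PipelineParams):
        rep = run_repeated_cv(cohort, p, plan)
        return rep.mean["ACC"], rep

    best_k, best_rep, best_acc = None, None, -1.0
    for k in k_values:
        acc, rep = score(PipelineParams(**{**base.__dict__, "k": k, "mu": 0.5, "threshold": 0.0}))
        if acc > best_acc:
            best_k, best_rep, best_acc = k, rep, acc
    best_mu, best_acc_mu = None, -1.0
    for mu in grid.mu_values:
        acc, rep = score(PipelineParams(**{**base.__dict__, "k": best_k, "mu": mu, "threshold": 0.0}))
        if acc > best_acc_mu:
            best_mu, best_rep, best_acc_mu = mu, rep, acc
    best_t, best_acc_t = None, -1.0
    for t in grid.threshold_values:
        acc, rep = score(PipelineParams(**{**base.__dict__, "k": best_k, "mu": best_mu, "threshold": t}))
        if acc > best_acc_t:
            best_t, best_rep, best_acc_t = t, rep, acc
    return (best_k, best_mu, best_t), best_rep
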