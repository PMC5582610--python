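"""Cross-validated accuracy, permutation nulls, and confusion reporting.

Classification performance of the shrunken-centroid signature is estimated
by repeated stratified k-fold cross-validation (10 x 10-fold by default).
The shrinkage parameter can be fixed, or selected per outer training set by
an inner nested cross-validation over a delta grid (max mean accuracy,
smallest delta on ties).  A permutation null re-runs the full procedure on
label-shuffled data; when zero permutations reach the observed accuracy the
exact permutation p-value is bounded by the upper limit of the
Clopper-Pearson binomial interval, ``1 - (alpha/2)^(1/n_perm)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from statsmodels.stats.proportion import proportion_confint

from . import nsc

logger = logging.getLogger(__name__)

__all__ = [
    "CVResult", "PermutationResult", "repeated_stratified_cv",
    "select_delta_cv", "permutation_test", "clopper_pearson_upper",
    "random_classifier_baseline", "table1_report", "Table1Report",
]


@dataclass
class CVResult:
    """Pooled cross-validation outcome."""

    confusion: pd.DataFrame           # predicted profile (rows) x true phenotype (cols)
    overall_accuracy: float           # percent
    per_class_accuracy: pd.Series     # percent, per true class
    per_repeat_accuracy: list         # percent, one per repeat
    selected_deltas: list             # one per outer fold (all repeats)
    repeats: int
    folds: int
    seed: int


@dataclass
class PermutationResult:
    """Permutation null of the cross-validated accuracy."""

    observed: float                   # percent
    permuted: np.ndarray              # percent, length n_perm
    exceedances: int                  # #{permuted >= observed}
    p_bound: float                    # Clopper-Pearson upper limit

    @property
    def summary(self) -> dict:
        p = self.permuted
        return {"mean": float(p.mean()), "sd": float(p.std(ddof=1)),
                "min": float(p.min()), "max": float(p.max())}


def _coerce(x, labels):
    if isinstance(x, pd.DataFrame):
        mat = x.to_numpy(dtype=float)
    else:
        mat = np.asarray(x, dtype=float)
    y = np.asarray(labels)
    if mat.shape[1] != y.shape[0]:
        raise ValueError("labels length does not match number of samples")
    return mat, y


def _scores_for_deltas(model: nsc.CentroidModel, x_test: np.ndarray,
                       deltas: np.ndarray) -> np.ndarray:
    """Discriminant scores for every delta at once, shape (D, S, K).

    Uses the expansion of the squared distance around the overall centroid;
    the sample-only term is class-constant and omitted (argmin-invariant),
    so scores are comparable across classes but not across samples.
    """
    a = model.m_k[None, :] * (model.pooled_sd + model.s0)[:, None]  # (G, K)
    w = (model.pooled_sd + model.s0) ** 2                            # (G,)
    xc = x_test.T - model.overall_centroid[None, :]                  # (S, G)
    xw = xc / w[None, :]
    prior_term = -2.0 * np.log(model.priors)                         # (K,)
    out = np.empty((len(deltas), x_test.shape[1], len(model.classes)))
    absd = np.abs(model.d)
    sgn = np.sign(model.d)
    for di, delta in enumerate(deltas):
        dp = sgn * np.maximum(absd - delta, 0.0)                     # (G, K)
        adp = a * dp
        cross = xw @ adp                                             # (S, K)
        quad = (adp ** 2 / w[:, None]).sum(axis=0)                   # (K,)
        out[di] = -2.0 * cross + quad[None, :] + prior_term[None, :]
    return out


def _make_splitter(folds, y, groups, rng):
    state = int(rng.integers(2 ** 31))
    if groups is not None:
        return StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                    random_state=state)
    return StratifiedKFold(n_splits=folds, shuffle=True, random_state=state)


def _effective_folds(folds, y):
    min_class = int(pd.Series(y).value_counts().min())
    if min_class < folds:
        logger.warning("reducing folds from %d to %d (smallest class)",
                       folds, min_class)
        return min_class
    return folds


def _inner_select_delta(x_train, y_train, inner_folds, n_grid, priors, rng,
                        groups=None):
    """Pick delta by inner CV: max mean accuracy, smallest delta on ties."""
    full = nsc.fit(x_train, y_train, priors=priors)
    grid = np.linspace(0.0, np.abs(full.d).max(), n_grid)
    inner_folds = _effective_folds(inner_folds, y_train)
    splitter = _make_splitter(inner_folds, y_train, groups, rng)
    correct = np.zeros(n_grid)
    total = 0
    for tr, te in splitter.split(x_train.T, y_train, groups):
        m = nsc.fit(x_train[:, tr], y_train[tr], priors=priors)
        scores = _scores_for_deltas(m, x_train[:, te], grid)
        pred = m.classes[np.argmin(scores, axis=2)]                  # (D, S)
        correct += (pred == y_train[te][None, :]).sum(axis=1)
        total += len(te)
    acc = correct / total
    return float(grid[int(np.argmax(acc))])  # first argmax = smallest delta


def repeated_stratified_cv(x, labels, repeats: int = 10, folds: int = 10,
                           shrinkage="nested", inner_folds: int = 10,
                           n_grid: int = 30, priors: str = "empirical",
                           seed: int = 0, groups=None) -> CVResult:
    """Repeated stratified k-fold CV of the shrunken-centroid classifier.

    Parameters
    ----------
    x : genes x samples matrix (DataFrame or array).
    labels : phenotype per sample.
    shrinkage : a fixed delta (float), or ``"nested"`` to select delta per
        outer training set by inner ``inner_folds``-fold CV over an
        ``n_grid``-point grid from 0 to max |d|.
    groups : optional subject id per sample; when given, folds never split
        a subject across training and test.

    Predictions are pooled over folds and repeats into a predicted x true
    confusion matrix; accuracies are percentages.
    """
    mat, y = _coerce(x, labels)
    if folds < 2:
        raise ValueError("folds must be at least 2")
    if isinstance(shrinkage, str) and shrinkage != "nested":
        raise ValueError(f"unknown shrinkage mode {shrinkage!r}")
    folds = _effective_folds(folds, y)
    classes = np.unique(y)
    rng_outer = np.random.default_rng([seed, 0x0F])
    rng_inner = np.random.default_rng([seed, 0xF0])

    conf = pd.DataFrame(0, index=classes, columns=classes)
    per_repeat = []
    deltas_used = []
    for _ in range(repeats):
        splitter = _make_splitter(folds, y, groups, rng_outer)
        rep_correct = rep_total = 0
        for tr, te in splitter.split(mat.T, y, groups):
            if shrinkage == "nested":
                delta = _inner_select_delta(mat[:, tr], y[tr], inner_folds,
                                            n_grid, priors, rng_inner)
            else:
                delta = float(shrinkage)
            deltas_used.append(delta)
            model = nsc.shrink(nsc.fit(mat[:, tr], y[tr], priors=priors), delta)
            pred, _ = nsc.classify(model, mat[:, te])
            pred = np.atleast_1d(pred)
            for p, t in zip(pred, y[te]):
                conf.loc[p, t] += 1
            rep_correct += int((pred == y[te]).sum())
            rep_total += len(te)
        per_repeat.append(100.0 * rep_correct / rep_total)

    total = conf.to_numpy().sum()
    diag = np.diag(conf.to_numpy())
    colsum = conf.to_numpy().sum(axis=0)
    return CVResult(
        confusion=conf,
        overall_accuracy=100.0 * diag.sum() / total,
        per_class_accuracy=pd.Series(100.0 * diag / colsum, index=classes),
        per_repeat_accuracy=per_repeat,
        selected_deltas=deltas_used,
        repeats=repeats, folds=folds, seed=seed,
    )


def select_delta_cv(x, labels, folds: int = 10, repeats: int = 1,
                    n_grid: int = 30, priors: str = "empirical",
                    rule: str = "1se", seed: int = 0) -> float:
    """Choose the shrinkage on the full data set by (repeated) k-fold CV.

    This is the non-nested protocol: one delta for the whole analysis.
    With ``rule="max"`` the delta with maximal mean CV accuracy is taken
    (smallest on ties).  The default ``rule="1se"`` applies the
    one-standard-error convention: the *largest* delta whose mean accuracy
    is within one standard error (over folds) of the best — the sparser
    model statistically indistinguishable from the best, which is the
    appropriate choice when the goal is a minimal signature rather than
    raw accuracy.
    """
    mat, y = _coerce(x, labels)
    full = nsc.fit(mat, y, priors=priors)
    grid = np.linspace(0.0, np.abs(full.d).max(), n_grid)
    folds = _effective_folds(folds, y)
    rng = np.random.default_rng([seed, 0x5E])
    fold_acc = []
    for _ in range(repeats):
        splitter = _make_splitter(folds, y, None, rng)
        for tr, te in splitter.split(mat.T, y):
            m = nsc.fit(mat[:, tr], y[tr], priors=priors)
            scores = _scores_for_deltas(m, mat[:, te], grid)
            pred = m.classes[np.argmin(scores, axis=2)]
            fold_acc.append((pred == y[te][None, :]).mean(axis=1))
    fold_acc = np.asarray(fold_acc)                      # (folds*repeats, D)
    acc = fold_acc.mean(axis=0)
    best = int(np.argmax(acc))
    if rule == "max":
        return float(grid[best])
    if rule != "1se":
        raise ValueError(f"unknown selection rule {rule!r}")
    se = fold_acc[:, best].std(ddof=1) / np.sqrt(fold_acc.shape[0])
    eligible = np.flatnonzero(acc >= acc[best] - se)
    return float(grid[int(eligible.max())])


def permutation_test(x, labels, n_perm: int = 100, repeats: int = 10,
                     folds: int = 10, shrinkage="nested",
                     inner_folds: int = 10, n_grid: int = 30,
                     priors: str = "empirical", seed: int = 0,
                     confidence: float = 0.95) -> PermutationResult:
    """Permutation null for the cross-validated accuracy.

    Labels are permuted uniformly for each of ``n_perm`` permutations and
    the full (optionally nested) CV accuracy recomputed.  The exceedance
    count b = #{permuted >= observed} feeds the Clopper-Pearson upper
    bound on the exact permutation p-value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    mat, y = _coerce(x, labels)
    cv_kwargs = dict(repeats=repeats, folds=folds, shrinkage=shrinkage,
                     inner_folds=inner_folds, n_grid=n_grid, priors=priors)
    observed = repeated_stratified_cv(mat, y, seed=seed, **cv_kwargs
                                      ).overall_accuracy
    rng = np.random.default_rng([seed, 0xBEEF])
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        permuted[b] = repeated_stratified_cv(
            mat, y_perm, seed=int(rng.integers(2 ** 31)), **cv_kwargs
        ).overall_accuracy
    exceed = int(np.sum(permuted >= observed))
    return PermutationResult(
        observed=observed, permuted=permuted, exceedances=exceed,
        p_bound=clopper_pearson_upper(exceed, n_perm, confidence),
    )


def clopper_pearson_upper(successes: int, trials: int,
                          confidence: float = 0.95) -> float:
    """Upper limit of the two-sided exact (Clopper-Pearson) binomial interval.

    For zero successes this is the closed form ``1 - (alpha/2)**(1/n)``,
    the bound quoted for a permutation test in which no permutation reaches
    the observed statistic.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials, trials >= 1")
    _, upper = proportion_confint(successes, trials, alpha=1 - confidence,
                                  method="beta")
    return float(upper)


def random_classifier_baseline(n_classes: int = 4, draws: int = 0,
                               labels=None, seed: int = 0):
    """Expected accuracy (percent) of a uniformly random classifier.

    Analytically ``100 / n_classes`` regardless of the label distribution;
    with ``draws`` > 0 a Monte-Carlo estimate over that many random
    prediction vectors is returned alongside.
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    analytic = 100.0 / n_classes
    if draws <= 0:
        return analytic, None
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = np.arange(n_classes)  # any labels; accuracy is distribution-free
        y = rng.integers(n_classes, size=draws)
        pred = rng.integers(n_classes, size=draws)
        mc = 100.0 * float(np.mean(pred == y))
    else:
        y = np.asarray(labels)
        classes = np.unique(y)
        idx = rng.integers(len(classes), size=(draws, len(y)))
        mc = 100.0 * float(np.mean(classes[idx] == y[None, :]))
    return analytic, mc


@dataclass
class Table1Report:
    """Counts-with-percents rendering of a predicted x true confusion matrix."""

    counts: pd.DataFrame
    column_percent: pd.DataFrame
    per_class_accuracy: pd.Series  # percent, per true class (diagonal/column)
    overall_accuracy: float        # percent, trace/total

    def __str__(self) -> str:
        lines = ["Expression profile\t" + "\t".join(
            f"{c} (n={int(n)})" for c, n in
            zip(self.counts.columns, self.counts.sum(axis=0)))]
        for r in self.counts.index:
            cells = [
                f"{int(self.counts.loc[r, c])} ({self.column_percent.loc[r, c]:.0f}%)"
                for c in self.counts.columns
            ]
            lines.append(str(r) + "\t" + "\t".join(cells))
        lines.append(f"overall accuracy: {self.overall_accuracy:.1f}%")
        return "\n".join(lines)


def table1_report(confusion) -> Table1Report:
    """Render a confusion matrix as counts with per-true-class percents.

    ``confusion`` has predicted profiles as rows and true phenotypes as
    columns; column sums are the class sample counts.  A class with zero
    samples makes the percents undefined and raises.
    """
    counts = pd.DataFrame(confusion).astype(int)
    colsum = counts.sum(axis=0)
    if (colsum == 0).any():
        empty = list(colsum.index[colsum == 0])
        raise ValueError(f"class(es) with zero samples: {empty}")
    pct = 100.0 * counts / colsum
    diag = pd.Series(
        [counts.iloc[i, i] for i in range(min(counts.shape))],
        index=counts.columns[: min(counts.shape)],
    )
    return Table1Report(
        counts=counts,
        column_percent=pct,
        per_class_accuracy=100.0 * diag / colsum,
        overall_accuracy=100.0 * np.trace(counts.to_numpy()) /
        counts.to_numpy().sum(),
    )
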