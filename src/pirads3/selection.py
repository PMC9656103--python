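"""Stability feature selection over repeated stratified subsampling.

The cohort is split 100 times into 5 stratified folds; each of the 500
(repetition, held-out fold) trials runs a univariate Mann-Whitney screen on
the 4-fold training portion and a greedy redundancy-filtered selection:
candidates are walked in order of ascending p-value, the smallest-p feature
seeds the selection, and a feature with p <= 0.01 is added only if its
absolute training-set Spearman rank correlation with every already selected
feature is below 0.5. Features are finally ranked by their selection rate
over the 500 trials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SplitScheme",
    "TrialSelection",
    "SelectionResult",
    "make_splits",
    "mann_whitney_p",
    "mann_whitney_p_columns",
    "spearman_rho",
    "select_one_trial",
    "run_stability_selection",
]


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass
class SplitScheme:
    """Stratified fold assignments for repeated cross-validation.

    ``assignments[r, i]`` is the fold (0..n_folds-1) of patient ``i`` in
    repetition ``r``. Iterating yields (repetition, fold, train_idx, val_idx)
    for all n_repetitions * n_folds trials.
    """

    n_repetitions: int
    n_folds: int
    seed: int
    assignments: np.ndarray  # (n_repetitions, n_patients) int

    @property
    def n_trials(self) -> int:
        return self.n_repetitions * self.n_folds

    def trials(self):
        n = self.assignments.shape[1]
        idx = np.arange(n)
        for r in range(self.n_repetitions):
            folds = self.assignments[r]
            for f in range(self.n_folds):
                yield r, f, idx[folds != f], idx[folds == f]


def make_splits(labels: np.ndarray, n_reps: int = 100, n_folds: int = 5, seed: int = 0) -> SplitScheme:
    """Build ``n_reps`` independent stratified ``n_folds``-fold partitions.

    Stratification keeps per-fold positive counts within 1 of each other
    (26 positives in 5 folds gives counts in {5, 6}).
    """
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot stratify into {n_folds} folds"
        )
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    assignments = np.empty((n_reps, len(labels)), dtype=np.int8)
    for r in range(n_reps):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=int(rep_seeds[r] % (2**32 - 1))
        )
        for f, (_, val) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            assignments[r, val] = f
    return SplitScheme(n_reps, n_folds, seed, assignments)


# ---------------------------------------------------------------------------
# univariate statistics
# ---------------------------------------------------------------------------

def _u_statistic(ranks_pos: np.ndarray, n_pos: int, n_neg: int) -> float:
    return float(ranks_pos.sum() - n_pos * (n_pos + 1) / 2.0)


def _exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumeration of all group assignments (midranks).

    p = P(|U - mn/2| >= |u_obs - mn/2|) under the permutation null.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, m = len(x), len(y)
    center = n * m / 2.0
    u_obs = _u_statistic(ranks[:n], n, m)
    dev = abs(u_obs - center) - 1e-12
    count = total = 0
    for comb in itertools.combinations(range(n + m), n):
        u = float(ranks[list(comb)].sum() - n * (n + 1) / 2.0)
        if abs(u - center) >= dev:
            count += 1
        total += 1
    return count / total


def mann_whitney_p(group_pos: np.ndarray, group_neg: np.ndarray) -> float:
    """Two-sided Mann-Whitney p-value.

    Exact enumeration over all C(n+m, n) assignments for combined n <= 12;
    otherwise the tie-corrected normal approximation with continuity
    correction. Symmetric in group exchange.
    """
    x = np.asarray(group_pos, dtype=float)
    y = np.asarray(group_neg, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size + y.size <= 12:
        return _exact_p(x, y)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def mann_whitney_p_columns(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Mann-Whitney p for every column of ``x``.

    Uses the tie-corrected normal approximation with continuity correction
    (identical to the scalar large-sample branch); NaN columns give NaN.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n2 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2
    nan_cols = np.isnan(x).any(axis=0)
    xw = np.where(np.isnan(x), 0.0, x)
    ranks = stats.rankdata(xw, axis=0)
    u1 = ranks[labels].sum(axis=0) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per column
    tie_term = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        _, cnt = np.unique(xw[:, j], return_counts=True)
        tie_term[j] = (cnt**3 - cnt).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    p = np.where(sigma2 > 0, 2.0 * stats.norm.sf(z), 1.0)
    p = np.minimum(p, 1.0)
    p[nan_cols] = np.nan
    return p


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of midranks.

    Returns NaN (flagged undefined) when either variable has zero rank
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


# ---------------------------------------------------------------------------
# greedy redundancy-filtered selection
# ---------------------------------------------------------------------------

@dataclass
class TrialSelection:
    """Outcome of one selection trial."""

    trial_id: tuple[int, int]
    selected: list[str]
    p_values: dict[str, float]


def select_one_trial(
    train_features: pd.DataFrame,
    train_labels: np.ndarray,
    p_cutoff: float = 0.01,
    rho_cutoff: float = 0.5,
    trial_id: tuple[int, int] = (0, 0),
) -> TrialSelection:
    """Greedy p-ordered selection with a Spearman redundancy filter.

    Equal p-values are broken lexicographically by feature name; columns with
    NaN sentinels are excluded from the candidate set.
    """
    y = np.asarray(train_labels, dtype=bool)
    names = np.asarray(train_features.columns)
    x = train_features.to_numpy(dtype=float)
    p = mann_whitney_p_columns(x, y)
    valid = ~np.isnan(p)
    order = np.lexsort((names[valid], p[valid]))
    cand_idx = np.flatnonzero(valid)[order]
    cand_idx = cand_idx[p[cand_idx] <= p_cutoff]

    selected: list[int] = []
    ranks = stats.rankdata(x, axis=0)
    for j in cand_idx:
        ok = True
        for k in selected:
            rho = np.corrcoef(ranks[:, j], ranks[:, k])[0, 1]
            if np.isnan(rho) or abs(rho) >= rho_cutoff:
                ok = False
                break
        if ok:
            selected.append(int(j))
    return TrialSelection(
        trial_id=trial_id,
        selected=[str(names[j]) for j in selected],
        p_values={str(names[j]): float(p[j]) for j in cand_idx},
    )


@dataclass
class SelectionResult:
    """Per-feature selection counts and rates over all trials."""

    counts: dict[str, int]
    n_trials: int
    trials: list[TrialSelection] = field(repr=False, default_factory=list)

    @property
    def rates(self) -> dict[str, float]:
        return {k: v / self.n_trials for k, v in self.counts.items()}

    def ranked(self) -> list[tuple[str, float]]:
        """Features by descending selection rate, ties broken by name."""
        return sorted(self.rates.items(), key=lambda kv: (-kv[1], kv[0]))

    def final_pool(self, rate_cutoff: float = 0.8) -> list[str]:
        return [name for name, rate in self.ranked() if rate >= rate_cutoff]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"feature": n, "count": c, "rate": c / self.n_trials}
            for n, c in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        return pd.DataFrame(rows, columns=["feature", "count", "rate"])


def run_stability_selection(
    features: pd.DataFrame,
    labels: np.ndarray,
    splits: SplitScheme,
    p_cutoff: float = 0.01,
    rho_cutoff: float = 0.5,
    keep_trials: bool = False,
) -> SelectionResult:
    """Apply :func:`select_one_trial` to every training portion of ``splits``
    and tally per-feature selection counts."""
    if len(features) != splits.assignments.shape[1]:
        raise ValueError("splits were built for a different number of patients")
    labels = np.asarray(labels, dtype=int)
    counts: dict[str, int] = {name: 0 for name in features.columns}
    trials: list[TrialSelection] = []
    for r, f, train_idx, _ in splits.trials():
        sel = select_one_trial(
            features.iloc[train_idx],
            labels[train_idx],
            p_cutoff=p_cutoff,
            rho_cutoff=rho_cutoff,
            trial_id=(r, f),
        )
        for name in sel.selected:
            counts[name] += 1
        if keep_trials:
            trials.append(sel)
    return SelectionResult(counts=counts, n_trials=splits.n_trials, trials=trials)
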