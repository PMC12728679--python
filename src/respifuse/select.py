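"""Contribution-based feature selection.

Each feature's contribution to the cancer / non-cancer separation is the
equal-weight mean of three min-max-normalized components:

1. **label correlation** — |point-biserial correlation| with the label;
2. **model importance** — impurity-based importance from a seeded random
   forest;
3. **distribution divergence** — the two-sample Kolmogorov-Smirnov
   statistic between the class-conditional distributions.

The ranking is sorted descending with ties broken by name order.  Ranked
names can be partitioned into the field's per-modality categories (fiber:
time/frequency/wavelet; audio: frequency/quality/rhythm; blood: the five
clinical panels), and the category groups evaluated with the SVS
classifier under 10-fold CV to pick the representative set per modality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .audio import AudioFeatureRegistry
from .blood import BLOOD_CATEGORIES, blood_category
from .classify import SvsConfig, cross_validate_svs
from .errors import ConfigurationError, InputError
from .fiber import FiberFeatureRegistry
from .metrics import MetricsReport
from .records import FeatureTable

FIBER_CATEGORIES = ("time", "frequency", "wavelet")
AUDIO_CATEGORIES = ("frequency", "quality", "rhythm")


@dataclass
class ContributionRanking:
    names: list[str]
    scores: np.ndarray
    components: pd.DataFrame  # columns: correlation, importance, divergence

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.names) != self.scores.size:
            raise InputError("names/scores length mismatch")
        if np.any(np.diff(self.scores) > 1e-12):
            raise InputError("scores must be sorted descending")

    def top_k(self, k: int) -> list[str]:
        if k < 0:
            raise ConfigurationError("k must be non-negative")
        return self.names[:k]


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def score_contributions(table: FeatureTable, seed: int = 0,
                        weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                        n_trees: int = 200) -> ContributionRanking:
    """Rank features by the combined contribution score (descending)."""
    y = table.labels
    if len(np.unique(y)) < 2:
        raise InputError("contribution scoring needs both classes")
    if min(np.bincount(y)) < 2:
        raise InputError("need at least 2 subjects per class")
    X = table.values
    names = table.feature_names

    yc = y - y.mean()
    x_sd = X.std(axis=0)
    y_sd = y.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (X - X.mean(axis=0)).T @ yc / (len(y) * x_sd * y_sd)
    corr = np.abs(np.nan_to_num(corr))

    # canonical row/column order makes the forest importances invariant to
    # subject and feature permutations of the input table
    row_order = np.argsort(np.asarray(table.subject_ids))
    col_order = np.argsort(np.asarray(names))
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1)
    forest.fit(X[row_order][:, col_order], y[row_order])
    importance = np.empty(X.shape[1])
    importance[col_order] = forest.feature_importances_

    pos, neg = X[y == 1], X[y == 0]
    divergence = np.array([stats.ks_2samp(pos[:, j], neg[:, j]).statistic
                           if x_sd[j] > 0 else 0.0
                           for j in range(X.shape[1])])

    w = np.asarray(weights, float)
    comps = np.column_stack([_minmax(corr), _minmax(importance),
                             _minmax(divergence)])
    score = comps @ (w / w.sum())

    order = sorted(range(len(names)), key=lambda j: (-score[j], names[j]))
    components = pd.DataFrame(
        {"correlation": corr, "importance": importance,
         "divergence": divergence, "score": score},
        index=names).iloc[order]
    return ContributionRanking([names[j] for j in order], score[order],
                               components)


@dataclass(frozen=True)
class FeatureGroup:
    modality: str
    category: str
    members: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.members)


def _category_lookup(modality: str,
                     fiber_registry: FiberFeatureRegistry | None = None,
                     audio_registry: AudioFeatureRegistry | None = None):
    if modality == "fiber":
        reg = fiber_registry or FiberFeatureRegistry()
        return FIBER_CATEGORIES, reg.category_of
    if modality == "audio":
        reg = audio_registry or AudioFeatureRegistry()
        return AUDIO_CATEGORIES, reg.category_of
    if modality == "blood":
        return BLOOD_CATEGORIES, blood_category
    raise ConfigurationError(f"unknown modality {modality!r}")


def partition_by_category(names, modality: str,
                          fiber_registry: FiberFeatureRegistry | None = None,
                          audio_registry: AudioFeatureRegistry | None = None
                          ) -> list[FeatureGroup]:
    """Assign every name to exactly one of the modality's categories.

    Returns one group per category (in canonical order), empty groups
    included; unknown names raise a lookup error.
    """
    categories, lookup = _category_lookup(modality, fiber_registry,
                                          audio_registry)
    buckets: dict[str, list[str]] = {c: [] for c in categories}
    for name in names:
        buckets[lookup(name)].append(name)
    return [FeatureGroup(modality, c, tuple(buckets[c])) for c in categories]


def group_counts(groups: list[FeatureGroup]) -> dict[str, int]:
    return {g.category: len(g) for g in groups}


def evaluate_groups(table: FeatureTable, groups: list[FeatureGroup],
                    cv_folds: int = 10, seed: int = 0,
                    config: SvsConfig | None = None
                    ) -> dict[str, MetricsReport]:
    """Train the SVS classifier per category group under k-fold CV.

    Groups with no members are skipped with a warning.  The returned
    reports carry a ``best`` flag on the group with the highest AUC.
    """
    cfg = config or SvsConfig(fast=True, seed=seed)
    if cfg.cv_folds != cv_folds:
        from dataclasses import replace as _replace
        cfg = _replace(cfg, cv_folds=cv_folds)
    reports: dict[str, MetricsReport] = {}
    for group in groups:
        if len(group) < 1:
            warnings.warn(f"group {group.category!r} has no features; skipped")
            continue
        sub = table.select(list(group.members))
        reports[group.category] = cross_validate_svs(sub, cfg).pooled
    if reports:
        best = max(reports, key=lambda c: reports[c].auc)
        for cat, rep in reports.items():
            rep.best = (cat == best)  # type: ignore[attr-defined]
    return reports


def significance_screen(table: FeatureTable, alpha: float = 0.05
                        ) -> pd.DataFrame:
    """Per-feature two-sample rank test (Mann-Whitney U) with
    Benjamini-Hochberg correction; the tabular counterpart of the
    violin-plot screen.  Informative only — it does not gate selection."""
    y = table.labels
    X = table.values
    pvals = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        pos, neg = X[y == 1, j], X[y == 0, j]
        if pos.std() == 0 and neg.std() == 0 and pos.mean() == neg.mean():
            continue
        pvals[j] = stats.mannwhitneyu(pos, neg,
                                      alternative="two-sided").pvalue
    m = pvals.size
    order = np.argsort(pvals)
    qvals = np.empty(m)
    running = 1.0
    for rank_from_end, j in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, pvals[j] * m / rank)
        qvals[j] = running
    return pd.DataFrame({"pvalue": pvals, "qvalue": qvals,
                         "significant": qvals <= alpha},
                        index=table.feature_names)
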