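"""Per-model feature importance, min-max scaled to [0, 1] across features.

The method follows the model family: linear models expose coefficient
magnitudes, tree ensembles expose impurity-decrease importances, and the
remaining families (SVMs, kNN) are scored by permutation importance — the
mean drop in balanced accuracy over seeded shuffles of one feature column.
Raw scores are then rescaled per model with (x - min) / (max - min) so
rankings are comparable across families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance

from ecgpain.features import FEATURE_COLUMNS

#: Families whose raw scores come from coefficients / impurities / permutation.
COEF_FAMILIES = ("lda", "logistic")
TREE_FAMILIES = ("adaboost", "decision_tree", "random_forest")
PERMUTATION_FAMILIES = ("knn", "svm_linear", "svm_rbf")


class ConfigurationError(ValueError):
    """Unknown model family or invalid importance parameters."""


@dataclass
class ImportanceTable:
    """Raw and [0, 1]-scaled per-feature scores for one model family."""

    family: str
    features: tuple[str, ...]
    raw: np.ndarray
    scaled: np.ndarray
    raw_min: float
    raw_max: float
    degenerate: bool = False    # all raw scores equal -> all scaled 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": self.family,
            "feature": list(self.features),
            "raw": self.raw,
            "scaled": self.scaled,
        })


def raw_importance(model, family: str, X_test: np.ndarray, y_test: np.ndarray,
                   n_repeats: int = 10, seed: int = 0) -> np.ndarray:
    """Family-appropriate raw per-feature scores for a fitted model."""
    if family in COEF_FAMILIES:
        return np.abs(np.asarray(model.coef_)).ravel()
    if family in TREE_FAMILIES:
        return np.asarray(model.feature_importances_, dtype=float)
    if family in PERMUTATION_FAMILIES:
        if n_repeats < 1:
            raise ConfigurationError("permutation importance needs n_repeats >= 1")
        result = permutation_importance(
            model, X_test, y_test, scoring="balanced_accuracy",
            n_repeats=n_repeats, random_state=seed,
        )
        return np.asarray(result.importances_mean, dtype=float)
    raise ConfigurationError(f"unknown model family {family!r}")


def minmax_scale(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    """(x - min) / (max - min); all-equal input maps to all zeros, flagged."""
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("need at least 2 features to scale")
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        return np.zeros_like(raw), True
    return (raw - lo) / (hi - lo), False


def importance_table(model, family: str, X_test: np.ndarray,
                     y_test: np.ndarray,
                     features: tuple[str, ...] = tuple(FEATURE_COLUMNS),
                     n_repeats: int = 10, seed: int = 0) -> ImportanceTable:
    """Raw scores plus their min-max rescaling for one fitted model."""
    raw = raw_importance(model, family, X_test, y_test,
                         n_repeats=n_repeats, seed=seed)
    if raw.size != len(features):
        raise ConfigurationError(
            f"model yields {raw.size} scores for {len(features)} features"
        )
    scaled, degenerate = minmax_scale(raw)
    return ImportanceTable(
        family=family, features=tuple(features), raw=raw, scaled=scaled,
        raw_min=float(raw.min()), raw_max=float(raw.max()),
        degenerate=degenerate,
    )


@dataclass
class RankReport:
    """Per-model rankings and the cross-model consensus ranking."""

    per_model: dict[str, list[str]]
    consensus: pd.Series                # mean scaled score, descending
    table: pd.DataFrame = field(repr=False, default=None)

    def top(self, k: int) -> list[str]:
        return list(self.consensus.index[:k])


def rank_report(tables: list[ImportanceTable]) -> RankReport:
    """Descending per-model rankings plus a mean-scaled-score consensus.

    Ties are broken by feature-name order.
    """
    if not tables:
        raise ValueError("need at least one importance table")
    feature_sets = {t.features for t in tables}
    if len(feature_sets) != 1:
        raise ValueError("importance tables carry mismatched feature sets")

    long = pd.concat([t.to_frame() for t in tables], ignore_index=True)
    per_model: dict[str, list[str]] = {}
    for t in tables:
        order = sorted(
            zip(t.features, t.scaled),
            key=lambda fs: (-fs[1], fs[0]),
        )
        per_model[t.family] = [f for f, _ in order]
    consensus = (
        long.groupby("feature")["scaled"].mean()
        .sort_index()                       # tie-break: feature-name order
        .sort_values(ascending=False, kind="stable")
    )
    return RankReport(per_model=per_model, consensus=consensus, table=long)
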