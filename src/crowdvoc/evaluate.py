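"""Train/test split enumeration, ensemble training, and ROC/PRC scoring.

The study design is leave-one-film-out-per-class: for each age class one
film is placed in the test set and the class's remaining films train the
model, with test eligibility restricted to films with at least 8 recorded
screenings.  A configured "always together" film group (the two FSK-16
single-screening films of the measurement campaign) partitions its class
into exactly two options: the group itself, or all the class's other
films.  The Cartesian product of per-class options yields the split plan —
24 combinations for the campaign film list.

Per combination a 500-tree random forest (6 variables per split, i.e.
p/3 for the 18-feature set) is trained on the training screenings of one
compound and scored on the unseen test screenings; one-vs-rest ROC-AUC and
precision–recall curves are computed per class from the ensemble's class
probabilities and aggregated across combinations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_curve

from .errors import ConfigError
from .io import ScreeningRecord

log = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "SplitPlan",
    "EvalResult",
    "RECALL_GRID",
    "enumerate_splits",
    "attendance_filter",
    "train_classifier",
    "roc_auc",
    "prc_curve",
    "evaluate_compound",
    "combo_seed",
]

#: Common recall abscissa used to average PRC curves across combinations.
RECALL_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class ModelConfig:
    """Randomized-ensemble settings (campaign defaults: 500 trees, p/3)."""

    n_trees: int = 500
    vars_per_split: int | None = None  # None -> floor(p / 3)
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def resolve_vars(self, n_features: int) -> int:
        if self.vars_per_split is not None:
            if not (1 <= self.vars_per_split <= n_features):
                raise ValueError("vars_per_split out of range")
            return self.vars_per_split
        return max(1, n_features // 3)


@dataclass(frozen=True)
class SplitPlan:
    """Ordered train/test combinations; each maps class -> test film set."""

    classes: tuple[int, ...]
    combos: tuple[dict[int, frozenset[str]], ...]

    @property
    def n_combos(self) -> int:
        return len(self.combos)

    def test_films(self, combo_index: int) -> frozenset[str]:
        return frozenset().union(*self.combos[combo_index].values())

    def combos_with_test_film(self, film: str) -> list[int]:
        return [i for i in range(self.n_combos)
                if film in self.test_films(i)]


def enumerate_splits(screenings: list[ScreeningRecord],
                     min_test_screenings: int = 8,
                     together: frozenset[str] | None = None) -> SplitPlan:
    """Build the Cartesian-product split plan over per-class test options.

    Per class the options are the single films with at least
    ``min_test_screenings`` screenings, except in the class containing the
    ``together`` group, which is partitioned into two options: the group as
    one pooled test set, or all remaining films of the class pooled (no
    screening-count threshold in that class — single-screening films can
    only be evaluated jointly).
    """
    counts: dict[str, int] = {}
    film_class: dict[str, int] = {}
    for r in screenings:
        counts[r.film_title] = counts.get(r.film_title, 0) + 1
        if film_class.setdefault(r.film_title, r.age_class) != r.age_class:
            raise ConfigError(f"film {r.film_title!r} appears with two classes")
    classes = tuple(sorted({r.age_class for r in screenings}))
    together = frozenset(together or ())
    unknown = together - set(film_class)
    if together and unknown == together:
        together = frozenset()  # group absent from this study
    per_class_options: list[list[frozenset[str]]] = []
    for cls in classes:
        films = sorted(f for f, c in film_class.items() if c == cls)
        if together and together <= set(films):
            rest = frozenset(f for f in films if f not in together)
            if not rest:
                raise ConfigError(
                    f"class {cls}: the grouped films are its only films")
            options = [frozenset(together), rest]
        else:
            options = [frozenset({f}) for f in films
                       if counts[f] >= min_test_screenings]
        if not options:
            raise ConfigError(
                f"class {cls}: no eligible test film "
                f"(threshold {min_test_screenings} screenings)")
        per_class_options.append(options)
    combos = tuple(
        dict(zip(classes, choice))
        for choice in itertools.product(*per_class_options)
    )
    return SplitPlan(classes=classes, combos=combos)


def attendance_filter(screenings: list[ScreeningRecord],
                      min_viewers: int) -> list[ScreeningRecord]:
    """Drop screenings attended by fewer than ``min_viewers`` people."""
    if min_viewers < 0:
        raise ValueError("min_viewers must be >= 0")
    kept = [r for r in screenings if r.viewer_count >= min_viewers]
    if len(kept) < len(screenings):
        log.info("attendance filter (<%d viewers) removed %d screenings",
                 min_viewers, len(screenings) - len(kept))
    return kept


def train_classifier(train_features: np.ndarray, train_labels: np.ndarray,
                     config: ModelConfig) -> RandomForestClassifier:
    """Fit the randomized-tree ensemble; probabilities = tree vote fractions."""
    labels = np.asarray(train_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set holds a single class; cannot train")
    X = np.asarray(train_features, dtype=float)
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.resolve_vars(X.shape[1]),
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(X, labels)
    return model


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """One-vs-rest AUC as the Mann-Whitney ordering probability.

    Equals the mean over all (positive, negative) pairs of
    [score_pos > score_neg] + 0.5 [score_pos == score_neg], computed from
    midranks.  Returns NaN (logged) when either class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        log.warning("AUC undefined: %d positives, %d negatives", n_pos, n_neg)
        return float("nan")
    ranks = rankdata(scores)  # average ranks give the half-credit tie rule
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def prc_curve(scores: np.ndarray, labels: np.ndarray,
              grid: np.ndarray = RECALL_GRID) -> np.ndarray:
    """Precision interpolated onto a fixed recall grid for cross-combo
    averaging.  Returns an all-NaN vector (logged) when no positives exist."""
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() == 0:
        log.warning("PRC undefined: no positive items")
        return np.full(len(grid), np.nan)
    precision, recall, _ = precision_recall_curve(labels, np.asarray(scores, float))
    # several thresholds can share a recall; keep the best precision there
    frame = pd.DataFrame({"recall": recall, "precision": precision})
    best = frame.groupby("recall", sort=True)["precision"].max()
    return np.interp(grid, best.index.to_numpy(), best.to_numpy())


@dataclass
class EvalResult:
    """Per-class AUC and PRC aggregates over all split combinations."""

    compound_id: str
    classes: tuple[int, ...]
    plan: SplitPlan
    auc: dict[int, np.ndarray]         # class -> (n_combos,), NaN = undefined
    prc: dict[int, np.ndarray]         # class -> (n_combos, len(grid))
    recall_grid: np.ndarray = field(default_factory=lambda: RECALL_GRID.copy())

    def auc_mean(self, cls: int) -> float:
        vals = self.auc[cls]
        return float(np.nanmean(vals)) if np.any(~np.isnan(vals)) else float("nan")

    def auc_sd(self, cls: int) -> float:
        vals = self.auc[cls][~np.isnan(self.auc[cls])]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")

    def prc_mean(self, cls: int) -> np.ndarray:
        return np.nanmean(self.prc[cls], axis=0)

    def n_missing(self, cls: int) -> int:
        return int(np.isnan(self.auc[cls]).sum())

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"age_class": c,
                 "auc_mean": self.auc_mean(c),
                 "auc_sd": self.auc_sd(c),
                 "n_combos": self.plan.n_combos,
                 "n_missing": self.n_missing(c)}
                for c in self.classes]
        return pd.DataFrame(rows)

    def long_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.classes:
            for i, v in enumerate(self.auc[c]):
                rows.append({
                    "compound_id": self.compound_id, "age_class": c,
                    "combo": i,
                    "test_films": "|".join(sorted(self.plan.test_films(i))),
                    "auc": v})
        return pd.DataFrame(rows)


def combo_seed(master_seed: int, combo_index: int, salt: int = 0) -> int:
    """Deterministic per-combo RNG seed derived from the master seed."""
    ss = np.random.SeedSequence([master_seed, combo_index, salt])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def split_rows(features: pd.DataFrame, combo: dict[int, frozenset[str]]
               ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (train, test) row masks for one combination."""
    test_films = frozenset().union(*combo.values())
    is_test = features["film_title"].isin(test_films).to_numpy()
    return ~is_test, is_test


def evaluate_compound(features: pd.DataFrame, plan: SplitPlan,
                      config: ModelConfig, feature_cols: list[str],
                      compound_id: str = "") -> EvalResult:
    """Run every combination for one compound's feature table.

    ``features`` holds one row per screening with ``film_title``,
    ``age_class`` and the feature columns.  Per combination the model is
    trained on all screenings of non-test films, scored on test screenings,
    and one-vs-rest AUC/PRC computed per class; (combo, class) pairs whose
    test set lacks positives or negatives stay NaN and are excluded from
    aggregate means.
    """
    classes = plan.classes
    n = plan.n_combos
    auc = {c: np.full(n, np.nan) for c in classes}
    prc = {c: np.full((n, len(RECALL_GRID)), np.nan) for c in classes}
    X = features[feature_cols].to_numpy(dtype=float)
    y = features["age_class"].to_numpy()
    for i, combo in enumerate(plan.combos):
        train_mask, test_mask = split_rows(features, combo)
        cfg = ModelConfig(config.n_trees, config.vars_per_split,
                          seed=combo_seed(config.seed, i))
        model = train_classifier(X[train_mask], y[train_mask], cfg)
        proba = model.predict_proba(X[test_mask])
        y_test = y[test_mask]
        for c in classes:
            if c not in model.classes_:
                continue
            scores = proba[:, list(model.classes_).index(c)]
            is_pos = y_test == c
            auc[c][i] = roc_auc(scores, is_pos)
            if is_pos.any():
                prc[c][i] = prc_curve(scores, is_pos)
    for c in classes:
        missing = int(np.isnan(auc[c]).sum())
        if missing:
            log.info("compound %s class %s: %d/%d combos without a defined AUC",
                     compound_id, c, missing, n)
    return EvalResult(compound_id=compound_id, classes=classes, plan=plan,
                      auc=auc, prc=prc)
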