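"""Label-shuffled null distribution and permutation p-values.

For each train/test combination the training films' age-class labels are
shuffled *at film level* (all screenings of a film move together, and the
class distribution over films is retained); the test set keeps its true
labels.  The model is refit per shuffle (default k = 50 shuffles per
combination) and the resulting AUCs form the null.  The pooled p-value
counts, pairwise within each combination, how often a permuted AUC meets
or exceeds the original one:

    p = (b + 1) / (n + 1),

the add-one exceedance estimate, so p is never exactly zero.  The raw
fraction b/n is selectable for comparison.  Per-film p-values apply the
same formula restricted to the combinations whose test set contains the
film.  No multiple-testing correction is applied by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .evaluate import (EvalResult, ModelConfig, SplitPlan, combo_seed,
                       evaluate_compound, roc_auc, split_rows,
                       train_classifier)

log = logging.getLogger(__name__)

__all__ = ["PermutationResult", "shuffle_film_labels", "permutation_pvalue",
           "run_permutation_test", "holm_bonferroni"]


def holm_bonferroni(pvalues: np.ndarray) -> np.ndarray:
    """Step-down Holm-adjusted p-values (NaNs pass through untouched).

    Not applied by default — the analysis is a screen for candidate
    compounds — but available for a corrected report.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    idx = np.where(~np.isnan(p))[0]
    m = len(idx)
    order = idx[np.argsort(p[idx])]
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        out[i] = min(running, 1.0)
    return out


def shuffle_film_labels(film_labels: dict[str, int],
                        rng: np.random.Generator) -> dict[str, int]:
    """Uniformly permute the class labels over films (multiset preserved)."""
    if len(film_labels) < 2:
        raise ValueError("need at least 2 films to shuffle")
    films = sorted(film_labels)
    labels = np.array([film_labels[f] for f in films])
    return dict(zip(films, labels[rng.permutation(len(films))].tolist()))


def permutation_pvalue(original: np.ndarray, permuted: np.ndarray,
                       variant: str = "add_one") -> float:
    """Pooled exceedance p-value over combinations.

    ``original`` has one AUC per combination; ``permuted`` is
    (n_combos, k).  Exceedance (permuted >= original, ties against the
    original) is counted pairwise within each combination and pooled.
    NaN pairs (undefined AUCs) are dropped.  Returns NaN when no valid
    pairs remain.
    """
    if variant not in ("add_one", "raw"):
        raise ValueError(f"unknown p-value variant {variant!r}")
    original = np.asarray(original, dtype=float)
    permuted = np.asarray(permuted, dtype=float)
    if permuted.shape[0] != original.shape[0]:
        raise ValueError("combo dimension mismatch between original and permuted")
    valid = ~np.isnan(original)[:, None] & ~np.isnan(permuted)
    n = int(valid.sum())
    if n == 0:
        log.warning("permutation p-value undefined: no valid pairs")
        return float("nan")
    b = int((permuted >= original[:, None])[valid].sum())
    if variant == "raw":
        return b / n
    return (b + 1) / (n + 1)


@dataclass
class PermutationResult:
    """Original and permuted per-combination AUCs for one compound."""

    compound_id: str
    classes: tuple[int, ...]
    plan: SplitPlan
    original: dict[int, np.ndarray]   # class -> (n_combos,)
    permuted: dict[int, np.ndarray]   # class -> (n_combos, k)
    k: int

    def pvalue(self, cls: int, variant: str = "add_one") -> float:
        return permutation_pvalue(self.original[cls], self.permuted[cls], variant)

    def per_film_pvalue(self, cls: int, film: str,
                        variant: str = "add_one") -> float:
        """Pooled p-value over only the combos whose test set holds ``film``."""
        idx = self.plan.combos_with_test_film(film)
        if not idx:
            raise ConfigError(f"film {film!r} never appears in a test set")
        return permutation_pvalue(self.original[cls][idx],
                                  self.permuted[cls][idx], variant)

    def pvalue_frame(self, variant: str = "add_one") -> pd.DataFrame:
        return pd.DataFrame([
            {"compound_id": self.compound_id, "age_class": c,
             "p_value": self.pvalue(c, variant)}
            for c in self.classes])


def run_permutation_test(features: pd.DataFrame, plan: SplitPlan,
                         config: ModelConfig, feature_cols: list[str],
                         k: int = 50, compound_id: str = "",
                         original: EvalResult | None = None
                         ) -> PermutationResult:
    """Build the shuffled null for one compound's feature table.

    Training labels are shuffled film-wise ``k`` times per combination and
    the model refit each time; the test set keeps the original labels.
    ``original`` may pass a precomputed :func:`evaluate_compound` result to
    avoid refitting the unshuffled models.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if original is None:
        original = evaluate_compound(features, plan, config, feature_cols,
                                     compound_id=compound_id)
    classes = plan.classes
    n = plan.n_combos
    permuted = {c: np.full((n, k), np.nan) for c in classes}
    X = features[feature_cols].to_numpy(dtype=float)
    y = features["age_class"].to_numpy()
    films = features["film_title"].to_numpy()
    for i, combo in enumerate(plan.combos):
        train_mask, test_mask = split_rows(features, combo)
        y_test = y[test_mask]
        train_films = films[train_mask]
        film_labels = {f: int(c) for f, c in zip(train_films, y[train_mask])}
        rng = np.random.default_rng(combo_seed(config.seed, i, salt=1))
        for j in range(k):
            shuffled_map = shuffle_film_labels(film_labels, rng)
            y_shuffled = np.array([shuffled_map[f] for f in train_films])
            if len(np.unique(y_shuffled)) < 2:  # cannot happen when >=2 classes
                continue
            cfg = ModelConfig(config.n_trees, config.vars_per_split,
                              seed=combo_seed(config.seed, i, salt=2 + j))
            model = train_classifier(X[train_mask], y_shuffled, cfg)
            proba = model.predict_proba(X[test_mask])
            for c in classes:
                if c not in model.classes_:
                    continue
                scores = proba[:, list(model.classes_).index(c)]
                permuted[c][i, j] = roc_auc(scores, y_test == c)
    return PermutationResult(compound_id=compound_id, classes=classes,
                             plan=plan, original=original.auc,
                             permuted=permuted, k=k)
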