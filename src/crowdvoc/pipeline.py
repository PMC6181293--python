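"""End-to-end assembly: raw tables -> features -> evaluation -> report tables.

The tested interface of a run is a set of tab-separated tables written to
the output directory:

``features.tsv``       one row per (screening, compound) with the feature set
``box_fits.tsv``       per-(screening, compound) box-model fit audit
``auc_mean.tsv``       compounds x classes mean AUC (Table-3 analogue)
``auc_sd.tsv``         matching standard deviations
``pvalues.tsv``        permutation p-values per compound and class
``auc_long.tsv``       per-combination AUCs (box-plot data)
``prc_mean.tsv``       grid-averaged precision-recall curves
``per_film.tsv``       per-test-film AUC mean/sd and restricted p-values
``peak_heights.tsv``   highest robust peak per screening (per-class boxplots)
``report.txt``         human-readable summary; AUC >= 0.70 flagged with '*'
``manifest.json``      config hash and master seed
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .evaluate import (EvalResult, attendance_filter, enumerate_splits,
                       evaluate_compound)
from .features import extract_features, feature_names
from .io import (CompoundSeries, StudyTable, build_study, read_compound_table,
                 read_screenings)
from .permutation import (PermutationResult, holm_bonferroni,
                          run_permutation_test)
from .preprocess import preprocess_screening

log = logging.getLogger(__name__)

__all__ = ["RunResult", "load_study", "build_feature_table", "run_study",
           "write_outputs"]

AUC_FLAG_THRESHOLD = 0.70


@dataclass
class RunResult:
    features: pd.DataFrame
    fits: pd.DataFrame
    evals: dict[str, EvalResult]
    perms: dict[str, PermutationResult]


def load_study(cfg: RunConfig) -> tuple[StudyTable, dict[str, CompoundSeries]]:
    """Read and window the input tables; apply QC and attendance filters."""
    records = read_screenings(cfg.metadata_path, exclude_ids=cfg.exclude_ids)
    records = attendance_filter(records, cfg.min_viewers)
    tables = read_compound_table(cfg.compound_path)
    study = build_study(records, tables, cfg.preprocess.max_gap_steps)
    for r in study.screenings:
        if r.excluded:
            log.info("screening %s (%s) excluded", r.screening_id, r.film_title)
    return study, tables


def build_feature_table(study: StudyTable, cfg: RunConfig,
                        full_tables: dict[str, CompoundSeries] | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(screening, compound) feature vectors plus the fit audit table."""
    names = feature_names(cfg.features)
    rows, fit_rows = [], []
    for rec in study.active_screenings():
        for cid in study.compounds:
            window = study.series.get((rec.screening_id, cid))
            if window is None:
                continue
            full = full_tables.get(cid) if full_tables else None
            residuals, fit = preprocess_screening(
                window, rec, cfg.room, cfg.preprocess, full_series=full)
            feats = extract_features(residuals, cfg.features)
            rows.append({"screening_id": rec.screening_id,
                         "film_title": rec.film_title,
                         "age_class": rec.age_class,
                         "viewer_count": rec.viewer_count,
                         "compound_id": cid, **feats})
            fit_rows.append({"screening_id": rec.screening_id,
                             "compound_id": cid,
                             "emission_rate": fit.emission_rate,
                             "initial_value": fit.initial_value,
                             "inflow": fit.inflow,
                             "rms_misfit": fit.rms_misfit,
                             "n_samples": fit.n_samples})
    features = pd.DataFrame(rows)
    if not features.empty:
        assert list(features.columns[5:]) == names
    return features, pd.DataFrame(fit_rows)


def run_study(cfg: RunConfig, with_permutation: bool = True) -> RunResult:
    """The full analysis for every compound in the input table."""
    study, tables = load_study(cfg)
    features, fits = build_feature_table(study, cfg, tables)
    if features.empty:
        raise ValueError("no usable screenings after QC filtering")
    plan = enumerate_splits(study.active_screenings(),
                            cfg.min_test_screenings,
                            frozenset(cfg.always_together) or None)
    names = feature_names(cfg.features)
    evals: dict[str, EvalResult] = {}
    perms: dict[str, PermutationResult] = {}
    for cid in sorted(features["compound_id"].unique()):
        sub = features[features["compound_id"] == cid].reset_index(drop=True)
        evals[cid] = evaluate_compound(sub, plan, cfg.model, names,
                                       compound_id=cid)
        if with_permutation:
            perms[cid] = run_permutation_test(
                sub, plan, cfg.model, names, k=cfg.permutation_k,
                compound_id=cid, original=evals[cid])
    return RunResult(features=features, fits=fits, evals=evals, perms=perms)


def _matrix_frame(evals: dict[str, EvalResult], getter) -> pd.DataFrame:
    rows = {}
    for cid, res in evals.items():
        rows[cid] = {f"fsk{c}": getter(res, c) for c in res.classes}
    frame = pd.DataFrame(rows).T
    frame.index.name = "compound_id"
    return frame


def write_outputs(result: RunResult, cfg: RunConfig) -> Path:
    """Write every report table; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = dict(sep="\t", float_format="%.6g")
    result.features.to_csv(out / "features.tsv", index=False, **fmt)
    result.fits.to_csv(out / "box_fits.tsv", index=False, **fmt)

    auc_mean = _matrix_frame(result.evals, lambda r, c: r.auc_mean(c))
    auc_sd = _matrix_frame(result.evals, lambda r, c: r.auc_sd(c))
    auc_mean.to_csv(out / "auc_mean.tsv", **fmt)
    auc_sd.to_csv(out / "auc_sd.tsv", **fmt)

    pd.concat([r.long_frame() for r in result.evals.values()],
              ignore_index=True).to_csv(out / "auc_long.tsv", index=False, **fmt)

    prc_rows = []
    for cid, res in result.evals.items():
        for c in res.classes:
            mean_curve = res.prc_mean(c)
            for r_val, p_val in zip(res.recall_grid, mean_curve):
                prc_rows.append({"compound_id": cid, "age_class": c,
                                 "recall": r_val, "precision": p_val})
    pd.DataFrame(prc_rows).to_csv(out / "prc_mean.tsv", index=False, **fmt)

    if result.perms:
        pvals = pd.concat([p.pvalue_frame(cfg.pvalue_variant)
                           for p in result.perms.values()],
                          ignore_index=True)
        pvals.to_csv(out / "pvalues.tsv", index=False, **fmt)
        if cfg.holm_correction:
            corrected = pvals.copy()
            # adjust across compounds within each class (one family per class)
            for cls, group in pvals.groupby("age_class"):
                corrected.loc[group.index, "p_value"] = \
                    holm_bonferroni(group["p_value"].to_numpy())
            corrected.to_csv(out / "pvalues_holm.tsv", index=False, **fmt)

    per_film_rows = []
    for cid, res in result.evals.items():
        perm = result.perms.get(cid)
        films = {f for i in range(res.plan.n_combos)
                 for f in res.plan.test_films(i)}
        for film in sorted(films):
            idx = res.plan.combos_with_test_film(film)
            for c in res.classes:
                vals = res.auc[c][idx]
                vals = vals[~np.isnan(vals)]
                row = {"compound_id": cid, "film_title": film, "age_class": c,
                       "auc_mean": float(np.mean(vals)) if len(vals) else np.nan,
                       "auc_sd": (float(np.std(vals, ddof=1))
                                  if len(vals) > 1 else np.nan),
                       "n_combos": len(idx)}
                if perm is not None:
                    row["p_value"] = perm.per_film_pvalue(c, film,
                                                          cfg.pvalue_variant)
                per_film_rows.append(row)
    pd.DataFrame(per_film_rows).to_csv(out / "per_film.tsv", index=False, **fmt)

    peaks = result.features[["screening_id", "compound_id", "film_title",
                             "age_class", "height_1"]]
    peaks.to_csv(out / "peak_heights.tsv", index=False, **fmt)

    _write_report(out / "report.txt", result, cfg)
    manifest = {"config_digest": cfg.digest(), "seed": cfg.seed,
                "n_screenings": int(result.features["screening_id"].nunique()),
                "compounds": sorted(result.evals)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _write_report(path: Path, result: RunResult, cfg: RunConfig) -> None:
    lines = ["Per-compound one-vs-rest mean AUC over split combinations",
             f"(values >= {AUC_FLAG_THRESHOLD:.2f} flagged with *)", ""]
    classes = next(iter(result.evals.values())).classes if result.evals else ()
    header = f"{'compound':<14}" + "".join(f"{'FSK ' + str(c):>10}" for c in classes)
    lines.append(header)
    for cid, res in sorted(result.evals.items()):
        cells = []
        for c in classes:
            v = res.auc_mean(c)
            mark = "*" if (not np.isnan(v) and v >= AUC_FLAG_THRESHOLD) else " "
            cells.append(f"{v:>9.2f}{mark}" if not np.isnan(v) else f"{'NA':>10}")
        lines.append(f"{cid:<14}" + "".join(cells))
    if result.perms:
        lines += ["", "Permutation p-values (uncorrected)"]
        lines.append(header)
        for cid, perm in sorted(result.perms.items()):
            cells = [f"{perm.pvalue(c, cfg.pvalue_variant):>10.3f}"
                     for c in classes]
            lines.append(f"{cid:<14}" + "".join(cells))
    lines += ["", f"config digest: {cfg.digest()}  seed: {cfg.seed}"]
    path.write_text("\n".join(lines) + "\n")
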