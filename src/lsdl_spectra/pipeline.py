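"""End-to-end orchestration: simulate -> decompose -> features -> balance ->
evaluate, with deterministic stage seeding from one master seed."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .balancing import BalanceSpec, smote_balance
from .errors import StageError, ValidationError
from .features import FeatureConfig, FeatureMatrix, extract_matrix
from .lsdl import LSDLModel, apply_model, threshold_search
from .modeling import CVConfig, MetricsTable, pca_projection, run_grid
from .spectra_io import SpectraDataset, concatenate_datasets, write_spectra_csv
from .synthetic import CohortSpec, EffectSpec, generate_cohort, generate_grade_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "simulate", "reproduce", "concat_feature_matrices"]


@dataclass
class RunConfig:
    """Everything needed to regenerate a full run from scratch."""

    seed: int = 0
    cohort: CohortSpec | None = None
    effect: EffectSpec | None = None
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    balance: BalanceSpec | None = None
    cv: CVConfig | None = None
    n_iterations: int = 4
    levels_per_iteration: int = 16
    min_samples: int = 8
    grade_target_per_class: int = 20
    leakage_safe: bool = False
    output_dir: Path | None = None

    def __post_init__(self):
        # one master seed deterministically derives every stage seed
        ss = np.random.SeedSequence(self.seed)
        s_cohort, s_balance, s_cv = (int(s) for s in ss.generate_state(3) % (2**31))
        if self.cohort is None:
            self.cohort = CohortSpec(seed=s_cohort)
        if self.effect is None:
            self.effect = EffectSpec()
        if self.balance is None:
            self.balance = BalanceSpec(seed=s_balance)
        if self.cv is None:
            self.cv = CVConfig(seed=s_cv)
        if self.output_dir is not None:
            self.output_dir = Path(self.output_dir)

    @property
    def reduced_config(self) -> FeatureConfig:
        from dataclasses import replace

        return replace(self.feature_config, reduced_after_lsdl=True)


def concat_feature_matrices(a: FeatureMatrix, b: FeatureMatrix) -> FeatureMatrix:
    if a.feature_names != b.feature_names:
        raise ValidationError("feature matrices disagree on columns")
    return FeatureMatrix(
        X=np.vstack([a.X, b.X]),
        feature_names=a.feature_names,
        labels=np.concatenate([a.labels, b.labels]),
        sample_ids=np.concatenate([a.sample_ids, b.sample_ids]),
        is_synthetic=np.concatenate([a.is_synthetic, b.is_synthetic]),
    )


def simulate(config: RunConfig) -> dict[str, SpectraDataset]:
    """Generate the cancer/noncancer dataset pair (plus their concatenation)
    and the grade dataset pair from the configured cohort."""
    d1, d2 = generate_cohort(config.cohort, config.effect)
    d3 = concatenate_datasets(d1, d2, name="dataset3")
    g1, g2 = generate_grade_cohort(config.cohort, effect_high=config.effect)
    out = {"dataset1": d1, "dataset2": d2, "dataset3": d3,
           "grade_dataset1": g1, "grade_dataset2": g2}
    if config.output_dir is not None:
        config.output_dir.mkdir(parents=True, exist_ok=True)
        for name, ds in out.items():
            write_spectra_csv(ds, config.output_dir / f"{name}.csv")
    return out


def _lsdl_features(
    ds: SpectraDataset, model: LSDLModel, config: RunConfig
) -> FeatureMatrix:
    subs = apply_model(model, ds)
    keep = [i for i, s in enumerate(subs) if s.meets_min]
    dropped = len(subs) - len(keep)
    if dropped:
        logger.warning("%s: excluding %d under-sampled sub-signals", ds.name, dropped)
    labels = [ds.spectra[i].label for i in keep]
    ids = [ds.spectra[i].sample_id for i in keep]
    return extract_matrix(
        [subs[i] for i in keep], config.reduced_config, labels=labels, sample_ids=ids
    )


def _search(ds: SpectraDataset, config: RunConfig) -> LSDLModel:
    return threshold_search(
        ds,
        feature_config=config.reduced_config,
        n_iterations=config.n_iterations,
        levels_per_iteration=config.levels_per_iteration,
        min_samples=config.min_samples,
    )


def _balanced(fm: FeatureMatrix, config: RunConfig, target) -> FeatureMatrix:
    from dataclasses import replace

    return smote_balance(fm, replace(config.balance, target_per_class=target))


def reproduce(config: RunConfig) -> dict:
    """Full benchmark: 6 cancer/noncancer tables + 3 grade tables, the two
    learned threshold models, PCA projections and a provenance report."""
    out_dir = config.output_dir
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    try:
        cohorts = simulate(config)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("simulate", str(exc)) from exc
    d1, d2 = cohorts["dataset1"], cohorts["dataset2"]
    g1, g2 = cohorts["grade_dataset1"], cohorts["grade_dataset2"]

    # --- threshold learning (never on the concatenated dataset 3) ---------
    try:
        models = {"dataset1": _search(d1, config), "dataset2": _search(d2, config)}
        grade_models = {
            "grade_dataset1": _search(g1, config),
            "grade_dataset2": _search(g2, config),
        }
    except Exception as exc:
        raise StageError("decompose", str(exc)) from exc

    # --- feature extraction ----------------------------------------------
    try:
        raw = {name: extract_matrix(ds, config.feature_config)
               for name, ds in (("dataset1", d1), ("dataset2", d2))}
        lsdl = {name: _lsdl_features(ds, models[name], config)
                for name, ds in (("dataset1", d1), ("dataset2", d2))}
        grade_lsdl = {name: _lsdl_features(ds, grade_models[name], config)
                      for name, ds in (("grade_dataset1", g1), ("grade_dataset2", g2))}
    except Exception as exc:
        raise StageError("features", str(exc)) from exc

    # --- balancing (paper-faithful: before CV; leakage-safe: inside folds) -
    balance_in_folds = None
    grade_balance_in_folds = None
    try:
        from dataclasses import replace

        if config.leakage_safe:
            # in-fold targets are relative to the fold: balance to the fold's
            # majority (fixed absolute targets only make sense pre-CV)
            balance_in_folds = replace(config.balance, target_per_class="majority")
            grade_balance_in_folds = replace(
                config.balance, target_per_class="majority"
            )
            bal_raw, bal_lsdl, bal_grade = raw, lsdl, grade_lsdl
            logger.warning("leakage-safe mode: SMOTE runs inside training folds")
        else:
            logger.warning(
                "paper-faithful mode: SMOTE applied to the full table before CV"
            )
            bal_raw = {k: _balanced(v, config, "majority") for k, v in raw.items()}
            bal_lsdl = {k: _balanced(v, config, "majority") for k, v in lsdl.items()}
            bal_grade = {
                k: _balanced(v, config, config.grade_target_per_class)
                for k, v in grade_lsdl.items()
            }
        cancer_sets = {
            "dataset1": {"raw": bal_raw["dataset1"], "lsdl": bal_lsdl["dataset1"]},
            "dataset2": {"raw": bal_raw["dataset2"], "lsdl": bal_lsdl["dataset2"]},
            "dataset3": {
                "raw": concat_feature_matrices(bal_raw["dataset1"], bal_raw["dataset2"]),
                "lsdl": concat_feature_matrices(bal_lsdl["dataset1"], bal_lsdl["dataset2"]),
            },
        }
        grade_sets = {
            "grade_dataset1": {"lsdl": bal_grade["grade_dataset1"]},
            "grade_dataset2": {"lsdl": bal_grade["grade_dataset2"]},
            "grade_dataset3": {
                "lsdl": concat_feature_matrices(
                    bal_grade["grade_dataset1"], bal_grade["grade_dataset2"]
                )
            },
        }
    except Exception as exc:
        raise StageError("balance", str(exc)) from exc

    # --- evaluation -------------------------------------------------------
    try:
        tables = run_grid(cancer_sets, cv=config.cv,
                          balance_in_folds=balance_in_folds)
        grade_cv = config.cv
        if config.leakage_safe:
            # unbalanced grade folds: cap at the smallest real class size
            min_class = min(
                min(fm.class_counts.values())
                for reps in grade_sets.values()
                for fm in reps.values()
            )
            if min_class < grade_cv.folds:
                from dataclasses import replace

                logger.warning(
                    "leakage-safe grade CV reduced to %d folds "
                    "(smallest real class)", min_class,
                )
                grade_cv = replace(grade_cv, folds=min_class)
        tables.update(
            run_grid(grade_sets, cv=grade_cv,
                     balance_in_folds=grade_balance_in_folds)
        )
    except Exception as exc:
        raise StageError("evaluate", str(exc)) from exc

    # --- PCA separability projection (98% explained variance) -------------
    pca = {}
    for rep in ("raw", "lsdl"):
        fm = cancer_sets["dataset1"][rep]
        scores, evr, k = pca_projection(fm, variance_target=0.98)
        pca[rep] = {"scores": scores, "explained_variance_ratio": evr,
                    "n_components": k, "labels": fm.labels}

    counts = {
        "dataset1": len(cancer_sets["dataset1"]["lsdl"]),
        "dataset2": len(cancer_sets["dataset2"]["lsdl"]),
        "dataset3": len(cancer_sets["dataset3"]["lsdl"]),
        "grade_dataset1": len(grade_sets["grade_dataset1"]["lsdl"]),
        "grade_dataset2": len(grade_sets["grade_dataset2"]["lsdl"]),
        "grade_dataset3": len(grade_sets["grade_dataset3"]["lsdl"]),
    }
    counts["cancer_cumulative"] = (
        counts["dataset1"] + counts["dataset2"] + counts["dataset3"]
    )
    counts["grade_cumulative"] = (
        counts["grade_dataset1"] + counts["grade_dataset2"] + counts["grade_dataset3"]
    )

    result = {
        "tables": tables,
        "models": {**models, **grade_models},
        "pca": pca,
        "counts": counts,
        "config": config,
    }
    if out_dir is not None:
        _write_outputs(result, config, out_dir)
    return result


def _write_outputs(result: dict, config: RunConfig, out_dir: Path) -> None:
    import pandas as pd

    tables: dict[tuple[str, str], MetricsTable] = result["tables"]
    md_parts = []
    for (ds, rep), table in tables.items():
        table.to_dataframe(rounded=True).to_csv(
            out_dir / f"metrics_{ds}_{rep}.csv", index=False
        )
        table.to_dataframe(rounded=False).to_csv(
            out_dir / f"metrics_{ds}_{rep}_unrounded.csv", index=False
        )
        md_parts.append(table.to_markdown())
    (out_dir / "metrics_tables.md").write_text("\n\n".join(md_parts), encoding="utf-8")

    for name, model in result["models"].items():
        model.save(out_dir / f"lsdl_model_{name}.json")
        rows = []
        for direction, entries in model.search_table().items():
            for e in entries:
                rows.append({"direction": direction, **e})
        pd.DataFrame(rows).to_csv(out_dir / f"lsdl_search_{name}.csv", index=False)

    for rep, p in result["pca"].items():
        df = pd.DataFrame(p["scores"], columns=["PC1", "PC2"])
        df["label"] = p["labels"]
        df.to_csv(out_dir / f"pca_{rep}.csv", index=False)
        _plot_pca(p, out_dir / f"pca_{rep}.png", rep)

    report = {
        "package_version": __version__,
        "seed": config.seed,
        "leakage_safe": config.leakage_safe,
        "counts": result["counts"],
        "n_tables": len(tables),
        "stage_seeds": {
            "cohort": config.cohort.seed,
            "balance": config.balance.seed,
            "cv": config.cv.seed,
        },
        "lsdl": {
            name: model.to_dict()["scheme"]
            for name, model in result["models"].items()
        },
        "versions": _versions(),
    }
    (out_dir / "run_report.json").write_text(
        json.dumps(report, indent=2), encoding="utf-8"
    )


def _plot_pca(p: dict, path: Path, rep: str) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # pragma: no cover - plotting is best-effort
        return
    fig, ax = plt.subplots(figsize=(5, 4))
    labels = np.asarray(p["labels"]).astype(str)
    colors = {"cancer": "tab:blue", "high_grade": "tab:blue"}
    for lbl in np.unique(labels):
        m = labels == lbl
        ax.scatter(p["scores"][m, 0], p["scores"][m, 1],
                   c=colors.get(lbl, "tab:red"), label=lbl, s=18, alpha=0.8)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title(f"{rep} features ({p['n_components']} PCs @ 98% var)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _versions() -> dict[str, str]:
    import sklearn
    import scipy
    import pandas

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
    }
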