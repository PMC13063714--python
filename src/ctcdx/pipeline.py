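"""End-to-end orchestration: simulate -> holdout -> ensembles -> diagnostics.

A run executes the full workflow on a synthetic (or supplied) cohort and
leaves a self-describing run directory::

    run_dir/
      manifest.json     every seed, grid and setting used
      cohort.csv        the analysed cohort
      family_table.csv  per-(family, feature set) mean AUC / CER
      predictions.csv   test-set predictions of the selected ensemble
      report.json       confusion metrics, ROC, threshold sweep, subgroups
      model/            fitted selected ensemble (joblib) + summary JSON

Re-running with the same manifest settings reproduces identical outputs;
every random draw derives from the single master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .cohort import Cohort, GeneratorConfig, compare_features, generate_cohort
from .ensemble import (
    FAMILIES,
    FEATURE_SETS,
    MCCVEnsembleClassifier,
    SplitPlan,
    compare_families,
    stratified_holdout,
)
from .metrics import (
    confusion_metrics,
    probability_group_tests,
    roc_auc,
    round_half_up,
    subgroup_metrics,
    sweep_thresholds,
)

__all__ = ["RunConfig", "run_pipeline", "make_report", "SCALES"]

logger = logging.getLogger(__name__)

#: Named problem scales: 'desk' finishes in minutes on one CPU, 'paper'
#: restores the study design (1000 splits, full grids, 10,000-tree GBM).
SCALES = {
    "desk": {"n_mc_splits": 100, "grid_scale": "desk", "imputer_trees": 30},
    "paper": {"n_mc_splits": 1000, "grid_scale": "paper", "imputer_trees": 100},
}


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    seed: int = 0
    scale: str = "desk"
    families: tuple[str, ...] = ("svm_linear",)
    feature_sets: tuple[str, ...] = ("model1", "model2")
    test_size: int = 48
    n_mc_splits: int | None = None  # None: taken from the scale tag
    cohort_csv: str | None = None  # None: simulate under the study conditions
    n_cancer: int = 228
    n_benign: int = 170
    exclude_families: tuple[str, ...] = ()
    prefer_family: str | None = None
    n_bootstrap: int = 2000
    subgroups: tuple[str, ...] = ("birads34",)
    vote_rule: str = "mean"
    n_jobs: int = 1
    out_dir: str = "ctcdx_run"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {sorted(SCALES)}")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families {sorted(unknown)}")
        unknown_fs = set(self.feature_sets) - set(FEATURE_SETS)
        if unknown_fs:
            raise ValueError(f"unknown feature sets {sorted(unknown_fs)}")

    @property
    def resolved_splits(self) -> int:
        return self.n_mc_splits or SCALES[self.scale]["n_mc_splits"]


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))


def _evaluate_on_test(
    model: MCCVEnsembleClassifier,
    test: Cohort,
    feature_cols: list[str],
    config: RunConfig,
) -> tuple[pd.DataFrame, dict]:
    X_test = test.frame[feature_cols]
    y_test = test.y
    proba = model.predict_proba(X_test)[:, 1]
    votes = model.vote_fraction(X_test)
    scores = proba if config.vote_rule == "mean" else votes
    pred = (scores > model.threshold).astype(int)

    predictions = pd.DataFrame(
        {
            "subject_id": test.frame["subject_id"].to_numpy(),
            "ensemble_probability": proba,
            "vote_fraction": votes,
            "label": pred,
        }
    )
    truth = pd.DataFrame(
        {"subject_id": test.frame["subject_id"].to_numpy(), "probability": scores,
         "label": y_test}
    )

    cs = confusion_metrics(y_test, scores, threshold=model.threshold)
    roc = roc_auc(
        y_test, scores, n_bootstrap=config.n_bootstrap, random_state=config.seed
    )
    block = {
        "confusion": cs.as_dict(),
        "confusion_rounded": cs.as_dict(rounded=True),
        "probability_tests": probability_group_tests(scores, y_test),
        "roc": roc.as_dict(),
        "threshold_sweep": sweep_thresholds(y_test, scores).reset_index().to_dict(
            orient="records"
        ),
        "subgroups": {
            g: subgroup_metrics(truth, test.frame, g, threshold=model.threshold)
            for g in config.subgroups
        },
    }
    return predictions, block


def run_pipeline(config: RunConfig, resume: bool = False) -> Path:
    """Execute the full analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if resume and manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError as err:
            raise RuntimeError(f"corrupted manifest at {manifest_path}: {err}")
        if previous.get("config") != _config_dict(config):
            raise RuntimeError("manifest does not match the requested config")
        if (out / "report.json").exists():
            logger.info("run already complete; nothing to do")
            return out

    # 1. cohort
    cohort_path = out / "cohort.csv"
    if config.cohort_csv:
        cohort = Cohort.from_csv(config.cohort_csv)
    elif resume and cohort_path.exists():
        cohort = Cohort.from_csv(cohort_path, provenance="resumed")
    else:
        cohort = generate_cohort(
            GeneratorConfig(
                n_cancer=config.n_cancer, n_benign=config.n_benign, seed=config.seed
            )
        )
    cohort.to_csv(cohort_path)
    feature_report = compare_features(cohort)
    feature_report.to_csv(out / "feature_comparison.csv")

    # 2. holdout
    plan = SplitPlan(
        seed=config.seed,
        test_size=config.test_size,
        n_mc_splits=config.resolved_splits,
    )
    train, test = stratified_holdout(cohort, plan)

    # 3. per-family ensembles on the training cohort
    scale = SCALES[config.scale]
    feature_sets = {name: FEATURE_SETS[name] for name in config.feature_sets}
    y_train = train.y
    table, selected, models = compare_families(
        train.frame,
        y_train,
        families=config.families,
        feature_sets=feature_sets,
        exclude=config.exclude_families,
        prefer=config.prefer_family,
        return_models=True,
        n_mc_splits=config.resolved_splits,
        scale=scale["grid_scale"],
        imputer_trees=scale["imputer_trees"],
        vote_rule=config.vote_rule,
        n_jobs=config.n_jobs,
        random_state=config.seed,
    )
    table.to_csv(out / "family_table.csv", index=False)

    # 4. test predictions + diagnostics for every feature set of the
    #    selected family (the study reports both feature sets side by side)
    sel_family = selected[0]
    report: dict = {
        "selected": {"family": sel_family, "feature_set": selected[1]},
        "family_table": table.to_dict(orient="records"),
        "feature_sets": {},
    }
    for fs_name in config.feature_sets:
        model = models[(sel_family, fs_name)]
        predictions, block = _evaluate_on_test(
            model, test, feature_sets[fs_name], config
        )
        block["validation_summary"] = model.summary_
        report["feature_sets"][fs_name] = block
        suffix = "" if fs_name == selected[1] else f"_{fs_name}"
        predictions.to_csv(out / f"predictions{suffix}.csv", index=False)

    model_dir = out / "model"
    model_dir.mkdir(exist_ok=True)
    sel_model = models[selected]
    _write_json(
        model_dir / "summary.json",
        {
            "family": sel_family,
            "feature_set": selected[1],
            "params_by_member": [m.params for m in sel_model.members_],
            "validation": sel_model.summary_,
        },
    )
    joblib.dump(sel_model, model_dir / "model.joblib")

    _write_json(out / "report.json", report)
    _write_json(manifest_path, {"config": _config_dict(config), "version": 1})
    return out


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return f"{round_half_up(float(x)):.2f}"


def make_report(run_dir) -> str:
    """Render a human-readable summary of a completed run."""
    run_dir = Path(run_dir)
    report_path = run_dir / "report.json"
    if not report_path.exists():
        raise FileNotFoundError(f"no report.json under {run_dir}")
    report = json.loads(report_path.read_text())
    lines = []
    sel = report["selected"]
    lines.append("# Run summary")
    lines.append(f"Selected model: {sel['family']} / {sel['feature_set']}")
    lines.append("")
    lines.append("## Ensemble family comparison (validation)")
    lines.append("family | feature_set | AUC (95% dispersion) | CER (SD)")
    lines.append("--- | --- | --- | ---")
    for row in report.get("family_table", []):
        lines.append(
            f"{row['family']} | {row['feature_set']} | "
            f"{_fmt(row['auc_mean'])} ({_fmt(row['auc_ci_lo'])}, "
            f"{_fmt(row['auc_ci_hi'])}) | {_fmt(row['cer_mean'])} "
            f"({_fmt(row['cer_sd'])})"
        )
    for fs_name, block in report.get("feature_sets", {}).items():
        lines.append("")
        lines.append(f"## Test-set performance — {fs_name}")
        cs = block.get("confusion")
        if not cs:
            lines.append("(missing block)")
            continue
        lines.append(
            f"counts: tp={cs['tp']} fp={cs['fp']} tn={cs['tn']} fn={cs['fn']}"
        )
        lines.append(
            "sensitivity {s} | specificity {sp} | accuracy {a} | "
            "PPV {p} | NPV {n}".format(
                s=_fmt(cs["sensitivity"]),
                sp=_fmt(cs["specificity"]),
                a=_fmt(cs["accuracy"]),
                p=_fmt(cs["ppv"]),
                n=_fmt(cs["npv"]),
            )
        )
        roc = block.get("roc", {})
        if roc:
            lines.append(
                f"test AUC {_fmt(roc['auc'])} "
                f"(DeLong {_fmt(roc['auc_ci_delong'][0])}-"
                f"{_fmt(roc['auc_ci_delong'][1])}, "
                f"bootstrap {_fmt(roc['auc_ci_bootstrap'][0])}-"
                f"{_fmt(roc['auc_ci_bootstrap'][1])}, "
                f"{roc['n_bootstrap']} replicates)"
            )
        pt = block.get("probability_tests", {})
        if pt:
            lines.append(
                f"probabilities: cancer {_fmt(pt['cancer_mean'])} "
                f"(±{_fmt(pt['cancer_sd'])}), benign {_fmt(pt['benign_mean'])} "
                f"(±{_fmt(pt['benign_sd'])}); WMW p={pt['wmw_p']:.2e}, "
                f"KS p={pt['ks_p']:.2e}"
            )
        for gname, sub in block.get("subgroups", {}).items():
            lines.append(f"### Subgroup: {gname}")
            if not sub["levels"]:
                lines.append("(n too small)")
            for level, stats_ in sorted(sub["levels"].items()):
                if stats_["n"] < 2:
                    lines.append(f"{level}: n too small (n={stats_['n']})")
                    continue
                lines.append(
                    f"{level}: n={stats_['n']} prevalence {_fmt(stats_['prevalence'])} "
                    f"sens {_fmt(stats_['sensitivity'])} spec {_fmt(stats_['specificity'])} "
                    f"acc {_fmt(stats_['accuracy'])} ppv {_fmt(stats_['ppv'])} "
                    f"npv {_fmt(stats_['npv'])}"
                )
    text = "\n".join(lines) + "\n"
    (run_dir / "report.md").write_text(text)
    return text
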