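"""End-to-end runner binding the modules into one seeded workflow.

Stages run in dependency order (generate -> preprocess -> train ->
evaluate -> entropy -> operate -> tea -> report); each writes CSV/JSON
artifacts plus a manifest (seed, input hashes, package version) into
the run directory, so stages are individually re-runnable and a rerun
with identical configuration is bit-identical for deterministic stages.
A single global seed fans out to per-stage seeds by fixed offsets.
"""

from __future__ import annotations

import hashlib
import json
import pickle
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .entropy import (
    KDEConfig,
    StateRules,
    entropy_increase,
    model_error_entropy,
    state_distribution,
)
from .evaluate import (
    classification_metrics,
    permutation_delta_rmse,
    regression_metrics,
    rf_importance,
)
from .exceptions import DependencyError
from .models import (
    ANNSpec,
    RFSpec,
    SVMSpec,
    fit_model,
    label_high_yield,
)
from .operation import (
    AdvisoryPolicy,
    DisturbanceModel,
    compare_daily_indices,
    simulate_operation,
    stability_improvement,
)
from .preprocess import (
    SplitSpec,
    ks_similarity,
    minmax_apply,
    minmax_fit,
    pearson_matrix,
    remove_outliers,
    select_features,
    split,
)
from .synth import (
    INPUT_VARIABLES,
    OUTPUT_VARIABLES,
    GeneratorConfig,
    PlantDataGenerator,
    default_config,
    read_records,
    write_records,
)
from .tea import (
    _emission_presets,
    annual_saving,
    carbon_reduction,
    discounted_payback,
    npv_of_savings,
    payback_sensitivity,
)

__all__ = ["STAGES", "run_pipeline"]

STAGES = ("generate", "preprocess", "train", "evaluate", "entropy", "operate", "tea", "report")

#: per-stage seed offsets from the global seed
_SEED_OFFSETS = {"generate": 0, "train": 100, "entropy": 200, "operate": 300}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _manifest(outdir: Path, stage: str, seed: int, inputs: list[Path], outputs: list[Path]):
    manifest = {
        "stage": stage,
        "seed": seed,
        "version": __version__,
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def _require(outdir: Path, filename: str, producer: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise DependencyError(
            f"missing artifact {filename!r}; run the {producer!r} stage first"
        )
    return path


def run_pipeline(config: RunConfig | None = None, stages=None, outdir="run") -> Path:
    """Execute the requested stages (all by default) into ``outdir``."""
    config = config if config is not None else RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage in requested:
        t0 = time.time()
        _STAGE_FUNCS[stage](config, outdir)
        (outdir / "timings.log").open("a").write(
            f"{stage}\t{time.time() - t0:.2f}s\n"
        )
    return outdir


def _generator_config(config: RunConfig) -> GeneratorConfig:
    return default_config(
        fault_rate=config.generator.fault_rate,
        seasonal_temp_amplitude=config.generator.seasonal_temp_amplitude,
        seed=config.seed + _SEED_OFFSETS["generate"],
    )


def _stage_generate(config: RunConfig, outdir: Path) -> None:
    gen = PlantDataGenerator(_generator_config(config))
    table = gen.generate(config.generator.n)
    out = outdir / "records.csv"
    write_records(table, out)
    _manifest(outdir, "generate", config.seed, [], [out])


def _stage_preprocess(config: RunConfig, outdir: Path) -> None:
    records = read_records(_require(outdir, "records.csv", "generate"))
    clean, removed = remove_outliers(records)
    spec = SplitSpec(mode=config.preprocess.split_mode, seed=config.seed)
    train, val, test = split(clean, spec)

    variables = list(INPUT_VARIABLES) + list(OUTPUT_VARIABLES)
    params = minmax_fit(train, variables)
    corr = pearson_matrix(train, variables)
    core, aux = select_features(corr, "biogas_yield", config.preprocess.core_threshold)

    ks_rows = []
    for var in variables:
        for name, other in (("validation", val), ("test", test)):
            D, p = ks_similarity(train[var], other[var])
            ks_rows.append({"variable": var, "subset": name, "D": D, "p": p})

    outputs = []
    for name, block in (("train", train), ("validation", val), ("test", test)):
        path = outdir / f"{name}.csv"
        write_records(block, path)
        outputs.append(path)
    (outdir / "normalization.json").write_text(json.dumps(params.to_dict(), indent=2))
    corr.to_csv(outdir / "correlation_matrix.csv")
    pd.DataFrame(ks_rows).to_csv(outdir / "ks_check.csv", index=False)
    (outdir / "features.json").write_text(
        json.dumps({"core": core, "auxiliary": aux, "removed_outliers": removed}, indent=2)
    )
    outputs += [
        outdir / "normalization.json",
        outdir / "correlation_matrix.csv",
        outdir / "ks_check.csv",
        outdir / "features.json",
    ]
    _manifest(outdir, "preprocess", config.seed, [outdir / "records.csv"], outputs)


def _load_blocks(config: RunConfig, outdir: Path):
    from .preprocess import NormalizationParams

    train = read_records(_require(outdir, "train.csv", "preprocess"))
    val = read_records(_require(outdir, "validation.csv", "preprocess"))
    test = read_records(_require(outdir, "test.csv", "preprocess"))
    params = NormalizationParams.from_dict(
        json.loads(_require(outdir, "normalization.json", "preprocess").read_text())
    )
    return train, val, test, params


def _stage_train(config: RunConfig, outdir: Path) -> None:
    train, val, test, params = _load_blocks(config, outdir)
    feats = list(INPUT_VARIABLES)
    targs = list(OUTPUT_VARIABLES)
    trs, vas = minmax_apply(train, params), minmax_apply(val, params)
    seed = config.seed + _SEED_OFFSETS["train"]

    m = config.models
    specs = {
        "svm_clf": SVMSpec(task="classify", C=m.svm.C, gamma=m.svm.gamma),
        "svm": SVMSpec(task="regress", C=m.svm.C, gamma=m.svm.gamma, epsilon=m.svm.epsilon),
        "rf_clf": RFSpec(m.rf.n_trees, m.rf.max_depth, m.rf.mtry, seed=seed),
        "rf": RFSpec(m.rf.n_trees, m.rf.max_depth, m.rf.mtry, seed=seed),
        "ann": ANNSpec(
            hidden_sizes=tuple(m.ann.hidden_sizes),
            learning_rate=m.ann.learning_rate,
            batch_size=m.ann.batch_size,
            l2_lambda=m.ann.l2_lambda,
            max_epochs=m.ann.max_epochs,
            early_stop_patience=m.ann.early_stop_patience,
            seed=seed,
        ),
    }
    labels = pd.Series(label_high_yield(train["biogas_yield"]), index=train.index)
    fitted = {
        "svm_clf": fit_model(specs["svm_clf"], trs[feats], labels, normalization=params),
        "svm": fit_model(specs["svm"], trs[feats], trs[targs], normalization=params),
        "rf_clf": fit_model(specs["rf_clf"], trs[feats], labels, normalization=params),
        "rf": fit_model(specs["rf"], trs[feats], trs[targs], normalization=params),
        "ann": fit_model(
            specs["ann"],
            trs[feats],
            trs[targs],
            validation=(vas[feats], vas[targs]),
            normalization=params,
        ),
    }
    path = outdir / "models.pkl"
    with open(path, "wb") as fh:
        pickle.dump(fitted, fh)
    _manifest(outdir, "train", seed, [outdir / "train.csv"], [path])


def _load_models(outdir: Path) -> dict:
    with open(_require(outdir, "models.pkl", "train"), "rb") as fh:
        return pickle.load(fh)


def _stage_evaluate(config: RunConfig, outdir: Path) -> None:
    train, val, test, params = _load_blocks(config, outdir)
    fitted = _load_models(outdir)
    feats = list(INPUT_VARIABLES)
    tes = minmax_apply(test, params)
    rows = []
    test_labels = label_high_yield(test["biogas_yield"])
    for name in ("svm", "rf", "ann"):
        # classification of high/low yield
        if name == "ann":
            pred = fitted["ann"].predict(tes[feats])
            lo, hi = params.bounds("biogas_yield")
            biogas_pred = pred["biogas_yield"].to_numpy() * (hi - lo) + lo
            labels_pred = label_high_yield(biogas_pred)
            scores = biogas_pred
        else:
            out = fitted[f"{name}_clf"].predict(tes[feats])
            labels_pred, scores = out["label"].to_numpy(), out["score"].to_numpy()
        cm = classification_metrics(test_labels, labels_pred, scores)
        rows.append(
            {
                "model": name,
                "metric_group": "classification",
                "target": "high_yield",
                "accuracy": cm.accuracy,
                "recall": cm.recall,
                "f1": cm.f1,
                "auroc": cm.auroc,
            }
        )
        # regression per target, in original units
        pred = fitted[name].predict(tes[feats])
        r2s = []
        for target in OUTPUT_VARIABLES:
            lo, hi = params.bounds(target)
            y_hat = pred[target].to_numpy() * (hi - lo) + lo
            m = regression_metrics(test[target].to_numpy(), y_hat)
            r2s.append(m.r2)
            rows.append(
                {
                    "model": name,
                    "metric_group": "regression",
                    "target": target,
                    "rmse": m.rmse,
                    "r2": m.r2,
                }
            )
        rows.append(
            {
                "model": name,
                "metric_group": "regression",
                "target": "average",
                "r2": float(np.mean(r2s)),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "metrics.csv", index=False)

    imp = rf_importance(fitted["rf"], target="biogas_yield")
    imp.to_csv(outdir / "rf_importance.csv", header=True)

    perm_rows = []
    trs = minmax_apply(train, params)
    for feature in INPUT_VARIABLES:
        d = permutation_delta_rmse(
            fitted["ann"], tes[feats], tes[list(OUTPUT_VARIABLES)], feature,
            seed=config.seed, target="biogas_yield",
        )
        perm_rows.append({"feature": feature, "delta_rmse": d})
    pd.DataFrame(perm_rows).to_csv(outdir / "permutation_delta_rmse.csv", index=False)
    _manifest(
        outdir,
        "evaluate",
        config.seed,
        [outdir / "test.csv", outdir / "models.pkl"],
        [outdir / "metrics.csv", outdir / "rf_importance.csv", outdir / "permutation_delta_rmse.csv"],
    )


def _stage_entropy(config: RunConfig, outdir: Path) -> None:
    train, val, test, params = _load_blocks(config, outdir)
    fitted = _load_models(outdir)
    feats = list(INPUT_VARIABLES)
    tes = minmax_apply(test, params)
    kde = KDEConfig(estimator=config.entropy.estimator)
    seed = config.seed + _SEED_OFFSETS["entropy"]

    rows = []
    for name in ("svm", "rf", "ann"):
        for target in OUTPUT_VARIABLES:
            res = model_error_entropy(
                fitted[name], tes[feats], tes[list(OUTPUT_VARIABLES)], kde, target=target
            )
            rows.append(
                {
                    "model": name,
                    "target": target,
                    "H": res.H,
                    "bandwidth": res.bandwidth,
                    "n": res.n,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "entropy_summary.csv", index=False)

    imp = pd.read_csv(outdir / "rf_importance.csv", index_col=0)["importance_share"]
    perm = pd.read_csv(outdir / "permutation_delta_rmse.csv").set_index("feature")["delta_rmse"]
    feat_rows = []
    for feature in INPUT_VARIABLES:
        res = entropy_increase(
            fitted["ann"], tes[feats], tes[list(OUTPUT_VARIABLES)], feature,
            n_perm=config.entropy.n_perm, seed=seed, config=kde, target="biogas_yield",
        )
        feat_rows.append(
            {
                "feature": feature,
                "delta_H": res.delta_H,
                "delta_rmse": float(perm[feature]),
                "rf_share": float(imp[feature]),
            }
        )
    pd.DataFrame(feat_rows).to_csv(outdir / "feature_entropy.csv", index=False)

    states = state_distribution(test, StateRules(), config.entropy.state_window)
    state_rows = [
        {"window": str(s.window), **{k: v for k, v in s.counts}} for s in states
    ]
    pd.DataFrame(state_rows).to_csv(outdir / "state_windows.csv", index=False)
    _manifest(
        outdir,
        "entropy",
        seed,
        [outdir / "test.csv", outdir / "models.pkl"],
        [outdir / "entropy_summary.csv", outdir / "feature_entropy.csv", outdir / "state_windows.csv"],
    )


def _stage_operate(config: RunConfig, outdir: Path) -> None:
    fitted = _load_models(outdir)
    op = config.operation
    dist = DisturbanceModel(
        shock_rate_per_hour=op.shock_rate_per_hour,
        shock_sd=op.shock_sd,
        unpredictable_sd=op.unpredictable_sd,
        seasonal_amplitude=op.seasonal_amplitude,
    )
    seed = config.seed + _SEED_OFFSETS["operate"]
    gen_cfg = _generator_config(config)
    baseline = simulate_operation(None, op.weeks, dist, seed, gen_cfg)
    policy = AdvisoryPolicy(model=fitted["ann"], gain=op.gain)
    assisted = simulate_operation(policy, op.weeks, dist, seed, gen_cfg)
    t, p = compare_daily_indices(baseline.daily_cv, assisted.daily_cv)
    summary = {
        "cv_baseline": baseline.cv,
        "cv_assisted": assisted.cv,
        "improvement": stability_improvement(baseline.cv, assisted.cv),
        "t_statistic": t,
        "p_value": p,
        "s_proc_baseline": baseline.s_proc,
        "s_proc_assisted": assisted.s_proc,
        "degradation_baseline": float(baseline.degradation.mean()),
        "degradation_assisted": float(assisted.degradation.mean()),
        "weeks": op.weeks,
        "seed": seed,
    }
    (outdir / "operation_summary.json").write_text(json.dumps(summary, indent=2))
    hourly = pd.DataFrame(
        {"baseline": baseline.hourly_yield, "assisted": assisted.hourly_yield}
    )
    hourly.to_csv(outdir / "hourly_yield.csv")
    pd.DataFrame(
        {"baseline": baseline.daily_cv, "assisted": assisted.daily_cv}
    ).to_csv(outdir / "daily_cv.csv", index=False)
    _manifest(
        outdir,
        "operate",
        seed,
        [outdir / "models.pkl"],
        [outdir / "operation_summary.json", outdir / "hourly_yield.csv", outdir / "daily_cv.csv"],
    )


def _stage_tea(config: RunConfig, outdir: Path) -> None:
    t = config.tea
    annual = annual_saving(t.operating_saving, t.capacity)
    throughput = t.capacity * 330.0
    rows = []
    for scen in _emission_presets(t.baseline_energy_intensity):
        energy, co2 = carbon_reduction(scen, throughput)
        rows.append(
            {
                "scenario": scen.region,
                "grid_factor": scen.grid_factor,
                "energy_saved_kwh_y": energy,
                "co2_avoided_kg_y": co2,
            }
        )
    payback = discounted_payback(t.capex, annual, t.discount_rate, t.lifetime)
    econ = {
        "capex": t.capex,
        "annual_saving": annual,
        "npv_savings": npv_of_savings(annual, t.discount_rate, t.lifetime),
        "payback_years": payback,
    }
    pd.DataFrame(rows).to_csv(outdir / "emissions.csv", index=False)
    (outdir / "tea_summary.json").write_text(json.dumps(econ, indent=2))
    payback_sensitivity(t.capex, t.capacity).to_csv(outdir / "payback_sensitivity.csv", index=False)
    _manifest(
        outdir,
        "tea",
        config.seed,
        [],
        [outdir / "emissions.csv", outdir / "tea_summary.json", outdir / "payback_sensitivity.csv"],
    )


def _stage_report(config: RunConfig, outdir: Path) -> None:
    """Assemble a plain-text report strictly from stage artifacts."""
    lines = [f"adentropy run report (seed {config.seed})", "=" * 40]
    metrics = outdir / "metrics.csv"
    if metrics.exists():
        lines += ["", "Model performance (test set):", pd.read_csv(metrics).to_string(index=False)]
    entropy_csv = outdir / "entropy_summary.csv"
    if entropy_csv.exists():
        lines += ["", "Error entropy (nats):", pd.read_csv(entropy_csv).to_string(index=False)]
    feat = outdir / "feature_entropy.csv"
    if feat.exists():
        lines += ["", "Feature attribution:", pd.read_csv(feat).to_string(index=False)]
    op = outdir / "operation_summary.json"
    if op.exists():
        lines += ["", "Operation campaign:", op.read_text()]
    tea = outdir / "tea_summary.json"
    if tea.exists():
        lines += ["", "Techno-economics:", tea.read_text()]
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    _manifest(outdir, "report", config.seed, [], [outdir / "report.txt"])


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "preprocess": _stage_preprocess,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "entropy": _stage_entropy,
    "operate": _stage_operate,
    "tea": _stage_tea,
    "report": _stage_report,
}
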