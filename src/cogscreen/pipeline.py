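"""Config-driven orchestration of the full analysis.

Stages run in a fixed order — cohort -> IRT scoring -> composites ->
cut search -> classifier benchmark -> bootstrap — and every emitted
table carries the resolved-config hash and the seeds in a leading
comment line, so a run log plus the config reproduces every number.
Identical configs produce byte-identical output bundles.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bench as bench_mod
from . import cutpoint
from .cohort import load_printed_fixture_frame, read_cohort_csv, summarize_cohort, write_cohort_csv
from .composites import apply_composite, assemble_scores, fit_composite, load_composite_fixtures
from .hoirt import HigherOrderIRT, HOIRTConfig
from .instruments import INSTRUMENTS
from .synthetic import CohortSimConfig, encode_demographics, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "verify_printed_results"]

STAGES = ("cohort", "hoirt", "composites", "cuts", "bench", "bootstrap")

#: Printed cut rules of the reference analysis (score, threshold, direction).
PRINTED_CUTS = {
    "ssho2d": (-0.026, cutpoint.BELOW),
    "composite3": (0.618, cutpoint.ABOVE),
    "composite5": (0.925, cutpoint.ABOVE),
}


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (no hidden defaults)."""

    input_kind: str = "synthetic"  # synthetic | csv | fixture
    input_path: str | None = None
    synthetic: dict = field(default_factory=lambda: asdict(CohortSimConfig()))
    stages: tuple[str, ...] = STAGES
    hoirt: dict = field(
        default_factory=lambda: {
            "domains": ["DCCS", "PSM"],
            "n_iter": 1200,
            "n_burn": 400,
            "thin": 1,
            "seed": 0,
            "five_dim": True,
        }
    )
    feature_spaces: tuple[str, ...] = ("F7", "F15")
    models: tuple[str, ...] = ("RF",)
    split: dict = field(default_factory=lambda: {"ratio": 0.8, "seed": 0})
    bootstrap: dict = field(default_factory=lambda: {"B": 10, "seed": 0})
    output_dir: str = "cogscreen_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, val)
        cfg.stages = tuple(cfg.stages)
        for st in cfg.stages:
            if st not in STAGES:
                raise ValueError(f"unknown stage {st!r}")
        return cfg

    def resolved_yaml(self) -> str:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["feature_spaces"] = list(self.feature_spaces)
        d["models"] = list(self.models)
        return yaml.safe_dump(d, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()[:12]


def _emit(df: pd.DataFrame, path: Path, config: PipelineConfig, seed) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the in-memory report bundle.

    Each stage appends a structured line to the run log (stage, wall
    time, seed, row counts); a stage failure aborts with the stage name
    and cause.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(config.resolved_yaml())
    log_rows: list[dict] = []
    bundle: dict = {"config": config}

    def log(stage: str, t0: float, seed, n_in: int, n_out: int) -> None:
        log_rows.append(
            {
                "stage": stage,
                "wall_s": round(time.perf_counter() - t0, 3),
                "seed": seed,
                "rows_in": n_in,
                "rows_out": n_out,
            }
        )

    def run_stage(stage: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            fn(t0)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- cohort ------------------------------------------------------
    def stage_cohort(t0: float) -> None:
        if config.input_kind == "synthetic":
            sim = CohortSimConfig(**config.synthetic)
            records, truth = generate_cohort(sim)
            bundle["records"], bundle["truth"] = records, truth
            write_cohort_csv(records, out / "cohort.csv")
            seed = sim.seed
        elif config.input_kind == "csv":
            records = read_cohort_csv(config.input_path)
            bundle["records"] = records
            seed = None
        elif config.input_kind == "fixture":
            fx = load_printed_fixture_frame()
            bundle["fixture"] = fx
            seed = None
        else:
            raise ValueError(f"unknown input kind {config.input_kind!r}")
        if "records" in bundle:
            summary = summarize_cohort(bundle["records"])
            _emit(summary.counts, out / "cohort_counts.csv", config, seed)
            if summary.alpha is not None:
                alpha = pd.DataFrame(
                    {"instrument": list(summary.alpha), "cronbach_alpha": list(summary.alpha.values())}
                )
                _emit(alpha, out / "cohort_alpha.csv", config, seed)
            n = len(bundle["records"])
        else:
            n = len(bundle["fixture"])
        log("cohort", t0, seed, n, n)

    # ---- IRT scoring -------------------------------------------------
    def stage_hoirt(t0: float) -> None:
        records = bundle["records"]
        hc = dict(config.hoirt)
        five = hc.pop("five_dim", False)
        domains = tuple(hc.pop("domains"))
        cfg2 = HOIRTConfig(domains=domains, **hc)
        res2 = HigherOrderIRT.from_cohort(records, domains).fit(cfg2)
        irt = res2.scores()
        if five:
            cfg5 = HOIRTConfig(domains=tuple(INSTRUMENTS), **hc)
            res5 = HigherOrderIRT.from_cohort(records, tuple(INSTRUMENTS)).fit(cfg5)
            irt = pd.concat([irt, res5.scores()], axis=1)
        bundle["irt_scores"] = irt
        _emit(irt, out / "irt_scores.csv", config, cfg2.seed)
        log("hoirt", t0, cfg2.seed, len(records), len(irt))

    # ---- composites --------------------------------------------------
    def stage_composites(t0: float) -> None:
        records = bundle["records"]
        scores = assemble_scores(records, bundle.get("irt_scores"))
        scores = pd.concat(
            [scores, encode_demographics(records).reset_index(drop=True)], axis=1
        )
        for name, model in load_composite_fixtures().items():
            if model.rt_unit_warning:
                feats = scores[model.feature_names]
                refit = fit_composite(feats, scores["impaired"].to_numpy(), name=name)
                scores[name] = apply_composite(refit, scores)
            else:
                scores[name] = apply_composite(model, scores)
        bundle["scores"] = scores
        _emit(scores, out / "scores.csv", config, None)
        log("composites", t0, None, len(records), len(scores))

    # ---- cut search --------------------------------------------------
    def stage_cuts(t0: float) -> None:
        rows = []
        if "fixture" in bundle:
            fx = bundle["fixture"]
            labels = fx["impaired"].to_numpy()
            for col, (threshold, direction) in PRINTED_CUTS.items():
                rule = cutpoint.CutRule(threshold, direction)
                printed = cutpoint.count_mismatches(
                    cutpoint.classify_by_cut(fx[col].to_numpy(), rule), labels
                )
                best_rule, best_m = cutpoint.search_optimal_cut(fx[col].to_numpy(), labels)
                rows.append(
                    {
                        "score": col,
                        "printed_cut": threshold,
                        "printed_direction": direction,
                        "printed_mismatches": printed,
                        "searched_cut": best_rule.threshold,
                        "searched_direction": best_rule.direction,
                        "searched_mismatches": best_m,
                    }
                )
        else:
            scores = bundle["scores"]
            labels = scores["impaired"].to_numpy().astype(int)
            for col in ("SSHO2D", "Composite1", "Composite2", "Composite3", "Composite4", "Composite5"):
                if col not in scores.columns:
                    continue
                rule, m = cutpoint.search_optimal_cut(scores[col].to_numpy(), labels)
                rows.append(
                    {
                        "score": col,
                        "searched_cut": rule.threshold,
                        "searched_direction": rule.direction,
                        "searched_mismatches": m,
                    }
                )
        cuts = pd.DataFrame(rows)
        bundle["cuts"] = cuts
        _emit(cuts, out / "cuts.csv", config, None)
        log("cuts", t0, None, len(rows), len(rows))

    # ---- benchmark ---------------------------------------------------
    def _bench_frame(self_scores: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
        labels = self_scores["impaired"].to_numpy().astype(int)
        return self_scores, labels

    def stage_bench(t0: float) -> None:
        scores, labels = _bench_frame(_bench_scores())
        ratio, seed = config.split["ratio"], config.split["seed"]
        train, test = bench_mod.split_cohort(len(labels), ratio, seed, labels)
        rows_test, rows_all = [], []
        for space in config.feature_spaces:
            try:
                X = bench_mod.build_feature_matrix(scores, space).to_numpy()
            except ValueError:
                continue  # space not constructible from this input (fixture mode)
            for model_name in config.models:
                spec = bench_mod.MODEL_ZOO[model_name]
                est = bench_mod.grid_search_train(spec, X[train], labels[train], seed=seed)
                for rows, idx, which in ((rows_test, test, "test"), (rows_all, np.arange(len(labels)), "all")):
                    preds = est.predict(X[idx])
                    sc = bench_mod._prediction_scores(est, X[idx])
                    res = bench_mod.evaluate(preds, labels[idx], scores=sc)
                    rows.append(
                        {"feature_space": space, "model": model_name, "data": which, **res.as_dict()}
                    )
        bench_test = pd.DataFrame(rows_test)
        bench_all = pd.DataFrame(rows_all)
        bundle["bench_test"], bundle["bench_all"] = bench_test, bench_all
        _emit(bench_test, out / "bench_test.csv", config, seed)
        _emit(bench_all, out / "bench_all.csv", config, seed)
        log("bench", t0, seed, len(labels), len(bench_test))

    def _bench_scores() -> pd.DataFrame:
        if "fixture" in bundle:
            fx = bundle["fixture"].rename(
                columns={"ssho2d": "SSHO2D", "composite3": "Composite3", "composite5": "Composite5"}
            )
            return fx
        return bundle["scores"]

    # ---- bootstrap ---------------------------------------------------
    def stage_bootstrap(t0: float) -> None:
        scores, labels = _bench_frame(_bench_scores())
        B, seed = config.bootstrap["B"], config.bootstrap["seed"]
        rows = []
        for space in config.feature_spaces:
            try:
                X = bench_mod.build_feature_matrix(scores, space)
            except ValueError:
                continue
            for model_name in config.models:
                spec = bench_mod.MODEL_ZOO[model_name]
                summ = bench_mod.bootstrap_evaluate(X, labels, spec, B=B, seed=seed)
                for metric in summ.means:
                    rows.append(
                        {
                            "feature_space": space,
                            "model": model_name,
                            "metric": metric,
                            "mean": summ.means[metric],
                            "sd": summ.sds[metric],
                            "skipped": summ.skipped[metric],
                            "B": B,
                        }
                    )
        boot = pd.DataFrame(rows)
        bundle["bootstrap"] = boot
        _emit(boot, out / "bootstrap.csv", config, seed)
        log("bootstrap", t0, seed, len(labels), len(rows))

    stage_fns = {
        "cohort": stage_cohort,
        "hoirt": stage_hoirt,
        "composites": stage_composites,
        "cuts": stage_cuts,
        "bench": stage_bench,
        "bootstrap": stage_bootstrap,
    }
    for stage in config.stages:
        if stage in ("hoirt", "composites") and "records" not in bundle:
            continue  # fixture mode carries printed scores; nothing to fit
        run_stage(stage, stage_fns[stage])

    log_df = pd.DataFrame(log_rows)
    _emit(log_df, out / "run_log.csv", config, None)
    bundle["run_log"] = log_df
    return bundle


def verify_printed_results(full: bool = False, seed: int = 0, B: int = 100) -> pd.DataFrame:
    """Observed-vs-expected table for the reference verification surfaces.

    The fast checks reproduce the printed per-patient table's row and
    label counts and the two exactly-reproducible linear-cut mismatch
    counts.  With ``full=True`` the bootstrap targets (mean precision /
    recall / accuracy / specificity of RF on {SSHO2D, age}) are also
    recomputed; their expected values are stochastic means with
    printed SDs, checked to ±2 SD/sqrt(100).
    """
    fx = load_printed_fixture_frame()
    labels = fx["impaired"].to_numpy()
    rows = []

    def add(name, observed, expected, tol=0.0):
        ok = abs(observed - expected) <= tol
        rows.append(
            {"target": name, "observed": observed, "expected": expected, "tolerance": tol, "pass": ok}
        )

    add("fixture_rows", len(fx), 86)
    add("fixture_impaired", int(labels.sum()), 19)
    for col, expected in (("ssho2d", 14), ("composite5", 14)):
        threshold, direction = PRINTED_CUTS[col]
        preds = cutpoint.classify_by_cut(fx[col].to_numpy(), cutpoint.CutRule(threshold, direction))
        add(f"{col}_cut_mismatches", cutpoint.count_mismatches(preds, labels), expected)
    if full:
        X = fx[["ssho2d", "age"]].rename(columns={"ssho2d": "SSHO2D"})[["age", "SSHO2D"]]
        summ = bench_mod.bootstrap_evaluate(X, labels, bench_mod.MODEL_ZOO["RF"], B=B, seed=seed)
        expected = {"precision": (0.803, 0.246), "recall": (0.758, 0.272), "accuracy": (0.902, 0.079), "specificity": (0.951, 0.067)}
        for metric, (mean, sd) in expected.items():
            add(f"bootstrap_rf_{metric}", summ.means[metric], mean, tol=2 * sd / np.sqrt(100))
    return pd.DataFrame(rows)
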