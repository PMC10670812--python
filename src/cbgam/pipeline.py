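"""End-to-end pipeline: simulate/load -> validate -> descriptives ->
model development -> evaluation -> survival, with a run manifest that
records enough (config snapshot, seeds, outputs, checksums) to re-run
identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import read_cohort, validate_cohort, write_cohort
from .descriptives import build_descriptives, scanner_anova
from .evaluation import evaluate_ensemble
from .protocol import ProtocolConfig, develop_model
from .simulate import GeneratorConfig, generate_cohort
from .survival import compare_subtypes, km_by_subtype

logger = logging.getLogger("cbgam.pipeline")

STAGES = ["cohort", "validate", "descriptives", "develop", "evaluate", "survival"]


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)   # stage -> status/outputs
    checksums: dict = field(default_factory=dict)
    started: float = field(default_factory=time.time)

    def record(self, stage: str, status: str, outputs=(), error: str | None = None):
        self.stages[stage] = {
            "status": status,
            "outputs": [str(p) for p in outputs],
            **({"error": error} if error else {}),
        }

    def checksum(self, path):
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.checksums[str(path)] = h

    def write(self, path) -> None:
        doc = {
            "version": self.version,
            "config": self.config,
            "stages": self.stages,
            "checksums": self.checksums,
            "wall_seconds": round(time.time() - self.started, 2),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def load_pipeline_config(source) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        return yaml.safe_load(fh.read())


def run_pipeline(config, out_dir, reps: float = 1.0, plot: bool = False) -> RunManifest:
    """Execute the full pipeline; any stage failure halts with a manifest
    recording partial progress.

    ``config`` is a dict or a YAML file with optional keys ``simulate``
    (GeneratorConfig fields), ``cohort`` (CSV path) and ``protocol``
    (ProtocolConfig fields); exactly one of simulate/cohort is required.
    ``reps`` scales the bootstrap iteration counts for desk-scale runs.
    """
    cfg = load_pipeline_config(config)
    if ("simulate" in cfg) == ("cohort" in cfg):
        raise ValueError("config must contain exactly one of 'simulate' or 'cohort'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg)
    manifest_path = out / "manifest.json"

    try:
        # -- cohort -------------------------------------------------------
        if "simulate" in cfg:
            gen = GeneratorConfig.from_dict(cfg["simulate"]) \
                if any(k in cfg["simulate"] for k in ("continuous_marginals",)) \
                else GeneratorConfig(**cfg["simulate"])
            df = generate_cohort(gen)
        else:
            df = read_cohort(cfg["cohort"])
        cohort_path = out / "cohort.csv"
        write_cohort(df, cohort_path)
        manifest.checksum(cohort_path)
        manifest.record("cohort", "completed", [cohort_path])

        # -- validate -----------------------------------------------------
        violations = validate_cohort(df)
        vpath = out / "validation.json"
        with open(vpath, "w") as fh:
            json.dump([dataclasses.asdict(v) for v in violations], fh, indent=2)
        if violations:
            manifest.record("validate", "failed", [vpath],
                            error=f"{len(violations)} violations")
            raise ValueError(f"cohort failed validation ({len(violations)})")
        manifest.record("validate", "completed", [vpath])

        # -- descriptives -------------------------------------------------
        report = build_descriptives(df)
        d1, d2 = out / "descriptives_continuous.csv", out / "descriptives_categorical.csv"
        report.to_csv(d1, d2)
        report.to_json(out / "descriptives.json")
        anova = scanner_anova(df)
        anova.to_csv(out / "scanner_anova.csv", index=False)
        manifest.record("descriptives", "completed",
                        [d1, d2, out / "descriptives.json", out / "scanner_anova.csv"])

        # -- develop ------------------------------------------------------
        proto = ProtocolConfig(**cfg.get("protocol", {}))
        dev = develop_model(df, proto, reps_scale=reps)
        model_path = out / "model.json"
        dev.ensemble.avg_model_.to_json(model_path)
        report_path = out / "report.json"
        dev.report_json(report_path)
        curve_paths = []
        for var, curve in dev.curves.items():
            p = out / f"partial_effect_{var}.csv"
            pd.DataFrame({
                "x_standardized": curve.x, "x_raw": curve.x_raw,
                "effect": curve.values,
                "spread": curve.spread,
            }).to_csv(p, index=False)
            curve_paths.append(p)
        manifest.checksum(model_path)
        manifest.checksum(report_path)
        manifest.record("develop", "completed",
                        [model_path, report_path, *curve_paths])

        # -- evaluate -----------------------------------------------------
        X = dev.standardizer.transform(df)[
            dev.filter.kept_continuous + dev.filter.kept_categorical
        ]
        ev = evaluate_ensemble(dev.ensemble, X, df["cb"].to_numpy(), df["subtype"])
        roc_path = out / "roc.csv"
        ev.roc.to_csv(roc_path)
        eval_path = out / "evaluation.json"
        with open(eval_path, "w") as fh:
            json.dump(ev.summary(), fh, indent=2)
        manifest.record("evaluate", "completed", [roc_path, eval_path])

        # -- survival -----------------------------------------------------
        surv_paths = []
        comparisons = {}
        for endpoint in ("OS", "PFS"):
            for subtype, curve in km_by_subtype(df, endpoint).items():
                p = out / f"km_{endpoint.lower()}_{subtype}.csv"
                curve.to_frame().to_csv(p, index=False)
                surv_paths.append(p)
            comparisons[endpoint] = compare_subtypes(df, endpoint).to_dict(
                orient="records"
            )
        cmp_path = out / "survival_comparisons.json"
        with open(cmp_path, "w") as fh:
            json.dump(comparisons, fh, indent=2)
        surv_paths.append(cmp_path)
        if plot:
            surv_paths += _plots(df, dev, ev, out)
        manifest.record("survival", "completed", surv_paths)
    except Exception as exc:
        for stage in STAGES:
            if stage not in manifest.stages:
                manifest.record(stage, "skipped")
        failed = [s for s, rec in manifest.stages.items()
                  if rec["status"] == "failed"]
        if not failed:
            done = [s for s in STAGES if manifest.stages[s]["status"] == "completed"]
            stage = STAGES[len(done)] if len(done) < len(STAGES) else STAGES[-1]
            manifest.record(stage, "failed", error=str(exc))
        manifest.write(manifest_path)
        raise
    manifest.write(manifest_path)
    return manifest


def _plots(df, dev, ev, out: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(ev.roc.fpr, ev.roc.tpr, lw=2)
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"ROC (AUC = {ev.roc.auc:.2f}, J = {ev.roc.youden_j:.2f})")
    p = out / "roc.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    for var, curve in dev.curves.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(curve.x_raw, curve.values, lw=2)
        if curve.spread is not None:
            ax.fill_between(curve.x_raw, curve.values - curve.spread,
                            curve.values + curve.spread, alpha=0.25)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel(var)
        ax.set_ylabel("influence on CB (log-odds)")
        p = out / f"partial_effect_{var}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)

    from .survival import km_by_subtype

    for endpoint in ("OS", "PFS"):
        fig, ax = plt.subplots(figsize=(5, 4))
        for subtype, curve in km_by_subtype(df, endpoint).items():
            ax.step(curve.time, curve.survival, where="post", label=subtype)
        ax.set_xlabel("months")
        ax.set_ylabel(f"{endpoint} probability")
        ax.legend(title="subtype")
        p = out / f"km_{endpoint.lower()}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths
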