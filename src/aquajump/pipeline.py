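"""End-to-end driver: simulate -> process -> develop -> validate.

One top-level seed fans out to every stochastic stage.  Each run leaves
a self-describing set of artifacts (``jumps.csv``, ``model.json``,
``report.json`` and optional agreement plots) stamped with a hash of the
configuration that produced them.
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

from . import __version__
from .agreement import agreement_report
from .regression import BackwardEliminationRegression, compare_groups, split_dd_vd
from .signal import process_session
from .simulate import SimulationConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "features_to_design"]

log = logging.getLogger("aquajump")

#: Feature-table column -> predictor name expected by the regression.
PREDICTOR_MAP = {"acc_c7": "c7acc", "pwdh": "pwdh", "age": "age", "weight": "weight"}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs."""

    out_dir: str = "aquajump_run"
    n_subjects: int = 12
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cutoff: float = 50.0
    order: int = 6
    threshold_frac: float = 0.10
    ratio: float = 2.0 / 3.0
    stratify_by: str | None = None
    alpha_remove: float = 0.10
    ba_k: float = 1.96
    make_plots: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def features_to_design(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Split the per-jump feature table into (X, y) for the regression."""
    X = features[list(PREDICTOR_MAP)].rename(columns=PREDICTOR_MAP)
    return X, features["grf_v_l_bw"]


def _stage(name: str, fn, *artifacts: Path):
    t0 = time.perf_counter()
    try:
        out = fn()
    except Exception as exc:
        for p in artifacts:
            Path(p).unlink(missing_ok=True)
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    log.info("stage %-10s done in %.2f s", name, time.perf_counter() - t0)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full chain and return artifacts and key results.

    Returns a dict with the fitted model, the agreement report, the
    per-jump table, and the paths of everything written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "version": __version__}

    subjects, sessions, truth = _stage(
        "simulate",
        lambda: generate_cohort(config.n_subjects, config.simulation, seed=config.seed),
    )

    def _process():
        frames = []
        for subj, traces in zip(subjects, sessions):
            _, feats = process_session(
                traces,
                subj,
                cutoff=config.cutoff,
                order=config.order,
                threshold_frac=config.threshold_frac,
            )
            frames.append(feats)
        return pd.concat(frames, ignore_index=True)

    jumps_path = out / "jumps.csv"
    features = _stage("process", _process, jumps_path)
    features.to_csv(jumps_path, index=False, float_format="%.12g")
    log.info("processed %d jumps from %d subjects", len(features), len(subjects))

    split = _stage(
        "split",
        lambda: split_dd_vd(features, ratio=config.ratio, seed=config.seed, stratify_by=config.stratify_by),
    )
    group_tests = compare_groups(split.dd, split.vd, ["grf_v_l_bw", "acc_c7", "age", "weight"])

    model_path = out / "model.json"

    def _develop():
        X, y = features_to_design(split.dd)
        est = BackwardEliminationRegression(alpha_remove=config.alpha_remove).fit(X, y)
        est.model_.to_json(model_path)
        return est

    est = _stage("develop", _develop, model_path)

    report_path = out / "report.json"

    def _validate():
        X_vd, y_vd = features_to_design(split.vd)
        predicted = est.model_.predict(X_vd)
        return agreement_report(y_vd.to_numpy(), predicted, k=config.ba_k), predicted

    report, predicted = _stage("validate", _validate, report_path)
    payload = {
        **stamp,
        "n_jumps": int(len(features)),
        "n_dd": int(len(split.dd)),
        "n_vd": int(len(split.vd)),
        "model": est.model_.to_dict(),
        "agreement": report.to_dict(),
        "dd_vd_comparison": group_tests.to_dict(orient="records"),
    }
    report_path.write_text(json.dumps(payload, indent=2))

    plot_paths: list[Path] = []
    if config.make_plots:

        def _plots():
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            measured = features_to_design(split.vd)[1].to_numpy()
            fig, axes = plt.subplots(1, 2, figsize=(10, 4.2))
            lims = [min(measured.min(), predicted.min()), max(measured.max(), predicted.max())]
            axes[0].scatter(measured, predicted, s=6, alpha=0.4)
            axes[0].plot(lims, lims, "k-", lw=1)
            axes[0].set_xlabel("measured GRF (BW)")
            axes[0].set_ylabel("predicted GRF (BW)")
            axes[0].set_title(f"concordance (CCC = {report.ccc:.3f})")
            means = 0.5 * (measured + predicted)
            diffs = measured - predicted
            axes[1].scatter(means, diffs, s=6, alpha=0.4)
            for yv, style in ((report.bias, "--"), (report.loa_low, ":"), (report.loa_high, ":")):
                axes[1].axhline(yv, color="k", ls=style, lw=1)
            axes[1].set_xlabel("mean of measured and predicted (BW)")
            axes[1].set_ylabel("difference (BW)")
            axes[1].set_title("Bland-Altman")
            fig.tight_layout()
            p = out / "agreement.png"
            fig.savefig(p, dpi=150)
            plt.close(fig)
            return [p]

        plot_paths = _stage("plots", _plots)

    return {
        "subjects": subjects,
        "truth": truth,
        "features": features,
        "split": split,
        "estimator": est,
        "model": est.model_,
        "report": report,
        "group_tests": group_tests,
        "paths": {
            "jumps": jumps_path,
            "model": model_path,
            "report": report_path,
            "plots": plot_paths,
        },
    }
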