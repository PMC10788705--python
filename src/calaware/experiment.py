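"""Desk-scale experimental protocol for comparing uncertainty-aware strategies.

Reproduces the study design around the losses: a shared pre-trained VAE
state per seed, per-strategy training of VAE + classifier, model selection
by validation BACC (or validation ECE), evaluation of the selected
checkpoint on an untouched test split under plain, epistemic and aleatoric
uncertainty, McNemar tests against the baseline, and aggregation over
seeds (mean ± sd).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import calibration as calib
from .losses import STRATEGIES, LossHyperparams
from .model import CineVAEClassifier, SelectionRecord, component_seed
from .synthetic import SyntheticConfig, generate_dataset, split
from .uncertainty import (aleatoric_samples, epistemic_samples,
                          metrics_under_uncertainty)

__all__ = ["ExperimentConfig", "ComparisonReport", "select_model", "run_experiment",
           "selection_comparison", "grid_search", "report_to_csv", "report_to_json"]


def select_model(records: Sequence[SelectionRecord],
                 criterion: Literal["bacc", "ece"] = "bacc") -> SelectionRecord:
    """Choose a checkpoint: argmax validation BACC or argmin validation ECE,
    earliest epoch on ties."""
    records = list(records)
    if not records:
        raise ValueError("empty selection record stream")
    if criterion == "bacc":
        values = np.array([r.val_bacc for r in records])
        return records[int(np.argmax(values))]
    if criterion == "ece":
        values = np.array([r.val_ece for r in records])
        return records[int(np.argmin(values))]
    raise ValueError(f"unknown selection criterion {criterion!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything a full strategy-comparison run needs."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    strategies: tuple[str, ...] = STRATEGIES
    n_seeds: int = 3
    base_seed: int = 0
    task: str = "desk"
    fractions: tuple[float, ...] = (0.72, 0.08, 0.20)
    epochs: int = 30
    pretrain_epochs: int = 6
    selection: Literal["bacc", "ece"] = "bacc"
    n_bins: int = 15
    n_uncertainty_samples: int = 20
    perturbation_rate: float = 0.2
    include_uncertainty: bool = True
    model_kwargs: dict = field(default_factory=dict)


@dataclass
class ComparisonReport:
    """Per-strategy test metrics over seeds, plus McNemar p vs baseline.

    ``metrics[strategy][source][name]`` is the list of per-seed values,
    with source one of plain/epistemic/aleatoric; ``failed`` lists
    strategies whose runs aborted.
    """

    criterion: str
    seeds: list[int]
    metrics: dict[str, dict[str, dict[str, list[float]]]]
    mcnemar: dict[str, list[float]]
    failed: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for strategy, sources in self.metrics.items():
            for source, named in sources.items():
                for name, values in named.items():
                    rows.append({"strategy": strategy, "source": source, "metric": name,
                                 "mean": float(np.mean(values)), "sd": float(np.std(values)),
                                 "n_runs": len(values)})
        return pd.DataFrame(rows)


def _evaluate(model: CineVAEClassifier, X_test, y_test, cfg: ExperimentConfig,
              seed: int) -> tuple[dict[str, dict[str, float]], calib.PredictionSet]:
    preds = model.prediction_set(X_test, y_test)
    out = {"plain": calib.metric_suite(preds, cfg.n_bins)}
    if cfg.include_uncertainty:
        epi = epistemic_samples(model, X_test, cfg.n_uncertainty_samples,
                                seed=component_seed(seed, "epistemic"))
        ale = aleatoric_samples(model, X_test, cfg.n_uncertainty_samples,
                                cfg.perturbation_rate,
                                seed=component_seed(seed, "aleatoric"))
        out["epistemic"] = metrics_under_uncertainty(epi, y_test, cfg.n_bins)
        out["aleatoric"] = metrics_under_uncertainty(ale, y_test, cfg.n_bins)
    return out, preds


def _train_strategy(strategy: str, cfg: ExperimentConfig, seed: int,
                    data, vae_params) -> CineVAEClassifier:
    X_train, y_train, X_val, y_val = data
    hp = LossHyperparams.preset(strategy, task=cfg.task)
    model = CineVAEClassifier(strategy=strategy, hyperparams=hp, epochs=cfg.epochs,
                              random_state=component_seed(seed, strategy),
                              **cfg.model_kwargs)
    model.fit(X_train, y_train, X_val=X_val, y_val=y_val, vae_init=vae_params)
    chosen = select_model(model.records_, cfg.selection)
    model.set_parameters(chosen.checkpoint)
    return model


def run_experiment(cfg: ExperimentConfig) -> ComparisonReport:
    """Train every strategy from a shared pre-trained VAE state, per seed,
    and evaluate the selected checkpoints on the untouched test split."""
    if "baseline" not in cfg.strategies:
        raise ValueError("the baseline strategy must always be present")
    dataset = generate_dataset(cfg.synthetic)
    idx = split(dataset, cfg.fractions, seed=component_seed(cfg.base_seed, "split"))
    X_train, y_train = dataset.X[idx["train"]], dataset.y[idx["train"]]
    X_val, y_val = dataset.X[idx["val"]], dataset.y[idx["val"]]
    X_test, y_test = dataset.X[idx["test"]], dataset.y[idx["test"]]
    data = (X_train, y_train, X_val, y_val)

    seeds = [cfg.base_seed + k for k in range(cfg.n_seeds)]
    metrics: dict[str, dict[str, dict[str, list[float]]]] = {}
    mcnemar: dict[str, list[float]] = {}
    failed: set[str] = set()

    for seed in seeds:
        pre = CineVAEClassifier(strategy="baseline", epochs=cfg.pretrain_epochs,
                                random_state=component_seed(seed, "pretrain"),
                                **cfg.model_kwargs)
        pre.fit(X_train, pretrain_only=True)
        vae_params = pre.get_parameters()

        baseline_preds = None
        ordered = ["baseline"] + [s for s in cfg.strategies if s != "baseline"]
        for strategy in ordered:
            try:
                model = _train_strategy(strategy, cfg, seed, data, vae_params)
                results, preds = _evaluate(model, X_test, y_test, cfg, seed)
            except Exception:
                failed.add(strategy)
                continue
            if strategy == "baseline":
                baseline_preds = preds
            bucket = metrics.setdefault(strategy, {})
            for source, named in results.items():
                for name, value in named.items():
                    bucket.setdefault(source, {}).setdefault(name, []).append(value)
            if strategy != "baseline" and baseline_preds is not None:
                _, p, _ = calib.mcnemar_test(baseline_preds, preds)
                mcnemar.setdefault(strategy, []).append(p)

    return ComparisonReport(criterion=cfg.selection, seeds=seeds, metrics=metrics,
                            mcnemar=mcnemar, failed=sorted(failed))


def selection_comparison(model: CineVAEClassifier, X_test, y_test,
                         n_bins: int = 15) -> dict[str, dict]:
    """Evaluate the BACC-selected and ECE-selected checkpoints of one
    training run on the test split, without retraining."""
    out = {}
    saved = model.get_parameters()
    try:
        for criterion in ("bacc", "ece"):
            record = select_model(model.records_, criterion)
            model.set_parameters(record.checkpoint)
            preds = model.prediction_set(X_test, y_test)
            out[criterion] = {"epoch": record.epoch,
                              **calib.metric_suite(preds, n_bins)}
    finally:
        model.set_parameters(saved)
    return out


def grid_search(cfg: ExperimentConfig, strategy: str,
                grid: dict[str, Sequence]) -> tuple[dict, pd.DataFrame]:
    """Exhaustive hyperparameter search on the validation split.

    Selects the combination with the highest validation BACC of the
    selected epoch; ties break toward the lexicographically smallest
    parameter tuple, so the result is invariant to grid enumeration order.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyperparameter grid")
    dataset = generate_dataset(cfg.synthetic)
    idx = split(dataset, cfg.fractions, seed=component_seed(cfg.base_seed, "split"))
    data = (dataset.X[idx["train"]], dataset.y[idx["train"]],
            dataset.X[idx["val"]], dataset.y[idx["val"]])

    names = sorted(grid)
    rows = []
    base_hp = LossHyperparams.preset(strategy, task=cfg.task)
    for values in product(*(sorted(grid[n]) for n in names)):
        point = dict(zip(names, values))
        hp = LossHyperparams(**{**vars(base_hp), **point})
        model = CineVAEClassifier(strategy=strategy, hyperparams=hp, epochs=cfg.epochs,
                                  random_state=component_seed(cfg.base_seed, strategy),
                                  **cfg.model_kwargs)
        model.fit(*data[:2], X_val=data[2], y_val=data[3])
        chosen = select_model(model.records_, "bacc")
        rows.append({**point, "val_bacc": chosen.val_bacc, "val_ece": chosen.val_ece,
                     "epoch": chosen.epoch})
    table = pd.DataFrame(rows)
    order = table.sort_values(["val_bacc"] + names,
                              ascending=[False] + [True] * len(names),
                              kind="stable")
    best = {n: order.iloc[0][n] for n in names}
    return best, table


def report_to_csv(report: ComparisonReport, path) -> None:
    report.summary().to_csv(path, index=False)


def report_to_json(report: ComparisonReport, path) -> None:
    payload = {
        "criterion": report.criterion,
        "seeds": report.seeds,
        "failed": report.failed,
        "metrics": report.metrics,
        "mcnemar": report.mcnemar,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
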