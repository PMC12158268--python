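"""End-to-end orchestration of the film-optimization analysis.

Stages, in dependency order: ``simulate`` (or CSV ingestion) ->
``stabilize`` -> ``select_features`` -> ``gp_fit`` -> ``optimize`` ->
``anova``. A single master seed deterministically derives one seed per
stage (``stage_seed = (master_seed * 1000003 + stage_index) mod 2^31``), so
stages can be re-run independently and an identical config + seed yields an
identical run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from halochrom import anova as anova_mod
from halochrom import feature_selection, gp, optimizers, stabilization, synthetic
from halochrom.color import CHANNELS

STAGES = ("simulate", "stabilize", "select_features", "gp_fit", "optimize", "anova")


class ConfigError(ValueError):
    """The pipeline configuration is inconsistent."""


@dataclass
class PipelineConfig:
    output_dir: str = "results/pipeline"
    master_seed: int = 0
    stages: tuple[str, ...] = STAGES
    # simulate
    design: synthetic.DesignSpec = field(default_factory=synthetic.DesignSpec)
    kinetics_noise_sd: float = 0.0005
    response_noise_sd: float = 111.5
    kinetics_replicates_per_ph: int = 2
    # stabilize
    stabilization: stabilization.StabilizationParams = field(
        default_factory=stabilization.StabilizationParams
    )
    # gp_fit
    gp_params: gp.GPHyperparams = field(default_factory=gp.GPHyperparams)
    # optimize
    algorithms: tuple[str, ...] = ("po", "poa", "sboa")
    objective: str = "eq2"  # "eq2" or "gp_model"
    population_size: int = 30
    iterations: int = 100
    # anova
    alpha: float = 0.05
    # externally supplied inputs (synthetic mode off)
    series_csvs: tuple[str, ...] = ()
    dataset_csv: str | None = None
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown configuration key {key!r}")
            current = getattr(cfg, key)
            if key == "design":
                value = synthetic.DesignSpec(**value)
            elif key == "stabilization":
                value = stabilization.StabilizationParams(**value)
            elif key == "gp_params":
                value = gp.GPHyperparams(**value)
            elif isinstance(current, tuple):
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stages {unknown}")
        on = set(self.stages)
        if "simulate" not in on:
            if "stabilize" in on and not self.series_csvs:
                raise ConfigError("stabilize needs series_csvs when simulate is off")
            if ("gp_fit" in on or "anova" in on) and not self.dataset_csv:
                raise ConfigError("gp_fit/anova need dataset_csv when simulate is off")
        if "optimize" in on and self.objective == "gp_model" and "gp_fit" not in on:
            raise ConfigError("optimize with objective=gp_model requires the gp_fit stage")
        if self.objective not in ("eq2", "gp_model"):
            raise ConfigError(f"unknown objective {self.objective!r}")

    def to_dict(self) -> dict:
        d = {}
        for key, value in self.__dict__.items():
            if hasattr(value, "__dict__"):
                d[key] = dict(value.__dict__)
            elif isinstance(value, tuple):
                d[key] = list(value)
            else:
                d[key] = value
        return d


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (master_seed * 1000003 + STAGES.index(stage)) % 2**31


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the run manifest.

    The manifest records the config hash, per-stage seeds and the artifacts
    written under ``config.output_dir``; it is also written there as
    ``manifest.json``. Identical config + master seed give a byte-identical
    manifest.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "master_seed": config.master_seed,
        "stages": {},
    }
    on = set(config.stages)
    series_paths: list[Path] = []
    dataset: pd.DataFrame | None = None
    model: gp.GPModel | None = None

    if "simulate" in on:
        seed = stage_seed(config.master_seed, "simulate")
        rng_offset = 0
        for ph in config.design.ph_levels:
            for rep in range(config.kinetics_replicates_per_ph):
                cfg = synthetic.default_kinetics_config(
                    int(ph), noise_sd=config.kinetics_noise_sd
                )
                series = synthetic.generate_color_kinetics(cfg, seed + rng_offset)
                rng_offset += 1
                path = out / f"kinetics_ph{ph}_rep{rep + 1}.csv"
                synthetic.write_series_csv(series, path)
                series_paths.append(path)
        dataset = synthetic.generate_formulation_dataset(
            config.design,
            surface=optimizers.fitness_eq2,
            noise_sd=config.response_noise_sd,
            seed=seed + rng_offset,
        )
        dataset.to_csv(out / "formulation_dataset.csv", index=False)
        manifest["stages"]["simulate"] = {
            "seed": seed,
            "n_series": len(series_paths),
            "n_records": int(len(dataset)),
        }
    else:
        series_paths = [Path(p) for p in config.series_csvs]
        if config.dataset_csv:
            dataset = pd.read_csv(config.dataset_csv)

    if "stabilize" in on:
        results = []
        for path in series_paths:
            series = stabilization.clean_series(synthetic.read_series_csv(path))
            res = stabilization.response_time(series, config.stabilization)
            results.append({"series": path.name, **res.to_dict()})
        (out / "stabilization.json").write_text(json.dumps(results, indent=2))
        if config.make_plots:
            _plot_stabilization(series_paths, config.stabilization, out)
        manifest["stages"]["stabilize"] = {
            "n_series": len(results),
            "n_stabilized": sum(r["stabilized"] for r in results),
        }

    if "select_features" in on:
        seed = stage_seed(config.master_seed, "select_features")
        frames, labels = [], []
        for path in series_paths:
            series = synthetic.read_series_csv(path)
            ph = int(path.stem.split("ph")[1].split("_")[0]) if "ph" in path.stem else 0
            sub = series.iloc[:: max(1, len(series) // 120)]
            frames.append(sub[list(CHANNELS)])
            labels.extend([ph] * len(sub))
        table = pd.concat(frames, ignore_index=True)
        pca = feature_selection.pca_correlation(table)
        weights = feature_selection.relieff(table, labels, k=10, seed=seed)
        ranked = feature_selection.rank_features(weights, top_n=12)
        payload = {
            "eigenvalues": pca.eigenvalues.tolist(),
            "retained": pca.retained,
            "loadings": pca.loadings.round(6).to_dict(),
            "relieff_weights": weights,
            "ranked_features": ranked,
        }
        (out / "feature_selection.json").write_text(json.dumps(payload, indent=2))
        manifest["stages"]["select_features"] = {
            "seed": seed,
            "retained_components": pca.retained,
            "top3": ranked[:3],
        }

    if "gp_fit" in on:
        seed = stage_seed(config.master_seed, "gp_fit")
        model = gp.evolve(dataset, config.gp_params, seed=seed)
        (out / "gp_model.json").write_text(model.to_json())
        (out / "gp_expression.txt").write_text(gp.model_to_expression(model) + "\n")
        manifest["stages"]["gp_fit"] = {
            "seed": seed,
            "train_rmse": round(model.train_rmse, 6),
            "n_genes": len(model.genes),
        }

    if "optimize" in on:
        seed = stage_seed(config.master_seed, "optimize")
        if config.objective == "eq2":
            objective = optimizers.EQ2_OBJECTIVE
        else:
            objective = optimizers.ObjectiveFunction(
                name="gp_model",
                evaluate=lambda x1, x2: gp.predict(model, x1, x2),
                bounds=np.array([optimizers.PEG_BOUNDS, optimizers.BTB_BOUNDS]),
            )
        rows = []
        curves = {}
        for alg in config.algorithms:
            res = optimizers.optimize(
                objective,
                alg,
                population_size=config.population_size,
                iterations=config.iterations,
                seed=seed,
            )
            rows.append(
                {
                    "algorithm": alg.upper(),
                    "peg_pct": res.best_x[0],
                    "btb_pct": res.best_x[1],
                    "fitness": res.best_f,
                }
            )
            curves[alg] = res.convergence
        summary = pd.DataFrame(rows)
        summary.to_csv(out / "optimization_summary.csv", index=False)
        conv = pd.DataFrame(curves)
        conv.insert(0, "iteration", np.arange(1, len(conv) + 1))
        conv.to_csv(out / "convergence.csv", index=False)
        if config.make_plots:
            _plot_convergence(curves, out)
        manifest["stages"]["optimize"] = {
            "seed": seed,
            "objective": config.objective,
            "best": {
                r["algorithm"]: [round(r["peg_pct"], 6), round(r["btb_pct"], 6),
                                 round(r["fitness"], 6)]
                for r in rows
            },
        }

    if "anova" in on:
        table = anova_mod.two_factor_anova(dataset, alpha=config.alpha)
        table.to_csv(out / "anova_table.csv")
        manifest["stages"]["anova"] = {
            "alpha": config.alpha,
            "F": {k: round(float(table.loc[k, "F"]), 4) for k in ("peg", "btb", "interaction")},
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _plot_stabilization(series_paths, params, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for path in series_paths[:3]:
        series = synthetic.read_series_csv(path)
        fig, ax = plt.subplots(figsize=(6, 4))
        for ch in ("H", "S", "a"):
            ax.plot(series["t_s"], series[ch], label=ch, lw=1)
        res = stabilization.response_time(series, params)
        if res.stabilized:
            ax.axvspan(res.stabilization_time_s, series["t_s"].iloc[-1], color="red", alpha=0.15)
            ax.axvline(res.stabilization_time_s, color="red", ls="--", lw=1)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("channel value")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / f"{path.stem}_stabilization.png", dpi=100)
        plt.close(fig)


def _plot_convergence(curves: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for alg, curve in curves.items():
        ax.plot(np.arange(1, len(curve) + 1), curve, label=alg.upper())
    ax.set_xlabel("iteration")
    ax.set_ylabel("best fitness (s)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "convergence.png", dpi=100)
    plt.close(fig)
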