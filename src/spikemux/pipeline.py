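"""Config-driven end-to-end runner.

One validated config document drives the full analysis: ingest trials from
the tabular dialect (or simulate a synthetic preset), apply the counting
window and trial filters, screen triplets, classify the survivors, tally
categories per regime, contrast mixture prevalence, and write reports,
figures and a machine-readable run manifest.  All analysis constants
(hypothesis priors, 0.67 threshold, Fano cap 3, log-IBF 3, 5-trial minimum)
are config defaults, never hard-coded in the stage logic, so sensitivity
runs (e.g. the stricter Fano < 2 screen) are one config change.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .io import WINDOW_PRESETS, CountWindow, build_triplets, read_trials
from .model import ModelConfig, classify_triplets, classifications_to_frame
from .population import (DegenerateTableError, compare_mixture_prevalence,
                         mixture_proportion, tally_classifications, tally_to_frame)
from .plotting import plot_category_bars, plot_count_histogram
from .screening import ScreeningConfig, reports_to_frame, screen_triplets
from .simulate import RegimeSpec, simulate_population

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline",
           "SYNTHETIC_PRESETS", "preset_specs"]


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message names the offending field."""


# ---------------------------------------------------------------------------
# Synthetic presets: named populations with fixed regime composition; trial
# counts 6 / 15 / 18 / 37 echo the motivating datasets' averages.
# ---------------------------------------------------------------------------

def _regime_block(n_per_regime: int, n_trials: int,
                  regimes=("mixture", "intermediate", "single_A", "outside_high"),
                  ) -> list[RegimeSpec]:
    return [
        RegimeSpec(regime=r, n_a=n_trials, n_b=n_trials, n_ab=n_trials)
        for r in regimes
        for _ in range(n_per_regime)
    ]


SYNTHETIC_PRESETS: dict[str, Any] = {
    "regimes-demo": lambda: _regime_block(12, 15),
    "regimes-n6": lambda: _regime_block(12, 6),
    "regimes-n18": lambda: _regime_block(12, 18),
    "regimes-n37": lambda: _regime_block(12, 37),
    "overdispersed-demo": lambda: (
        _regime_block(10, 15)
        + [RegimeSpec(regime="mixture", dispersion=5.0, n_a=15, n_b=15, n_ab=15)
           for _ in range(10)]
    ),
}


def preset_specs(name: str) -> list[RegimeSpec]:
    if name not in SYNTHETIC_PRESETS:
        raise ConfigError(f"input.preset: unknown preset {name!r}; "
                          f"available: {sorted(SYNTHETIC_PRESETS)}")
    return SYNTHETIC_PRESETS[name]()


@dataclass(frozen=True)
class PipelineConfig:
    """Validated end-to-end run configuration."""

    trials_path: str | None = None
    eye_path: str | None = None
    preset: str | None = None
    window: CountWindow = WINDOW_PRESETS["MT"]
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    output_dir: str = "spikemux-output"
    seed: int = 0
    log_level: str = "INFO"
    microsaccade_n_sd: float = 6.0
    tally_threshold: float = 0.67

    def __post_init__(self) -> None:
        if (self.trials_path is None) == (self.preset is None):
            raise ConfigError("input: exactly one of input.trials or input.preset "
                              "must be given")


def _check_keys(section: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")


def _build(cls, section: Mapping, where: str):
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def validate_config(document: Mapping[str, Any] | None) -> PipelineConfig:
    """Normalise a parsed config document, filling defaults and rejecting
    unknown or out-of-range fields."""
    doc = dict(document or {})
    _check_keys(doc, {"input", "window", "screening", "model", "output_dir",
                      "seed", "log_level", "tally_threshold"}, "config")

    inp = dict(doc.get("input") or {})
    _check_keys(inp, {"trials", "eye_traces", "preset"}, "input")
    trials_path = inp.get("trials")
    preset = inp.get("preset")
    if trials_path is None and preset is None:
        preset = "regimes-demo"
    if preset is not None and preset not in SYNTHETIC_PRESETS:
        raise ConfigError(f"input.preset: unknown preset {preset!r}")

    window_doc = doc.get("window", "MT")
    if isinstance(window_doc, str):
        if window_doc not in WINDOW_PRESETS:
            raise ConfigError(f"window: unknown preset {window_doc!r}; "
                              f"available: {sorted(WINDOW_PRESETS)}")
        window = WINDOW_PRESETS[window_doc]
    else:
        _check_keys(dict(window_doc), {"latency_offset", "duration"}, "window")
        window = _build(CountWindow, dict(window_doc), "window")

    screening_doc = dict(doc.get("screening") or {})
    _check_keys(screening_doc,
                {f.name for f in dataclasses.fields(ScreeningConfig)}, "screening")
    screening = _build(ScreeningConfig, screening_doc, "screening")

    model_doc = dict(doc.get("model") or {})
    _check_keys(model_doc, {f.name for f in dataclasses.fields(ModelConfig)}, "model")
    if "hypothesis_priors" in model_doc:
        model_doc["hypothesis_priors"] = tuple(model_doc["hypothesis_priors"])
    model = _build(ModelConfig, model_doc, "model")

    try:
        return PipelineConfig(
            trials_path=trials_path,
            eye_path=inp.get("eye_traces"),
            preset=preset,
            window=window,
            screening=screening,
            model=model,
            output_dir=str(doc.get("output_dir", "spikemux-output")),
            seed=int(doc.get("seed", 0)),
            log_level=str(doc.get("log_level", "INFO")),
            tally_threshold=float(doc.get("tally_threshold", 0.67)),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def _config_echo(cfg: PipelineConfig) -> dict:
    echo = dataclasses.asdict(cfg)
    echo["window"] = dataclasses.asdict(cfg.window)
    echo["screening"] = dataclasses.asdict(cfg.screening)
    echo["model"] = dataclasses.asdict(cfg.model)
    return echo


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute ingest -> screen -> classify -> summarise; returns the manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- ingest ---------------------------------------------------------
    regime_of: dict[str, str] = {}
    if config.preset is not None:
        dataset = simulate_population(preset_specs(config.preset),
                                      master_seed=config.seed)
        triplets = dataset.triplets
        regime_of = {t.unit_id: s.regime for t, s in dataset.pairs}
        logger.info("simulated %d triplets from preset %r", len(triplets), config.preset)
    else:
        trials = read_trials(config.trials_path, config.eye_path)
        triplets = build_triplets(trials, config.window,
                                  microsaccade_n_sd=config.microsaccade_n_sd)
        logger.info("assembled %d triplets from %d trials",
                    len(triplets), len(trials))

    # --- screen ---------------------------------------------------------
    reports = screen_triplets(triplets, config.screening)
    screening_frame = reports_to_frame(reports)
    screening_frame.to_csv(out / "screening.csv", index=False, float_format="%.12g")
    included = [r.triplet for r in reports if r.included]
    by_reason = {
        reason: sum(reason in r.failure_reasons for r in reports)
        for reason in ("trials", "fano", "separability")
    }
    logger.info("screening: %d/%d included (failures by criterion: %s)",
                len(included), len(reports), by_reason)

    # --- classify -------------------------------------------------------
    classifications = classify_triplets(included, config.model)
    cls_frame = classifications_to_frame(classifications)
    if regime_of:
        cls_frame.insert(2, "regime", [regime_of[c.triplet.unit_id]
                                       for c in classifications])
    cls_frame.to_csv(out / "classifications.csv", index=False, float_format="%.12g")
    n_fluctuating = sum(c.fluctuating for c in classifications)
    logger.info("classified %d triplets; %d fluctuating",
                len(classifications), n_fluctuating)

    # --- summarise ------------------------------------------------------
    groups: dict[str, list] = {}
    for c in classifications:
        groups.setdefault(regime_of.get(c.triplet.unit_id, "all"), []).append(c)
    screened_out_of = {label: 0 for label in groups}
    for r in reports:
        if not r.included:
            label = regime_of.get(r.triplet.unit_id, "all")
            screened_out_of[label] = screened_out_of.get(label, 0) + 1
    tallies = [
        tally_classifications(groups[label], threshold=config.tally_threshold,
                              regime=label,
                              n_screened_out=screened_out_of.get(label, 0))
        for label in sorted(groups)
    ]
    tally_to_frame(tallies).to_csv(out / "tallies.csv", index=False)

    comparison_rows = []
    for t1, t2 in itertools.combinations(tallies, 2):
        row = {"regime_1": t1.regime, "regime_2": t2.regime}
        try:
            res = compare_mixture_prevalence(t1, t2)
            row.update(statistic=res.statistic, dof=res.dof, p_value=res.p_value,
                       proportion_1=mixture_proportion(t1),
                       proportion_2=mixture_proportion(t2))
        except (DegenerateTableError, ValueError) as exc:
            row.update(statistic=np.nan, dof=np.nan, p_value=np.nan,
                       proportion_1=np.nan, proportion_2=np.nan)
            logger.warning("comparison %s vs %s skipped: %s",
                           t1.regime, t2.regime, exc)
        comparison_rows.append(row)
    pd.DataFrame(comparison_rows).to_csv(out / "comparisons.csv", index=False,
                                         float_format="%.12g")

    # --- figures --------------------------------------------------------
    if tallies:
        plot_category_bars(tallies, path=out / "category_bars.svg")
    if classifications:
        example = classifications[0].triplet
        plot_count_histogram(example.ab_counts,
                             mean_a=float(np.mean(example.a_counts)),
                             mean_b=float(np.mean(example.b_counts)),
                             window_duration=config.window.duration,
                             path=out / "example_histogram.svg")

    manifest = {
        "config": _config_echo(config),
        "versions": {"spikemux": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__,
                     "python": sys.version.split()[0]},
        "seed": config.seed,
        "attrition": {
            "n_triplets": len(reports),
            "n_included": len(included),
            "screen_failures_by_criterion": by_reason,
            "n_classified_at_threshold": int(sum(t.n_classified for t in tallies)),
            "n_unclassified": int(sum(t.n_unclassified for t in tallies)),
            "n_fluctuating": int(n_fluctuating),
        },
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
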