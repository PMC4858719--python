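"""End-to-end analysis: segmentation → detection → colocalization → metrics.

`analyze_stack` runs the full per-vessel analysis; `run_all` reproduces an
entire simulated study (generate cohorts, analyse every vessel, write all
tables) and `compare_cohorts` produces the group-statistics report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (Compartment, CompartmentGeometry, CompartmentMask,
                   ColocalizationResult, ImageStack, SpotSet, VesselQuantification)
from .coloc import corrected_colocalization
from .io import write_stack, write_table
from .segmentation import measure_geometry, segment_stack
from .spots import assign_compartments, detect_spots
from .stats import fishers_lsd, fold_change, quantify_vessel
from .synth import (
    CohortScenario,
    VesselSceneConfig,
    control_scenario,
    generate_cohort,
    pericyte_deficient_scenario,
    steadystate_config,
)

METRICS = ("bl_intensity_per_um2", "parenchyma_intensity_per_um3", "vesicles_per_um3")


@dataclass
class AnalysisConfig:
    """Resolved parameters for every analysis stage of one run."""

    collagen_channel: str = "collagen"
    cargo_channel: str = "cargo"
    marker_channel: str = "lysosome"
    threshold: float | str = "auto"
    min_component_volume_um3: float = 1.0
    expected_diameter_um: float = 0.8
    quality_cutoff: float | str = "auto"
    mad_k: float = 15.0
    min_separation_um: float = 0.4
    n_randomizations: int = 100
    coloc_seed: int = 0
    d_min_um: float = 0.25
    background: float | str = "interior-median"
    vessel_volume: str = "filled"
    run_colocalization: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"analysis": asdict(self)}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        params = data.get("analysis", data)
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(params) - valid
        if unknown:
            raise KeyError(
                f"unknown analysis config key(s) {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        return cls(**params)


@dataclass
class VesselAnalysis:
    """Everything the pipeline computed for one vessel field."""

    stack: ImageStack
    mask: CompartmentMask
    geometry: CompartmentGeometry
    cargo_spots: SpotSet
    marker_spots: SpotSet | None
    colocalization: ColocalizationResult | None
    quantification: VesselQuantification | None = None


def analyze_stack(stack: ImageStack, config: AnalysisConfig | None = None,
                  genotype: str = "", animal: str = "") -> VesselAnalysis:
    """Run segmentation, detection, colocalization and quantification."""
    cfg = config or AnalysisConfig()
    mask = segment_stack(stack, cfg.collagen_channel, cfg.threshold,
                         min_component_volume_um3=cfg.min_component_volume_um3)
    geometry = measure_geometry(mask)
    detector_kwargs = dict(
        expected_diameter_um=cfg.expected_diameter_um,
        quality_cutoff=cfg.quality_cutoff,
        mad_k=cfg.mad_k,
        min_separation_um=cfg.min_separation_um,
    )
    cargo = assign_compartments(detect_spots(stack, cfg.cargo_channel, **detector_kwargs), mask)
    marker = None
    result = None
    if cfg.run_colocalization and cfg.marker_channel in stack.channel_names:
        marker = assign_compartments(detect_spots(stack, cfg.marker_channel, **detector_kwargs), mask)
        cargo_in = cargo.in_compartment(Compartment.INTERIOR)
        marker_in = marker.in_compartment(Compartment.INTERIOR)
        if len(cargo_in) and len(marker_in):
            result = corrected_colocalization(
                cargo_in, marker_in, mask,
                n_rand=cfg.n_randomizations, seed=cfg.coloc_seed, d_min_um=cfg.d_min_um,
            )
    quant = quantify_vessel(
        stack, mask, cargo, geometry,
        cargo_channel=cfg.cargo_channel, background=cfg.background,
        vessel_volume=cfg.vessel_volume, genotype=genotype, animal=animal,
    )
    return VesselAnalysis(stack=stack, mask=mask, geometry=geometry,
                          cargo_spots=cargo, marker_spots=marker,
                          colocalization=result, quantification=quant)


def _scenario_by_name(name: str, master_seed: int, n_animals: int,
                      vessels_per_animal: int) -> CohortScenario:
    common = dict(master_seed=master_seed, n_animals=n_animals,
                  vessels_per_animal=vessels_per_animal)
    if name in ("steadystate", "control"):
        return control_scenario(**common)
    if name == "pericyte_deficient":
        return pericyte_deficient_scenario(**common)
    raise KeyError(f"unknown scenario {name!r}; use steadystate, control or pericyte_deficient")


def analyze_cohort(cohort, config: AnalysisConfig | None = None,
                   genotype: str = "") -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Analyse a generated cohort; returns (metrics, coloc, spots) frames."""
    cfg = config or AnalysisConfig()
    metric_rows, coloc_rows, spot_frames = [], [], []
    for a, animal in enumerate(cohort):
        for stack, _manifest in animal:
            res = analyze_stack(stack, cfg, genotype=genotype, animal=f"a{a}")
            metric_rows.append(res.quantification.to_dict())
            if res.colocalization is not None:
                c = res.colocalization
                coloc_rows.append({
                    "stack_id": stack.stack_id, "genotype": genotype, "animal": f"a{a}",
                    "observed": c.observed_fraction, "random_mean": c.random_fraction_mean,
                    "random_sd": c.random_fraction_sd, "corrected": c.corrected_fraction,
                    "excess": c.excess_fraction, "n_rand": c.n_randomizations,
                })
            spot_frames.append(res.cargo_spots.to_frame())
    metrics = pd.DataFrame(metric_rows)
    coloc = pd.DataFrame(coloc_rows, columns=[
        "stack_id", "genotype", "animal", "observed", "random_mean",
        "random_sd", "corrected", "excess", "n_rand"])
    spots = pd.concat(spot_frames, ignore_index=True) if spot_frames else pd.DataFrame()
    return metrics, coloc, spots


def run_all(
    out_dir,
    scenarios=("control", "pericyte_deficient"),
    seed: int = 0,
    n_animals: int = 3,
    vessels_per_animal: int = 10,
    base_config: VesselSceneConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    write_stacks: bool = False,
) -> dict:
    """Simulate, analyse and report one full in-silico study.

    Writes per-vessel ``metrics.csv``, ``colocalization.csv``, ``spots.csv``,
    the group-comparison ``report.csv`` (when two or more scenarios are run),
    and the resolved configuration next to the outputs. Identical
    (configuration, seed) always reproduce byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = base_config or steadystate_config()
    cfg = analysis_config or AnalysisConfig()

    all_metrics, all_coloc, all_spots = [], [], []
    for i, name in enumerate(scenarios):
        scenario = _scenario_by_name(name, master_seed=seed + i, n_animals=n_animals,
                                     vessels_per_animal=vessels_per_animal)
        cohort = generate_cohort(scenario, base)
        if write_stacks:
            for animal in cohort:
                for stack, manifest in animal:
                    write_stack(stack, out_dir / "stacks" / f"{stack.stack_id}.tif")
                    manifest.to_json(out_dir / "stacks" / f"{stack.stack_id}.manifest.json")
        metrics, coloc, spots = analyze_cohort(cohort, cfg, genotype=name)
        all_metrics.append(metrics)
        all_coloc.append(coloc)
        all_spots.append(spots)

    metrics = pd.concat(all_metrics, ignore_index=True)
    coloc = pd.concat(all_coloc, ignore_index=True)
    spots = pd.concat(all_spots, ignore_index=True)
    write_table(metrics, out_dir / "metrics.csv", sort_by=["genotype", "stack_id"])
    write_table(coloc, out_dir / "colocalization.csv", sort_by=["genotype", "stack_id"])
    write_table(spots, out_dir / "spots.csv",
                sort_by=["stack_id", "channel", "z_um", "y_um", "x_um"] if len(spots) else None)

    report = None
    if metrics["genotype"].nunique() >= 2:
        report = compare_cohorts(metrics)
        write_table(report, out_dir / "report.csv")

    resolved = {
        "vesiq_version": __version__,
        "seed": seed,
        "scenarios": list(scenarios),
        "n_animals": n_animals,
        "vessels_per_animal": vessels_per_animal,
        "base_scene": asdict(base),
        "analysis": asdict(cfg),
    }
    with open(out_dir / "resolved_config.json", "w", encoding="utf-8") as fh:
        json.dump(resolved, fh, indent=1, sort_keys=True)
    return {"metrics": metrics, "colocalization": coloc, "spots": spots, "report": report}


def compare_cohorts(metrics: pd.DataFrame, boot_seed: int = 0) -> pd.DataFrame:
    """Group-statistics report over the per-vessel metrics table.

    One row per metric per genotype pair: Fisher's LSD t and p, fold change
    of means (group_a / group_b) with a bootstrap CI.
    """
    rows = []
    for metric in METRICS:
        groups = {g: sub[metric].to_numpy() for g, sub in metrics.groupby("genotype")}
        comparison = fishers_lsd(groups, metric=metric)
        for pair in comparison.pairwise.itertuples(index=False):
            a = groups[pair.group_a]
            b = groups[pair.group_b]
            try:
                fc = fold_change(a, b, seed=boot_seed)
                ratio, lo, hi = fc.ratio, fc.ci_low, fc.ci_high
            except ValueError:
                ratio = lo = hi = float("nan")
            rows.append({
                "metric": metric, "group_a": pair.group_a, "group_b": pair.group_b,
                "mean_a": float(np.mean(a)), "mean_b": float(np.mean(b)),
                "t": pair.t, "p": pair.p, "df": comparison.df_within,
                "fold_change": ratio, "fold_ci_low": lo, "fold_ci_high": hi,
            })
    return pd.DataFrame(rows)
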