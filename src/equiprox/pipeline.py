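"""Orchestration: simulate → clean → metrics → associations → network →
events → stats, as a configured, seeded, reproducible run.

Every stage persists its output as plain text (CSV / GraphML / JSON) inside
the run's output directory, so each stage can be re-run or inspected
independently, and the final report JSON carries the provenance a reader
needs: seeds, per-filter removal counts, event counts and rates. Identical
config and seed give a byte-identical report.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from ._util import dyad_key
from .associations import affiliation_strata, associate_table, association_matrices
from .cleaning import DistanceSeries, clean_all, load_distance_csv
from .config import EnclosureConfig, EventConfig, FilterConfig
from .events import detect_events, summarize_rates
from .metrics import format_summary_row, group_summary, summarize_dyads
from .network import build_network, export_graph
from .simulate import (
    NoiseConfig,
    SimConfig,
    SpontaneousAggression,
    default_affinity,
    schedule_events,
    simulate_herd,
    trajectories_to_distances,
    write_distance_csv,
    write_ground_truth,
)
from .stats import fisher_pitman, spearman


class NoiseSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    jitter_sd_cm: float = Field(default=2.0, ge=0)
    replicate_sd_cm: float = Field(default=3.0, ge=0)
    p_spike: float = Field(default=0.001, ge=0, le=1)
    p_under5: float = Field(default=0.0005, ge=0, le=1)


class SimulateSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    duration_s: int = Field(ge=60)
    equilibrium_dist_m: float = Field(default=3.0, gt=0)
    wander_sd_m_s: float = Field(default=0.15, ge=0)
    feeder: bool = False
    n_scripted_events: int = Field(default=0, ge=0)
    spontaneous_rate_per_pair_s: float = Field(default=0.02, ge=0, le=1)
    noise: NoiseSpec = Field(default_factory=NoiseSpec)


class SourceSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    csv: Optional[str] = None
    simulate: Optional[SimulateSpec] = None

    @model_validator(mode="after")
    def _exactly_one(self) -> "SourceSpec":
        if (self.csv is None) == (self.simulate is None):
            raise ValueError("source needs exactly one of 'csv' or 'simulate'")
        return self


class ConditionSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    enclosure: EnclosureConfig
    source: SourceSpec


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    output_dir: str = "equiprox_run"
    n_boot: int = Field(default=1000, ge=10)
    relative_method: str = Field(default="median_of_ratios", pattern="^(median_of_ratios|ratio_of_medians)$")
    filters: FilterConfig = Field(default_factory=FilterConfig)
    events: EventConfig = Field(default_factory=EventConfig)
    conditions: list[ConditionSpec] = Field(min_length=1)

    @model_validator(mode="after")
    def _unique_names(self) -> "RunConfig":
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("condition names must be unique")
        return self


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return RunConfig.model_validate(doc)


def _sim_config(cond: ConditionSpec, run: RunConfig) -> SimConfig:
    spec = cond.source.simulate
    enc = cond.enclosure
    n = enc.n_horses
    ids = [f"h{i + 1:02d}" for i in range(n)]
    # roster and affinity are shared across conditions: seeded by the run
    affinity = default_affinity(n, run.seed)
    schedule = (
        schedule_events(spec.n_scripted_events, spec.duration_s, ids, seed=run.seed + 7)
        if spec.n_scripted_events
        else []
    )
    spont = (
        SpontaneousAggression(rate_per_pair_s=spec.spontaneous_rate_per_pair_s)
        if spec.spontaneous_rate_per_pair_s > 0
        else None
    )
    feeder_xy = (enc.length_m / 2.0, enc.width_m / 2.0) if spec.feeder else None
    cond_offset = [c.name for c in run.conditions].index(cond.name)
    return SimConfig(
        enclosure_length_m=enc.length_m,
        enclosure_width_m=enc.width_m,
        n_agents=n,
        duration_s=spec.duration_s,
        seed=run.seed + 1000 * (cond_offset + 1),
        affinity=affinity,
        equilibrium_dist_m=spec.equilibrium_dist_m,
        feeder_xy=feeder_xy,
        event_schedule=schedule,
        noise=NoiseConfig(
            jitter_sd_cm=spec.noise.jitter_sd_cm,
            replicate_sd_cm=spec.noise.replicate_sd_cm,
            p_spike=spec.noise.p_spike,
            p_under5=spec.noise.p_under5,
        ),
        spontaneous=spont,
        wander_sd_m_s=spec.wander_sd_m_s,
        agent_ids=ids,
    )


def stage_simulate(run: RunConfig, outdir: Path) -> dict:
    """Simulate every simulate-mode condition; write raw CSVs + ground truth."""
    info = {}
    for cond in run.conditions:
        if cond.source.simulate is None:
            continue
        sim_cfg = _sim_config(cond, run)
        sim = simulate_herd(sim_cfg)
        table = trajectories_to_distances(sim, seed=sim_cfg.seed + 1)
        write_distance_csv(table, outdir / f"raw_{cond.name}.csv")
        write_ground_truth(sim.ground_truth, outdir / f"ground_truth_{cond.name}.json")
        sim_cfg.to_yaml(outdir / f"sim_config_{cond.name}.yaml")
        info[cond.name] = {
            "simulated": True,
            "seed": sim_cfg.seed,
            "n_true_events": len(sim.ground_truth.events),
            "n_injected_artifacts": len(sim.ground_truth.injected_artifacts),
        }
    return info


def _roster(enc: EnclosureConfig) -> list[str]:
    return [f"h{i + 1:02d}" for i in range(enc.n_horses)]


def stage_clean(run: RunConfig, outdir: Path) -> dict:
    """Load raw tables (simulated or user CSV), clean, persist per-dyad series."""
    info = {}
    for cond in run.conditions:
        path = cond.source.csv or outdir / f"raw_{cond.name}.csv"
        roster = _roster(cond.enclosure)
        table, load_report = load_distance_csv(path, roster)
        series, clean_report = clean_all(table, roster, cond.enclosure, filters=run.filters)
        long = pd.concat(
            [
                ds.samples.assign(animal_a=dyad[0], animal_b=dyad[1])
                for dyad, ds in sorted(series.items())
            ],
            ignore_index=True,
        )
        long[["animal_a", "animal_b", "t", "d"]].to_csv(
            outdir / f"cleaned_{cond.name}.csv", index=False
        )
        info[cond.name] = {"load": load_report, "cleaning": clean_report}
    return info


def load_cleaned(path) -> dict[tuple[str, str], DistanceSeries]:
    """Read a cleaned per-dyad intermediate CSV back into DistanceSeries."""
    long = pd.read_csv(path, dtype={"animal_a": str, "animal_b": str})
    out = {}
    for (a, b), grp in long.groupby(["animal_a", "animal_b"]):
        out[dyad_key(a, b)] = DistanceSeries(
            dyad=dyad_key(a, b), samples=grp[["t", "d"]].reset_index(drop=True)
        )
    return out


def stage_metrics(run: RunConfig, outdir: Path) -> dict:
    """Per-dyad and pooled distance summaries (absolute + relative)."""
    pooled_rows = []
    for cond in run.conditions:
        series = load_cleaned(outdir / f"cleaned_{cond.name}.csv")
        dyads = summarize_dyads(
            series, cond.enclosure, cond.name, n_boot=run.n_boot, seed=run.seed
        )
        dyads.to_csv(outdir / f"dyad_metrics_{cond.name}.csv", index=False)
        pooled_rows.append(
            format_summary_row(
                group_summary(
                    dyads, n_boot=run.n_boot, seed=run.seed, relative_method=run.relative_method
                )
            )
        )
    summary = pd.DataFrame(pooled_rows)
    summary.to_csv(outdir / "distance_summary.csv", index=False)
    return {row["condition"]: row for row in pooled_rows}


def stage_associations(run: RunConfig, outdir: Path) -> dict:
    info = {}
    for cond in run.conditions:
        series = load_cleaned(outdir / f"cleaned_{cond.name}.csv")
        roster = _roster(cond.enclosure)
        mats = association_matrices(series, roster)
        for lab, mat in mats.items():
            mat.to_csv(outdir / f"assoc_{cond.name}_{lab}.csv")
        assoc = associate_table(mats, roster, cond.name)
        assoc.to_csv(outdir / f"associates_{cond.name}.csv", index=False)
        strata = affiliation_strata(mats, assoc)
        strata.to_csv(outdir / f"strata_{cond.name}.csv", index=False)
        info[cond.name] = {
            "closest": dict(zip(assoc["animal"], assoc["closest"])),
            "least_frequent": dict(zip(assoc["animal"], assoc["least_frequent"])),
        }
    return info


def stage_network(run: RunConfig, outdir: Path) -> dict:
    info = {}
    for cond in run.conditions:
        series = load_cleaned(outdir / f"cleaned_{cond.name}.csv")
        roster = _roster(cond.enclosure)
        net = build_network(series, roster)
        cent = net["centralities"].round(6)
        cent.insert(0, "condition", cond.name)
        cent.to_csv(outdir / f"centralities_{cond.name}.csv", index_label="animal")
        export_graph(
            net,
            outdir / f"network_{cond.name}.graphml",
            outdir / f"edges_{cond.name}.csv",
        )
        info[cond.name] = {
            "threshold_cm": net["threshold_cm"],
            "n_edges": int(net["adjacency"].to_numpy().sum() // 2),
        }
    return info


def stage_events(run: RunConfig, outdir: Path) -> dict:
    info = {}
    rate_frames = []
    for cond in run.conditions:
        series = load_cleaned(outdir / f"cleaned_{cond.name}.csv")
        evts = detect_events(series, run.events)
        evts.to_csv(outdir / f"events_{cond.name}.csv", index=False)
        rates = summarize_rates(
            evts, cond.enclosure.n_horses, cond.enclosure.tracking_hours, cond.name
        )
        rate_frames.append(rates)
        info[cond.name] = {
            row["kind"]: {
                "n": row["n_events"],
                "rate_per_horse_hour": row["rate_per_horse_hour"],
            }
            for _, row in rates.iterrows()
        }
    pd.concat(rate_frames, ignore_index=True).to_csv(outdir / "event_rates.csv", index=False)
    return info


def stage_stats(run: RunConfig, outdir: Path) -> dict:
    """Cross-condition inference: permutation test of per-dyad median
    distances between the first two conditions, and the Spearman correlation
    between per-dyad approach counts and median distances."""
    info: dict = {}
    tables = {
        cond.name: pd.read_csv(outdir / f"dyad_metrics_{cond.name}.csv")
        for cond in run.conditions
    }
    if len(run.conditions) >= 2:
        a, b = run.conditions[0].name, run.conditions[1].name
        res = fisher_pitman(
            tables[a]["median_cm"], tables[b]["median_cm"], n_iter=1000, seed=run.seed
        )
        info["median_distance_permutation"] = {
            "conditions": [a, b],
            "observed_mean_diff_cm": res.observed_stat,
            "p_value": res.p_value,
            "n_iter": res.n_iter,
        }
    counts, medians = [], []
    for cond in run.conditions:
        evts = pd.read_csv(outdir / f"events_{cond.name}.csv")
        ap = evts[evts["kind"] == "approach"]
        per_dyad = ap.groupby(["animal_a", "animal_b"]).size()
        for row in tables[cond.name].itertuples():
            counts.append(int(per_dyad.get((row.animal_a, row.animal_b), 0)))
            medians.append(float(row.median_cm))
    if len(counts) >= 3 and len(set(counts)) > 1:
        info["approaches_vs_distance_spearman"] = spearman(counts, medians)
    return info


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the report dict (also written as JSON)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {
        "version": __version__,
        "seed": config.seed,
        "relative_method": config.relative_method,
        "stages": {},
    }
    report["stages"]["simulate"] = stage_simulate(config, outdir)
    report["stages"]["clean"] = stage_clean(config, outdir)
    report["stages"]["metrics"] = stage_metrics(config, outdir)
    report["stages"]["associations"] = stage_associations(config, outdir)
    report["stages"]["network"] = stage_network(config, outdir)
    report["stages"]["events"] = stage_events(config, outdir)
    report["stages"]["stats"] = stage_stats(config, outdir)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    return report
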