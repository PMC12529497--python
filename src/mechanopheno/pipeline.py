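"""Configuration schema and the end-to-end pipeline driver.

A single YAML config describes any subset of stages; ``run_pipeline``
executes the requested stages in order (simulate -> hertz / tfm / migrate
/ morpho -> report) and writes CSV tables, TIFF scenes, YAML sidecars and
a JSON run manifest into the output directory.  Reruns with an identical
config and seed are byte-identical (no timestamps in outputs).

Analysis stages consume either the simulated scene of the same run or
user-supplied files named in the config.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__, indentation, io, migration, morphometry
from . import stats as mstats
from . import synthgen, tfm

__all__ = ["PipelineConfig", "run_pipeline", "default_config"]


class SimulateConfig(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    indentation: Optional[synthgen.SyntheticIndentationSpec] = None
    tfm: Optional[synthgen.SyntheticTractionSpec] = None
    migration: Optional[synthgen.SyntheticPRWSpec] = None
    morpho: Optional[synthgen.SyntheticFASceneSpec] = None


class HertzConfig(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    input: Optional[str] = None           # CSV depth_m, force_n
    R_m: float = Field(5e-4, gt=0)
    poisson: float = Field(0.5, ge=0, le=0.5)
    depth_fraction: Optional[tuple[float, float]] = None


class PivConfig(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    window_px: int = Field(32, ge=16)
    overlap: float = Field(0.5, ge=0, lt=1)


class FttcConfig(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    lam: float = Field(tfm.DEFAULT_LAMBDA, ge=0, alias="lambda")


class TfmConfig(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid",
                              populate_by_name=True)

    reference: Optional[str] = None       # TIFF paths; None = simulated scene
    stack: Optional[str] = None
    pixel_size_um: float = Field(0.4, gt=0)
    E_gel_pa: float = Field(30000.0, gt=0)
    poisson: float = Field(0.5, ge=0, le=0.5)
    align: bool = False
    piv: PivConfig = PivConfig()
    fttc: FttcConfig = FttcConfig()


class MigrateConfig(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    trajectories: Optional[str] = None    # CSV; None = simulated
    stack: Optional[str] = None           # nuclei TIFF stack alternative
    pixel_size_um: float = Field(2.0, gt=0)
    frame_interval_min: float = Field(10.0, gt=0)
    min_area_um2: float = Field(30.0, ge=0)
    max_step_um: float = Field(12.0, gt=0)
    max_lag_fraction: float = Field(0.25, gt=0, le=1)


class MorphoConfig(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    nuclei: Optional[str] = None          # TIFF paths; None = simulated
    cell: Optional[str] = None
    fa: Optional[str] = None
    pixel_size_um: float = Field(0.2, gt=0)
    saturation: float = Field(0.35, ge=0, lt=50)
    tophat_radius_px: int = Field(5, ge=1)
    nuclei_min_area_um2: float = Field(30.0, ge=0)
    fa_min_area_um2: float = Field(0.1, ge=0)
    fa_max_area_um2: float = Field(30.0, gt=0)


class ReportConfig(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    figures: bool = False


class PipelineConfig(BaseModel):
    """Top-level schema; omit a section to skip that stage."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    seed: int = 0
    simulate: Optional[SimulateConfig] = None
    hertz: Optional[HertzConfig] = None
    tfm: Optional[TfmConfig] = None
    migrate: Optional[MigrateConfig] = None
    morpho: Optional[MorphoConfig] = None
    report: Optional[ReportConfig] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.model_validate(io.read_yaml(path) or {})


def default_config() -> PipelineConfig:
    """A fully populated synthetic end-to-end configuration."""
    return PipelineConfig(
        simulate=SimulateConfig(
            indentation=synthgen.SyntheticIndentationSpec(),
            tfm=synthgen.SyntheticTractionSpec(),
            migration=synthgen.SyntheticPRWSpec(
                n_cells=50, arena=(800.0, 800.0)),
            morpho=synthgen.SyntheticFASceneSpec()),
        hertz=HertzConfig(), tfm=TfmConfig(), migrate=MigrateConfig(),
        morpho=MorphoConfig(), report=ReportConfig())


def _reseed(model, seed: int):
    return model.model_copy(update={"seed": seed})


def run_pipeline(config: PipelineConfig | dict | str | Path,
                 out_dir, seed: int | None = None) -> Path:
    """Execute the configured stages and return the output directory.

    ``seed`` overrides the config seed (and reseeds every simulate spec).
    Raises ``pydantic.ValidationError`` with field paths on a malformed
    config; stage failures propagate as exceptions.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.model_validate(config)
    if seed is not None:
        config = config.model_copy(update={"seed": int(seed)})
    seed = config.seed

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": seed,
                      "config": json.loads(config.model_dump_json(by_alias=True)),
                      "outputs": []}

    def save_table(name, df):
        io.write_table(out / name, df)
        manifest["outputs"].append(name)

    def save_yaml(name, payload):
        io.write_yaml(out / name, payload)
        manifest["outputs"].append(name)

    def save_tiff(name, img):
        io.write_tiff(out / name, img)
        manifest["outputs"].append(name)

    sim = config.simulate
    scene: dict = {}

    # ---- simulate -------------------------------------------------------
    if sim is not None:
        ss = np.random.SeedSequence(seed)
        subseeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
        if sim.indentation is not None:
            spec = _reseed(sim.indentation, subseeds[0])
            curve, gt = synthgen.gen_indentation_curve(spec)
            scene["indentation"] = curve
            save_table("indentation_curve.csv",
                       io.curve_to_frame(curve.depth, curve.force))
            save_yaml("indentation_truth.yaml", gt.to_dict())
        if sim.tfm is not None:
            spec = _reseed(sim.tfm, subseeds[1])
            ref, dfm, tr, disp, gt = synthgen.gen_traction_scene(spec)
            scene["tfm"] = (ref, dfm, tr, disp)
            save_tiff("beads_reference.tif", ref)
            save_tiff("beads_deformed.tif", dfm)
            save_table("true_fields.csv", io.fields_to_frame(disp, tr))
            save_yaml("tfm_truth.yaml", {"scenario": gt.scenario,
                                         "spec": spec.model_dump()})
        if sim.migration is not None:
            spec = _reseed(sim.migration, subseeds[2])
            trajs, gt = synthgen.gen_prw_trajectories(spec)
            scene["migration"] = trajs
            io.write_trajectories(out / "trajectories.csv", trajs)
            manifest["outputs"].append("trajectories.csv")
            save_yaml("migration_truth.yaml", {
                "scenario": gt.scenario,
                "speed_scale": gt.params["speed_scale"],
                "persistence_time": gt.params["persistence_time"],
                "spec": spec.model_dump()})
        if sim.morpho is not None:
            spec = _reseed(sim.morpho, subseeds[3])
            fa_img, nuc_img, cell_img, gt = synthgen.gen_fa_scene(spec)
            scene["morpho"] = (fa_img, nuc_img, cell_img)
            save_tiff("fa_channel.tif", fa_img)
            save_tiff("nuclei_channel.tif", nuc_img)
            save_tiff("cell_channel.tif", cell_img)
            save_table("fa_truth.csv", gt.params["fa_table"])
            save_yaml("morpho_truth.yaml", {"scenario": gt.scenario,
                                            "spec": spec.model_dump()})

    # ---- hertz ----------------------------------------------------------
    if config.hertz is not None:
        hc = config.hertz
        if hc.input is not None:
            df = pd.read_csv(hc.input)
            curve = indentation.ForceDepthCurve(
                df["depth_m"].to_numpy(), df["force_n"].to_numpy(),
                R=hc.R_m, poisson=hc.poisson)
        elif "indentation" in scene:
            curve = scene["indentation"]
        else:
            raise ValueError("hertz stage: no input curve (set hertz.input "
                             "or simulate.indentation)")
        est = indentation.fit_hertz(curve, depth_fraction=hc.depth_fraction)
        save_table("hertz_fit.csv", pd.DataFrame([{
            "E_pa": est.E, "stderr_pa": est.stderr, "rmse_n": est.rmse,
            "n_points": est.n_points,
            "depth_min_m": est.depth_range_used[0],
            "depth_max_m": est.depth_range_used[1]}]))

    # ---- tfm ------------------------------------------------------------
    if config.tfm is not None:
        tc = config.tfm
        if tc.reference is not None and tc.stack is not None:
            ref = io.read_tiff(tc.reference)
            stack = io.read_tiff(tc.stack)
            if stack.ndim == 2:
                stack = stack[None]
        elif "tfm" in scene:
            ref, dfm = scene["tfm"][0], scene["tfm"][1]
            stack = dfm[None]
        else:
            raise ValueError("tfm stage: no images (set tfm.reference/stack "
                             "or simulate.tfm)")
        if tc.align:
            stack, ref, shifts = tfm.align_to_reference(stack, ref)
            save_table("alignment_shifts.csv",
                       pd.DataFrame(shifts, columns=["dy_px", "dx_px"]))
        tractions = []
        for i, frame in enumerate(stack):
            pair = tfm.BeadImagePair(ref, frame, pixel_size=tc.pixel_size_um)
            disp = tfm.piv_displacement(pair, window=tc.piv.window_px,
                                        overlap=tc.piv.overlap)
            tr = tfm.fttc_traction(disp, E_gel=tc.E_gel_pa,
                                   poisson=tc.poisson, lam=tc.fttc.lam)
            tractions.append(tr)
            save_table(f"tfm_fields_f{i:03d}.csv",
                       io.fields_to_frame(disp, tr))
        summary = tfm.summarize_traction(tractions)
        save_table("traction_summary.csv", pd.DataFrame({
            "frame": np.arange(len(summary.frame_medians)),
            "spatial_median_pa": summary.frame_medians}))
        save_yaml("traction_mean.yaml",
                  {"temporal_mean_pa": summary.temporal_mean})

    # ---- migrate --------------------------------------------------------
    if config.migrate is not None:
        mc = config.migrate
        if mc.trajectories is not None:
            trajs = io.read_trajectories(mc.trajectories)
        elif mc.stack is not None:
            stack = io.read_tiff(mc.stack)
            frames = [migration.detect_nuclei(
                img, mc.pixel_size_um, mc.min_area_um2, frame=k,
                t=k * mc.frame_interval_min) for k, img in enumerate(stack)]
            trajs = migration.link_trajectories(frames, mc.max_step_um)
        elif "migration" in scene:
            trajs = scene["migration"]
        else:
            raise ValueError("migrate stage: no trajectories (set "
                             "migrate.trajectories/stack or "
                             "simulate.migration)")
        st = migration.ensemble_stats(trajs,
                                      max_lag_fraction=mc.max_lag_fraction)
        scene["migration_stats"] = st
        save_table("speeds.csv", pd.DataFrame({
            "cell_id": [tr.cell_id for tr in trajs],
            "mean_speed_um_min": st.speeds}))
        save_table("msd.csv", pd.DataFrame({
            "lag_min": st.lags, "msd_mean_um2": st.msd_mean,
            "msd_sd_um2": st.msd_sd, "n_cells": st.msd_n}))
        prw = migration.fit_prw(st)
        save_yaml("prw_fit.yaml", {
            "speed_scale_um_min": prw.S, "persistence_min": prw.P,
            "at_identifiability_bound": bool(prw.at_bound)})

    # ---- morpho ---------------------------------------------------------
    if config.morpho is not None:
        oc = config.morpho
        if oc.nuclei is not None:
            nuc = io.read_tiff(oc.nuclei)
            cell = io.read_tiff(oc.cell) if oc.cell else None
            fa = io.read_tiff(oc.fa) if oc.fa else None
        elif "morpho" in scene:
            fa, nuc, cell = scene["morpho"]
        else:
            raise ValueError("morpho stage: no images (set morpho.nuclei/"
                             "cell/fa or simulate.morpho)")
        px = oc.pixel_size_um
        nuclab = morphometry.segment_primary(
            morphometry.preprocess(
                morphometry.ChannelImage(nuc, "nuclei", px),
                saturation=oc.saturation),
            min_area=oc.nuclei_min_area_um2)
        save_table("nuclei_measurements.csv",
                   morphometry.measure_objects(nuclab).table)
        if cell is not None:
            cells = morphometry.segment_secondary(
                morphometry.preprocess(
                    morphometry.ChannelImage(cell, "cell", px),
                    saturation=oc.saturation), nuclab)
            cm = morphometry.measure_objects(cells)
            save_table("cell_measurements.csv", cm.table)
            save_yaml("area_occupied.yaml",
                      {"cell_area_fraction": cm.area_occupied_fraction})
            if fa is not None:
                fal = morphometry.segment_fa(
                    morphometry.preprocess(
                        morphometry.ChannelImage(fa, "fa", px),
                        saturation=oc.saturation,
                        tophat_radius=oc.tophat_radius_px,
                        apply_tophat=True),
                    cells, min_area=oc.fa_min_area_um2,
                    max_area=oc.fa_max_area_um2)
                if fal.n_objects:
                    save_table("fa_measurements.csv",
                               morphometry.measure_objects(fal).table)

    # ---- report ---------------------------------------------------------
    if config.report is not None and "migration_stats" in scene:
        st = scene["migration_stats"]
        ds = mstats.ConditionDataset.from_samples(
            {"synthetic": list(st.speeds)}, variable="mean_speed_um_min")
        save_table("speed_summary.csv", mstats.summarize_condition(ds))
        if config.report.figures:
            _report_figures(out, st, manifest)

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _report_figures(out: Path, st, manifest: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    axes[0].boxplot([st.speeds], tick_labels=["synthetic"])
    axes[0].set_ylabel("mean speed (um/min)")
    axes[1].errorbar(st.lags, st.msd_mean, yerr=st.msd_sd, fmt="o-",
                     ms=3, capsize=2)
    axes[1].set_xlabel("lag (min)")
    axes[1].set_ylabel("MSD (um$^2$)")
    fig.tight_layout()
    fig.savefig(out / "migration_report.png", dpi=120,
                metadata={"Software": None})
    plt.close(fig)
    manifest["outputs"].append("migration_report.png")
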