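"""End-to-end orchestration: simulate -> condition -> align -> measure -> infer.

A single validated config (unknown keys rejected) drives every stage; its
hash, the seed and per-stage output hashes are stamped into ``log.json`` so
a rerun with the same config is verifiably identical for the deterministic
stages.  Stage failures halt the run with the stage name; outputs written
so far are left in place.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import calcium as ca
from . import csd as csd_mod
from . import muae as muae_mod
from . import synth, units as units_mod, vep as vep_mod
from .io_core import DlamError, write_schedule, write_table
from .lfp import preprocess_lfp
from .stats import paired_contrasts, rm_anova_oneway

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "config_hash"]


class StageError(DlamError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    n_channels: int = 64
    spacing_um: float = 20.0
    fs: float = 25_000.0
    n_blocks_per_condition: int = 5
    block_s: float = 100.0
    interblock_s: float = 30.0
    reversal_rate_hz: float = 1.0
    sink_channel: int = 32
    n_units: int = 24


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t_trial_ms: float = 500.0
    vep_channel: str = "L4"            # "L4" or an explicit channel index
    neg_window_ms: tuple[float, float] = (25.0, 100.0)
    pos_window_ms: tuple[float, float] = (60.0, 250.0)
    csd_k_sd: float = 2.0
    csd_search_window_ms: tuple[float, float] = (20.0, 120.0)
    early_window_ms: tuple[float, float] = (40.0, 80.0)
    late_window_ms: tuple[float, float] = (100.0, 200.0)
    reference_condition: str = "monocular"
    alpha: float = 0.05


class CalciumConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    preset: str = "excitatory"
    n_rois: int = 120
    n_blocks_per_condition: int = 12


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    simulate: SimulateConfig = SimulateConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    calcium: CalciumConfig = CalciumConfig()


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on a simulated session; returns the result bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    results: dict = {"config_hash": config_hash(config), "seed": config.simulate.seed}

    def record(stage: str, files: list[Path]) -> None:
        log.append({"stage": stage,
                    "outputs": {f.name: _file_hash(f) for f in files if f.exists()}})

    sim, ana = config.simulate, config.analysis

    # -- simulate -----------------------------------------------------------
    try:
        params = synth.SessionParams(
            n_channels=sim.n_channels, spacing_um=sim.spacing_um, fs=sim.fs,
            n_blocks_per_condition=sim.n_blocks_per_condition, block_s=sim.block_s,
            interblock_s=sim.interblock_s, reversal_rate_hz=sim.reversal_rate_hz,
            sink_channel=sim.sink_channel)
        session, schedule, truth = synth.generate_session(params, seed=sim.seed)
        unit_list, truth = synth.generate_units(
            synth.UnitParams(n_units=sim.n_units), schedule, truth, seed=sim.seed + 1)
        write_schedule(schedule, out / "schedule.csv")
        record("simulate", [out / "schedule.csv", out / "events.csv"])
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    # -- LFP conditioning ---------------------------------------------------
    try:
        lfp = preprocess_lfp(session)
    except Exception as exc:
        raise StageError("lfp_preprocess", exc) from exc
    record("lfp_preprocess", [])

    # -- CSD and laminar alignment -----------------------------------------
    try:
        trials = np.stack([
            vep_mod.extract_trials(lfp, schedule, ana.reference_condition, ch,
                                   ana.t_trial_ms)
            for ch in range(session.n_channels)
        ])
        avg = trials.mean(axis=1)
        cmap = csd_mod.compute_csd(avg, session.spacing_um, lfp.fs)
        l4 = csd_mod.find_l4_sink(cmap, search_window_ms=ana.csd_search_window_ms,
                                  k_sd=ana.csd_k_sd)
        alignment = csd_mod.assign_layers(l4, session.n_channels, session.spacing_um)
        (out / "alignment.json").write_text(json.dumps({
            "l4_channel_index": alignment.l4_channel_index,
            "depths_um": alignment.depths_um.tolist(),
            "layers": alignment.layers,
        }, indent=1))
        record("csd_laminar", [out / "alignment.json"])
        results["l4_channel"] = l4
        results["true_sink_channel"] = truth.sink_channel_index
    except Exception as exc:
        raise StageError("csd_laminar", exc) from exc

    # -- VEP components -----------------------------------------------------
    try:
        ch = l4 if ana.vep_channel == "L4" else int(ana.vep_channel)
        vep_rows = []
        comps = {}
        for cond in schedule.conditions:
            tr = vep_mod.extract_trials(lfp, schedule, cond, ch, ana.t_trial_ms)
            wf = vep_mod.normalize_and_smooth(tr, lfp.fs, cond, ch)
            c = vep_mod.measure_components(wf, ana.neg_window_ms, ana.pos_window_ms)
            comps[cond] = c
            vep_rows.append({
                "session": session.session_id, "condition": cond, "channel": ch,
                "negativity_uV": c.negativity_v * 1e6,
                "negativity_latency_ms": c.negativity_latency_ms,
                "positivity_uV": c.positivity_v * 1e6,
                "positivity_latency_ms": c.positivity_latency_ms,
                "magnitude_uV": c.magnitude_v * 1e6,
            })
        write_table(vep_rows, out / "vep_components.csv")
        record("vep_analysis", [out / "vep_components.csv"])
        results["vep_magnitude_uv"] = {k: v.magnitude_v * 1e6 for k, v in comps.items()}
        results["vep_normalized"] = vep_mod.normalize_to_reference(
            comps, ana.reference_condition)
    except Exception as exc:
        raise StageError("vep_analysis", exc) from exc

    # -- MUAe (needs the wide-band 25 kHz trace) ---------------------------
    if session.fs == 25_000.0:
        try:
            ref = muae_mod.common_median_reference(session.samples)
            ref = muae_mod.notch60_iir(ref, session.fs)
            env = muae_mod.compute_muae(ref, session.fs)
            env = muae_mod.zscore_interblock(env, schedule)
            resp = muae_mod.condition_response(env, schedule, alignment, ana.t_trial_ms,
                                               ana.reference_condition)
            muae_rows = []
            for cond, by_layer in resp["aligned"].items():
                stacked = np.stack(list(by_layer.values()))
                early, late = muae_mod.window_means(stacked, env.fs,
                                                    ana.early_window_ms, ana.late_window_ms)
                muae_rows.append({"condition": cond, "early_z": early, "late_z": late})
            write_table(muae_rows, out / "muae_windows.csv")
            record("mua_envelope", [out / "muae_windows.csv"])
            results["muae_windows"] = {r["condition"]: (r["early_z"], r["late_z"])
                                       for r in muae_rows}
        except Exception as exc:
            raise StageError("mua_envelope", exc) from exc
    else:
        log.append({"stage": "mua_envelope", "skipped": "input not wide-band 25 kHz"})

    # -- single units -------------------------------------------------------
    try:
        unit_rows = []
        for u in unit_list:
            ttp = units_mod.trough_to_peak_ms(u.waveform_mv, u.waveform_fs)
            cls = units_mod.classify_unit(ttp)
            layer = units_mod.assign_unit_layer(u.depth_um)
            for cond in schedule.conditions:
                psth = units_mod.compute_psth(u, schedule, cond, ana.t_trial_ms)
                ws = units_mod.window_rates(psth, ana.early_window_ms, ana.late_window_ms)
                unit_rows.append({
                    "unit_id": u.unit_id, "cls": cls, "ttp_ms": ttp, "layer": layer,
                    "condition": cond, "early_rate_hz": ws.early_rate_hz,
                    "late_rate_hz": ws.late_rate_hz,
                })
        write_table(unit_rows, out / "unit_stats.csv")
        record("unit_analysis", [out / "unit_stats.csv"])
    except Exception as exc:
        raise StageError("unit_analysis", exc) from exc

    # -- repeated-measures inference on unit window rates -------------------
    try:
        conds = schedule.conditions
        ref_i = conds.index(ana.reference_condition)
        stats_rows = []
        for win in ("early_rate_hz", "late_rate_hz"):
            mat = np.array([
                [next(r[win] for r in unit_rows
                      if r["unit_id"] == u.unit_id and r["condition"] == c)
                 for c in conds] for u in unit_list])
            res = rm_anova_oneway(mat)
            contrasts = paired_contrasts(mat, [(i, ref_i) for i in range(len(conds))
                                               if i != ref_i])
            stats_rows.append({
                "window": win.split("_")[0], "F": res.f, "df1_gg": res.df1_corrected,
                "df2_gg": res.df2_corrected, "epsilon": res.epsilon, "p_gg": res.p,
                **{f"p_{conds[c.pair[0]]}_vs_{ana.reference_condition}": c.p_adjusted
                   for c in contrasts},
            })
            results[f"anova_{win.split('_')[0]}"] = res
            results[f"contrasts_{win.split('_')[0]}"] = contrasts
        write_table(stats_rows, out / "anova.csv")
        record("stats_rm", [out / "anova.csv"])
    except Exception as exc:
        raise StageError("stats_rm", exc) from exc

    # -- calcium ------------------------------------------------------------
    if config.calcium.enabled:
        try:
            traces, csched, info = synth.generate_calcium_session(
                preset=config.calcium.preset, n_rois=config.calcium.n_rois,
                n_blocks_per_condition=config.calcium.n_blocks_per_condition,
                seed=sim.seed)
            if not ca.qc_session(traces.n_rois):
                raise DlamError("calcium session failed the 100-ROI QC rule")
            f_true = ca.neuropil_correct(traces.F, traces.F_neuropil)
            dff = ca.dff_vs_gray(f_true, csched, traces.frame_rate)
            resp = ca.condition_responses(dff, csched, traces.frame_rate)
            write_table([{"condition": c, "population_dff": v}
                         for c, v in resp["population"].items()],
                        out / "dff_summary.csv")
            record("calcium_analysis", [out / "dff_summary.csv"])
            results["calcium_population_dff"] = resp["population"]
        except Exception as exc:
            raise StageError("calcium_analysis", exc) from exc

    (out / "log.json").write_text(json.dumps(
        {"config_hash": results["config_hash"], "seed": sim.seed, "stages": log}, indent=1))
    return results
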