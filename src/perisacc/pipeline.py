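"""End-to-end synthetic run: simulate, detect, fit, decode, modulate,
model, psychophysics, report.

``pipeline_run`` chains every analysis stage on generated data, emits CSV
tables and a YAML manifest when given an output directory, and returns a
summary of the headline quantities. Every stage draws from seeds spawned
deterministically from the run seed, so the same configuration reproduces
every number; a failing stage is recorded and its downstream stages are
skipped.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .decoding import (binwise_separation_test, compression_curve,
                       decode_neuron, decode_population)
from .eye_events import bin_left_edges, bin_perisaccadic_rates, detect_saccades, \
    select_snippets
from .kernels import SuppressionKernel, default_kernels
from .model import ModelConfig, compare_modes, run_model
from .modulation import assign_conditions, extract_kernels, index_sign_tests, \
    modulation_index
from .psychophysics import behavioral_compression, cross_correlate_compression, \
    discrimination_dprime, perceived_timecourse, reference_frame_analysis
from .synthetic import (BehavioralGenParams, OknParams,
                        gaussian_compression_profile, generate_behavioral_trials,
                        generate_discrimination_trials, generate_eye_trace,
                        generate_population, generate_spike_trains)
from .tuning import fit_from_binned, heading_significance, slice_rates

STAGES = ("simulate", "detect", "fit", "decode", "modulate", "model",
          "psychophys", "report")


@dataclass
class RunConfig:
    """Configuration and thresholds of a full synthetic run."""

    seed: int = 0
    headings_physio: tuple[float, ...] = (-30.0, 0.0, 30.0)
    trace_duration_s: float = 120.0
    okn: OknParams = field(default_factory=OknParams)
    n_neurons: int = 71
    n_negative: int = 38
    speed_threshold_deg_s: float = 80.0
    central_limit_deg: float = 20.0
    alpha: float = 0.05
    fit_window_ms: tuple[float, float] = (300.0, 450.0)
    model_repetitions: int = 50
    behavioral: BehavioralGenParams = field(default_factory=lambda: BehavioralGenParams(
        compression_profile=gaussian_compression_profile(peak=0.8, center_ms=-5.0)))
    discrimination_trials: int = 2000

    def manifest(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (str, int, float, bool)) or obj is None:
                return obj
            return repr(obj)

        return clean(self)


@dataclass
class PipelineResult:
    config: RunConfig
    status: dict[str, str]
    summary: dict

    @property
    def ok(self) -> bool:
        return all(s == "ok" for s in self.status.values())


def pipeline_run(config: RunConfig, outdir=None) -> PipelineResult:
    """Run the full synthetic analysis chain. See module docstring."""
    out = Path(outdir) if outdir is not None else None
    status = {stage: "skipped" for stage in STAGES}
    summary: dict = {"seed": config.seed}
    seeds = np.random.SeedSequence(config.seed).spawn(8)
    rngs = {stage: np.random.default_rng(s) for stage, s in zip(STAGES, seeds)}
    kernels = default_kernels()
    half_cong = SuppressionKernel(
        kernels["congruent"].time_ms,
        1.0 + 0.5 * (kernels["congruent"].gain - 1.0), label="half-congruent")

    state: dict = {}

    def stage(name):
        def deco(fn):
            if any(v.startswith("failed") for v in status.values()):
                return
            try:
                fn()
                status[name] = "ok"
            except Exception as exc:  # record and halt downstream stages
                status[name] = f"failed: {exc}"
            return fn
        return deco

    @stage("simulate")
    def _simulate():
        population = generate_population(
            n_negative=config.n_negative,
            n_positive=config.n_neurons - config.n_negative,
            seed=rngs["simulate"])
        traces, spike_sets, schedules = {}, {}, {}
        for h in config.headings_physio:
            trace, _ = generate_eye_trace(config.okn, config.trace_duration_s,
                                          seed=rngs["simulate"])
            # ground-truth selective modulation: suppression for the driven
            # subpopulation, release from inhibition for the other
            onsets = [s.onset_ms for s in
                      detect_saccades(trace, config.speed_threshold_deg_s)]

            def assignment(idx, neuron, _h=h):
                if _h == 0:
                    return half_cong
                side = np.sign(neuron.slope_a) * np.sign(_h)
                return kernels["congruent"] if side > 0 else kernels["incongruent"]

            spike_sets[h] = generate_spike_trains(
                population, h, onsets, kernel_assignment=assignment,
                duration_s=config.trace_duration_s, seed=rngs["simulate"])
            traces[h] = trace
            schedules[h] = [(0.0, config.trace_duration_s * 1000.0, h)]
        state.update(population=population, traces=traces,
                     spike_sets=spike_sets, schedules=schedules)
        if out is not None:
            for h in config.headings_physio:
                tag = f"heading_{h:+.0f}".replace("+", "p").replace("-", "m")
                io.write_eye_trace(traces[h], out / f"eye_trace_{tag}.csv")
                io.write_spikes(spike_sets[h], out / f"spikes_{tag}.csv")

    @stage("detect")
    def _detect():
        snippets = {}
        for h in config.headings_physio:
            trace = state["traces"][h]
            sacc = detect_saccades(trace, config.speed_threshold_deg_s)
            snippets[h] = select_snippets(sacc, trace,
                                          central_limit_deg=config.central_limit_deg,
                                          schedule=state["schedules"][h])
        state["snippets"] = snippets
        summary["n_snippets"] = {h: len(s) for h, s in snippets.items()}
        if any(len(s) == 0 for s in snippets.values()):
            raise RuntimeError("a heading has no eligible snippets")

    @stage("fit")
    def _fit():
        fits, binned_all = [], []
        duration_ms = config.trace_duration_s * 1000.0
        for i in range(config.n_neurons):
            groups = [slice_rates(state["spike_sets"][h][i], duration_ms)
                      for h in config.headings_physio]
            _, p_anova = heading_significance(groups)
            binned = _bin_by_heading(state, config, i)
            fits.append(fit_from_binned(binned, config.fit_window_ms,
                                        p_anova=p_anova))
            binned_all.append(binned)
        state.update(fits=fits, binned=binned_all)
        tuned = [i for i, f in enumerate(fits)
                 if f.significant_tuning and f.invertible]
        state["tuned"] = tuned
        n_neg = sum(1 for i in tuned if fits[i].slope_a < 0)
        summary["n_tuned"] = len(tuned)
        summary["subpopulations"] = {"left": n_neg, "right": len(tuned) - n_neg}
        if len(tuned) < 2:
            raise RuntimeError("fewer than 2 significantly tuned neurons")

    @stage("decode")
    def _decode():
        fits, binned, tuned = state["fits"], state["binned"], state["tuned"]
        decoded_per_heading = {}
        series = {}
        for h in config.headings_physio:
            per_neuron = np.vstack([decode_neuron(binned[i].rates[h], fits[i])
                                    for i in tuned])
            decoded_per_heading[h] = per_neuron
            series[h] = decode_population(per_neuron)
        bins = binned[tuned[0]].bin_left_ms
        comp = compression_curve(series, bins)
        sep = binwise_separation_test(decoded_per_heading, alpha=config.alpha)
        state.update(decoded=series, neural_compression=comp)
        summary["compression"] = {
            "min_normalized_sd": float(np.min(comp.normalized_sd)),
            "t_max_compression_ms": comp.t_max_compression_ms,
            "n_significant_bins": int(sep.significant.sum())}
        if out is not None:
            io.write_table(_series_frame(bins, series), out / "decoded_heading.csv")

    @stage("modulate")
    def _modulate():
        fits, binned, tuned = state["fits"], state["binned"], state["tuned"]
        left, right = min(config.headings_physio), max(config.headings_physio)
        cong, incong, kept = assign_conditions(
            [fits[i] for i in tuned],
            [binned[i].rates for i in tuned],
            left_heading=left, right_heading=right)
        bins = binned[tuned[0]].bin_left_ms
        idx_c = [modulation_index(row, bins) for row in cong]
        idx_i = [modulation_index(row, bins) for row in incong]
        tests = index_sign_tests(idx_c, idx_i, seed=rngs["modulate"])
        state["extracted_kernels"] = extract_kernels(bins + 10.0, cong, incong)
        summary["modulation_index"] = {
            "congruent_median": tests["congruent"].median,
            "congruent_p": tests["congruent"].p_value,
            "incongruent_median": tests["incongruent"].median,
            "incongruent_p": tests["incongruent"].p_value}

    @stage("model")
    def _model():
        kset = dict(state["extracted_kernels"])
        results = {}
        for mode in ("global", "selective"):
            cfg = ModelConfig(n_neurons=config.n_neurons,
                              n_negative=config.n_negative,
                              n_repetitions=config.model_repetitions,
                              kernel_mode=mode,
                              seed=int(rngs["model"].integers(2**31)))
            results[mode] = run_model(cfg, kernels=kset)
        comparison = compare_modes(results["global"], results["selective"])
        state["model"] = results
        summary["model"] = {
            "min_global": comparison.min_global,
            "t_min_global_ms": comparison.t_min_global_ms,
            "min_selective": comparison.min_selective,
            "t_min_selective_ms": comparison.t_min_selective_ms,
            "selective_deeper": comparison.selective_deeper}

    @stage("psychophys")
    def _psychophys():
        trials = generate_behavioral_trials(config.behavioral,
                                            seed=rngs["psychophys"])
        series, _ = perceived_timecourse(trials)
        comp = behavioral_compression(series)
        latency = cross_correlate_compression(state["neural_compression"], comp)
        disc = generate_discrimination_trials(config.discrimination_trials,
                                              seed=rngs["psychophys"])
        dres, percents = discrimination_dprime(disc)
        head_cfg = dataclasses.replace(config.behavioral, head_offset=-15.0)
        gaze_cfg = dataclasses.replace(config.behavioral, gaze_offset=-15.0)
        ref = reference_frame_analysis({
            "head_offset": generate_behavioral_trials(head_cfg,
                                                      seed=rngs["psychophys"]),
            "gaze_offset": generate_behavioral_trials(gaze_cfg,
                                                      seed=rngs["psychophys"])})
        summary["behavioral"] = {
            "t_max_compression_ms": comp.t_max_compression_ms,
            "min_normalized_sd": float(np.min(comp.normalized_sd)),
            "latency_tau_ms": latency.tau_ms,
            "d_prime": dres.d_prime,
            "percent_correct": percents,
            "reference_frame": ref.classified}
        if out is not None:
            io.write_trials(trials, out / "behavioral_trials.csv")

    @stage("report")
    def _report():
        if out is not None:
            io.write_manifest(config.manifest(), out / "manifest.yaml")
            with open(out / "summary.json", "w") as fh:
                json.dump(summary, fh, indent=2, default=float)

    return PipelineResult(config=config, status=status, summary=summary)


def _bin_by_heading(state, config, neuron_idx):
    """Bin one neuron across all headings, keeping heading labels intact.

    Each heading was recorded in its own simulated trial, so spikes and
    snippets are binned per heading and merged into one response table.
    """
    from .eye_events import BinnedResponse

    rates, nsnip, bins = {}, {}, None
    for h in config.headings_physio:
        br = bin_perisaccadic_rates(state["spike_sets"][h][neuron_idx],
                                    state["snippets"][h])
        if h in br.rates:
            rates[h] = br.rates[h]
            nsnip[h] = br.n_snippets[h]
        bins = br.bin_left_ms
    return BinnedResponse(bin_left_ms=bins, rates=rates, n_snippets=nsnip)


def _series_frame(bin_left_ms, series):
    import pandas as pd

    data = {"bin_left_ms": bin_left_ms}
    for h, v in series.items():
        data[f"decoded_{h:+.0f}deg"] = v
    return pd.DataFrame(data)
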