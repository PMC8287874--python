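"""End-to-end synthetic replication pipeline.

Chains the modules into the study's flow: stimulus synthesis (upright /
inverted / phase-scrambled depth maps rendered as RDSs), simulated
behavioral sessions with QUEST staircases and per-condition scanner SNR
ranges, synthetic block-design BOLD runs, univariate GLM betas, SVM-RFE
decoding of the three condition pairs plus the upright-vs-non-upright
concatenation, permutation baselines, and the behavioral / brain-behavior
statistics.  Every stage draws its randomness from a seed derived from
the global seed, so reruns with the same config reproduce all numbers.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import glm, mvpa, psychophys, stats, stimgen, synthfmri

__all__ = ["PipelineConfig", "run_full_pipeline"]

PAIRS = (("upright", "random"), ("inverted", "random"), ("upright", "inverted"))


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | None = None
    n_subjects: int = 4
    # stimuli
    grid_size: tuple[int, int] = (96, 68)
    spec: stimgen.StimulusSpec = field(
        default_factory=lambda: stimgen.StimulusSpec(max_disparity_arcmin=5.4))
    # observers: per-condition criterion-threshold (linear SNR) means
    observer_alpha_snr: dict[str, float] = field(default_factory=lambda: {
        "upright": 0.45, "inverted": 0.38, "random": 0.37})
    observer_alpha_sd_log10: float = 0.08
    # synthetic fMRI
    n_runs: int = 4
    n_voxels: int = 120
    n_informative: int = 12
    effect_sizes: dict[str, float] = field(default_factory=lambda: {
        "upright-random": 0.8, "inverted-random": 0.8, "upright-inverted": 0.8})
    noise_sigma: float = 1.0
    ar1_rho: float = 0.0
    # decoding
    stop_size: int = 40
    n_permutations: int = 50
    rfe_resamples: int = 20

    def stage_seed(self, stage: str, index: int = 0) -> np.random.Generator:
        # process-independent stage hash (str hash() is salted per process)
        h = zlib.crc32(stage.encode()) & 0xFFFFFFFF
        return np.random.default_rng(np.random.SeedSequence([self.seed, h, index]))


def _simulate_subject_behavior(cfg: PipelineConfig, subject: int):
    rng = cfg.stage_seed("behavior", subject)
    observers = {}
    for cond, alpha in cfg.observer_alpha_snr.items():
        a = np.log10(alpha) + rng.normal(0, cfg.observer_alpha_sd_log10)
        observers[cond] = psychophys.PsychometricObserver(threshold_alpha=a)
    table, results = psychophys.run_session(
        observers, task="snr", seed=rng, subject=f"S{subject:02d}")
    ranges = {}
    for cond in cfg.observer_alpha_snr:
        sid = table[table.condition == cond].staircase.iloc[0]
        res = results[sid]
        ranges[cond] = psychophys.derive_fmri_sampling_range(res.history, res.state)
    return table, ranges


def _subject_effect_pattern(cfg: PipelineConfig, subject: int) -> synthfmri.VoxelPatternModel:
    rng = cfg.stage_seed("pattern", subject)
    mean_effect = float(np.mean(list(cfg.effect_sizes.values())))
    return synthfmri.VoxelPatternModel.planted(
        n_voxels=cfg.n_voxels, n_informative=cfg.n_informative,
        effect_size=mean_effect, seed=rng)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report bundle (also written to disk
    when ``config.out_dir`` is set).  Deterministic given the config."""
    cfg = config
    bundle: dict = {"config": _config_dict(cfg), "stages": {}}

    # --- stimuli -----------------------------------------------------------
    rng = cfg.stage_seed("stimuli")
    upright = synthfmri.make_face_like_depth_map(rng, grid_size=cfg.grid_size)
    inverted = stimgen.invert_depth_map(upright)
    scrambled = stimgen.phase_randomize(upright, rng)
    pairs = {name: stimgen.render_rds(dm, cfg.spec, rng)
             for name, dm in (("upright", upright), ("inverted", inverted),
                              ("random", scrambled))}
    bundle["stages"]["stimuli"] = {
        "n_dots": {k: int(len(p.dots)) for k, p in pairs.items()},
        "max_abs_disparity_arcmin": {
            k: float(p.dots.disparity_arcmin.abs().max()) for k, p in pairs.items()},
    }

    # --- behavior ----------------------------------------------------------
    tables, range_rows = [], []
    for s in range(cfg.n_subjects):
        table, ranges = _simulate_subject_behavior(cfg, s)
        tables.append(table)
        for cond, r in ranges.items():
            range_rows.append({"subject": f"S{s:02d}", "condition": cond,
                               "low": r.low, "high": r.high, "fallback": r.fallback})
    behavior = pd.concat(tables, ignore_index=True)
    thresholds = (behavior.groupby(["subject", "condition"], as_index=False)
                  ["threshold"].mean())
    bundle["stages"]["behavior"] = {
        "condition_mean_threshold": thresholds.groupby("condition")["threshold"]
                                              .mean().to_dict(),
        "n_staircases": int(len(behavior)),
        "fmri_ranges": range_rows,
    }

    # --- synthetic fMRI + GLM + decoding per subject -----------------------
    glm_rows, decode_rows, perm_rows = [], [], []
    acc_by_pair: dict[str, dict[str, float]] = {f"{a}-{b}": {} for a, b in PAIRS}
    for s in range(cfg.n_subjects):
        model = _subject_effect_pattern(cfg, s)
        data = synthfmri.simulate_timeseries(
            model, n_runs=cfg.n_runs, noise_sigma=cfg.noise_sigma,
            ar1_rho=cfg.ar1_rho, seed=cfg.stage_seed("fmri", s))
        design0 = data.designs[0]
        dm = glm.build_design(design0.condition_onsets(), data.motion[0],
                              design0.n_volumes, design0.tr_s)
        est = glm.fit_glm(data.runs[0], dm)
        psc = est.percent_signal_change().mean()
        for cond, val in psc.items():
            glm_rows.append({"subject": f"S{s:02d}", "condition": cond,
                             "beta_psc": float(val)})
        for a, b in PAIRS:
            patterns = mvpa.prepare_patterns(data, (a, b))
            result, _ = mvpa.rfe_decode(
                patterns, stop_size=cfg.stop_size,
                seed=cfg.stage_seed(f"rfe_{a}_{b}", s),
                n_resamples=cfg.rfe_resamples)
            acc_by_pair[f"{a}-{b}"][f"S{s:02d}"] = result.final_accuracy
            decode_rows.append({"subject": f"S{s:02d}", "pair": f"{a}-{b}",
                                "accuracy": result.final_accuracy})
            if cfg.n_permutations > 0:
                null = mvpa.permutation_baseline(
                    patterns, n=cfg.n_permutations,
                    seed=cfg.stage_seed(f"perm_{a}_{b}", s),
                    stop_size=cfg.stop_size)
                perm_rows.append({"subject": f"S{s:02d}", "pair": f"{a}-{b}",
                                  "baseline": null.baseline,
                                  "null_mean": float(null.null_accuracies.mean())})
    bundle["stages"]["glm"] = {"beta_psc": glm_rows}
    bundle["stages"]["decoding"] = {"accuracies": decode_rows,
                                    "permutation": perm_rows}

    # --- statistics --------------------------------------------------------
    anova = stats.rm_anova_oneway(thresholds)
    posthocs = [stats.posthoc_bonferroni(thresholds, p) for p in PAIRS]
    correlations = []
    if cfg.n_subjects >= 3:
        for a, b in PAIRS:
            idx = stats.behavioral_index(thresholds, a, b)
            acc = pd.Series(acc_by_pair[f"{a}-{b}"])
            try:
                cres = stats.correlate(idx, acc, roi="synthetic",
                                       comparison=f"{a}-{b}", family_size=1)
                correlations.append(dataclasses.asdict(cres))
            except ValueError:
                pass  # degenerate accuracy vector at tiny n
        idx_nonface = stats.behavioral_index(thresholds, "upright",
                                             ["inverted", "random"])
        bundle["stages"]["nonface_index_mean"] = float(idx_nonface.mean())
    bundle["stages"]["stats"] = {
        "anova": dataclasses.asdict(anova),
        "posthoc": [dataclasses.asdict(p) for p in posthocs],
        "correlations": correlations,
    }

    if cfg.out_dir is not None:
        _write_bundle(cfg, bundle, behavior, thresholds,
                      pd.DataFrame(glm_rows), pd.DataFrame(decode_rows), pairs)
    return bundle


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["spec"] = asdict(cfg.spec)
    return d


def _write_bundle(cfg, bundle, behavior, thresholds, glm_df, decode_df, stim_pairs):
    out = Path(cfg.out_dir)
    for sub in ("stimuli", "behavior", "fmri", "decoding", "stats"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for name, pair in stim_pairs.items():
        stimgen.export_stimulus(pair, str(out / "stimuli" / name))
    behavior.to_csv(out / "behavior" / "staircase_estimates.tsv", sep="\t", index=False)
    thresholds.to_csv(out / "behavior" / "thresholds.tsv", sep="\t", index=False)
    glm_df.to_csv(out / "fmri" / "glm_betas.tsv", sep="\t", index=False)
    decode_df.to_csv(out / "decoding" / "accuracies.tsv", sep="\t", index=False)
    with open(out / "stats" / "summary.json", "w") as fh:
        json.dump(bundle["stages"]["stats"], fh, indent=2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
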