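"""End-to-end pipeline runs on synthetic datasets.

These functions tie generator -> stride/phase segmentation -> event
detection -> statistics together and compute the summary statistics of the
top-view and side-view crawling analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from . import kinematics, muscle_dynamics, phase_stats
from .synthetic import CalibrationProfile, simulate_crawl_dataset, \
    simulate_muscle_traces


def _default_config(profile: CalibrationProfile) -> AnalysisConfig:
    return AnalysisConfig(frame_rate_hz=profile.frame_rate_hz,
                          segment_length_mm=profile.segment_length_mm)


def segment_dataset(profile: CalibrationProfile, seed: int,
                    config: AnalysisConfig | None = None):
    """Generate the dataset and run stride/phase segmentation on every
    episode.  Returns (list of (track, ground truth, stride table))."""
    config = config or _default_config(profile)
    out = []
    for track, gt in simulate_crawl_dataset(profile, seed):
        table = kinematics.analyze_track(track, config)
        out.append((track, gt, table))
    return out


def stride_frame(episodes) -> pd.DataFrame:
    """Pooled per-stride metrics across episodes (detected, non-degenerate
    strides only), with episode speed attached."""
    frames = []
    for _, _, table in episodes:
        if len(table) == 0:
            continue
        df = kinematics.compute_stride_metrics(table)
        frames.append(df[~df["degenerate"]])
    return pd.concat(frames, ignore_index=True)


def run_topview(profile: CalibrationProfile, seed: int,
                config: AnalysisConfig | None = None) -> dict:
    """Top-view statistics: the duty-factor-on-speed regression and the four
    phase/speed/stride-duration correlations, all across detected strides."""
    episodes = segment_dataset(profile, seed, config)
    df = stride_frame(episodes)
    slope, intercept, r2 = phase_stats.ols_fit(df["episode_speed"],
                                               df["duty_factor"])
    r = lambda x, y: phase_stats.pearson_r(df[x], df[y], x, y).r
    return dict(
        duty_vs_speed_slope=slope,
        duty_vs_speed_r2=r2,
        wave_vs_speed_r=r("episode_speed", "wave_duration"),
        interwave_vs_speed_r=r("episode_speed", "interwave_duration"),
        interwave_vs_stride_r=r("stride_duration", "interwave_duration"),
        wave_vs_stride_r=r("stride_duration", "wave_duration"),
        n_strides=len(df),
        n_episodes=df.groupby(["animal_id", "episode_id"]).ngroups,
        speed_min=float(df["episode_speed"].min()),
        speed_max=float(df["episode_speed"].max()),
    )


def lt2_stride_pairs(profile: CalibrationProfile, seed: int,
                     config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Side-view pipeline: detect strides and LT2 contraction events, pair
    events to strides, and average the paired contraction metrics across
    segments within each stride."""
    config = config or _default_config(profile)
    rows = []
    for track, gt, table in segment_dataset(profile, seed, config):
        if len(table) == 0:
            continue
        traces = simulate_muscle_traces(profile, gt, seed)
        lt2 = [tr for tr in traces if tr.muscle == "LT2"]
        per_stride: dict[int, list] = {}
        for tr in lt2:
            events = muscle_dynamics.detect_contractions(tr, config)
            pairs, _ = muscle_dynamics.pair_events_to_strides(events, table)
            for e, s in pairs:
                per_stride.setdefault(s.index, []).append(e)
        speed = table.episode_speed
        by_index = {s.index: s for s in table}
        for idx, evs in per_stride.items():
            s = by_index[idx]
            if s.degenerate:
                continue
            rows.append(dict(
                animal_id=track.animal_id, episode_id=track.episode_id,
                stride=idx,
                contraction_duration=float(np.mean([e.duration for e in evs])),
                contraction_amplitude=float(np.mean([e.amplitude for e in evs])),
                interwave_duration=s.interwave_duration,
                wave_duration=s.wave_duration,
                stride_duration=s.stride_duration,
                episode_speed=speed))
    return pd.DataFrame(rows)


def run_sideview(profile: CalibrationProfile, seed: int,
                 config: AnalysisConfig | None = None) -> dict:
    """Side-view statistics: LT2 contraction duration against the phase
    durations (per stride) and against crawling speed (episode means)."""
    df = lt2_stride_pairs(profile, seed, config)
    r = lambda x, y: phase_stats.pearson_r(df[x], df[y], x, y).r
    ep = df.groupby(["animal_id", "episode_id"]).agg(
        mean_dur=("contraction_duration", "mean"),
        speed=("episode_speed", "first"))
    return dict(
        lt2_duration_vs_interwave_r=r("interwave_duration", "contraction_duration"),
        lt2_duration_vs_stride_r=r("stride_duration", "contraction_duration"),
        lt2_duration_vs_wave_r=r("wave_duration", "contraction_duration"),
        lt2_episode_duration_vs_speed_r=phase_stats.pearson_r(
            ep["speed"], ep["mean_dur"], "episode_speed",
            "mean_contraction_duration").r,
        n_strides=len(df),
        n_episodes=len(ep),
    )


TOPVIEW_MAPPING = {
    "duty_vs_speed_slope": "kinematics.duty_speed_slope",
    "duty_vs_speed_r2": "kinematics.duty_noise_stride",
    "wave_vs_speed_r": "kinematics.duration_noise_episode",
    "interwave_vs_speed_r": "kinematics.duty_noise_speed_exponent",
    "interwave_vs_stride_r": "kinematics.duration_duty_coupling",
    "wave_vs_stride_r": "kinematics.duration_noise_stride",
}

SIDEVIEW_MAPPING = {
    "lt2_duration_vs_interwave_r": "muscles.lt2.noise_stride",
    "lt2_duration_vs_stride_r": "kinematics.wave_noise_stride",
    "lt2_duration_vs_wave_r": "kinematics.wave_interwave_coupling",
    "lt2_episode_duration_vs_speed_r": "muscles.lt2.noise_episode",
}
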