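"""Synthetic crawling, muscle and calcium data with ground truth.

The generator emulates the statistical structure of freely crawling
third-instar larvae: per-episode speed variation, a two-phase stride cycle
whose interwave duration shrinks with speed (down to zero at the fastest
speeds) while the wave duration varies weakly, synchronous transverse-muscle
(LT2) contraction confined to the interwave phase, sequential
posterior-to-anterior longitudinal-muscle (VL4/DO1) contraction during the
wave, and wave-like versus synchronous segmental calcium activity.

Speed is emergent: stride length follows the kinematic identity
``length = drive_speed x stride_duration`` (plus noise), so an episode's
measured speed (total length / total duration) concentrates at its latent
drive.  Calibrated profiles use variance-matched sampling — stride-level
noise streams are projected to zero episode mean and orthonormalized
against the speed design and one another — so that the emergent statistics
of a dataset of the study's size are stable across seeds.  Plain i.i.d.
sampling is available with ``moment_matching: false``.
"""

from __future__ import annotations

import copy
import importlib.resources as resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .types import (
    CalciumTrace,
    HierarchicalDataset,
    InputError,
    LandmarkTrack,
    MuscleTrace,
)


class ConfigError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# profiles


@dataclass
class CalibrationProfile:
    """Full parameterization of the synthetic study conditions."""

    name: str = "custom"
    counts: dict = field(default_factory=lambda: dict(
        n_animals=18, episodes_per_animal=3, strides_per_episode=5))
    speed: dict = field(default_factory=lambda: dict(
        law="stratified_uniform", v_min=0.45, v_max=1.25, episode_delta=0.05))
    kinematics: dict = field(default_factory=lambda: dict(
        model="phase",
        interwave_intercept=0.9, interwave_speed_slope=-0.5,
        interwave_noise_episode=0.05, interwave_noise_stride=0.2,
        interwave_floor=0.02,
        wave_intercept=1.1, wave_speed_slope=-0.35,
        wave_interwave_coupling=0.0, wave_noise_stride=0.08,
        wave_noise_episode=0.03, wave_floor=0.3,
        length_noise=0.05, moment_matching=True))
    geometry: dict = field(default_factory=lambda: dict(
        frame_rate_hz=30.0, body_length_mm=4.0, lead_in_s=1.2, lead_out_s=1.0,
        head_advance_frac=0.6, tail_advance_frac=0.8, landmark_noise_mm=0.004))
    muscles: dict | None = None
    calcium: dict | None = None
    opto: dict | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c["n_animals"] < 1 or c["episodes_per_animal"] < 1:
            raise ConfigError("counts must be positive")
        if c["strides_per_episode"] < 1:
            raise ConfigError("strides_per_episode must be positive")
        if not (0 < self.speed["v_min"] < self.speed["v_max"]):
            raise ConfigError("speed range must be positive and ordered")
        for key, val in self.kinematics.items():
            if key.startswith(("interwave_noise", "wave_noise", "duty_noise",
                               "duration_noise", "length_noise")) and val < 0:
                raise ConfigError(f"noise sd {key} must be >= 0")

    @property
    def frame_rate_hz(self) -> float:
        return self.geometry["frame_rate_hz"]

    @property
    def segment_length_mm(self) -> float:
        return self.geometry["body_length_mm"] / 11.0

    def copy(self) -> "CalibrationProfile":
        return copy.deepcopy(self)

    def get_param(self, path: str) -> float:
        section, *keys = path.split(".")
        node = getattr(self, section)
        for k in keys[:-1]:
            node = node[k]
        return node[keys[-1]]

    def set_param(self, path: str, value: float) -> None:
        section, *keys = path.split(".")
        node = getattr(self, section)
        for k in keys[:-1]:
            node = node[k]
        node[keys[-1]] = float(value)

    @classmethod
    def from_dict(cls, data: dict) -> "CalibrationProfile":
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "CalibrationProfile":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in
                ("name", "counts", "speed", "kinematics", "geometry")}
        for k in ("muscles", "calcium", "opto"):
            if getattr(self, k) is not None:
                data[k] = getattr(self, k)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_profile(name: str) -> CalibrationProfile:
    """Load a packaged profile (fig1_topview, fig1_sideview, fig2_calcium,
    fig4_calcium, opto_null, opto_effect) or a YAML file path."""
    pkg_file = resources.files("larvacrawl") / "profiles" / f"{name}.yaml"
    if pkg_file.is_file():
        return CalibrationProfile.from_dict(yaml.safe_load(pkg_file.read_text()))
    p = Path(name)
    if p.exists():
        return CalibrationProfile.from_yaml(p)
    raise ConfigError(f"unknown profile {name!r}")


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Per-episode truth emitted alongside the synthetic data."""

    animal_id: str
    episode_id: str
    drive_speed: float
    t_unhook: np.ndarray          # S+1 unhooking times (s)
    t_wave_onset: np.ndarray      # S wave-onset times (s)
    stride_length: np.ndarray     # S lengths (mm)
    lt2_duration: np.ndarray | None = None      # S contraction durations (s)
    lt2_amplitude: np.ndarray | None = None
    contraction_events: list | None = None      # (muscle, seg, on, off, amp)
    intersegmental_lag_s: float | None = None

    @property
    def n_strides(self) -> int:
        return self.t_wave_onset.size

    @property
    def stride_duration(self) -> np.ndarray:
        return np.diff(self.t_unhook)

    @property
    def interwave_duration(self) -> np.ndarray:
        return self.t_wave_onset - self.t_unhook[:-1]

    @property
    def wave_duration(self) -> np.ndarray:
        return self.t_unhook[1:] - self.t_wave_onset

    @property
    def duty_factor(self) -> np.ndarray:
        return self.interwave_duration / self.stride_duration

    @property
    def episode_speed(self) -> float:
        return float(self.stride_length.sum() / self.stride_duration.sum())


# ---------------------------------------------------------------------------
# noise streams (variance-matched sampling)


def _episode_streams(rng, n_ep, v0, n_streams, matched):
    out = []
    basis = np.column_stack([np.ones(n_ep), v0 - v0.mean()])
    for _ in range(n_streams):
        u = rng.normal(size=n_ep)
        if matched and n_ep > basis.shape[1] + 1:
            coef, *_ = np.linalg.lstsq(basis, u, rcond=None)
            u = u - basis @ coef
            u = u / u.std()
            basis = np.column_stack([basis, u])
        out.append(u)
    return out


def _stride_streams(rng, n_ep, strides, n_streams, matched, extra_cols=()):
    """Stride-level unit-sd streams; when matched, each has zero episode
    mean and is orthogonal to ``extra_cols`` and to previous streams."""
    n_st = n_ep * strides
    ep = np.repeat(np.arange(n_ep), strides)
    cols = [np.asarray(c, float) for c in extra_cols]
    basis = np.column_stack(cols) if cols else np.empty((n_st, 0))
    out = []
    for _ in range(n_streams):
        z = rng.normal(size=n_st)
        if matched and strides > 1 and n_st > basis.shape[1] + strides:
            z = z - np.bincount(ep, z)[ep] / strides
            if basis.shape[1]:
                coef, *_ = np.linalg.lstsq(basis, z, rcond=None)
                z = z - basis @ coef
                z = z - np.bincount(ep, z)[ep] / strides
            z = z / z.std()
            basis = np.column_stack([basis, z]) if basis.size else z[:, None]
        out.append(z)
    return out


def _episode_speeds(rng, profile):
    sp = profile.speed
    n_animals = profile.counts["n_animals"]
    eps_per = profile.counts["episodes_per_animal"]
    law = sp.get("law", "stratified_uniform")
    if law == "stratified_uniform":
        q = (np.arange(n_animals) + 0.5) / n_animals
        va = sp["v_min"] + (sp["v_max"] - sp["v_min"]) * q
        rng.shuffle(va)
        base = (np.linspace(-1.0, 1.0, eps_per) if eps_per > 1
                else np.zeros(1)) * sp.get("episode_delta", 0.0)
        return np.concatenate([a + rng.permutation(base) for a in va])
    if law == "uniform":
        return rng.uniform(sp["v_min"], sp["v_max"], n_animals * eps_per)
    raise ConfigError(f"unknown speed law {law!r}")


# ---------------------------------------------------------------------------
# stride plans


def _plan_dataset(profile: CalibrationProfile, seed: int) -> dict:
    """Generate the full dataset's per-stride kinematic (and LT2) truth."""
    rng = np.random.default_rng(seed)
    counts = profile.counts
    n_ep = counts["n_animals"] * counts["episodes_per_animal"]
    S = counts["strides_per_episode"]
    kin = profile.kinematics
    matched = bool(kin.get("moment_matching", True))
    v0 = _episode_speeds(rng, profile)
    v0s = np.repeat(v0, S)
    ep = np.repeat(np.arange(n_ep), S)

    if kin["model"] == "duty":
        uD, uT = [np.repeat(u, S) for u in
                  _episode_streams(rng, n_ep, v0, 2, matched)]
        zD, zT, zL = _stride_streams(rng, n_ep, S, 3, matched,
                                     extra_cols=[v0s, uD, uT])
        duty_bar = kin["duty_intercept"] + kin["duty_speed_slope"] * v0s
        v_ref = 0.5 * (profile.speed["v_min"] + profile.speed["v_max"])
        ref = kin["duty_intercept"] + kin["duty_speed_slope"] * v_ref
        scale = np.clip(duty_bar / ref, 0.1, 3.0) ** kin.get(
            "duty_noise_speed_exponent", 0.0)
        zDh = scale * zD
        uDh = scale * uD
        if matched and zDh.std() > 0:
            zDh = zDh / zDh.std()
            uDh = uDh / uDh.std()
        eD = kin["duty_noise_episode"] * uDh + kin["duty_noise_stride"] * zDh
        duty = np.clip(duty_bar + eD, 0.0, 0.9)
        eT = (kin["duration_duty_coupling"] * eD
              + kin["duration_noise_stride"] * zT
              + kin["duration_noise_episode"] * uT)
        T = np.maximum(kin["duration_floor"],
                       kin["duration_intercept"]
                       + kin["duration_speed_slope"] * v0s + eT)
        Ti = duty * T
        Tw = (1.0 - duty) * T
        C = amp = None
    elif kin["model"] == "phase":
        u1, u2, u3 = [np.repeat(u, S) for u in
                      _episode_streams(rng, n_ep, v0, 3, matched)]
        z1, z2, z3, zc = _stride_streams(rng, n_ep, S, 4, matched,
                                         extra_cols=[v0s, u1, u2, u3])
        ei = kin["interwave_noise_episode"] * u1 + kin["interwave_noise_stride"] * z1
        Ti = np.maximum(kin.get("interwave_floor", 0.0),
                        kin["interwave_intercept"]
                        + kin["interwave_speed_slope"] * v0s + ei)
        wn = kin["wave_noise_stride"] * z2 + kin["wave_noise_episode"] * u2
        Tw = np.maximum(kin.get("wave_floor", 0.3),
                        kin["wave_intercept"] + kin["wave_speed_slope"] * v0s
                        + kin["wave_interwave_coupling"] * ei + wn)
        T = Ti + Tw
        C = amp = None
        if profile.muscles is not None:
            lt2 = profile.muscles["lt2"]
            wn_sd = float(np.hypot(kin["wave_noise_stride"],
                                   kin["wave_noise_episode"]))
            wn_unit = wn / wn_sd if wn_sd > 0 else wn
            C = np.maximum(lt2.get("duration_floor", 0.04),
                           lt2["duration_coupling"] * Ti
                           + lt2.get("wave_noise_coupling", 0.0) * wn_unit
                           + lt2["noise_episode"] * u3
                           + lt2["noise_stride"] * zc)
            amp = np.clip(lt2["amp_intercept"] + lt2["amp_slope"] * Ti
                          + lt2["amp_noise"] * rng.normal(size=Ti.size),
                          *lt2.get("amp_range", (0.08, 0.6)))
    else:
        raise ConfigError(f"unknown kinematics model {kin['model']!r}")

    zL = zL if kin["model"] == "duty" else z3
    L = np.maximum(0.1, v0s * T * (1.0 + kin["length_noise"] * zL))
    return dict(ep=ep, v0=v0, Ti=Ti, Tw=Tw, T=T, L=L, C=C, amp=amp,
                n_ep=n_ep, strides=S)


def _plan_to_ground_truths(profile: CalibrationProfile, plan: dict) -> list[GroundTruth]:
    geo = profile.geometry
    eps_per = profile.counts["episodes_per_animal"]
    out = []
    for e in range(plan["n_ep"]):
        m = plan["ep"] == e
        Ti, Tw, L = plan["Ti"][m], plan["Tw"][m], plan["L"][m]
        T = Ti + Tw
        t0 = geo["lead_in_s"]
        unhooks = t0 + np.concatenate([[0.0], np.cumsum(T)])
        gt = GroundTruth(
            animal_id=f"animal{e // eps_per:02d}",
            episode_id=f"episode{e % eps_per}",
            drive_speed=float(plan["v0"][e]),
            t_unhook=unhooks,
            t_wave_onset=unhooks[:-1] + Ti,
            stride_length=L,
        )
        if plan["C"] is not None:
            gt.lt2_duration = plan["C"][m]
            gt.lt2_amplitude = plan["amp"][m]
        out.append(gt)
    return out


# ---------------------------------------------------------------------------
# landmark synthesis


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _inv_smoothstep(q: float) -> float:
    """Solve 3u^2 - 2u^3 = q for u in [0, 1] by bisection."""
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if 3 * mid * mid - 2 * mid**3 < q:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _landmark_track(profile: CalibrationProfile, gt: GroundTruth,
                    rng: np.random.Generator) -> LandmarkTrack:
    geo = profile.geometry
    fps = geo["frame_rate_hz"]
    half_seg = 0.5 * profile.segment_length_mm
    T = gt.stride_duration
    duration = gt.t_unhook[-1] + geo["lead_out_s"]
    n = int(round(duration * fps)) + 1
    t = np.arange(n) / fps

    tail = np.zeros(n)
    head = np.zeros(n)
    landing = 0.0
    head_base = 0.0
    prev_end = -np.inf
    for s in range(gt.n_strides):
        U0, W, U1 = gt.t_unhook[s], gt.t_wave_onset[s], gt.t_unhook[s + 1]
        L = gt.stride_length[s]
        # head: advances L during the first part of the stride
        h = max(0.15, min(geo["head_advance_frac"] * T[s], T[s] - 0.25))
        head += L * _smoothstep((t - U0) / h)
        # tail: advance crosses half a segment length exactly at W
        d8 = geo["tail_advance_frac"] * gt.wave_duration[s]
        q = min(0.95, half_seg / L) if L > 0 else 0.5
        for _ in range(8):
            tau = W - _inv_smoothstep(q) * d8
            if tau >= prev_end + 0.15:
                break
            d8 *= 0.7
        prev_end = tau + d8
        tail += L * _smoothstep((t - tau) / d8)
        landing += L
    # trailing head advance at the final unhook so the last stride has a
    # closing boundary detectable as a motion onset
    U_last = gt.t_unhook[-1]
    h_last = max(0.15, min(0.5 * geo["lead_out_s"], 0.6))
    head += gt.stride_length[-1] * _smoothstep((t - U_last) / h_last)
    body = geo["body_length_mm"]
    noise = geo.get("landmark_noise_mm", 0.0)
    pos = {
        "head": np.column_stack([
            head + body + noise * rng.normal(size=n),
            0.05 * np.sin(2 * np.pi * t / 3.0) + noise * rng.normal(size=n)]),
        "A8_denticle": np.column_stack([
            tail + noise * rng.normal(size=n),
            noise * rng.normal(size=n)]),
    }
    return LandmarkTrack(gt.animal_id, gt.episode_id, fps, pos)


# ---------------------------------------------------------------------------
# public generators


def simulate_crawl_dataset(profile: CalibrationProfile, seed: int
                           ) -> list[tuple[LandmarkTrack, GroundTruth]]:
    """Generate every episode of the study with dataset-level variance
    matching (when the profile enables it)."""
    plan = _plan_dataset(profile, seed)
    gts = _plan_to_ground_truths(profile, plan)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    return [( _landmark_track(profile, gt, rng), gt) for gt in gts]


def simulate_crawl_episode(profile: CalibrationProfile, seed: int
                           ) -> tuple[LandmarkTrack, GroundTruth]:
    """Generate a single episode (independent draws, no cross-episode
    variance matching)."""
    single = profile.copy()
    single.counts = dict(n_animals=1, episodes_per_animal=1,
                         strides_per_episode=profile.counts["strides_per_episode"])
    single.kinematics = dict(single.kinematics, moment_matching=False)
    track, gt = simulate_crawl_dataset(single, seed)[0]
    return track, gt


def simulate_muscle_traces(profile: CalibrationProfile, gt: GroundTruth,
                           seed: int) -> list[MuscleTrace]:
    """Muscle-length traces consistent with one episode's ground truth.

    LT2 (segments A2..A7) shortens synchronously within each interwave with
    the planned duration/amplitude; VL4/DO1 shorten sequentially
    posterior-to-anterior during the wave with the profile's intersegmental
    lag; VL4/DO1 in A6-A7 also contract during the interwave.
    """
    if profile.muscles is None:
        raise ConfigError("profile has no muscles section")
    mus = profile.muscles
    geo = profile.geometry
    fps = geo["frame_rate_hz"]
    duration = gt.t_unhook[-1] + geo["lead_out_s"]
    n = int(round(duration * fps)) + 1
    t = np.arange(n) / fps
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    traces = []
    events = []

    def pulse(center, fwhm):
        # raised-cosine dip with full base 2*fwhm: crosses half depth at
        # center -/+ fwhm/2
        u = (t - center) / (2 * fwhm)
        y = np.zeros(n)
        m = np.abs(u) <= 0.5
        y[m] = 0.5 * (1.0 + np.cos(2 * np.pi * u[m]))
        return y

    lt2 = mus.get("lt2")
    if lt2 is not None and gt.lt2_duration is not None:
        rest = lt2["rest_length_mm"]
        for seg in lt2.get("segments", ["A2", "A3", "A4", "A5", "A6", "A7"]):
            depth_jitter = 1.0 + lt2.get("segment_jitter", 0.02) * rng.normal(
                size=gt.n_strides)
            y = np.zeros(n)
            for s in range(gt.n_strides):
                C = gt.lt2_duration[s]
                amp = float(np.clip(gt.lt2_amplitude[s] * depth_jitter[s],
                                    0.02, 0.8))
                center = gt.t_unhook[s] + 0.5 * gt.interwave_duration[s]
                y += amp * pulse(center, C)
                events.append(("LT2", seg, center - C / 2, center + C / 2, amp))
            length = rest * (1.0 - np.clip(y, 0.0, 0.95))
            length += mus.get("trace_noise_mm", 0.0) * rng.normal(size=n)
            traces.append(MuscleTrace("LT2", seg, None,
                                      np.maximum(length, 0.05 * rest), fps,
                                      animal_id=gt.animal_id,
                                      episode_id=gt.episode_id))
    lon = mus.get("longitudinal")
    if lon is not None:
        lag = lon["intersegmental_lag_s"]
        rest = lon["rest_length_mm"]
        segs = lon.get("segments", ["A2", "A3", "A4", "A5", "A6", "A7"])
        gt.intersegmental_lag_s = lag
        for muscle in lon.get("muscles", ["VL4", "DO1"]):
            for seg in segs:
                j = int(seg[1])
                y = np.zeros(n)
                for s in range(gt.n_strides):
                    dur = lon["duration_frac_of_wave"] * gt.wave_duration[s]
                    onset = gt.t_wave_onset[s] + lag * (7 - j)
                    center = onset + dur / 2
                    y += lon["amplitude"] * pulse(center, dur)
                    events.append((muscle, seg, onset, onset + dur,
                                   lon["amplitude"]))
                    if seg in lon.get("posterior_interwave_segments", ()):
                        C = 0.8 * gt.interwave_duration[s]
                        if C > 0.05:
                            ic = gt.t_unhook[s] + 0.5 * gt.interwave_duration[s]
                            y += lon["amplitude"] * pulse(ic, C)
                            events.append((muscle, seg, ic - C / 2, ic + C / 2,
                                           lon["amplitude"]))
                length = rest * (1.0 - np.clip(y, 0.0, 0.95))
                length += mus.get("trace_noise_mm", 0.0) * rng.normal(size=n)
                traces.append(MuscleTrace(muscle, seg, None,
                                          np.maximum(length, 0.05 * rest), fps,
                                          animal_id=gt.animal_id,
                                          episode_id=gt.episode_id))
    gt.contraction_events = events
    return traces


def simulate_calcium(profile: CalibrationProfile, seed: int
                     ) -> tuple[list[CalciumTrace], dict]:
    """Segmental calcium traces of a fictive preparation.

    nSyb traces show wave-like sequential peaks (posterior to anterior, the
    configured lag per segment) plus synchronous posterior (A6-A7) activity
    between waves; A31c and A26f show zero-lag synchronous bursts between
    fictive waves, the A26f burst falling between two consecutive A31c
    bursts.  Returns (traces, ground-truth peak times).
    """
    if profile.calcium is None:
        raise ConfigError("profile has no calcium section")
    cal = profile.calcium
    fps = cal.get("frame_rate_hz", 10.0)
    period = cal["cycle_period_s"]
    n_cycles = cal.get("n_cycles", 6)
    lead = cal.get("lead_s", 3.0)
    duration = lead + n_cycles * period + lead
    n = int(round(duration * fps)) + 1
    t = np.arange(n) / fps
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    tau_r = cal.get("rise_s", 0.2)
    tau_d = cal.get("decay_s", 0.8)
    t_peak = tau_r * np.log(1.0 + tau_d / tau_r)
    noise = cal.get("noise_sd", 0.02)

    def burst(peak_time, amp):
        dt = t - (peak_time - t_peak)
        y = np.zeros(n)
        m = dt > 0
        y[m] = (1 - np.exp(-dt[m] / tau_r)) * np.exp(-dt[m] / tau_d)
        return amp * y / ((1 - np.exp(-t_peak / tau_r)) * np.exp(-t_peak / tau_d))

    cycle_starts = lead + period * np.arange(n_cycles)
    traces, truth = [], {}
    for roi in cal["rois"]:
        cell = roi["cell_type"]
        lag = roi.get("intersegmental_lag_s", 0.0)
        offset = roi.get("cycle_offset_frac", 0.0)
        wave_delay = roi.get("wave_delay_s", 0.0)
        for seg in roi["segments"]:
            j = int(seg[1])
            amp = roi.get("amplitude", 1.0) * (
                1.0 + roi.get("segment_amp_jitter", 0.0) * rng.normal())
            y = np.zeros(n)
            peaks = []
            for c0 in cycle_starts:
                pk = c0 + offset * period + wave_delay + lag * (8 - j)
                y += burst(pk, amp)
                peaks.append(pk)
                if (roi.get("posterior_interwave", False) and seg in ("A6", "A7")):
                    pk2 = c0 + 0.02
                    y += burst(pk2, 0.7 * amp)
                    peaks.append(pk2)
            y += noise * rng.normal(size=n)
            traces.append(CalciumTrace(cell, seg, y, fps))
            truth[f"{cell}_{seg}"] = np.array(sorted(peaks))
    return traces, truth


def simulate_optogenetic_trials(profile: CalibrationProfile, seed: int
                                ) -> tuple[HierarchicalDataset,
                                           HierarchicalDataset, float]:
    """Two nested animals-x-trials datasets (control, effect group) with the
    configured between-animal sd, within-animal sd and condition effect.
    Returns (control, treated, true effect size)."""
    if profile.opto is None:
        raise ConfigError("profile has no opto section")
    op = profile.opto
    if op["n_animals"] < 2 or op["trials_per_animal"] < 1:
        raise ConfigError("need >= 2 animals and >= 1 trial per animal")
    rng = np.random.default_rng(seed)
    delta = op.get("effect", 0.0)

    def group(label, shift):
        animals = []
        for _ in range(op["n_animals"]):
            a_eff = rng.normal(0.0, op["animal_sd"])
            animals.append(op["baseline"] + shift + a_eff
                           + rng.normal(0.0, op["trial_sd"],
                                        op["trials_per_animal"]))
        return HierarchicalDataset(label, animals)

    return group("control", 0.0), group("treated", delta), float(delta)


# ---------------------------------------------------------------------------
# calibration


def calibrate_profile(targets: dict[str, float], base: CalibrationProfile,
                      statistic_fn, mapping: dict[str, str],
                      seeds=(1, 2, 3), tol: float = 0.02,
                      max_sweeps: int = 6, step_frac: float = 0.15
                      ) -> CalibrationProfile:
    """Tune one profile parameter per target statistic.

    ``statistic_fn(profile, seed) -> dict`` evaluates the pipeline's
    statistics; ``mapping`` sends each target statistic name to the profile
    parameter (``"section.key"``) that controls it.  Parameters are updated
    by damped secant steps, sweeping over the targets until all statistics
    fall within ``tol`` (mean over ``seeds``) or raising CalibrationError.
    """
    missing = set(targets) - set(mapping)
    if missing:
        raise CalibrationError(f"no parameter mapped for {sorted(missing)}")
    profile = base.copy()

    def measure():
        acc = {}
        for s in seeds:
            stats = statistic_fn(profile, s)
            for k, v in stats.items():
                acc.setdefault(k, []).append(v)
        return {k: float(np.mean(v)) for k, v in acc.items()}

    for _ in range(max_sweeps):
        m = measure()
        errs = {k: m[k] - targets[k] for k in targets}
        if max(abs(e) for e in errs.values()) < tol:
            return profile
        for stat, target in targets.items():
            err0 = measure()[stat] - target
            if abs(err0) < tol:
                continue
            par = mapping[stat]
            x0 = profile.get_param(par)
            step = step_frac * (abs(x0) if x0 != 0 else 0.05)
            profile.set_param(par, x0 + step)
            err1 = measure()[stat] - target
            slope = (err1 - err0) / step
            if abs(slope) < 1e-9:
                profile.set_param(par, x0)
                continue
            delta = float(np.clip(-err0 / slope, -4 * step, 4 * step))
            profile.set_param(par, x0 + delta)
    m = measure()
    errs = {k: abs(m[k] - targets[k]) for k in targets}
    worst = max(errs, key=errs.get)
    if errs[worst] >= tol:
        raise CalibrationError(
            f"calibration did not converge: {worst} off by {errs[worst]:.3f}")
    return profile
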