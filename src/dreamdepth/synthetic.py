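"""Synthetic serial-awakening cohorts with known ground truth.

The generator emulates the data structure the downstream statistics assume:
~44 participants (nested in two experiments) x 4 nights of repeated N2
awakenings, a five-way dream-report classification (CE, rCEWR, sCEWR, CESP,
UNC), 1-5 Likert ratings of perceived sleep depth and sleepiness driven by
participant random intercepts plus experiment/night/time-of-night fixed
effects, phenomenology ratings organized by two latent factors (perceptual
immersion and reflective thought), and per-electrode log band-power tables
with participant offsets, spatially correlated noise and an optional
spatially clustered effect region coupling cortical activation to the
ratings.

Every draw is deterministic given the master seed: each stage derives its
own child stream by stable-hashing the stage name, so adding a stage never
perturbs the others.

Ratings are generated on a latent Gaussian scale and then rounded/clipped
to the 1-5 Likert grid (set ``likert=False`` for the continuous versions).
Latent variables are kept in ``CohortDataset.truth`` so tests can compute
the implied (attenuated) regression slope when the fitted regressor is a
noisy proxy of the generating one.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .spectral import DEFAULT_BANDS, BandDefinition, EEGSegment

__all__ = [
    "SimConfig",
    "SensorArray",
    "CohortDataset",
    "spherical_cap_grid",
    "generate_cohort",
    "generate_eeg_segment",
    "inject_cluster_effect",
    "DEFAULT_REPORT_PROBABILITIES",
    "DEFAULT_FIXED_EFFECTS",
]

REPORT5_LEVELS = ("CE", "rCEWR", "sCEWR", "CESP", "UNC")
REPORT3_OF = {"CE": "CE", "rCEWR": "CEWR", "sCEWR": "CEWR",
              "CESP": "NCE", "UNC": "NCE"}
PHENO_FEATURES = ("duration_seconds", "vividness", "perceptual_vs_thought",
                  "bizarreness", "emotional_intensity", "dream_awareness")

# report mix of the emulated study: 432 CE / 364 CEWR / 228 NCE of 1,024,
# with 70.39% of CEWR simple and 50.15% of NCE fully unconscious
DEFAULT_REPORT_PROBABILITIES: dict[str, float] = {
    "CE": 432 / 1024,
    "rCEWR": (364 / 1024) * (1 - 0.7039),
    "sCEWR": (364 / 1024) * 0.7039,
    "CESP": (228 / 1024) * (1 - 0.5015),
    "UNC": (228 / 1024) * 0.5015,
}

# generating coefficients; rating-scale units (Likert points) throughout.
# time enters in decimal hours relative to midnight.
DEFAULT_FIXED_EFFECTS: dict[str, float] = {
    "depth_intercept": 3.1,
    "sleepiness_intercept": 2.8,
    "depth_time": 0.127,
    "sleepiness_time": 0.33,     # with the quadratic term: peak at 3.3 h
    "sleepiness_time2": -0.05,
    "depth_experiment2": 0.10,
    "sleepiness_experiment2": 0.0,
    "depth_report_CE": 0.552,
    "depth_report_rCEWR": 0.68,
    "depth_report_sCEWR": 0.42,
    "depth_report_CESP": 0.0,
    "depth_report_UNC": 0.593,
    "sleepiness_report_CE": 0.0,
    "sleepiness_report_rCEWR": 0.0,
    "sleepiness_report_sCEWR": 0.0,
    "sleepiness_report_CESP": 0.0,
    "sleepiness_report_UNC": 0.31,
    "depth_pc1": 0.277,
    "depth_pc2": -0.195,
    "sleepiness_pc1": 0.079,
    "sleepiness_pc2": 0.0,
    "pc1_time": 0.103,
    "depth_brain": 0.0,
    "sleepiness_brain": 0.0,
}

# loadings of the six phenomenology features on the two latent factors
_PHENO_LOADINGS = np.array(
    [
        # immersion  reflective
        [0.8, 0.0],   # duration (log scale)
        [0.7, -0.3],  # vividness
        [0.6, -0.5],  # perceptual vs thought-like
        [0.7, 0.0],   # bizarreness
        [0.7, 0.0],   # emotional intensity
        [0.1, 0.8],   # awareness of dreaming
    ]
)
_PHENO_NOISE_SD = 0.45


@dataclass(frozen=True)
class SimConfig:
    """Generating conditions for a synthetic cohort."""

    n_participants: int = 44
    n_nights: int = 4
    awakenings_per_night: tuple[int, int] = (4, 8)
    report_probabilities: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REPORT_PROBABILITIES)
    )
    participant_sd: float = 0.5
    residual_sd: float = 0.8
    fixed_effects: Mapping[str, float] = field(default_factory=dict)
    effect_topography: np.ndarray | None = None
    time_window: tuple[float, float] = (-1.0, 7.5)
    n_channels: int = 256
    likert: bool = True
    feature_baselines: Mapping[str, float] = field(
        default_factory=lambda: {"delta": 5.5, "gamma": 0.5}
    )
    feature_participant_sd: float = 0.3
    feature_spatial_sd: float = 0.45
    feature_spatial_scale: float = 0.10  # same length units as sensor positions
    feature_white_sd: float = 0.15
    seed: int = 0

    def effects(self) -> dict[str, float]:
        eff = dict(DEFAULT_FIXED_EFFECTS)
        eff.update(self.fixed_effects)
        return eff

    def validate(self) -> None:
        probs = self.report_probabilities
        if set(probs) != set(REPORT5_LEVELS):
            raise ValueError(f"report_probabilities must cover {REPORT5_LEVELS}")
        vals = np.array([probs[k] for k in REPORT5_LEVELS], float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("report probabilities must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"report probabilities sum to {vals.sum()}, not 1")
        for name in ("participant_sd", "residual_sd", "feature_participant_sd",
                     "feature_spatial_sd", "feature_white_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_participants", "n_nights", "n_channels"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.awakenings_per_night
        if not (0 <= lo <= hi):
            raise ValueError("awakenings_per_night must be a nondecreasing pair")
        if self.time_window[0] >= self.time_window[1]:
            raise ValueError("time_window must be an increasing pair")
        if self.effect_topography is not None and (
            len(np.atleast_1d(self.effect_topography)) != self.n_channels
        ):
            raise ValueError("effect_topography length must equal n_channels")


@dataclass(frozen=True)
class SensorArray:
    """Electrode labels and 3-D positions (common origin, arbitrary units)."""

    channel_labels: tuple[str, ...]
    positions: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, float)
        object.__setattr__(self, "positions", pos)
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if pos.shape != (len(self.channel_labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return len(self.channel_labels)

    def index_of(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None


@dataclass
class CohortDataset:
    """Sensor array + awakening records + feature tables (+ raw segments)."""

    sensors: SensorArray
    records: pd.DataFrame
    features: dict[str, pd.DataFrame]
    segments: dict[str, EEGSegment] | None = None
    truth: "CohortTruth | None" = None

    def __post_init__(self):
        ids = self.records["record_id"]
        if ids.duplicated().any():
            raise ValueError("record ids must be unique")
        idset = set(ids)
        for name, tab in self.features.items():
            if set(tab.index) != idset:
                raise ValueError(f"feature table {name!r} rows do not match records")


@dataclass
class CohortTruth:
    """Generating configuration plus per-record latent variables."""

    config: SimConfig
    latents: pd.DataFrame  # record_id, b (participant intercept), a, u1, u2,
    #                        depth_raw, sleepiness_raw


def _stream(seed: int, stage: str) -> np.random.Generator:
    """Child RNG derived from the master seed by stable-hashing the stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )


def spherical_cap_grid(n: int = 256, radius: float = 0.1,
                       cap_angle: float = 1.9) -> SensorArray:
    """Deterministic Fibonacci grid on a spherical cap (a stand-in scalp).

    ``radius`` is the head radius (default 0.1, i.e. 10 cm in meters);
    ``cap_angle`` the polar angle the cap spans (radians from the vertex).
    """
    if n < 1:
        raise ValueError("need at least one electrode")
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n)
    z_lo = np.cos(cap_angle)
    z = 1.0 - (1.0 - z_lo) * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z**2, 0, None))
    theta = golden * k
    pos = radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    labels = tuple(f"E{i + 1:03d}" for i in range(n))
    return SensorArray(labels, pos)


def inject_cluster_effect(sensors: SensorArray, center_label: str,
                          radius: float, amplitude: float,
                          taper: str = "flat") -> np.ndarray:
    """Per-electrode coefficient vector: ``amplitude`` within ``radius`` of
    the center electrode (optionally Gaussian-tapered), zero outside."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    center = sensors.positions[sensors.index_of(center_label)]
    d = np.linalg.norm(sensors.positions - center, axis=1)
    inside = d <= radius
    if taper == "flat":
        return np.where(inside, amplitude, 0.0)
    if taper == "gaussian":
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.exp(-((d / max(radius, 1e-300)) ** 2))
        out = np.where(inside, amplitude * g, 0.0)
        out[d == 0] = amplitude
        return out
    raise ValueError(f"unknown taper {taper!r}")


def _spatial_chol(sensors: SensorArray, scale: float) -> np.ndarray:
    d = np.linalg.norm(
        sensors.positions[:, None, :] - sensors.positions[None, :, :], axis=2
    )
    K = np.exp(-0.5 * (d / max(scale, 1e-12)) ** 2)
    K[np.diag_indices_from(K)] += 1e-8
    return np.linalg.cholesky(K)


def _likertize(x: np.ndarray, likert: bool) -> np.ndarray:
    return np.clip(np.round(x), 1, 5) if likert else x


def generate_cohort(config: SimConfig) -> CohortDataset:
    """Draw a full synthetic cohort; byte-identical given config + seed."""
    config.validate()
    eff = config.effects()
    sensors = spherical_cap_grid(config.n_channels)
    cols = ["record_id", "participant_id", "experiment", "night", "time",
            "report3", "report5", "sleep_depth", "sleepiness",
            *PHENO_FEATURES]

    if config.n_participants == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
        feats = {
            b: pd.DataFrame(
                np.empty((0, config.n_channels)),
                index=pd.Index([], name="record_id"),
                columns=list(sensors.channel_labels),
            )
            for b in ("delta", "gamma", "ratio")
        }
        return CohortDataset(sensors, empty, feats, None,
                             CohortTruth(config, pd.DataFrame()))

    rng_design = _stream(config.seed, "design")
    rng_reports = _stream(config.seed, "reports")
    rng_latents = _stream(config.seed, "latents")
    rng_ratings = _stream(config.seed, "ratings")
    rng_features = _stream(config.seed, "features")
    rng_pheno = _stream(config.seed, "phenomenology")

    P = config.n_participants
    pids = [f"P{i + 1:02d}" for i in range(P)]
    experiment_of = {pid: (1 if i < (P + 1) // 2 else 2) for i, pid in enumerate(pids)}
    b = rng_design.normal(0.0, config.participant_sd, P)
    b_of = dict(zip(pids, b))

    lo, hi = config.awakenings_per_night
    rows = []
    for pid in pids:
        for night in range(1, config.n_nights + 1):
            k = int(rng_design.integers(lo, hi + 1)) if hi > 0 else 0
            times = np.sort(rng_design.uniform(*config.time_window, k))
            for j, t in enumerate(times):
                rows.append((f"{pid}N{night}A{j + 1:02d}", pid,
                             experiment_of[pid], night, float(t)))
    rec = pd.DataFrame(rows, columns=["record_id", "participant_id",
                                      "experiment", "night", "time"])
    n = len(rec)

    probs = np.array([config.report_probabilities[k] for k in REPORT5_LEVELS])
    r5 = rng_reports.choice(REPORT5_LEVELS, size=n, p=probs)
    rec["report3"] = [REPORT3_OF[r] for r in r5]
    rec["report5"] = r5

    # latent variables: cortical activation a, phenomenology factors u1/u2
    a = rng_latents.normal(0.0, 1.0, n)
    u1 = eff["pc1_time"] * rec["time"].to_numpy() + rng_latents.normal(0, 1, n)
    u2 = rng_latents.normal(0.0, 1.0, n)
    is_ce = (r5 == "CE").astype(float)

    t_h = rec["time"].to_numpy()
    bvec = rec["participant_id"].map(b_of).to_numpy()
    e2 = (rec["experiment"] == 2).to_numpy(float)

    def night_effect(prefix):
        out = np.zeros(n)
        for nt in range(2, config.n_nights + 1):
            key = f"{prefix}_night{nt}"
            if key in eff:
                out += eff[key] * (rec["night"] == nt).to_numpy(float)
        return out

    rep_d = np.array([eff[f"depth_report_{r}"] for r in r5])
    rep_s = np.array([eff[f"sleepiness_report_{r}"] for r in r5])

    depth_raw = (
        eff["depth_intercept"] + bvec + eff["depth_experiment2"] * e2
        + night_effect("depth") + eff["depth_time"] * t_h + rep_d
        + is_ce * (eff["depth_pc1"] * u1 + eff["depth_pc2"] * u2)
        + eff["depth_brain"] * a
        + rng_ratings.normal(0, config.residual_sd, n)
    )
    sleep_raw = (
        eff["sleepiness_intercept"] + bvec + eff["sleepiness_experiment2"] * e2
        + night_effect("sleepiness") + eff["sleepiness_time"] * t_h
        + eff["sleepiness_time2"] * t_h**2 + rep_s
        + is_ce * (eff["sleepiness_pc1"] * u1 + eff["sleepiness_pc2"] * u2)
        + eff["sleepiness_brain"] * a
        + rng_ratings.normal(0, config.residual_sd, n)
    )
    rec["sleep_depth"] = _likertize(depth_raw, config.likert)
    rec["sleepiness"] = _likertize(sleep_raw, config.likert)

    # phenomenology ratings for CE records only
    pheno = np.full((n, 6), np.nan)
    ce_idx = np.flatnonzero(is_ce)
    if len(ce_idx):
        z = np.column_stack([u1[ce_idx], u2[ce_idx]])
        noise = rng_pheno.normal(0, _PHENO_NOISE_SD, (len(ce_idx), 6))
        f = z @ _PHENO_LOADINGS.T + noise
        # duration: lognormal seconds around 60 s; others: Likert around 3
        pheno[ce_idx, 0] = np.exp(np.log(60.0) + f[:, 0])
        for j in range(1, 6):
            pheno[ce_idx, j] = _likertize(3.0 + 0.8 * f[:, j], config.likert)
    for j, name in enumerate(PHENO_FEATURES):
        rec[name] = pheno[:, j]

    # band-power tables: baseline + participant offset + activation coupling
    # (gamma only) + spatially smooth record noise + white noise
    tau = (np.zeros(config.n_channels) if config.effect_topography is None
           else np.asarray(config.effect_topography, float))
    L = _spatial_chol(sensors, config.feature_spatial_scale)
    pcodes = rec["participant_id"].map({p: i for i, p in enumerate(pids)}).to_numpy()
    feats = {}
    for band in ("delta", "gamma"):
        base = config.feature_baselines[band]
        part = rng_features.normal(0, config.feature_participant_sd, P)[pcodes]
        smooth = (config.feature_spatial_sd
                  * rng_features.normal(0, 1, (n, config.n_channels)) @ L.T)
        white = rng_features.normal(0, config.feature_white_sd,
                                    (n, config.n_channels))
        vals = base + part[:, None] + smooth + white
        if band == "gamma":
            vals = vals + np.outer(a, tau)
        feats[band] = pd.DataFrame(
            vals, index=pd.Index(rec["record_id"], name="record_id"),
            columns=list(sensors.channel_labels),
        )
    feats["ratio"] = feats["gamma"] - feats["delta"]

    latents = pd.DataFrame(
        {"record_id": rec["record_id"], "b": bvec, "a": a, "u1": u1, "u2": u2,
         "depth_raw": depth_raw, "sleepiness_raw": sleep_raw}
    )
    return CohortDataset(sensors, rec, feats, None, CohortTruth(config, latents))


def generate_eeg_segment(
    band_profile: Mapping[str | BandDefinition, float],
    duration: float,
    fs: float,
    seed: int = 0,
    n_channels: int = 1,
    channel_labels: list[str] | None = None,
    pink_sd: float = 0.0,
    white_sd: float = 0.0,
    alarm_offset: float = 0.0,
) -> EEGSegment:
    """Multichannel test signal: 1/f background + white noise + one
    sinusoid per requested band (at the band's center frequency, random
    phase per channel).  ``alarm_offset`` seconds of post-alarm data are
    kept at the end of the segment.
    """
    if fs <= 100:
        raise ValueError(
            f"fs = {fs} Hz too low: the 25-50 Hz gamma band is unresolvable"
        )
    n = duration * fs
    if abs(n - round(n)) > 1e-9:
        raise ValueError("duration * fs must be an integer number of samples")
    n = int(round(n))
    bands = []
    for key, amp in band_profile.items():
        band = DEFAULT_BANDS[key] if isinstance(key, str) else key
        if band.f_hi >= fs / 2:
            raise ValueError(
                f"band {band.name} upper edge {band.f_hi} Hz >= Nyquist {fs / 2} Hz"
            )
        bands.append((band, float(amp)))
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    data = np.zeros((n_channels, n))
    for band, amp in bands:
        f0 = 0.5 * (band.f_lo + band.f_hi)
        phases = rng.uniform(0, 2 * np.pi, n_channels)
        if amp != 0:
            data += amp * np.sin(2 * np.pi * f0 * t[None, :] + phases[:, None])
    if pink_sd > 0:
        freqs = np.fft.rfftfreq(n, 1 / fs)
        shape = np.zeros_like(freqs)
        shape[1:] = 1.0 / np.sqrt(freqs[1:])
        spec = (rng.normal(size=(n_channels, len(freqs)))
                + 1j * rng.normal(size=(n_channels, len(freqs)))) * shape
        pink = np.fft.irfft(spec, n=n, axis=1)
        sd = pink.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        data += pink_sd * pink / sd
    if white_sd > 0:
        data += rng.normal(0, white_sd, (n_channels, n))
    labels = channel_labels or [f"E{i + 1:03d}" for i in range(n_channels)]
    alarm_index = n - int(round(alarm_offset * fs))
    return EEGSegment(data=data, fs=fs, channel_labels=labels,
                      alarm_index=alarm_index)
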