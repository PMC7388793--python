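"""Synthetic forward models, phase-coupled oscillatory sources, scalp
projections, and full multi-group cohorts with known ground truth.

Every downstream stage of the analysis (screening, source imaging,
connectivity, graph metrics, statistics) can be exercised against cohorts
generated here, whose coupling levels, corrupted segments, and covariates are
known exactly.

Geometry and physics
--------------------
Sensors sit quasi-uniformly on the unit sphere (Fibonacci lattice); sources
sit at random interior positions with radius in [0.3, 0.9] (respecting an
electrode standoff) and carry a fixed random dipole orientation. The gain of
source *s* at sensor *m* is the projection of
a current dipole field in an infinite homogeneous medium onto the sensor
direction, with an inverse-square distance law:

    g_ms = cos(angle(r_m - r_s, d_s)) / ||r_m - r_s||^2

so column norms fall off with source depth, which is what the depth-weighted
inverse has to compensate. The gain matrix is scaled once so the mean column
norm is 1; scalp signals are nominally in microvolts.

Oscillatory content
-------------------
Each node signal is a sum over the six canonical bands of narrowband noise
(white noise band-passed with the package's zero-phase Butterworth filter).
Within band *b* with coupling level ``c``:

    x_i = amp_b * ( sqrt(1 - c) * e_i  +  sqrt(c) * s )

where ``e_i`` is node-specific and ``s`` a shared driver, all unit variance,
so ``c`` monotonically controls the expected pairwise phase-locking in that
band while leaving the band amplitude unchanged. Drivers are noise, not
sinusoids, so PLV < 1 generically and phase estimates are non-degenerate.

Defaults emulate eyes-closed resting EEG: alpha-dominant amplitudes (so clean
epochs robustly pass the theta/alpha drowsiness screen), 62 sensors at
1,000 Hz, amplitude artifacts as +-100 uV single-sample deviations (safely
beyond the +-75 uV criterion), and drowsy segments whose theta content is
boosted above alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import spectral
from .preprocess import RawRecording

DEFAULT_N_SENSORS = 62
DEFAULT_N_SOURCES = 500
DEFAULT_N_NODES = 148
DEFAULT_FS = 1000.0

#: Eyes-closed-like band amplitudes (arbitrary source units projecting to a
#: scalp RMS of roughly 10 uV with the normalized gain). Alpha dominates
#: theta so that clean epochs satisfy theta/alpha power < 1 by construction.
REST_AMPLITUDES: dict[str, float] = {
    "delta": 0.95,
    "theta": 0.65,
    "alpha": 1.45,
    "low_beta": 0.5,
    "high_beta": 0.4,
    "gamma": 0.3,
}

#: Baseline inter-node coupling per band (moderate resting synchrony).
REST_COUPLING: dict[str, float] = {b.name: 0.2 for b in spectral.CANONICAL_BANDS}

ARTIFACT_DEVIATION_UV = 100.0  # single-sample rectangular deviation
DROWSY_THETA_BOOST = 1.0       # injected theta RMS as a multiple of alpha RMS
DROWSY_ALPHA_SUPPRESSION = 0.7  # fraction of the alpha band removed in-segment
EOG_TOPOGRAPHY_SCALE = 0.5     # exponential decay scale from the frontal pole
FRONTAL_POLE = np.array([0.0, 1.0, 0.0])
SEGMENT_LEN_S = 2.0            # grid on which artifacts/drowsiness are injected


@dataclass
class ForwardModel:
    """Leadfield with geometry and the node-seed parcellation.

    ``gain`` is sensors x sources; ``node_seeds`` lists one source index per
    network node (the "seed point" representing a parcel).
    """

    gain: np.ndarray
    source_pos: np.ndarray
    sensor_pos: np.ndarray
    node_seeds: np.ndarray

    def __post_init__(self):
        self.gain = np.asarray(self.gain, float)
        self.source_pos = np.asarray(self.source_pos, float)
        self.sensor_pos = np.asarray(self.sensor_pos, float)
        self.node_seeds = np.asarray(self.node_seeds, int)
        n_sens, n_src = self.gain.shape
        if self.source_pos.shape != (n_src, 3):
            raise ValueError("source_pos must be n_sources x 3")
        if self.sensor_pos.shape != (n_sens, 3):
            raise ValueError("sensor_pos must be n_sensors x 3")
        if len(np.unique(self.node_seeds)) != len(self.node_seeds):
            raise ValueError("node_seeds must be distinct")
        if self.node_seeds.min() < 0 or self.node_seeds.max() >= n_src:
            raise ValueError("node_seeds out of range")
        norms = np.linalg.norm(self.gain, axis=0)
        if not np.all(np.isfinite(norms)) or np.any(norms == 0):
            raise ValueError("every gain column must have finite nonzero norm")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]

    @property
    def n_nodes(self) -> int:
        return len(self.node_seeds)

    @property
    def source_depth(self) -> np.ndarray:
        """Distance of each source from the sensor shell (unit sphere)."""
        return 1.0 - np.linalg.norm(self.source_pos, axis=1)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _farthest_point_seeds(pos: np.ndarray, k: int) -> np.ndarray:
    """Greedy farthest-point subset of ``k`` source indices, spread over the
    interior (deterministic: starts from the point nearest the centroid)."""
    n = len(pos)
    start = int(np.argmin(np.linalg.norm(pos - pos.mean(axis=0), axis=1)))
    chosen = [start]
    d = np.linalg.norm(pos - pos[start], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pos - pos[nxt], axis=1))
    return np.array(sorted(chosen), int)


def make_forward_model(n_sensors: int = DEFAULT_N_SENSORS,
                       n_sources: int = DEFAULT_N_SOURCES,
                       n_nodes: int = DEFAULT_N_NODES,
                       seed: int = 0) -> ForwardModel:
    """Build the spherical-geometry forward model described in the module docs."""
    if n_nodes > n_sources:
        raise ValueError(f"n_nodes ({n_nodes}) may not exceed n_sources ({n_sources})")
    if n_sensors < 8:
        raise ValueError("need at least 8 sensors")
    rng = np.random.default_rng(seed)
    sensors = _fibonacci_sphere(n_sensors)
    # Sources keep radius in [0.3, 0.9] but additionally respect an electrode
    # standoff (the scalp/skull gap): no source closer than 0.25 radii to any
    # sensor, which bounds the largest single gain entry.
    standoff = 0.25
    sources = np.empty((n_sources, 3))
    filled = 0
    for _ in range(200):
        need = n_sources - filled
        if need == 0:
            break
        direc = rng.standard_normal((need, 3))
        direc /= np.linalg.norm(direc, axis=1, keepdims=True)
        radius = rng.uniform(0.3, 0.9, need)
        cand = direc * radius[:, None]
        dmin = np.linalg.norm(cand[:, None, :] - sensors[None, :, :],
                              axis=2).min(axis=1)
        ok = cand[dmin >= standoff]
        sources[filled:filled + len(ok)] = ok
        filled += len(ok)
    if filled < n_sources:
        raise RuntimeError("could not place sources respecting the standoff")
    # Fixed random dipole orientations: cortical dipole orientation follows
    # local folding rather than the radius vector, and decorrelated scalp
    # patterns keep neighbouring sources resolvable by the inverse.
    orient = rng.standard_normal((n_sources, 3))
    orient /= np.linalg.norm(orient, axis=1, keepdims=True)

    diff = sensors[:, None, :] - sources[None, :, :]      # m x s x 3
    dist = np.linalg.norm(diff, axis=2)
    cosang = np.einsum("msk,sk->ms", diff, orient) / dist
    gain = cosang / dist**2
    gain /= np.linalg.norm(gain, axis=0).mean()           # mean column norm = 1

    seeds = _farthest_point_seeds(sources, n_nodes)
    return ForwardModel(gain=gain, source_pos=sources, sensor_pos=sensors,
                        node_seeds=seeds)


@dataclass
class CouplingSpec:
    """Ground-truth knobs for one group's recordings.

    ``coupling`` maps band name to the coupling level ``c`` in [0, 1];
    ``amplitude`` maps band name to the base amplitude. Bands absent from
    ``coupling`` default to the resting baseline; unknown band names are
    rejected.
    """

    label: str = "group"
    coupling: dict[str, float] = field(default_factory=dict)
    amplitude: dict[str, float] = field(default_factory=dict)
    artifact_fraction: float = 0.0
    drowsy_fraction: float = 0.0
    eog_gain: float = 0.0

    def __post_init__(self):
        for d in (self.coupling, self.amplitude):
            for name in d:
                if name not in spectral.BAND_MAP:
                    raise KeyError(f"unknown band name {name!r}")
        for name, c in self.coupling.items():
            if not 0 <= c <= 1:
                raise ValueError(f"coupling for {name!r} must be in [0, 1], got {c}")
        if not 0 <= self.drowsy_fraction <= 1:
            raise ValueError("drowsy_fraction must be in [0, 1]")
        if not 0 <= self.artifact_fraction <= 1:
            raise ValueError("artifact_fraction must be in [0, 1]")

    def band_coupling(self, name: str) -> float:
        return self.coupling.get(name, REST_COUPLING[name])

    def band_amplitude(self, name: str) -> float:
        return self.amplitude.get(name, REST_AMPLITUDES[name])


@dataclass
class GroupSpec:
    """One cohort group: label and size live with its coupling spec."""

    n_subjects: int
    spec: CouplingSpec

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def label(self) -> str:
        return self.spec.label


@dataclass
class CohortSpec:
    """Study conditions for a full synthetic cohort."""

    groups: tuple[GroupSpec, ...]
    duration_s: float = 300.0
    fs: float = DEFAULT_FS
    n_sensors: int = DEFAULT_N_SENSORS
    n_sources: int = DEFAULT_N_SOURCES
    n_nodes: int = DEFAULT_N_NODES
    covariate_mean: float = 100.0   # premorbid-IQ-like covariate
    covariate_sd: float = 10.0
    sensor_noise_sd: float = 1.0    # uV, white
    seed: int = 0

    def __post_init__(self):
        self.groups = tuple(self.groups)
        if not self.groups:
            raise ValueError("at least one group required")
        if self.fs <= 2 * spectral.CANONICAL_BANDS[-1].hi:
            raise ValueError(
                f"fs must exceed twice the highest band edge "
                f"(2 x {spectral.CANONICAL_BANDS[-1].hi} Hz)"
            )
        if self.duration_s < 2:
            raise ValueError("duration_s must be >= 2")


@dataclass
class SubjectRecord:
    subject: str
    group: str
    recording: RawRecording


@dataclass
class Cohort:
    """Simulated subjects, their metadata table, and ground-truth bookkeeping.

    ``ground_truth[subject]`` maps ``"drowsy"`` and ``"artifact"`` to the
    sorted 2-s segment indices that were corrupted in that recording.
    """

    subjects: list[SubjectRecord]
    metadata: pd.DataFrame
    ground_truth: dict[str, dict[str, list[int]]]
    forward_model: ForwardModel
    spec: CohortSpec


def _narrowband(rng: np.random.Generator, shape: tuple[int, int], fs: float,
                band: spectral.BandDefinition) -> np.ndarray:
    """Unit-variance narrowband noise rows: band-passed white noise."""
    x = spectral.bandpass(rng.standard_normal(shape), fs, band)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_coupled_sources(fm: ForwardModel, spec: CouplingSpec,
                             duration_s: float, fs: float,
                             seed: int = 0) -> np.ndarray:
    """Simulate the node source signals (n_nodes x samples).

    Per band ``b``: each node's band component is
    ``sqrt(1 - c_b) * e_i + sqrt(c_b) * s`` with unit-variance narrowband
    noises, scaled by the band amplitude; components are summed over bands.
    """
    if duration_s < 2:
        raise ValueError("duration_s must be >= 2")
    if fs < 200:
        raise ValueError("fs must be >= 200 Hz")
    rng = np.random.default_rng(seed)
    n = fm.n_nodes
    t = int(round(duration_s * fs))
    x = np.zeros((n, t))
    for band in spectral.CANONICAL_BANDS:
        c = spec.band_coupling(band.name)
        amp = spec.band_amplitude(band.name)
        e = _narrowband(rng, (n, t), fs, band)
        s = _narrowband(rng, (1, t), fs, band)
        x += amp * (np.sqrt(1.0 - c) * e + np.sqrt(c) * s)
    return x


def make_eog_signal(duration_s: float, fs: float, seed: int = 0,
                    rms: float = 25.0, blink_rate_hz: float = 0.25) -> np.ndarray:
    """Ocular reference signal: slow drift plus blink-like Gaussian bumps (uV)."""
    rng = np.random.default_rng(seed)
    t = int(round(duration_s * fs))
    drift = spectral.bandpass(rng.standard_normal(t), fs,
                              spectral.BandDefinition("eog_drift", 1.0, 5.0))
    drift *= rms / max(drift.std(), 1e-12)
    n_blinks = rng.poisson(blink_rate_hz * duration_s)
    centers = rng.uniform(0, duration_s, n_blinks)
    width = 0.075  # s, Gaussian sigma
    tt = np.arange(t) / fs
    sig = drift
    for c in centers:
        sig = sig + 3.0 * rms * np.exp(-0.5 * ((tt - c) / width) ** 2)
    return sig


def project_to_scalp(fm: ForwardModel, node_signals: np.ndarray, fs: float,
                     sensor_noise_sd: float = 1.0,
                     eog_signal: np.ndarray | None = None,
                     eog_gain: float = 0.0, seed: int = 0) -> RawRecording:
    """Project node signals through the leadfield to a scalp recording (uV).

    ``scalp = gain[:, node_seeds] @ node_signals + eog_gain * (topography x
    eog_signal) + white noise``; the EOG topography decays exponentially with
    sensor distance from the frontal pole (scale 0.5 sphere radii). If
    ``eog_signal`` is given, an EOG channel carrying it is appended.
    """
    node_signals = np.asarray(node_signals, float)
    if node_signals.ndim != 2 or node_signals.shape[0] != fm.n_nodes:
        raise ValueError(
            f"node_signals must be {fm.n_nodes} x samples, got {node_signals.shape}"
        )
    rng = np.random.default_rng(seed)
    scalp = fm.gain[:, fm.node_seeds] @ node_signals
    if eog_signal is not None:
        eog_signal = np.asarray(eog_signal, float)
        if eog_signal.shape != (node_signals.shape[1],):
            raise ValueError("eog_signal length must match node_signals samples")
        topo = np.exp(-np.linalg.norm(fm.sensor_pos - FRONTAL_POLE, axis=1)
                      / EOG_TOPOGRAPHY_SCALE)
        scalp += eog_gain * topo[:, None] * eog_signal[None, :]
    if sensor_noise_sd > 0:
        scalp += rng.normal(0.0, sensor_noise_sd, scalp.shape)
    labels = [f"EEG{i + 1:03d}" for i in range(fm.n_sensors)]
    eog_channels: tuple[str, ...] = ()
    if eog_signal is not None:
        scalp = np.vstack([scalp, eog_signal])
        labels.append("EOG")
        eog_channels = ("EOG",)
    return RawRecording(data=scalp, fs=fs, labels=tuple(labels),
                        eog_channels=eog_channels, reference="original")


def _inject_drowsy(data: np.ndarray, eeg_rows: np.ndarray, segments: np.ndarray,
                   fs: float, rng: np.random.Generator) -> None:
    """Emulate sleep-onset EEG inside the given 2-s segments (in place).

    Within each flagged segment the alpha band is attenuated (alpha dropout)
    and theta-band noise with RMS ``DROWSY_THETA_BOOST`` times the
    recording's alpha RMS is added, driving the per-epoch theta/alpha power
    ratio far above 1 while keeping peak amplitudes well below the +-75 uV
    artifact criterion. A short Hann taper avoids step edges bleeding into
    neighbouring segments.
    """
    if len(segments) == 0:
        return
    alpha_rms = np.sqrt(
        np.mean(spectral.bandpass(data[eeg_rows], fs, "alpha") ** 2)
    )
    seg_len = int(round(SEGMENT_LEN_S * fs))
    taper_len = max(int(0.05 * fs), 2)
    taper = np.hanning(2 * taper_len)
    window = np.ones(seg_len)
    window[:taper_len] = taper[:taper_len]
    window[-taper_len:] = taper[taper_len:]
    cols = np.arange(seg_len)
    for seg in segments:
        sl = cols + seg * seg_len
        block = data[np.ix_(eeg_rows, sl)]
        alpha_part = spectral.bandpass(block, fs, "alpha")
        theta = _narrowband(rng, (1, seg_len), fs, spectral.BAND_MAP["theta"])[0]
        gains = rng.uniform(0.7, 1.0, len(eeg_rows))
        correction = (DROWSY_THETA_BOOST * alpha_rms * np.outer(gains, theta)
                      - DROWSY_ALPHA_SUPPRESSION * alpha_part)
        data[np.ix_(eeg_rows, sl)] += correction * window


def _inject_artifacts(data: np.ndarray, eeg_rows: np.ndarray,
                      segments: np.ndarray, fs: float,
                      rng: np.random.Generator) -> None:
    """Add a +-100 uV single-sample deviation in each flagged segment (in place)."""
    seg_len = int(round(SEGMENT_LEN_S * fs))
    for seg in segments:
        ch = rng.choice(eeg_rows)
        offset = rng.integers(int(0.1 * seg_len), int(0.9 * seg_len))
        idx = seg * seg_len + int(offset)
        sign = np.sign(data[ch, idx]) or 1.0
        data[ch, idx] += sign * ARTIFACT_DEVIATION_UV


def simulate_subject(fm: ForwardModel, spec: CouplingSpec, duration_s: float,
                     fs: float, sensor_noise_sd: float = 1.0,
                     seed: int = 0) -> tuple[RawRecording, dict[str, list[int]]]:
    """Simulate one subject's recording plus its corrupted-segment ground truth."""
    rng = np.random.default_rng(seed)
    src_seed, eog_seed, noise_seed = rng.integers(0, 2**31, 3)
    sources = simulate_coupled_sources(fm, spec, duration_s, fs, seed=int(src_seed))
    eog = (make_eog_signal(duration_s, fs, seed=int(eog_seed))
           if spec.eog_gain > 0 else None)
    raw = project_to_scalp(fm, sources, fs, sensor_noise_sd=sensor_noise_sd,
                           eog_signal=eog, eog_gain=spec.eog_gain,
                           seed=int(noise_seed))
    n_seg = raw.n_samples // int(round(SEGMENT_LEN_S * fs))
    n_drowsy = int(round(spec.drowsy_fraction * n_seg))
    n_artifact = int(round(spec.artifact_fraction * n_seg))
    perm = rng.permutation(n_seg)
    drowsy = np.sort(perm[:n_drowsy])
    artifact = np.sort(perm[n_drowsy:n_drowsy + n_artifact])
    eeg_rows = raw.eeg_picks
    _inject_drowsy(raw.data, eeg_rows, drowsy, fs, rng)
    _inject_artifacts(raw.data, eeg_rows, artifact, fs, rng)
    truth = {"drowsy": [int(i) for i in drowsy],
             "artifact": [int(i) for i in artifact]}
    return raw, truth


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a full multi-group cohort, deterministically under ``spec.seed``.

    The metadata table carries, per subject: group label, a premorbid-IQ-like
    covariate, a synthetic symptom-like ``score`` (higher with stronger theta
    coupling), and medication/illness-duration-like nuisance columns for the
    covariate-adjusted correlation analysis.
    """
    fm = make_forward_model(spec.n_sensors, spec.n_sources, spec.n_nodes,
                            seed=spec.seed)
    subjects: list[SubjectRecord] = []
    rows = []
    truth: dict[str, dict[str, list[int]]] = {}
    idx = 0
    for g in spec.groups:
        for _ in range(g.n_subjects):
            subject_id = f"sub-{idx + 1:03d}"
            rng = np.random.default_rng([spec.seed, idx])
            rec_seed = int(rng.integers(0, 2**31))
            raw, t = simulate_subject(fm, g.spec, spec.duration_s, spec.fs,
                                      sensor_noise_sd=spec.sensor_noise_sd,
                                      seed=rec_seed)
            covariate = rng.normal(spec.covariate_mean, spec.covariate_sd)
            c_theta = g.spec.band_coupling("theta")
            score = 40.0 + 60.0 * c_theta + rng.normal(0.0, 5.0)
            med_dose = float(np.exp(rng.normal(5.0, 0.5)))
            illness_duration = float(rng.uniform(0.0, 20.0))
            subjects.append(SubjectRecord(subject_id, g.label, raw))
            truth[subject_id] = t
            rows.append({"subject": subject_id, "group": g.label,
                         "covariate": covariate, "score": score,
                         "med_dose": med_dose,
                         "illness_duration": illness_duration})
            idx += 1
    metadata = pd.DataFrame(rows)
    return Cohort(subjects=subjects, metadata=metadata, ground_truth=truth,
                  forward_model=fm, spec=spec)
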