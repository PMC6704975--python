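"""Synthetic resting-state EEG with planted microstate structure.

The generator emulates the acquisition conditions of a typical high-density
resting-state study -- 110 average-referenced channels at 125 Hz for five
minutes -- as a semi-Markov alternation of a small set of fixed scalp
topographies with dwell times on the order of 80-120 ms, an alpha-band
amplitude envelope, and spatially correlated noise at a controllable SNR.
Because the planted templates, label sequence and dwell statistics are
known exactly, every downstream stage can be validated by parameter
recovery.  This is a statistical stand-in, not a biophysical forward model:
there is no head model, no dipole sources and no ocular/cardiac artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import EEGRecording
from .segment import Segmentation, compute_metrics, segments_from_labels

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_templates",
    "generate_state_sequence",
    "synthesize_eeg",
    "simulate_recording",
    "simulate_cohort",
    "generate_clinical",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic recording.

    Defaults emulate the target acquisition: 110 channels, 125 Hz (after
    8:1 down-sampling from 1 kHz), 300 s, six alternating topographies with
    a mean dwell of 100 ms (the classical 80-120 ms microstate range), and a
    signal-to-noise RMS ratio of 2.  Dwell times are gamma distributed with
    shape ``dwell_shape`` (positive, right-skewed, few near-zero dwells).
    ``snr`` is the ratio of the RMS of the noiseless signal to the RMS of
    the noise, pooled over channels and time; ``snr=None`` means noiseless
    and ``snr=0`` pure noise.
    """

    n_channels: int = 110
    fs: float = 125.0
    duration_s: float = 300.0
    k_true: int = 6
    mean_dwell_ms: float = 100.0
    dwell_shape: float = 2.0
    snr: float | None = 2.0
    seed: int = 0
    template_min_separation: float = 0.5
    envelope_freq_hz: float = 10.0
    amplitude_uv: float = 10.0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if not self.mean_dwell_ms > 0:
            raise ValueError("mean_dwell_ms must be positive")
        if self.snr is not None and self.snr < 0:
            raise ValueError("snr must be >= 0 (or None for noiseless)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class GroundTruth:
    """Planted structure of a synthetic recording.

    Holds the template maps, the per-sample class labels, and the exact
    per-class temporal metrics computed from the label sequence with the
    same conventions as the analysis stage, so recovered and true values
    are directly comparable.
    """

    templates: np.ndarray  # (k_true, n_channels)
    labels: np.ndarray  # (n_samples,)
    fs: float
    duration_ms: np.ndarray = field(init=False)
    occurrence_per_s: np.ndarray = field(init=False)
    coverage: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        seg = Segmentation(labels=self.labels, fs=self.fs, n_classes=self.templates.shape[0])
        m = compute_metrics(seg)
        self.duration_ms = m.duration_ms
        self.occurrence_per_s = m.occurrence_per_s
        self.coverage = m.coverage

    @property
    def segments(self) -> list[tuple[int, int, int]]:
        return segments_from_labels(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": np.arange(self.templates.shape[0]),
                "duration_ms": self.duration_ms,
                "occurrence_per_s": self.occurrence_per_s,
                "coverage": self.coverage,
            }
        )


def generate_templates(
    K: int,
    n_channels: int,
    min_separation: float = 0.5,
    seed: int | None = None,
    n_modes: int | None = None,
) -> np.ndarray:
    """K average-referenced, unit-norm, mutually orthogonal template maps.

    Templates are built as random combinations of smooth low-order spatial
    modes (cosine profiles over a randomly permuted channel ordering, a
    geometry-free surrogate for smooth scalp fields), centered to the
    average reference, and orthonormalised.  Orthogonality makes every
    pairwise absolute spatial correlation zero, trivially satisfying any
    ``min_separation`` bound.

    Raises when K maps cannot fit in the (n_channels - 1)-dimensional
    average-reference subspace.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_channels < K + 1:
        raise ValueError(
            f"cannot place {K} mutually separated maps on {n_channels} channels: "
            f"need n_channels >= K + 1"
        )
    rng = np.random.default_rng(seed)
    m = n_modes if n_modes is not None else min(n_channels - 1, max(4 * K, 16))
    order = rng.permutation(n_channels)
    c = np.arange(n_channels)
    modes = np.stack(
        [np.cos(np.pi * j * (c[order.argsort()] + 0.5) / n_channels) for j in range(1, m + 1)]
    )  # (m, C), smooth over the permuted virtual layout
    T = rng.normal(size=(K, m)) @ modes  # (K, C)
    T = T - T.mean(axis=1, keepdims=True)
    # QR orthonormalisation stays inside the zero-mean subspace
    Q, _ = np.linalg.qr(T.T)  # (C, K)
    templates = Q[:, :K].T
    if np.linalg.matrix_rank(T) < K:  # pragma: no cover - pathological draw
        raise RuntimeError("degenerate template draw; use a different seed")
    templates = templates / np.linalg.norm(templates, axis=1, keepdims=True)
    G = np.abs(templates @ templates.T)
    np.fill_diagonal(G, 0.0)
    if G.max() > min_separation + 1e-10:
        raise RuntimeError(
            f"template separation {G.max():.3f} exceeds requested bound {min_separation}"
        )
    return templates


def generate_state_sequence(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Semi-Markov microstate label sequence.

    Each segment's class is drawn uniformly from the ``k_true`` classes
    excluding the previous one; its dwell time is gamma distributed with
    shape ``dwell_shape`` and mean ``mean_dwell_ms``, rounded to at least
    one sample.  The sequence is truncated to exactly
    ``round(duration_s * fs)`` samples.  With ``k_true = 1`` the whole
    recording is a single unbroken segment.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ms = 1000.0 / config.fs
    if config.mean_dwell_ms < sample_ms:
        raise ValueError(
            f"mean_dwell_ms={config.mean_dwell_ms} is shorter than one sample "
            f"period ({sample_ms:.3f} ms) at fs={config.fs}"
        )
    if config.k_true == 1:
        labels = np.zeros(n, dtype=int)
        return labels, [(0, 0, n)]
    scale = config.mean_dwell_ms / config.dwell_shape
    labels = np.empty(n, dtype=int)
    pos = 0
    prev = -1
    while pos < n:
        choices = [k for k in range(config.k_true) if k != prev]
        cls = int(rng.choice(choices))
        dwell_ms = rng.gamma(config.dwell_shape, scale)
        length = max(1, int(round(dwell_ms / sample_ms)))
        length = min(length, n - pos)
        labels[pos : pos + length] = cls
        pos += length
        prev = cls
    return labels, segments_from_labels(labels)


def synthesize_eeg(
    templates: np.ndarray,
    labels: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    subject: str | None = None,
    group: str | None = None,
) -> tuple[EEGRecording, GroundTruth]:
    """Render a label sequence into a noisy multichannel recording.

    At each sample the active template is scaled by a strictly positive
    amplitude envelope (a rectified sinusoid at ``envelope_freq_hz``,
    unit mean -- an alpha-band surrogate that produces GFP peaks roughly
    every half cycle) and summed with zero-mean spatially correlated
    Gaussian noise (random rotation of an exponentially decaying eigenvalue
    spectrum), scaled so the pooled signal-to-noise RMS ratio equals
    ``config.snr``.  Every output sample is average-referenced.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    templates = np.asarray(templates, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= templates.shape[0]:
        raise ValueError("labels index outside the template set")
    C = templates.shape[1]
    n = labels.size
    t = np.arange(n) / config.fs
    phase = rng.uniform(0, 2 * np.pi)
    env = np.abs(np.sin(2 * np.pi * config.envelope_freq_hz * t + phase))
    env = env * (np.pi / 2.0)  # E|sin| = 2/pi -> unit mean
    signal = templates[labels].T * env[None, :]  # (C, n); templates are centered

    # spatially correlated noise: random orthogonal mixing of decaying spectrum
    Qn, _ = np.linalg.qr(rng.normal(size=(C, C)))
    eigvals = np.exp(-np.arange(C) / 10.0)
    cov_half = Qn * np.sqrt(eigvals)[None, :]
    noise = cov_half @ rng.normal(size=(C, n))
    noise -= noise.mean(axis=0, keepdims=True)

    rms_s = float(np.sqrt((signal**2).mean()))
    if config.snr is None or np.isinf(config.snr):
        data = signal.copy()
    else:
        rms_n = float(np.sqrt((noise**2).mean()))
        if config.snr == 0:
            data = noise * (rms_s / rms_n)
        else:
            data = signal + noise * (rms_s / (config.snr * rms_n))
    data -= data.mean(axis=0, keepdims=True)
    rms = float(np.sqrt((data**2).mean()))
    if rms > 0:
        data *= config.amplitude_uv / rms
    rec = EEGRecording(
        data=data, fs=config.fs, subject=subject, group=group,
        channel_labels=[f"E{i + 1:03d}" for i in range(C)],
    )
    gt = GroundTruth(templates=templates, labels=labels, fs=config.fs)
    return rec, gt


def simulate_recording(
    config: SimulationConfig, subject: str | None = None, group: str | None = None,
    templates: np.ndarray | None = None,
) -> tuple[EEGRecording, GroundTruth]:
    """Templates + state sequence + rendering, all driven by ``config.seed``.

    Bit-identical output for identical config and seed.  Pass ``templates``
    to share one template set across a cohort.
    """
    ss = np.random.SeedSequence(config.seed)
    s_templ, s_seq, s_eeg = ss.spawn(3)
    if templates is None:
        templates = generate_templates(
            config.k_true,
            config.n_channels,
            min_separation=config.template_min_separation,
            seed=int(s_templ.generate_state(1)[0] % (2**31)),
        )
    labels, _ = generate_state_sequence(config, rng=np.random.default_rng(s_seq))
    return synthesize_eeg(
        templates, labels, config, rng=np.random.default_rng(s_eeg),
        subject=subject, group=group,
    )


def simulate_cohort(
    config: SimulationConfig,
    n_subjects: int,
    seed: int | None = None,
    share_templates: bool = True,
) -> tuple[list[EEGRecording], list[GroundTruth], np.ndarray]:
    """A cohort of synthetic subjects, half patients and half controls.

    All subjects share the planted template set by default (different state
    sequences and noise), mirroring a group-level microstate study.  Returns
    ``(recordings, ground_truths, templates)``.
    """
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    child = ss.spawn(n_subjects + 1)
    templates = generate_templates(
        config.k_true,
        config.n_channels,
        min_separation=config.template_min_separation,
        seed=int(child[0].generate_state(1)[0] % (2**31)),
    )
    recs, gts = [], []
    for i in range(n_subjects):
        sub_cfg = SimulationConfig(
            **{**config.__dict__, "seed": int(child[i + 1].generate_state(1)[0] % (2**31))}
        )
        group = "patient" if i < (n_subjects + 1) // 2 else "control"
        rec, gt = simulate_recording(
            sub_cfg,
            subject=f"S{i:03d}",
            group=group,
            templates=None if not share_templates else templates,
        )
        recs.append(rec)
        gts.append(gt)
    return recs, gts, templates


def generate_clinical(
    subjects: list[str], seed: int | None = None
) -> pd.DataFrame:
    """Synthetic clinical covariate table for a patient cohort.

    Draws plausible values for a moderate-to-severe depression sample:
    MADRS 9-39, CGI 3-6, 1-11 lifetime episodes, illness duration up to
    ~27 years, benzodiazepine-equivalent dose 0-6 mg, and the ordinal
    medication scale 1-4 (number of psychotropic medicaments and whether
    doses are therapeutic).  Entirely synthetic; columns follow the schema
    expected by :func:`microstates.stats.correlate_with_clinical`.
    """
    rng = np.random.default_rng(seed)
    n = len(subjects)
    return pd.DataFrame(
        {
            "subject": subjects,
            "group": "patient",
            "madrs": rng.integers(9, 40, size=n),
            "cgi": rng.integers(3, 7, size=n),
            "n_episodes": rng.integers(1, 12, size=n),
            "illness_duration_y": np.round(rng.gamma(1.5, 6.0, size=n), 2),
            "bzd_equivalent": np.round(rng.choice([0, 1, 1.33, 2, 3, 6], size=n), 2),
            "medication_scale": rng.integers(1, 5, size=n),
        }
    )
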