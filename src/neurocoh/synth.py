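"""Synthetic EEG cohort generator with controlled connectivity structure.

Real periodic-discharge EEG from encephalopathy patients is not publicly
distributable, so this module simulates the two cohort archetypes whose
contrast the downstream network analysis is designed to detect:

* **integrated** (``"tme_like"``): every channel is driven by one shared
  periodic-discharge source plus independent noise — a globally coupled,
  efficient network, the signature of diffuse metabolic cortical dysfunction.
* **segregated** (``"ncse_like"``): channels are partitioned into contiguous
  electrode communities, each driven by its own source; cross-community
  mixing is controlled by a ``leakage`` coefficient — a modular network, the
  signature of a focal irritative zone.

A matched clinical covariate table (age, sex, liver disease and five
laboratory values) is drawn with group shifts in the clinically expected
direction (the encephalopathy group older, more often female, with renal and
hepatic derangement).

All randomness flows from one master seed through per-subject
``numpy.random.SeedSequence`` derivations, so enlarging a cohort never
perturbs previously generated subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS_1020",
    "SPATIAL_ORDER_1020",
    "GROUP_INTEGRATED",
    "GROUP_SEGREGATED",
    "CohortConfig",
    "EEGRecording",
    "make_discharge_waveform",
    "generate_subject",
    "generate_cohort",
    "generate_clinical",
    "community_layout",
    "clinical_defaults",
]

#: Canonical ordering of the 19 scalp electrodes of the International 10-20
#: system, anterior to posterior, left before right.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: A scalp-contiguous path through the 19 electrodes (left fronto-temporal →
#: left parieto-occipital → midline → right). Contiguous slices of this list
#: form spatially compact electrode neighborhoods, used to lay out the
#: source communities of segregated subjects.
SPATIAL_ORDER_1020: tuple[str, ...] = (
    "Fp1", "F7", "F3", "T3", "C3", "T5", "P3", "O1",
    "Fz", "Cz", "Pz",
    "Fp2", "F8", "F4", "T4", "C4", "T6", "P4", "O2",
)

GROUP_INTEGRATED = "tme_like"
GROUP_SEGREGATED = "ncse_like"
_GROUPS = (GROUP_SEGREGATED, GROUP_INTEGRATED)


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for one synthetic cohort.

    Parameters
    ----------
    n_per_group : int
        Subjects per archetype; at least 2.
    fs : float
        Sampling rate in Hz. Must exceed twice the highest analysis
        frequency (50 Hz).
    n_channels : int
        Number of scalp channels (19 for the full 10-20 montage).
    record_duration : float
        Recording length per subject in seconds; must accommodate ten
        non-consecutive 2-s epochs.
    discharge_rate : float
        Repetition rate of the periodic discharges in Hz (clinically 0.5-3).
    snr : float
        Linear source-to-noise amplitude ratio. 0 gives pure noise.
    n_communities : int
        Number of source communities for segregated subjects (>= 2).
    leakage : float
        Cross-community mixing coefficient in [0, 1]; 0 means fully
        independent communities, 1 means every community also receives the
        mean of all others at full amplitude.
    seed : int
        Master seed; every derived random stream descends from it.
    """

    n_per_group: int = 30
    fs: float = 200.0
    n_channels: int = 19
    record_duration: float = 60.0
    discharge_rate: float = 2.0
    snr: float = 3.0
    n_communities: int = 3
    leakage: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0 <= self.leakage <= 1:
            raise ValueError("leakage must lie in [0, 1]")
        if self.fs <= 2 * 50.0:
            raise ValueError("fs must exceed twice the highest analysis frequency (50 Hz)")
        if self.n_communities < 2:
            raise ValueError("n_communities must be >= 2")
        if self.n_channels < 2 or self.n_channels > len(CHANNELS_1020):
            raise ValueError(f"n_channels must be in [2, {len(CHANNELS_1020)}]")
        # ten 2-s epochs plus nine 1-s gaps is the minimal epoching layout
        if self.record_duration < 10 * 2 + 9 * 1:
            raise ValueError(
                "record_duration must allow 10 non-consecutive 2-s epochs "
                f"(>= 29 s); got {self.record_duration}"
            )
        if self.discharge_rate <= 0 or self.discharge_rate >= self.fs / 2:
            raise ValueError("discharge_rate must lie in (0, fs/2)")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")


@dataclass
class EEGRecording:
    """A continuous multichannel scalp EEG recording (microvolt scale)."""

    channel_labels: tuple[str, ...]
    fs: float
    data: np.ndarray  # channels x samples
    group_label: str
    subject_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data must be (n_channels, n_samples) with "
                f"{len(self.channel_labels)} rows; got shape {self.data.shape}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _triphasic_pulse(fs: float, rate: float) -> np.ndarray:
    """One stylized triphasic transient: a dominant sharp wave flanked by
    two smaller opposite-polarity Gaussian lobes, spanning most of the
    discharge period."""
    period = 1.0 / rate
    span = 0.8 * period
    t = np.arange(int(round(span * fs))) / fs
    centers = np.array([0.18, 0.45, 0.78]) * span
    widths = np.array([0.08, 0.17, 0.10]) * span
    amps = np.array([-0.35, 1.0, -0.25])
    pulse = np.zeros_like(t)
    for c, w, a in zip(centers, widths, amps):
        u = (t - c) / w
        pulse += a * np.exp(-0.5 * u**2)
    return pulse


def make_discharge_waveform(
    fs: float,
    duration: float,
    rate: float,
    seed: int,
    *,
    background: float = 0.15,
    jitter: float = 0.04,
    random_onset: bool = False,
) -> np.ndarray:
    """Generate a periodic-discharge-like source signal.

    A stylized triphasic transient (a large sharp wave flanked by two
    smaller lobes of opposite polarity, each a Gaussian bump) repeats
    quasi-periodically at ``rate`` Hz, with seeded cycle-to-cycle amplitude
    and timing variation plus a low-level 1/f background. The output is
    zero-mean, unit-RMS, and its periodogram peaks at ``rate`` (within one
    frequency bin of the ``duration``-long window).

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    duration : float
        Signal length in seconds; must cover at least one discharge cycle.
    rate : float
        Discharge repetition rate in Hz; must be below the Nyquist frequency.
    seed : int
        Seed for cycle-to-cycle jitter and the background noise.
    background : float
        RMS of the 1/f background relative to the pulse train.
    jitter : float
        SD of the inter-discharge-interval variation as a fraction of the
        period. Applied cumulatively, so the discharge phase drifts the way
        quasi-periodic clinical discharges do; independently generated
        trains therefore decohere over tens of seconds.
    random_onset : bool
        If True, start the train at a seeded random phase of the cycle
        instead of at time zero.
    """
    if rate >= fs / 2:
        raise ValueError(f"discharge rate {rate} Hz is not below Nyquist ({fs / 2} Hz)")
    if rate <= 0:
        raise ValueError("discharge rate must be positive")
    n = int(round(fs * duration))
    if n < fs / rate:
        raise ValueError("duration must cover at least one discharge cycle")
    rng = np.random.default_rng(seed)
    pulse = _triphasic_pulse(fs, rate)
    period = 1.0 / rate
    x = np.zeros(n)
    t_onset = float(rng.uniform(0, period)) if random_onset else 0.0
    while t_onset < duration:
        start = int(round(t_onset * fs))
        amp = 1.0 + 0.1 * rng.standard_normal()
        stop = min(start + pulse.size, n)
        if stop > start:
            x[start:stop] += amp * pulse[: stop - start]
        t_onset += period * (1.0 + jitter * rng.standard_normal())
    x = x - x.mean()
    x = x / x.std()
    x = x + background * _pink_noise(rng, n)
    x = x - x.mean()
    return x / x.std()


def _community_assignment(
    n_channels: int, n_communities: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign channels to spatially contiguous communities.

    Channels are split into contiguous, nearly equal blocks along the
    scalp path ``SPATIAL_ORDER_1020``, with a seeded rotation of the path so
    the focus location varies across subjects.
    """
    labels = list(CHANNELS_1020[:n_channels])
    order = [ch for ch in SPATIAL_ORDER_1020 if ch in labels]
    shift = int(rng.integers(len(order)))
    order = order[shift:] + order[:shift]
    bounds = np.linspace(0, len(order), n_communities + 1).round().astype(int)
    assignment = np.empty(n_channels, dtype=int)
    for k in range(n_communities):
        for ch in order[bounds[k]:bounds[k + 1]]:
            assignment[labels.index(ch)] = k
    return assignment


def _make_source(
    config: CohortConfig,
    rate: float,
    rng: np.random.Generator,
    *,
    random_onset: bool = False,
    broadband_frac: float = 0.55,
) -> np.ndarray:
    """One unit-RMS driving source: discharge train plus broadband activity.

    The broadband component (white + 1/f mixture) models the ongoing
    cortical activity that is conducted together with the discharges; it is
    what gives the driven channels coherence above the noise floor in every
    analysis band, not just at the discharge fundamental. ``broadband_frac``
    is its share of the source power.
    """
    n = int(round(config.fs * config.record_duration))
    train = make_discharge_waveform(
        config.fs, config.record_duration, rate,
        int(rng.integers(2**31)), random_onset=random_onset,
    )
    w = rng.standard_normal(n)
    p = _pink_noise(rng, n)
    bb = 0.85 * w + 0.5 * p
    bb = bb / bb.std()
    src = np.sqrt(1 - broadband_frac) * train + np.sqrt(broadband_frac) * bb
    return src / src.std()


def _subject_rng(
    config: CohortConfig, group: str, index: int, stream: int = 0
) -> np.random.Generator:
    """Independent per-subject random stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, _GROUPS.index(group), index, stream])
    )


def community_layout(config: CohortConfig, subject_seed: int) -> np.ndarray:
    """Community index per channel for a segregated subject.

    Deterministic given (config, subject_seed); the same layout is used by
    :func:`generate_subject` for that subject.
    """
    rng = _subject_rng(config, GROUP_SEGREGATED, subject_seed, stream=3)
    return _community_assignment(config.n_channels, config.n_communities, rng)


def generate_subject(
    config: CohortConfig, group: str, subject_seed: int
) -> EEGRecording:
    """Generate one subject's multichannel recording.

    ``group`` selects the archetype: ``"tme_like"`` (one shared source on
    all channels) or ``"ncse_like"`` (community-structured sources with
    cross-community ``leakage``). ``subject_seed`` indexes the subject within
    its group; together with the config's master seed it fully determines
    the output.
    """
    if group not in _GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {_GROUPS}")
    if config.n_communities > config.n_channels:
        raise ValueError(
            f"n_communities ({config.n_communities}) exceeds "
            f"n_channels ({config.n_channels})"
        )
    noise_rng = _subject_rng(config, group, subject_seed, stream=1)
    src_rng = _subject_rng(config, group, subject_seed, stream=2)
    n = int(round(config.fs * config.record_duration))
    nch = config.n_channels

    # broadband sensor noise: white + 1/f mixture, unit variance per channel
    noise = np.empty((nch, n))
    for c in range(nch):
        w = noise_rng.standard_normal(n)
        p = _pink_noise(noise_rng, n)
        mix = 0.6 * w + 0.8 * p
        noise[c] = mix / mix.std()

    if config.snr == 0:
        data = noise
    elif group == GROUP_INTEGRATED:
        src = _make_source(config, config.discharge_rate, src_rng)
        gains = 1.0 + 0.1 * src_rng.standard_normal(nch)
        gains = np.clip(gains, 0.5, None)
        data = config.snr * gains[:, None] * src[None, :] + noise
    else:
        assignment = community_layout(config, subject_seed)
        # each community discharges at its own rate within the delta range,
        # with independent phase drift, so communities are mutually
        # incoherent while channels within a community stay locked
        rates = config.discharge_rate * np.linspace(0.75, 1.25, config.n_communities)
        sources = np.stack([
            _make_source(config, rates[k], src_rng, random_onset=True)
            for k in range(config.n_communities)
        ])
        mixed = np.empty((nch, n))
        for c in range(nch):
            k = assignment[c]
            others = np.delete(np.arange(config.n_communities), k)
            drive = sources[k] + config.leakage * sources[others].mean(axis=0)
            mixed[c] = drive / drive.std()
        gains = 1.0 + 0.1 * src_rng.standard_normal(nch)
        gains = np.clip(gains, 0.5, None)
        data = config.snr * gains[:, None] * mixed + noise

    # microvolt scale: periodic discharges ride at tens of microvolts
    data = 20.0 * data
    return EEGRecording(
        channel_labels=CHANNELS_1020[:nch],
        fs=config.fs,
        data=data,
        group_label=group,
        subject_id=f"{group}_{subject_seed:03d}",
    )


# Clinical covariate generator defaults: (integrated-group mean/sd or rate,
# segregated-group mean/sd or rate). Continuous laboratory values are drawn
# log-Gaussian (moment-matched), age Gaussian, binary flags Bernoulli.
_CLINICAL_DEFAULTS: dict[str, dict] = {
    "age": {"kind": "gaussian", GROUP_SEGREGATED: (66.12, 17.43), GROUP_INTEGRATED: (73.52, 13.13)},
    "sex_female": {"kind": "bernoulli", GROUP_SEGREGATED: 0.44, GROUP_INTEGRATED: 0.727},
    "chronic_liver_disease": {"kind": "bernoulli", GROUP_SEGREGATED: 0.04, GROUP_INTEGRATED: 0.204},
    "platelet": {"kind": "lognormal", GROUP_SEGREGATED: (214.88, 104.49), GROUP_INTEGRATED: (144.14, 105.13)},
    "magnesium": {"kind": "lognormal", GROUP_SEGREGATED: (1.09, 0.54), GROUP_INTEGRATED: (0.85, 0.16)},
    "blood_urea_nitrogen": {"kind": "lognormal", GROUP_SEGREGATED: (21.67, 14.13), GROUP_INTEGRATED: (49.80, 36.30)},
    "creatinine": {"kind": "lognormal", GROUP_SEGREGATED: (1.09, 1.00), GROUP_INTEGRATED: (2.23, 3.20)},
    "aspartate_transaminase": {"kind": "lognormal", GROUP_SEGREGATED: (38.24, 51.56), GROUP_INTEGRATED: (123.18, 230.53)},
}

#: Binary clinical covariates (all others are continuous).
CLINICAL_BINARY = ("sex_female", "chronic_liver_disease")


def clinical_defaults() -> dict[str, dict]:
    """Per-variable generator parameters for the clinical covariate table."""
    return {k: dict(v) for k, v in _CLINICAL_DEFAULTS.items()}


def _draw_clinical(rng: np.random.Generator, spec: dict, group: str) -> float:
    if spec["kind"] == "bernoulli":
        return float(rng.random() < spec[group])
    m, s = spec[group]
    if spec["kind"] == "gaussian":
        return float(np.clip(rng.normal(m, s), 18.0, 105.0))
    # moment-matched log-normal keeps laboratory values strictly positive
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def generate_clinical(
    config: CohortConfig,
    *,
    clinical_params: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Clinical covariate table alone (no EEG), one row per subject.

    Uses the same per-subject seed derivation as :func:`generate_cohort`,
    so the table matches the one returned there.
    """
    params = clinical_params or _CLINICAL_DEFAULTS
    rows = []
    for group in _GROUPS:
        for i in range(config.n_per_group):
            crng = np.random.default_rng(
                np.random.SeedSequence([config.seed, _GROUPS.index(group), i, 7])
            )
            row = {"subject_id": f"{group}_{i:03d}", "group_label": group}
            for name, spec in params.items():
                row[name] = _draw_clinical(crng, spec, group)
            rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def generate_cohort(
    config: CohortConfig,
    *,
    clinical_params: dict[str, dict] | None = None,
) -> tuple[list[EEGRecording], pd.DataFrame]:
    """Generate the full two-group cohort.

    Returns ``n_per_group`` recordings per archetype plus a clinical
    covariate table (one row per subject) whose group means are shifted in
    the clinically expected direction: the integrated (encephalopathy-like)
    group older, more often female, with lower platelets and magnesium and
    higher blood urea nitrogen, creatinine and aspartate transaminase.

    The whole cohort is a pure function of ``config`` (byte-for-byte
    reproducible); per-subject seeds are derived from the master seed so the
    cohort is extensible without perturbing existing subjects.
    """
    recordings = [
        generate_subject(config, group, i)
        for group in _GROUPS
        for i in range(config.n_per_group)
    ]
    clinical = generate_clinical(config, clinical_params=clinical_params)
    return recordings, clinical
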