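"""Synthetic EEG with known event-related amplitude modulation.

The generator produces three-channel recordings (C3, C4, bipolar EOG) in
which narrow-band alpha (8-14 Hz) and beta (15-30 Hz) Mu-rhythm carriers are
amplitude-modulated around each movement onset: a Gaussian suppression bump
(event-related desynchronization, ERD) centred near the onset and a Gaussian
rebound bump (event-related synchronization, ERS) after it.  Because the
modulation is an explicit multiplicative gain

    g(t) = 1 - d * sum_k exp(-(t - t_k - t_erd)^2 / (2 sigma_erd^2))
             + r * sum_k exp(-(t - t_k - t_ers)^2 / (2 sigma_ers^2))

(clipped below at 0.05), the amplitude response of the averaged envelope has
a closed form when the bumps of neighbouring movements do not overlap:
Amp_min = A(1-d), Amp_max = A(1+r), hence

    PAmp_resp = 100 * ((1+r) - (1-d)) / (((1+r) + (1-d)) / 2)
              = 200 (d + r) / (2 + r - d)   [percent].

Every recording is paired with a :class:`SimulationGroundTruth` carrying the
true modulation parameters and these expected values, so each downstream
stage can be verified without any recorded data.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .envelope import BANDS
from .recording import Recording, RecordingMeta

__all__ = [
    "ModulationParams",
    "Scenario",
    "SimulationGroundTruth",
    "expected_pamp_resp",
    "expected_pamp_numeric",
    "simulate_triggers",
    "simulate_mu_carrier",
    "modulation_gain",
    "pink_noise",
    "blink_train",
    "simulate_recording",
]

#: Hard floor for the modulation gain (keeps the envelope strictly positive).
GAIN_FLOOR = 0.05

#: Minimum allowed gap between successive movement onsets (s).
MIN_GAP = 0.2


@dataclass
class ModulationParams:
    """True event-related modulation of one band on the contralateral channel.

    Parameters
    ----------
    band : {"alpha", "beta"}
    a_base : float
        Baseline envelope amplitude in µV.
    depth : float
        ERD depth d in [0, 1): fractional suppression at the trough.
    rebound : float
        ERS gain r >= 0: fractional enhancement at the rebound peak.
    t_erd, sigma_erd : float
        Centre (s, relative to movement onset) and width of the suppression
        bump.  Suppression builds up before the onset and is deepest around
        it, so the default centre is 0 s.  The default widths keep the two
        bumps separated to within <1 % overlap, so the closed-form expected
        PAmp_resp is exact.
    t_ers, sigma_ers : float
        Centre and width of the post-movement rebound bump (default 1.0 s
        after onset, i.e. 0.7-1 s after a brief finger lift ends).
    lat : float
        Laterality factor: the ipsilateral channel uses (lat*depth,
        lat*rebound).  lat = 1 gives a symmetric response (LI = 0); lat < 1
        gives contralateral dominance (LI > 0).
    """

    band: str = "alpha"
    a_base: float = 15.0
    depth: float = 0.4
    rebound: float = 0.2
    t_erd: float = 0.0
    sigma_erd: float = 0.3
    t_ers: float = 1.0
    sigma_ers: float = 0.25
    lat: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.depth < 1:
            raise ValueError(f"ERD depth must be in [0, 1), got {self.depth}")
        if self.rebound < 0:
            raise ValueError(f"rebound gain must be >= 0, got {self.rebound}")
        if self.sigma_erd <= 0 or self.sigma_ers <= 0:
            raise ValueError("bump widths must be positive")
        if self.a_base <= 0:
            raise ValueError("baseline amplitude must be positive")

    def for_role(self, role: str) -> "ModulationParams":
        """Effective parameters on the contralateral or ipsilateral channel."""
        if role == "contra":
            return self
        if role == "ipsi":
            out = copy.copy(self)
            out.depth = self.lat * self.depth
            out.rebound = self.lat * self.rebound
            return out
        raise ValueError(f"role must be 'contra' or 'ipsi', got {role!r}")


def expected_pamp_resp(depth: float, rebound: float) -> float:
    """Closed-form expected PAmp_resp (%) for well-separated bumps.

    ``200 (d + r) / (2 + r - d)``; exact when the gain extrema within the
    extremum-search windows are 1 - d and 1 + r.
    """
    return 200.0 * (depth + rebound) / (2.0 + rebound - depth)


def simulate_triggers(
    imi: float,
    jitter_sd: float,
    n: int,
    outlier_rate: float = 0.0,
    outlier_shift: float = 0.8,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    t0: float = 3.0,
) -> np.ndarray:
    """Movement-onset times around a designated inter-movement interval.

    Successive onset-to-onset differences are ``imi + N(0, jitter_sd)``; a
    fraction ``outlier_rate`` of them is additionally shifted by
    ``+/- outlier_shift`` (sign equiprobable) to emulate mistimed movements
    and exercise the timing-retention filter.  Gaps are clamped at 0.2 s.

    Returns strictly increasing onset times (s), the first at ``t0``.
    """
    if imi <= 0:
        raise ValueError(f"designated IMI must be positive, got {imi}")
    if n < 2:
        raise ValueError(f"need at least 2 movements, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    gaps = imi + rng.normal(0.0, jitter_sd, size=n - 1)
    if outlier_rate > 0:
        hit = rng.random(n - 1) < outlier_rate
        sign = rng.choice([-1.0, 1.0], size=n - 1)
        gaps = gaps + hit * sign * outlier_shift
    gaps = np.maximum(gaps, MIN_GAP)
    triggers = t0 + np.concatenate([[0.0], np.cumsum(gaps)])
    if np.any(np.diff(triggers) <= 0):
        raise ValueError("trigger generation produced non-increasing onsets")
    return triggers


def _fm_carrier(
    low: float, high: float, fs: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Constant-envelope carrier whose instantaneous frequency wanders in-band."""
    bw = high - low
    center = 0.5 * (low + high)
    # slow (< ~0.5 Hz) frequency wander, kept off the band edges
    wander = rng.standard_normal(n)
    sos = scipy.signal.butter(2, 0.5, btype="lowpass", fs=fs, output="sos")
    wander = scipy.signal.sosfiltfilt(sos, wander)
    sd = wander.std()
    if sd > 0:
        wander = wander / sd
    # stay on the flat part of the analysis band-pass (the outer ~25 % of the
    # band sits on the filter skirt and would compress the AM depth)
    inst_freq = center + 0.25 * bw * np.clip(wander, -1.0, 1.0)
    phase = 2 * np.pi * np.cumsum(inst_freq) / fs + rng.uniform(0, 2 * np.pi)
    return np.cos(phase)


def simulate_mu_carrier(
    band: str,
    fs: float,
    duration: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    kind: str = "fm",
) -> np.ndarray:
    """Unit-envelope narrow-band carrier for one Mu-rhythm sub-band.

    Kinds
    -----
    ``fm`` (default)
        Constant-envelope cosine whose instantaneous frequency performs a
        slow, clipped random walk inside the band.  Its Hilbert envelope is
        1 everywhere, which makes amplitude-modulation ground truth exact.
    ``tone``
        Pure sinusoid at the band centre.
    ``narrowband_noise``
        Band-pass-filtered Gaussian noise, normalized to unit mean Hilbert
        envelope.  Reproduces the Rayleigh-like envelope fluctuation of real
        Mu rhythm.

    All kinds are zero-mean with >= 90 % of spectral power inside the band
    and long-run mean Hilbert envelope 1.
    """
    if band not in BANDS:
        raise KeyError(f"unknown band {band!r}; known: {sorted(BANDS)}")
    low, high = BANDS[band]
    if fs < 4 * high:
        raise ValueError(f"fs={fs} too low for band {band} (need >= {4 * high})")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    if kind == "tone":
        t = np.arange(n) / fs
        return np.sin(2 * np.pi * 0.5 * (low + high) * t)
    if kind == "fm":
        return _fm_carrier(low, high, fs, n, rng)
    if kind == "narrowband_noise":
        white = rng.standard_normal(n)
        sos = scipy.signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
        x = scipy.signal.sosfiltfilt(sos, white)
        env_mean = np.abs(scipy.signal.hilbert(x)).mean()
        return x / env_mean
    raise ValueError(f"unknown carrier kind {kind!r}")


def modulation_gain(
    params: ModulationParams, triggers: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Multiplicative envelope gain g(t) for a train of movement onsets.

    Sum of a negative ERD Gaussian and a positive ERS Gaussian per onset,
    clipped below at 0.05 so the envelope stays positive.
    """
    t = np.asarray(t, dtype=float)
    g = np.ones_like(t)
    dt = t[1] - t[0] if t.size > 1 else 1.0
    for center, sigma, amp in (
        (params.t_erd, params.sigma_erd, -params.depth),
        (params.t_ers, params.sigma_ers, params.rebound),
    ):
        if amp == 0.0:
            continue
        half = 5.0 * sigma
        for tk in np.asarray(triggers, dtype=float):
            c = tk + center
            i0 = max(0, int(np.floor((c - half - t[0]) / dt)))
            i1 = min(t.size, int(np.ceil((c + half - t[0]) / dt)) + 1)
            if i0 >= i1:
                continue
            seg = t[i0:i1] - c
            g[i0:i1] += amp * np.exp(-(seg**2) / (2 * sigma**2))
    return np.clip(g, GAIN_FLOOR, None)


def expected_pamp_numeric(
    params: ModulationParams,
    triggers: np.ndarray,
    fs: float,
    duration: float,
    window: tuple[float, float] = (-1.5, 2.0),
    pre_window: tuple[float, float] = (-1.5, 0.0),
    post_window: tuple[float, float] = (0.0, 2.0),
) -> float:
    """Expected PAmp_resp (%) from the realized gain trace.

    Averages g(t) over the movement-anchored windows that fit in the
    recording and reads the extrema off the mean trace — the ground truth
    when neighbouring bumps overlap (fast movement rates), where the
    closed form no longer applies.
    """
    t = np.arange(int(round(duration * fs))) / fs
    g = modulation_gain(params, triggers, t)
    n_samp = int(round((window[1] - window[0]) * fs))
    segs = []
    for tk in triggers:
        i0 = int(round((tk + window[0]) * fs))
        if i0 < 0 or i0 + n_samp > t.size:
            continue
        segs.append(g[i0 : i0 + n_samp])
    if not segs:
        raise ValueError("no movement window fits inside the recording")
    mean = np.mean(segs, axis=0)
    rel = window[0] + np.arange(n_samp) / fs
    pre = (rel >= pre_window[0]) & (rel < pre_window[1])
    post = (rel >= post_window[0]) & (rel < post_window[1])
    amp_min = mean[pre].min()
    amp_max = mean[post].max()
    return 100.0 * (amp_max - amp_min) / ((amp_max + amp_min) / 2.0)


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-power background noise, standardized to zero mean and unit sd."""
    if n < 2:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    spectrum = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spectrum, n=n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _blink_waveform(fs: float) -> np.ndarray:
    """Smooth biphasic blink deflection (difference of two Gaussians, ~0.25 s),
    normalized to unit peak."""
    tt = np.arange(-0.5, 0.5, 1.0 / fs)
    w = np.exp(-(tt**2) / (2 * 0.08**2)) - 0.6 * np.exp(-(tt**2) / (2 * 0.16**2))
    return w / np.abs(w).max()


def blink_train(
    duration: float,
    fs: float,
    rate: float,
    peak_range: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson train of blink deflections (µV) on the EOG channel."""
    n = int(round(duration * fs))
    out = np.zeros(n)
    if rate <= 0:
        return out
    n_blinks = rng.poisson(rate * duration)
    wave = _blink_waveform(fs)
    half = wave.size // 2
    for _ in range(n_blinks):
        center = int(rng.uniform(0, n))
        peak = rng.uniform(*peak_range)
        i0, i1 = center - half, center - half + wave.size
        w0, w1 = max(0, -i0), wave.size - max(0, i1 - n)
        i0, i1 = max(0, i0), min(n, i1)
        if i0 < i1:
            out[i0:i1] += peak * wave[w0:w1]
    return out


@dataclass
class Scenario:
    """Configuration of one synthetic recording.

    Defaults follow the study conditions: ~1 kHz sampling, designated IMI of
    3/2/1 s (default 2 s), realized inter-movement jitter of 0.06 s (the
    healthy-subject range), alpha baseline 15 µV and beta baseline 6 µV with
    5 µV background noise, and blink artifacts on the EOG channel whose
    peaks straddle the 300 µV rejection threshold.
    """

    subject: str = "S01"
    hand: str = "right"
    hand_status: str = "healthy"
    imi: float = 2.0
    n_triggers: int = 70
    fs: float = 1000.0
    jitter_sd: float = 0.06
    outlier_rate: float = 0.0
    outlier_shift: float = 0.8
    carrier: str = "fm"
    noise_sd: float = 5.0
    line_amp: float = 0.0
    line_freq: float = 60.0
    blink_rate: float = 0.15
    blink_peak: tuple[float, float] = (100.0, 350.0)
    eog_noise_sd: float = 10.0
    t0: float = 3.0
    tail: float = 3.0
    bands: dict[str, ModulationParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.bands:
            self.bands = {
                "alpha": ModulationParams(band="alpha", a_base=15.0),
                "beta": ModulationParams(band="beta", a_base=6.0),
            }
        for name, mp in self.bands.items():
            if name not in BANDS:
                raise ValueError(f"unknown band {name!r} in scenario")
            if mp.band != name:
                raise ValueError(f"band key {name!r} does not match params.band {mp.band!r}")

    @classmethod
    def from_dict(cls, cfg: dict) -> "Scenario":
        cfg = dict(cfg)
        bands = cfg.pop("bands", None)
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        if "blink_peak" in cfg:
            cfg["blink_peak"] = tuple(cfg["blink_peak"])
        sc = cls(**cfg)
        if bands:
            sc.bands = {
                name: ModulationParams(**{"band": name, **dict(bp)})
                for name, bp in bands.items()
            }
            sc.__post_init__()
        return sc


@dataclass
class SimulationGroundTruth:
    """True modulation parameters and analytic expectations of one recording.

    ``expected_pamp`` maps (channel, band) to the expected PAmp_resp in
    percent; ``expected_li`` maps band to the expected laterality index.
    Expectations use the closed form when the designated IMI leaves the
    ERD/ERS bumps separated (IMI >= 2 s) and the numeric gain-trace average
    otherwise.
    """

    scenario: Scenario
    seed: int | None
    params: dict[tuple[str, str], ModulationParams]
    expected_pamp: dict[tuple[str, str], float]
    expected_li: dict[str, float]
    jitter_sd: float


def _role_of(channel: str, hand: str) -> str:
    contra = "C3" if hand == "right" else "C4"
    return "contra" if channel == contra else "ipsi"


def simulate_recording(
    scenario: Scenario, seed: int | None = None
) -> tuple[Recording, SimulationGroundTruth]:
    """Generate one synthetic recording plus its ground truth.

    C3/C4 are sums over bands of ``a_base * g(t) * carrier(t)`` plus pink
    background noise and an optional power-line tone; the EOG channel
    carries blink deflections plus noise.  The ipsilateral channel's
    modulation is scaled by each band's laterality factor.  All randomness
    flows from one seeded generator, so identical (scenario, seed) pairs
    give bit-identical recordings.
    """
    rng = np.random.default_rng(seed)
    triggers = simulate_triggers(
        scenario.imi,
        scenario.jitter_sd,
        scenario.n_triggers,
        outlier_rate=scenario.outlier_rate,
        outlier_shift=scenario.outlier_shift,
        rng=rng,
        t0=scenario.t0,
    )
    duration = triggers[-1] + scenario.tail
    n = int(round(duration * scenario.fs))
    t = np.arange(n) / scenario.fs

    params: dict[tuple[str, str], ModulationParams] = {}
    expected: dict[tuple[str, str], float] = {}
    data = []
    for channel in ("C3", "C4"):
        role = _role_of(channel, scenario.hand)
        sig = np.zeros(n)
        for band, mp in scenario.bands.items():
            eff = mp.for_role(role)
            params[(channel, band)] = eff
            gain = modulation_gain(eff, triggers, t)
            carrier = simulate_mu_carrier(
                band, scenario.fs, duration, rng=rng, kind=scenario.carrier
            )[:n]
            sig += eff.a_base * gain * carrier
            if scenario.imi >= 2.0:
                expected[(channel, band)] = expected_pamp_resp(eff.depth, eff.rebound)
            else:
                expected[(channel, band)] = expected_pamp_numeric(
                    eff, triggers, scenario.fs, duration
                )
        if scenario.noise_sd > 0:
            sig += scenario.noise_sd * pink_noise(n, rng)
        if scenario.line_amp > 0:
            sig += scenario.line_amp * np.sin(2 * np.pi * scenario.line_freq * t)
        data.append(sig)

    eog = blink_train(duration, scenario.fs, scenario.blink_rate, scenario.blink_peak, rng)
    if scenario.eog_noise_sd > 0:
        eog += scenario.eog_noise_sd * pink_noise(n, rng)
    data.append(eog)

    contra_ch = "C3" if scenario.hand == "right" else "C4"
    ipsi_ch = "C4" if scenario.hand == "right" else "C3"
    expected_li = {}
    for band in scenario.bands:
        pc = expected[(contra_ch, band)]
        pi = expected[(ipsi_ch, band)]
        expected_li[band] = (pc - pi) / (pc + pi) if (pc + pi) > 0 else np.nan

    rec = Recording(
        channels=["C3", "C4", "EOG"],
        fs=scenario.fs,
        data=np.vstack(data),
        triggers=triggers,
        meta=RecordingMeta(
            subject=scenario.subject,
            hand=scenario.hand,
            hand_status=scenario.hand_status,
            imi=scenario.imi,
        ),
    )
    truth = SimulationGroundTruth(
        scenario=scenario,
        seed=seed,
        params=params,
        expected_pamp=expected,
        expected_li=expected_li,
        jitter_sd=scenario.jitter_sd,
    )
    return rec, truth
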