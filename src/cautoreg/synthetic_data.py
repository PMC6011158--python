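"""Synthetic paired ABP/CBFV recordings with known ground truth.

The generator emulates the statistical structure of low-variability
baseline recordings and of the bed-tilting intervention: a mean pressure
level with small spontaneous oscillations (slow sinusoids, respiratory
and cardiac components, 1/f noise) whose post-filter coefficient of
variation is calibrated to a target, plus — for the intervention — a
trapezoidal tilt-protocol pressure perturbation and amplified slow
oscillations raising the CV to a higher target.  The flow channel is the
pressure channel passed through a configurable linear frequency-domain
autoregulation model (band gain and phase) plus independent colored
noise; the realized band responses are stored as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy import signal as sps

from cautoreg.preprocess import lowpass_zero_phase
from cautoreg.signal_io import SignalRecord

__all__ = [
    "TiltProtocol",
    "AutoregModel",
    "SyntheticConfig",
    "generate_tilt_wave",
    "count_plateaus",
    "tilt_pressure_wave",
    "generate_abp",
    "generate_cbfv",
    "generate_record",
    "generate_cohort",
    "CohortRecord",
]


@dataclass
class TiltProtocol:
    """Repeated Trendelenburg / anti-Trendelenburg bed-tilt cycles."""

    n_cycles: int = 3
    transition_s: float = 15.0
    hold_s: float = 45.0
    angle_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.transition_s <= 0 or self.hold_s <= 0:
            raise ValueError("transition_s and hold_s must be positive")

    @property
    def cycle_s(self) -> float:
        return 2.0 * (self.transition_s + self.hold_s)

    @property
    def total_s(self) -> float:
        return self.n_cycles * self.cycle_s


@dataclass
class AutoregModel:
    """Linear MAP->MFV model: gain ((cm/s)/mmHg) and phase (deg) per band.

    The impaired (pressure-passive) ground truth is a flat gain of
    ``mean_mfv / mean_map`` with zero phase; the intact ground truth has
    reduced VLF gain and a phase lead, following the qualitative pattern
    of working autoregulation (higher phase and lower gain in VLF than
    in LF).
    """

    gain_vlf: float = 0.6
    gain_lf: float = 0.9
    phase_vlf_deg: float = 50.0
    phase_lf_deg: float = 20.0
    impaired: bool = False
    noise_cv: float = 3.0

    def __post_init__(self) -> None:
        if self.gain_vlf <= 0 or self.gain_lf <= 0:
            raise ValueError("band gains must be positive")
        for p in (self.phase_vlf_deg, self.phase_lf_deg):
            if not abs(p) < 180:
                raise ValueError("band phases must satisfy |phase| < 180 deg")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @classmethod
    def intact(cls, noise_cv: float = 3.0) -> "AutoregModel":
        return cls(noise_cv=noise_cv)

    @classmethod
    def pressure_passive(
        cls, mean_map: float, mean_mfv: float, noise_cv: float = 3.0
    ) -> "AutoregModel":
        g = mean_mfv / mean_map
        return cls(
            gain_vlf=g, gain_lf=g, phase_vlf_deg=0.0, phase_lf_deg=0.0,
            impaired=True, noise_cv=noise_cv,
        )

    def frequency_response(self, freqs: np.ndarray) -> np.ndarray:
        """Complex response interpolated through band anchor points.

        Positive phase = flow leads pressure.  Phase is pinned to zero at
        DC and above 0.5 Hz so the impulse response stays real and the
        cardiac band passes without artificial lead.
        """
        freqs = np.asarray(freqs, dtype=float)
        nyq = float(freqs.max()) if len(freqs) else 1.0
        g_mid = 0.5 * (self.gain_vlf + self.gain_lf)
        p_mid = 0.5 * (self.phase_vlf_deg + self.phase_lf_deg)
        f_pts = [0.0, 0.02, 0.045, 0.07, 0.135, 0.2, 0.5]
        g_pts = [self.gain_vlf, self.gain_vlf, self.gain_vlf, g_mid,
                 self.gain_lf, self.gain_lf, self.gain_lf]
        p_pts = [0.0, self.phase_vlf_deg, self.phase_vlf_deg, p_mid,
                 self.phase_lf_deg, self.phase_lf_deg, 0.0]
        if nyq > 0.5:
            f_pts.append(nyq)
            g_pts.append(self.gain_lf)
            p_pts.append(0.0)
        gain = np.interp(freqs, f_pts, g_pts)
        phase = np.radians(np.interp(freqs, f_pts, p_pts))
        return gain * np.exp(1j * phase)

    def realized_band_response(
        self, bands: dict[str, tuple[float, float]], df: float = 0.01
    ) -> dict[str, dict[str, float]]:
        """Band-averaged gain/phase of the response on a df-spaced grid."""
        out = {}
        for name, (lo, hi) in bands.items():
            f = np.arange(np.ceil(lo / df), np.ceil(hi / df)) * df
            H = self.frequency_response(f)
            out[name] = {
                "gain": float(np.abs(H).mean()),
                "phase_deg": float(np.degrees(np.angle(H)).mean()),
            }
        return out


@dataclass
class SyntheticConfig:
    """Full parameterization of the paired-recording generator."""

    mean_map: float = 90.0
    mean_mfv: float = 50.0
    baseline_cv_target: float = 3.056
    intervention_cv_target: float = 8.238
    #: spontaneous slow oscillations as (freq_hz, amplitude_mmHg, phase_rad)
    oscillations: tuple[tuple[float, float, float], ...] = (
        (0.03, 1.0, 0.0),
        (0.1, 0.7, 1.1),
    )
    respiratory_hz: float = 0.25
    respiratory_amp: float = 0.5
    cardiac_hz: float = 1.0
    cardiac_amp: float = 10.0
    pink_noise_amp: float = 0.5
    tilt: TiltProtocol = field(default_factory=TiltProtocol)
    tilt_gain_mmhg_per_deg: float = 0.25
    tilt_lag_s: float = 5.0
    model: AutoregModel = field(default_factory=AutoregModel)
    fs: float = 200.0
    duration_s: float = 360.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f, a, _ in self.oscillations:
            if a < 0 or f <= 0:
                raise ValueError("oscillation amplitudes must be >= 0, freqs > 0")
        if min(self.respiratory_amp, self.cardiac_amp, self.pink_noise_amp) < 0:
            raise ValueError("component amplitudes must be >= 0")
        if self.mean_map <= 0 or self.mean_mfv <= 0:
            raise ValueError("mean levels must be positive")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")


BANDS = {"vlf": (0.02, 0.07), "lf": (0.07, 0.2)}


def generate_tilt_wave(protocol: TiltProtocol, fs: float) -> np.ndarray:
    """Trapezoidal bed-angle trace in degrees over the protocol duration.

    Each cycle holds the Trendelenburg angle (-angle_deg), ramps linearly
    to +angle_deg over transition_s, holds, and ramps back; plateaus are
    exact constants so plateau runs can be counted by equality.
    """
    a = protocol.angle_deg
    hold_n = round(protocol.hold_s * fs)
    trans_n = round(protocol.transition_s * fs)
    up = -a + (np.arange(trans_n) / trans_n) * 2 * a
    down = a - (np.arange(trans_n) / trans_n) * 2 * a
    cycle = np.concatenate([np.full(hold_n, -a), up, np.full(hold_n, a), down])
    return np.tile(cycle, protocol.n_cycles)


def count_plateaus(wave: np.ndarray, value: float) -> int:
    """Number of maximal constant runs where the trace equals ``value``."""
    at = np.asarray(wave) == value
    starts = at & ~np.concatenate([[False], at[:-1]])
    return int(starts.sum())


def tilt_pressure_wave(
    protocol: TiltProtocol,
    fs: float,
    n_samples: int,
    gain_mmhg_per_deg: float = 0.25,
    lag_s: float = 5.0,
) -> np.ndarray:
    """Zero-mean pressure perturbation driven by the tilt angle.

    The angle trace (tiled cyclically to cover ``n_samples``) is scaled
    by ``gain_mmhg_per_deg`` and passed through a first-order lag
    modelling the sluggish hemodynamic response to posture change.
    """
    wave = generate_tilt_wave(protocol, fs)
    reps = int(np.ceil(n_samples / len(wave)))
    x = np.tile(wave, reps)[:n_samples] * gain_mmhg_per_deg
    dt = 1.0 / fs
    alpha = dt / (lag_s + dt)
    zi = sps.lfiltic([alpha], [1.0, alpha - 1.0], [x[0]], [x[0]])
    y, _ = sps.lfilter([alpha], [1.0, alpha - 1.0], x, zi=zi)
    return y - y.mean()


def _pink_noise(n: int, rng: np.random.Generator, f_floor: float, fs: float) -> np.ndarray:
    """Unit-SD 1/f (amplitude ~ f^-1/2) noise, flat below f_floor."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, f_floor))
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _components(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    n = round(config.duration_s * config.fs)
    t = np.arange(n) / config.fs
    fluct = np.zeros(n)
    for f, amp, ph in config.oscillations:
        fluct += amp * np.sin(2 * np.pi * f * t + ph)
    fluct += config.respiratory_amp * np.sin(2 * np.pi * config.respiratory_hz * t)
    fluct += config.cardiac_amp * np.sin(2 * np.pi * config.cardiac_hz * t)
    if config.pink_noise_amp > 0:
        fluct += config.pink_noise_amp * _pink_noise(n, rng, 0.01, config.fs)
    return fluct


def _scale_for_cv(
    fluct: np.ndarray, mean_level: float, cv_target: float, fs: float
) -> np.ndarray:
    """Scale a zero-mean-ish fluctuation so the post-filter CV hits target."""
    ff = lowpass_zero_phase(fluct, fs)
    sd = ff.std()
    if sd == 0:
        return fluct
    # CV(s) = 100 * s * sd / (mean + s * mean(ff)); solve for s exactly
    s = cv_target * mean_level / (100.0 * sd - cv_target * ff.mean())
    scaled = fluct * s
    if np.max(np.abs(scaled)) >= mean_level:
        raise ValueError(
            f"CV target {cv_target}% unattainable: fluctuation amplitude "
            f"would exceed the mean level {mean_level}"
        )
    return scaled


def generate_abp(
    config: SyntheticConfig,
    condition: str = "baseline",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Synthesize one ABP channel for the given condition.

    Baseline: mean level plus spontaneous components scaled so the
    post-filter CV equals ``baseline_cv_target``.  Intervention: the
    baseline signal plus a tilt-driven perturbation and amplified slow
    oscillations, jointly scaled so the post-filter CV equals
    ``intervention_cv_target``.
    """
    if condition not in ("baseline", "intervention"):
        raise ValueError(f"unknown condition {condition!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = round(config.duration_s * config.fs)
    t = np.arange(n) / config.fs

    base_fluct = _scale_for_cv(
        _components(config, rng), config.mean_map, config.baseline_cv_target, config.fs
    )
    if condition == "baseline":
        return config.mean_map + base_fluct

    perturb = tilt_pressure_wave(
        config.tilt, config.fs, n, config.tilt_gain_mmhg_per_deg, config.tilt_lag_s
    )
    # amplified slow oscillations accompanying the tilt maneuver
    perturb = perturb + np.sin(2 * np.pi * 0.03 * t + 0.4) + np.sin(2 * np.pi * 0.05 * t)

    fb = lowpass_zero_phase(base_fluct, config.fs)
    fp = lowpass_zero_phase(perturb, config.fs)

    def cv_at(s: float) -> float:
        total = config.mean_map + fb + s * fp
        return 100.0 * total.std() / total.mean()

    target = config.intervention_cv_target
    if cv_at(0.0) >= target:
        raise ValueError(
            "intervention CV target must exceed the baseline CV actually realized"
        )
    s_hi = 1.0
    while cv_at(s_hi) < target:
        s_hi *= 2.0
        if s_hi > 1e6:
            raise ValueError("intervention CV target unattainable")
    s = optimize.brentq(lambda v: cv_at(v) - target, 0.0, s_hi, xtol=1e-10)
    scaled = base_fluct + s * perturb
    if np.max(np.abs(scaled)) >= config.mean_map:
        raise ValueError("intervention CV target unattainable: amplitude exceeds mean")
    return config.mean_map + scaled


def generate_cbfv(
    abp: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Flow channel from a pressure channel via the autoregulation model.

    Returns the CBFV trace and a ground-truth dict with the realized
    band-averaged gain and phase of the applied frequency response.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    abp = np.asarray(abp, dtype=float)
    n = len(abp)
    fluct = abp - abp.mean()
    freqs = np.fft.rfftfreq(n, 1.0 / config.fs)
    H = config.model.frequency_response(freqs)
    mfv_fluct = np.fft.irfft(np.fft.rfft(fluct) * H, n)
    cbfv = config.mean_mfv + mfv_fluct
    if config.model.noise_cv > 0:
        noise = _pink_noise(n, rng, 0.01, config.fs)
        filt = lowpass_zero_phase(noise, config.fs)
        sd = filt.std()
        if sd > 0:
            target_sd = config.model.noise_cv / 100.0 * config.mean_mfv
            cbfv = cbfv + noise * (target_sd / sd)
    truth = {
        "model": {
            "gain_vlf": config.model.gain_vlf,
            "gain_lf": config.model.gain_lf,
            "phase_vlf_deg": config.model.phase_vlf_deg,
            "phase_lf_deg": config.model.phase_lf_deg,
            "impaired": config.model.impaired,
            "noise_cv": config.model.noise_cv,
        },
        "realized_bands": config.model.realized_band_response(BANDS),
    }
    return cbfv, truth


def generate_record(
    config: SyntheticConfig,
    condition: str = "baseline",
    meta: dict | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SignalRecord, dict]:
    """One complete synthetic recording plus its ground truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    abp = generate_abp(config, condition, rng)
    cbfv, truth = generate_cbfv(abp, config, rng)
    n = len(abp)
    full_meta = {"condition": condition, "seed": str(config.seed)}
    if meta:
        full_meta.update(meta)
    record = SignalRecord(
        time_s=np.arange(n) / config.fs,
        abp=abp,
        cbfv=cbfv,
        fs=config.fs,
        meta=full_meta,
    )
    truth = dict(truth, condition=condition)
    return record, truth


@dataclass
class CohortRecord:
    subject: int
    timepoint: int
    condition: str
    record: SignalRecord
    ground_truth: dict


def generate_cohort(
    n_subjects: int = 13,
    n_timepoints: int = 4,
    mix: float = 0.5,
    seed: int = 0,
    config: SyntheticConfig | None = None,
) -> list[CohortRecord]:
    """Paired baseline/intervention recordings for a synthetic cohort.

    Each subject draws an intact or pressure-passive autoregulation model
    (probability ``mix`` of impaired) shared across all of that subject's
    recordings; every subject x timepoint contributes one baseline and
    one intervention record.  Fully reproducible per seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0 <= mix <= 1:
        raise ValueError("mix must be in [0, 1]")
    if config is None:
        config = SyntheticConfig()
    ss = np.random.SeedSequence(seed)
    assign_rng = np.random.default_rng(ss.spawn(1)[0])
    impaired_flags = assign_rng.random(n_subjects) < mix
    out: list[CohortRecord] = []
    for subj in range(n_subjects):
        if impaired_flags[subj]:
            model = AutoregModel.pressure_passive(
                config.mean_map, config.mean_mfv, noise_cv=config.model.noise_cv
            )
        else:
            model = replace(config.model, impaired=False)
        subj_config = replace(config, model=model)
        for tp in range(n_timepoints):
            for condition in ("baseline", "intervention"):
                child = np.random.default_rng(
                    np.random.SeedSequence(
                        entropy=seed,
                        spawn_key=(subj + 1, tp + 1, 0 if condition == "baseline" else 1),
                    )
                )
                record, truth = generate_record(
                    subj_config,
                    condition,
                    meta={"subject": str(subj), "timepoint": str(tp)},
                    rng=child,
                )
                out.append(
                    CohortRecord(
                        subject=subj,
                        timepoint=tp,
                        condition=condition,
                        record=record,
                        ground_truth=truth,
                    )
                )
    return out
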