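"""Time- and frequency-domain variability measures for MAP and MFV."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cautoreg.tfa import TfaSettings, band_average, welch_spectra

__all__ = ["VariabilityResult", "coefficient_of_variation", "band_power", "compute_variability"]

VLF_BAND = (0.02, 0.07)
LF_BAND = (0.07, 0.2)


@dataclass
class VariabilityResult:
    cv_map: float
    cv_mfv: float
    power_map_vlf: float
    power_map_lf: float
    power_mfv_vlf: float
    power_mfv_lf: float


def coefficient_of_variation(x: np.ndarray) -> float:
    """SD/mean of the signal, in percent of the mean.

    Population SD (divisor n); undefined and an error for signals with a
    non-positive mean, since the physiological channels are positive.
    """
    x = np.asarray(x, dtype=float)
    mean = x.mean()
    if mean <= 0:
        raise ValueError(f"CV undefined for non-positive mean ({mean:g})")
    return float(100.0 * x.std(ddof=0) / mean)


def band_power(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    settings: TfaSettings | None = None,
) -> float:
    """Average one-sided spectral power density over a frequency band.

    Uses the same Welch windowing as the transfer-function pipeline
    (100-s Hanning windows, 50% overlap, triangular smoothing); bins are
    assigned to the band by center frequency, half-open ``[f_lo, f_hi)``.
    """
    f_lo, f_hi = band
    if not (0 <= f_lo < f_hi <= fs / 2):
        raise ValueError(f"band [{f_lo}, {f_hi}) outside (0, fs/2]")
    if settings is None:
        settings = TfaSettings(fs=fs)
    elif abs(settings.fs - fs) > 1e-12:
        raise ValueError("settings.fs disagrees with fs")
    Sxx, _, _, freqs, _ = welch_spectra(x, x, settings)
    return band_average(Sxx, freqs, band)


def compute_variability(
    map_sig: np.ndarray,
    mfv_sig: np.ndarray,
    fs: float,
    vlf: tuple[float, float] = VLF_BAND,
    lf: tuple[float, float] = LF_BAND,
) -> VariabilityResult:
    """CV and VLF/LF band powers for a pair of filtered MAP/MFV signals."""
    settings = TfaSettings(fs=fs)
    return VariabilityResult(
        cv_map=coefficient_of_variation(map_sig),
        cv_mfv=coefficient_of_variation(mfv_sig),
        power_map_vlf=band_power(map_sig, fs, vlf, settings),
        power_map_lf=band_power(map_sig, fs, lf, settings),
        power_mfv_vlf=band_power(mfv_sig, fs, vlf, settings),
        power_mfv_lf=band_power(mfv_sig, fs, lf, settings),
    )
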