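"""Waveform conditioning: zero-phase low-pass filtering, segment extraction,
band-limited resampling, and construction of analysis-ready MAP/MFV segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from cautoreg.signal_io import SegmentSelection, SignalRecord

__all__ = [
    "Segment",
    "lowpass_zero_phase",
    "extract_segment",
    "resample_uniform",
    "make_segment",
]

DEFAULT_CUTOFF_HZ = 0.5
DEFAULT_ORDER = 3
DEFAULT_TFA_FS = 10.0
DEFAULT_SEGMENT_S = 300.0


@dataclass
class Segment:
    """A filtered, analysis-ready window of MAP and MFV.

    ``fs_out`` is 10 Hz on the transfer-function path and the source rate
    on the time-domain path.
    """

    map_sig: np.ndarray
    mfv_sig: np.ndarray
    fs_out: float
    mean_map: float
    mean_mfv: float
    condition: str | None = None

    def __post_init__(self) -> None:
        self.map_sig = np.asarray(self.map_sig, dtype=float)
        self.mfv_sig = np.asarray(self.mfv_sig, dtype=float)
        if len(self.map_sig) != len(self.mfv_sig):
            raise ValueError("MAP and MFV lengths differ")

    @property
    def duration_s(self) -> float:
        return len(self.map_sig) / self.fs_out


def lowpass_zero_phase(
    x: np.ndarray,
    fs: float,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Forward-backward Butterworth low-pass (zero phase lag).

    The effective magnitude response is the squared Butterworth
    magnitude; edge transients are suppressed by reflective padding.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2 * cutoff:
        raise ValueError(f"fs={fs} must exceed twice the cutoff {cutoff}")
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    padlen = 3 * (order + 1)
    if len(x) <= padlen:
        raise ValueError(
            f"signal too short for zero-phase filtering: {len(x)} <= {padlen}"
        )
    return sps.sosfiltfilt(sos, x, padtype="even")


def extract_segment(
    record: SignalRecord, selection: SegmentSelection
) -> tuple[np.ndarray, np.ndarray]:
    """Slice raw ABP and CBFV channels for the selected window."""
    selection.validate_against(record)
    start = round(selection.start_s * record.fs)
    n = round(selection.duration_s * record.fs)
    if start + n > record.n_samples:
        raise ValueError("selection exceeds record bounds")
    return record.abp[start : start + n], record.cbfv[start : start + n]


def resample_uniform(
    x: np.ndarray, fs_in: float, fs_out: float = DEFAULT_TFA_FS
) -> np.ndarray:
    """Band-limited polyphase resampling to a uniform lower rate."""
    if fs_out > fs_in:
        raise ValueError(f"fs_out={fs_out} exceeds fs_in={fs_in}")
    x = np.asarray(x, dtype=float)
    if fs_out == fs_in:
        return x.copy()
    ratio = Fraction(fs_out / fs_in).limit_denominator(10_000)
    return sps.resample_poly(x, ratio.numerator, ratio.denominator, padtype="line")


def make_segment(
    record: SignalRecord,
    selection: SegmentSelection | None = None,
    for_tfa: bool = False,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
    tfa_fs: float = DEFAULT_TFA_FS,
) -> Segment:
    """Filter, (optionally) resample, and average a record window.

    Both channels are low-passed at the source rate; when ``for_tfa`` the
    filtered signals are resampled to ``tfa_fs`` (default 10 Hz).
    """
    if selection is None:
        selection = SegmentSelection(start_s=0.0)
    abp, cbfv = extract_segment(record, selection)
    map_sig = lowpass_zero_phase(abp, record.fs, cutoff=cutoff, order=order)
    mfv_sig = lowpass_zero_phase(cbfv, record.fs, cutoff=cutoff, order=order)
    fs_out = record.fs
    if for_tfa:
        map_sig = resample_uniform(map_sig, record.fs, tfa_fs)
        mfv_sig = resample_uniform(mfv_sig, record.fs, tfa_fs)
        fs_out = tfa_fs
    return Segment(
        map_sig=map_sig,
        mfv_sig=mfv_sig,
        fs_out=fs_out,
        mean_map=float(np.mean(map_sig)),
        mean_mfv=float(np.mean(mfv_sig)),
        condition=record.meta.get("condition"),
    )
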