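"""The Mx autoregulation index: Pearson correlation of 10-second averages
of pressure and flow velocity over an analysis window, with a binary
intact/impaired classification at a configurable cut-off.

A high positive correlation means flow passively follows pressure, i.e.
impaired autoregulation; the default direction is ``mx > cutoff`` =>
impaired, ``mx <= cutoff`` => intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cautoreg.preprocess import Segment

__all__ = ["MxResult", "block_average", "compute_mx", "compute_mx_from_signals"]

DEFAULT_BLOCK_S = 10.0
DEFAULT_CUTOFF = 0.3


@dataclass
class MxResult:
    mx: float
    n_blocks: int
    classification: str  # "intact" | "impaired"
    cutoff: float = DEFAULT_CUTOFF


def block_average(x: np.ndarray, fs: float, block_s: float = DEFAULT_BLOCK_S) -> np.ndarray:
    """Non-overlapping consecutive block means; trailing partial block dropped."""
    x = np.asarray(x, dtype=float)
    per = fs * block_s
    if abs(per - round(per)) > 1e-9:
        raise ValueError(f"fs * block_s = {per} is not an integer sample count")
    per = round(per)
    n_blocks = len(x) // per
    if n_blocks < 2:
        raise ValueError(f"need at least 2 full blocks, got {n_blocks}")
    return x[: n_blocks * per].reshape(n_blocks, per).mean(axis=1)


def compute_mx_from_signals(
    map_sig: np.ndarray,
    mfv_sig: np.ndarray,
    fs: float,
    block_s: float = DEFAULT_BLOCK_S,
    cutoff: float = DEFAULT_CUTOFF,
) -> MxResult:
    """Mx from a pair of filtered source-rate MAP/MFV signals."""
    a = block_average(map_sig, fs, block_s)
    b = block_average(mfv_sig, fs, block_s)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Mx undefined: constant input")
    mx = float(np.corrcoef(a, b)[0, 1])
    return MxResult(
        mx=mx,
        n_blocks=len(a),
        classification="impaired" if mx > cutoff else "intact",
        cutoff=cutoff,
    )


def compute_mx(
    segment: Segment,
    cutoff: float = DEFAULT_CUTOFF,
    block_s: float = DEFAULT_BLOCK_S,
) -> MxResult:
    """Mx of one analysis segment (uses the segment's own sampling rate)."""
    return compute_mx_from_signals(
        segment.map_sig, segment.mfv_sig, segment.fs_out, block_s=block_s, cutoff=cutoff
    )
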