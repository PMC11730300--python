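"""Minimal WFDB reader/writer for 12-lead ECG records.

Supports the subset of the WFDB standard this package emits: a single
``.dat`` file in format 16 (interleaved little-endian int16 frames), one
``.hea`` text header, millivolt units, integer ADC gain with zero baseline.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

__all__ = ["write_record", "read_record"]

_INT16_MAX = 32767


def _checksum(digital: np.ndarray) -> int:
    """16-bit signed checksum of one signal's samples, per the WFDB header spec."""
    s = int(digital.astype(np.int64).sum()) & 0xFFFF
    return s - 0x10000 if s >= 0x8000 else s


def write_record(
    path_stem: str | Path,
    signals: np.ndarray,
    fs: float,
    lead_names: list[str],
    adc_gain: int = 1000,
    comments: list[str] | None = None,
) -> None:
    """Write ``signals`` (n_sig x n_samples, millivolts) as <stem>.hea / <stem>.dat.

    ``adc_gain`` is in ADC units per millivolt; 1000 gives 1 uV resolution.
    Samples clip at the int16 range (~+/-32.7 mV at the default gain).
    """
    path_stem = Path(path_stem)
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2 or signals.shape[0] != len(lead_names):
        raise ValueError("signals must be (n_leads, n_samples) matching lead_names")
    n_sig, n_samp = signals.shape
    digital = np.clip(np.rint(signals * adc_gain), -_INT16_MAX, _INT16_MAX).astype(np.int16)

    record = path_stem.name
    lines = [f"{record} {n_sig} {fs:g} {n_samp}"]
    for i, lead in enumerate(lead_names):
        first = int(digital[i, 0]) if n_samp else 0
        lines.append(
            f"{record}.dat 16 {adc_gain}(0)/mV 16 0 {first} {_checksum(digital[i])} 0 {lead}"
        )
    for c in comments or []:
        lines.append(f"# {c}")
    path_stem.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    # format 16: one frame per sample instant, signals interleaved
    digital.T.astype("<i2").tofile(path_stem.with_suffix(".dat"))


def read_record(path_stem: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read a format-16 WFDB record; returns (signals in mV, fs, lead names)."""
    path_stem = Path(path_stem)
    header = path_stem.with_suffix(".hea").read_text().splitlines()
    rec_line = header[0].split()
    n_sig, fs, n_samp = int(rec_line[1]), float(rec_line[2]), int(rec_line[3])

    gains, leads = [], []
    for line in header[1 : 1 + n_sig]:
        tok = line.split()
        if tok[1] != "16":
            raise ValueError(f"unsupported WFDB format {tok[1]!r}; only format 16 is handled")
        gain_spec = tok[2].split("/")[0]
        gain = float(gain_spec.split("(")[0]) or 200.0  # 0 means the WFDB default gain
        gains.append(gain)
        leads.append(tok[-1])

    raw = np.fromfile(path_stem.with_suffix(".dat"), dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise ValueError(
            f"{path_stem}.dat holds {raw.size} samples, header promises {n_sig * n_samp}"
        )
    digital = raw.reshape(n_samp, n_sig).T
    signals = digital.astype(float) / np.asarray(gains)[:, None]
    return signals, fs, leads
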