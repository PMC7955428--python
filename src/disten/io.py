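"""Plain-text I/O for RRI series, ECG records, annotations and manifests.

Formats are deliberately simple and diff-friendly:

* RRI file: one interval in ms per line; ``#``-prefixed comment lines
  allowed (a ``# pacemaker`` flag marks pacemaker records).
* ECG record: single-column CSV of samples in mV with a header line
  ``sampling_rate_hz=<float>``.
* Peak annotations: CSV with columns ``index,time_s``.
* Manifest: ``key: value`` lines, one per parameter.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def write_rri(path, series: np.ndarray, pacemaker: bool = False) -> None:
    lines = []
    if pacemaker:
        lines.append("# pacemaker")
    lines += [f"{v:.6f}" for v in np.asarray(series, dtype=float)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_rri(path) -> tuple[np.ndarray, bool]:
    """Read an RRI file; returns (intervals in ms, pacemaker flag)."""
    pacemaker = False
    values = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "pacemaker" in line.lower():
                pacemaker = True
            continue
        values.append(float(line))
    return np.asarray(values, dtype=float), pacemaker


def write_ecg_csv(path, samples: np.ndarray, sampling_rate: float) -> None:
    with open(path, "w") as fh:
        fh.write(f"sampling_rate_hz={sampling_rate}\n")
        for v in np.asarray(samples, dtype=float):
            fh.write(f"{v:.6f}\n")


def read_ecg_csv(path) -> tuple[np.ndarray, float]:
    """Read a single-column ECG CSV; returns (samples in mV, rate in Hz)."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("sampling_rate_hz="):
            raise ValueError(f"{path}: first line must be 'sampling_rate_hz=<value>'")
        rate = float(header.split("=", 1)[1])
        samples = np.array([float(line) for line in fh if line.strip()])
    return samples, rate


def write_peaks_csv(path, indices: np.ndarray, sampling_rate: float) -> None:
    pd.DataFrame(
        {"index": np.asarray(indices, dtype=int), "time_s": np.asarray(indices) / sampling_rate}
    ).to_csv(path, index=False)


def write_manifest(path, entries: dict) -> None:
    with open(path, "w") as fh:
        for key, value in entries.items():
            fh.write(f"{key}: {value}\n")


def read_manifest(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        key, _, value = line.partition(":")
        out[key.strip()] = value.strip()
    return out
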