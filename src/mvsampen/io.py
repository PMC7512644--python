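"""Plain-text I/O for multichannel series.

The on-disk format is a CSV with one column per channel, an optional header
row of channel labels, and optional ``#``-prefixed metadata comment lines,
of which ``# fs=<Hz>`` sets the sampling rate (default 1 Hz).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .multivariate import MultiSeries

__all__ = ["read_multichannel_csv", "write_multichannel_csv"]

_FS_RE = re.compile(r"#\s*fs\s*=\s*([0-9.eE+-]+)")


def read_multichannel_csv(path) -> MultiSeries:
    """Read a channels-as-columns CSV into a :class:`MultiSeries`.

    Raises ``ValueError`` with the offending line number for ragged rows or
    non-numeric cells.
    """
    path = Path(path)
    fs = None
    with open(path) as fh:
        head = [fh.readline() for _ in range(5)]
    for line in head:
        m = _FS_RE.match(line)
        if m:
            fs = float(m.group(1))
            break
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    # a purely numeric first row means the file had no header
    if all(_is_number(c) for c in df.columns):
        df = pd.read_csv(path, comment="#", header=None, float_precision="round_trip")
        labels = None
    else:
        labels = [str(c) for c in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0][0])
        raise ValueError(f"{path}: non-numeric cell in data row {row + 1}")
    if numeric.isna().to_numpy().any():
        row = int(np.argwhere(numeric.isna().to_numpy())[0][0])
        raise ValueError(f"{path}: missing value in data row {row + 1}")
    return MultiSeries(
        numeric.to_numpy(dtype=float),
        sample_interval=1.0 / fs if fs else 1.0,
        channel_labels=labels,
    )


def _is_number(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def write_multichannel_csv(X: MultiSeries, path, metadata: dict | None = None) -> None:
    """Write a :class:`MultiSeries` as CSV with metadata comment lines."""
    path = Path(path)
    labels = X.channel_labels or [f"ch{k + 1}" for k in range(X.n_channels)]
    with open(path, "w") as fh:
        fh.write(f"# fs={1.0 / X.sample_interval:g}\n")
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write(",".join(labels) + "\n")
        np.savetxt(fh, X.data, delimiter=",", fmt="%.17g")
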