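"""Plain-text readers/writers for CoP trials and derived tables.

Trial files are delimited text with a ``#``-prefixed header carrying the
sampling rate and design labels, followed by ``x,y`` columns (mm), e.g.::

    # fs=200 subject=S01 session=Sham condition=Easy trial=3
    x,y
    0.1243,-0.0712
    ...

Files with a ``time`` column instead of a header ``fs`` are accepted;
the rate is inferred from the median time step and rejected if the step
jitters by more than 1%.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from swaylab.sway import CoPTrial

__all__ = ["read_cop_csv", "write_cop_csv", "read_metrics", "write_metrics"]


class CoPFormatError(ValueError):
    """Malformed CoP trial file."""


def write_cop_csv(trial: CoPTrial, path: str | Path, precision: int = 6) -> Path:
    path = Path(path)
    header = (
        f"# fs={trial.fs:g} subject={trial.subject} session={trial.session} "
        f"condition={trial.condition} trial={trial.trial_index}\n"
    )
    buf = _io.StringIO()
    buf.write(header)
    pd.DataFrame({"x": trial.x, "y": trial.y}).to_csv(
        buf, index=False, float_format=f"%.{precision}g"
    )
    path.write_text(buf.getvalue())
    return path


def _parse_header(line: str) -> dict:
    fields = {}
    for tok in line.lstrip("#").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            fields[k] = v
    return fields


def read_cop_csv(path: str | Path) -> CoPTrial:
    """Read one CoP trial file (header form or time-column form)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    meta = _parse_header(first) if first.startswith("#") else {}
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise CoPFormatError(f"{path}: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "x" not in cols or "y" not in cols:
        raise CoPFormatError(f"{path}: need x and y columns, got {cols}")
    for c in ("x", "y"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    if df[["x", "y"]].isna().any().any():
        raise CoPFormatError(f"{path}: ragged or non-numeric rows")
    if "fs" in meta:
        fs = float(meta["fs"])
    elif "time" in cols:
        dt = np.diff(df["time"].to_numpy(dtype=float))
        if dt.size == 0 or np.any(dt <= 0):
            raise CoPFormatError(f"{path}: non-increasing time column")
        step = float(np.median(dt))
        if np.max(np.abs(dt - step)) > 0.01 * step:
            raise CoPFormatError(f"{path}: time step jitter exceeds 1%")
        fs = 1.0 / step
    else:
        raise CoPFormatError(f"{path}: no fs header and no time column")
    return CoPTrial(
        subject=meta.get("subject", path.stem),
        session=meta.get("session", "Sham"),
        condition=meta.get("condition", "Silent"),
        trial_index=int(meta.get("trial", 1)),
        fs=fs,
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
    )


def write_metrics(metrics: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(path, index=False)
    return path


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
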