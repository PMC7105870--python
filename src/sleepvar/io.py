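"""Delimited-text table I/O with round-trip-stable float formatting.

Floats are written with 10 significant digits, so write -> read -> write
reproduces files byte-identically (shortest-repr output is not stable under
re-parsing).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
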