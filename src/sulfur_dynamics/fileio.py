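"""CSV round-tripping for state and flux tables.

All numeric output is written with 17 significant digits, so a
write-read cycle reproduces every double exactly.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["write_table", "read_table"]


def write_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "date" in out.columns:
        out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
    return df
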