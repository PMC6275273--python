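"""Reading and writing the pipeline's file formats.

Images travel as 16-bit grayscale TIFF (multi-page for stacks and time
series), tables as CSV with documented headers, models and reports as JSON.
Float fields in [0, ~1.1] are scaled by ``FULL_SCALE`` counts at export and
unscaled on read; clipping to the representable range happens only here,
never inside the analysis.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

FULL_SCALE = 10_000.0  # counts per unit normalized intensity


def write_tiff16(path, data: np.ndarray, full_scale: float = FULL_SCALE) -> None:
    """Write a float array as 16-bit grayscale TIFF (scaled, clipped)."""
    arr = np.asarray(data, dtype=float) * full_scale
    arr = np.clip(np.round(arr), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_tiff16(path, full_scale: float = FULL_SCALE) -> np.ndarray:
    """Read a 16-bit TIFF back to float units."""
    return tifffile.imread(str(path)).astype(float) / full_scale


def write_table(path, df) -> None:
    df.to_csv(path, index=False)


def read_table(path):
    import pandas as pd
    return pd.read_csv(path)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
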