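"""CSV dialects for photon traces and localization tables, and TIFF export.

Trace files carry one row per detection with header ``i,phi,Cx,Cy,R,d``;
localization tables carry one row per localization with header
``id,Cx,Cy,N,Nc,sigma_C,sigma_hat,converged``.  Images are written as
single-plane 32-bit float TIFF (lossless), optionally with an 8-bit
min-max-scaled PNG preview.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TRACE_COLUMNS = ["i", "phi", "Cx", "Cy", "R", "d"]
TABLE_COLUMNS = ["id", "Cx", "Cy", "N", "Nc", "sigma_C", "sigma_hat", "converged"]


def write_trace(trace: pd.DataFrame, path) -> None:
    trace.loc[:, TRACE_COLUMNS].to_csv(path, index=False)


def read_trace(path) -> pd.DataFrame:
    trace = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(trace.columns)
    if missing:
        raise ValueError(f"trace file {path} lacks columns {sorted(missing)}")
    return trace


def records_to_table(records) -> pd.DataFrame:
    """Build a localization table from LocalizationRecord objects."""
    rows = [
        dict(id=j, Cx=r.C_bar[0], Cy=r.C_bar[1], N=r.N, Nc=r.N_c,
             sigma_C=r.sigma_C, sigma_hat=r.sigma_hat, converged=r.converged)
        for j, r in enumerate(records)
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_table(table: pd.DataFrame, path) -> None:
    cols = [c for c in TABLE_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table.loc[:, cols + extra].to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"Cx", "Cy"} - set(table.columns)
    if missing:
        raise ValueError(f"localization table {path} lacks columns {sorted(missing)}")
    return table


def write_image(img: np.ndarray, path, png_preview=None) -> None:
    """Write a float32 TIFF; optionally an 8-bit min-max-scaled PNG preview
    (the float TIFF remains the lossless record)."""
    import tifffile

    tifffile.imwrite(path, np.asarray(img, dtype=np.float32))
    if png_preview is not None:
        from PIL import Image

        arr = np.asarray(img, dtype=float)
        lo, hi = float(arr.min()), float(arr.max())
        scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
        Image.fromarray((scaled * 255).astype(np.uint8)).save(png_preview)
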