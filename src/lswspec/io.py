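"""CSV input/output for series, spectra and spectrum estimates.

Spectra and periodograms travel as plain CSV: one header row
``z_0,z_1,...`` and J data rows, finest process scale first.  A series
is a one-column CSV with an optional single header line.  Estimates are
written to a directory as ``point.csv``, ``lower_XX.csv`` /
``upper_XX.csv`` per band level, ``meta.json`` and a long-format
``long.csv`` for plotting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import SpectrumEstimate

__all__ = [
    "read_series",
    "write_series",
    "read_matrix",
    "write_matrix",
    "write_estimate",
    "read_estimate",
]


def read_series(path) -> np.ndarray:
    """Read a one-column CSV/TSV series, tolerating a single header line."""
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = [p for p in line.replace("\t", ",").split(",") if p != ""]
            if len(fields) != 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected one value, got {len(fields)}"
                )
            try:
                values.append(float(fields[0]))
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ValueError(
                    f"{path}: line {lineno}: could not parse {fields[0]!r} as a number"
                ) from None
    if not values:
        raise ValueError(f"{path}: no numeric data found")
    return np.asarray(values, dtype=float)


def write_series(x: np.ndarray, path, header: str = "x") -> None:
    pd.DataFrame({header: np.asarray(x, dtype=float)}).to_csv(path, index=False)


def write_matrix(M: np.ndarray, path) -> None:
    """Write a J x T matrix (finest scale first) with a z_k header row."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    cols = [f"z_{k}" for k in range(M.shape[1])]
    pd.DataFrame(M, columns=cols).to_csv(path, index=False)


def read_matrix(path) -> np.ndarray:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from None
    M = df.to_numpy(dtype=float)
    if M.ndim != 2 or M.size == 0:
        raise ValueError(f"{path}: expected a non-empty 2-D matrix")
    return M


def write_estimate(est: SpectrumEstimate, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(est.point, outdir / "point.csv")
    for q, (lo, hi) in est.bands.items():
        tag = f"{round(q * 100):d}"
        write_matrix(lo, outdir / f"lower_{tag}.csv")
        write_matrix(hi, outdir / f"upper_{tag}.csv")
    with open(outdir / "meta.json", "w") as fh:
        json.dump(est.metadata, fh, indent=2, default=str)
    # long format for plotting: scale, z, mean and per-level band columns
    J, T = est.point.shape
    rows = {
        "scale": np.repeat(np.arange(1, J + 1), T),
        "z": np.tile(np.arange(T) / T, J),
        "mean": est.point.ravel(),
    }
    for q, (lo, hi) in sorted(est.bands.items()):
        tag = f"{round(q * 100):d}"
        rows[f"l{tag}"] = lo.ravel()
        rows[f"u{tag}"] = hi.ravel()
    pd.DataFrame(rows).to_csv(outdir / "long.csv", index=False)


def read_estimate(outdir) -> SpectrumEstimate:
    outdir = Path(outdir)
    point = read_matrix(outdir / "point.csv")
    with open(outdir / "meta.json") as fh:
        metadata = json.load(fh)
    bands = {}
    for q in metadata.get("levels", []):
        tag = f"{round(float(q) * 100):d}"
        lo_p, hi_p = outdir / f"lower_{tag}.csv", outdir / f"upper_{tag}.csv"
        if lo_p.exists() and hi_p.exists():
            bands[float(q)] = (read_matrix(lo_p), read_matrix(hi_p))
    return SpectrumEstimate(point=point, bands=bands, metadata=metadata)
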