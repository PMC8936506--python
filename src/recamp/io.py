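"""Delimited-text input and spectrum output with a metadata sidecar."""
from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd

from . import __version__
from .series import Series
from .spectrum import TimeFrequencySpectrum

__all__ = ["read_series", "read_all_channels", "write_spectrum", "read_spectrum"]


def _read_table(path) -> pd.DataFrame:
    p = pathlib.Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    with open(p) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{p}: empty file")
    # single optional header line: skip it when its tokens are not numeric
    tokens = first.replace(",", " ").replace("\t", " ").split()
    try:
        [float(t) for t in tokens]
        skip = 0
    except ValueError:
        skip = 1
    sep = "," if "," in first else ("\t" if "\t" in first else r"\s+")
    df = pd.read_csv(p, sep=sep, engine="python", header=None, skiprows=skip,
                     comment="#")
    if df.empty:
        raise ValueError(f"{p}: no data rows")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{p}: non-numeric cell ({exc})") from exc
    if df.isna().any().any():
        raise ValueError(f"{p}: ragged rows or missing values")
    return df


def read_series(path, fs: float, column: int = 0) -> Series:
    """Read one channel (0-based column) of a delimited text file.

    Comma/tab/whitespace delimiters are autodetected; a single non-numeric
    header line is skipped.
    """
    df = _read_table(path)
    if not 0 <= column < df.shape[1]:
        raise ValueError(f"column {column} out of range for {df.shape[1]} channels")
    return Series(df.iloc[:, column].to_numpy(float), fs,
                  label=f"{pathlib.Path(path).name}:{column}")


def read_all_channels(path, fs: float) -> list[Series]:
    df = _read_table(path)
    return [Series(df.iloc[:, c].to_numpy(float), fs,
                   label=f"{pathlib.Path(path).name}:{c}")
            for c in range(df.shape[1])]


def write_spectrum(tfs: TimeFrequencySpectrum, out_prefix, seed: int | None = None,
                   extra_meta: dict | None = None) -> tuple[pathlib.Path, pathlib.Path]:
    """Write a time-frequency spectrum as TSV plus a JSON metadata sidecar.

    TSV layout: first row holds the frequency axis (Hz) after a ``time_s``
    label, each following row a window center time and its spectrum.
    """
    if tfs.values.size == 0:
        raise ValueError("refusing to write an empty spectrum")
    prefix = pathlib.Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = prefix.with_suffix(".tsv")
    meta_path = prefix.with_suffix(".meta.json")
    with open(tsv, "w") as fh:
        fh.write("time_s\t" + "\t".join(f"{f:.10g}" for f in tfs.freqs) + "\n")
        for t, row in zip(tfs.times, tfs.values):
            fh.write(f"{t:.10g}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    meta = {
        "software": "recamp",
        "version": __version__,
        "fs": tfs.fs,
        "window_samples": tfs.window_len,
        "overlap": tfs.overlap,
        "scale": tfs.scale,
        "db": tfs.db,
        "db_floor": -120.0,
        "seed": seed,
        "config": tfs.config.to_dict() if tfs.config is not None else None,
        "params_per_window": [list(p) for p in tfs.params_per_window],
        "degenerate_windows": list(tfs.degenerate_windows),
        "period_grid": [int(tfs.T_grid[0]), int(tfs.T_grid[-1])],
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return tsv, meta_path


def read_spectrum(tsv_path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Round-trip reader for :func:`write_spectrum` TSV output.

    Returns ``(times, freqs, values)``.
    """
    raw = np.loadtxt(tsv_path, delimiter="\t", skiprows=1)
    raw = np.atleast_2d(raw)
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    freqs = np.array([float(h) for h in header[1:]])
    return raw[:, 0], freqs, raw[:, 1:]
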