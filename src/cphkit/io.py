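"""Text I/O: xvg-style files, CSV tables, JSON/YAML configuration.

The xvg dialect is the two-column whitespace-separated text format of the
MD ecosystem: lines beginning with ``#`` are comments and lines beginning
with ``@`` are plot directives; both are skipped on read and re-emitted
on write.  Round trips preserve values to 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import MissingDataError, ParseError
from .model import CorrectionPotential, TorsionModel

__all__ = [
    "read_xvg",
    "write_xvg",
    "read_dvdl_csv",
    "write_dvdl_csv",
    "correction_to_json",
    "correction_from_json",
    "torsion_model_to_yaml",
    "torsion_model_from_yaml",
    "load_config",
]


def read_xvg(path):
    """Read an xvg-style file; returns (data, metadata_lines).

    ``data`` is an (n_rows, n_cols) float array.  Malformed numeric lines
    raise :class:`ParseError` naming the line number; an empty file (no
    data lines) raises :class:`MissingDataError`.
    """
    rows = []
    meta = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#") or s.startswith("@"):
                meta.append(s)
                continue
            try:
                rows.append([float(tok) for tok in s.split()])
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric data on line {lineno}: {s!r}") from exc
    if not rows:
        raise MissingDataError(f"{path}: no data lines")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise ParseError(f"{path}: inconsistent column count on data row {i + 1}")
    return np.asarray(rows, dtype=float), meta


def write_xvg(path, columns, labels=None, comments=None):
    """Write columns as xvg-style text (12 significant digits)."""
    cols = [np.asarray(c, dtype=float) for c in columns]
    n = len(cols[0])
    if any(len(c) != n for c in cols):
        raise ValueError("all columns must have equal length")
    with open(path, "w") as fh:
        for c in comments or []:
            fh.write(c if c.startswith(("#", "@")) else f"# {c}")
            fh.write("\n")
        if labels:
            fh.write("# " + "\t".join(labels) + "\n")
        for i in range(n):
            fh.write(" ".join(f"{c[i]:.17g}" for c in cols) + "\n")


def read_dvdl_csv(path):
    """Read raw TI samples from CSV with columns ``lambda, value``.

    Returns ``(lambda_points, samples_per_point)`` with points sorted
    ascending; order of samples within a point is preserved.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "lambda" not in cols or "value" not in cols:
        raise ParseError(f"{path}: expected columns 'lambda' and 'value'")
    lam_col, val_col = cols["lambda"], cols["value"]
    if df.empty:
        raise MissingDataError(f"{path}: no rows")
    pts = sorted(df[lam_col].unique())
    samples = [df.loc[df[lam_col] == p, val_col].to_numpy(dtype=float) for p in pts]
    return np.asarray(pts, dtype=float), samples


def write_dvdl_csv(path, lambda_points, samples_per_point):
    rows = []
    for lam, s in zip(lambda_points, samples_per_point):
        for v in np.asarray(s, dtype=float):
            rows.append((lam, v))
    pd.DataFrame(rows, columns=["lambda", "value"]).to_csv(path, index=False)


def correction_to_json(cp: CorrectionPotential, path) -> None:
    with open(path, "w") as fh:
        json.dump(cp.to_dict(), fh, indent=2)


def correction_from_json(path) -> CorrectionPotential:
    with open(path) as fh:
        return CorrectionPotential.from_dict(json.load(fh))


def torsion_model_to_yaml(t: TorsionModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(t.to_dict(), fh, sort_keys=False)


def torsion_model_from_yaml(path) -> TorsionModel:
    with open(path) as fh:
        return TorsionModel.from_dict(yaml.safe_load(fh))


def load_config(path) -> dict:
    """Load a YAML config (JSON is valid YAML, so both parse)."""
    text = Path(path).read_text()
    return yaml.safe_load(text)
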