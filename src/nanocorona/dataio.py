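"""Column-file I/O and the shared curve containers.

All stages exchange data as plain-text column files: whitespace- or
comma-delimited numeric columns, ``#``-prefixed comment/metadata lines, units
fixed by convention (nm, °C, Å⁻¹, cm⁻¹, M) and recorded in the header rather
than inferred from magnitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "XYCurve",
    "ScatteringCurve",
    "DuplicateAbscissaError",
    "read_xy_table",
    "write_xy_table",
]


class DuplicateAbscissaError(ValueError):
    """Raised when the abscissa contains duplicate values after sorting."""


@dataclass
class XYCurve:
    """An ordered (x, y[, dy]) curve with free-form metadata.

    Parameters
    ----------
    x : array
        Strictly increasing abscissa (nm, °C, Å⁻¹ ... depending on stage).
    y : array
        Ordinate, same length as ``x``.
    dy : array, optional
        Per-point 1-sigma uncertainty on ``y``; strictly positive.
    meta : dict
        Free-form annotations (excitation wavelength, contrast name, ...).
    """

    x: np.ndarray
    y: np.ndarray
    dy: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.dy is not None:
            self.dy = np.asarray(self.dy, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.x.ndim != 1 or self.y.shape != self.x.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        dx = np.diff(self.x)
        if np.any(dx == 0):
            raise DuplicateAbscissaError("duplicate abscissa values")
        if np.any(dx < 0):
            raise ValueError("abscissa must be strictly increasing")
        if self.dy is not None:
            if self.dy.shape != self.x.shape:
                raise ValueError("dy must match x in length")
            if np.any(self.dy <= 0):
                raise ValueError("dy must be strictly positive")

    def __len__(self) -> int:
        return self.x.size


@dataclass
class ScatteringCurve(XYCurve):
    """(q, I, dI) curve shared by the SANS and NR stages.

    ``x`` is the momentum transfer q in Å⁻¹ (strictly positive), ``y`` the
    differential cross section in cm⁻¹ (SANS) or dimensionless reflectivity
    (NR), ``dy`` its uncertainty.
    """

    def validate(self) -> None:
        super().validate()
        if np.any(self.x <= 0):
            raise ValueError("q must be strictly positive")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("intensity must be finite")

    # domain-named views
    @property
    def q(self) -> np.ndarray:
        return self.x

    @property
    def intensity(self) -> np.ndarray:
        return self.y

    @property
    def uncertainty(self) -> np.ndarray | None:
        return self.dy


def _detect_delimiter(line: str) -> str | None:
    """Comma if the first data line contains one, else whitespace (None)."""
    return "," if "," in line else None


def read_xy_table(
    path: str | Path,
    expected_columns: int | None = None,
    *,
    as_scattering: bool = False,
    sort: bool = False,
) -> XYCurve:
    """Read a 2- or 3-column text table into a curve.

    Lines starting with ``#`` are comments; ``# key: value`` comment lines are
    collected into ``meta``. Rows containing non-finite values are dropped and
    counted in ``meta['n_rejected']`` (with a logged warning). Points are never
    silently reordered: a non-increasing abscissa raises unless ``sort=True``,
    in which case the sort is logged.

    Parameters
    ----------
    path : str or Path
    expected_columns : int, optional
        Minimum number of numeric columns required.
    as_scattering : bool
        Return a :class:`ScatteringCurve` (enforces q > 0).
    sort : bool
        Explicitly sort by abscissa (logged); duplicates still raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    meta: dict = {}
    rows: list[list[float]] = []
    delim: str | None = None
    ncols: int | None = None
    n_rejected = 0

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if delim is None and ncols is None:
                delim = _detect_delimiter(line)
            parts = line.split(delim) if delim else line.split()
            try:
                vals = [float(p) for p in parts if p != ""]
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric data line {line!r}") from exc
            if ncols is None:
                ncols = len(vals)
                if expected_columns is not None and ncols < expected_columns:
                    raise ValueError(
                        f"{path}: found {ncols} columns, expected at least "
                        f"{expected_columns}"
                    )
            if not all(np.isfinite(v) for v in vals):
                n_rejected += 1
                continue
            rows.append(vals[:ncols])

    if not rows:
        raise ValueError(f"{path}: no data rows")
    if n_rejected:
        logger.warning("%s: rejected %d non-finite row(s)", path, n_rejected)
        meta["n_rejected"] = n_rejected

    arr = np.asarray(rows, dtype=float)
    x = arr[:, 0]
    if sort and np.any(np.diff(x) < 0):
        order = np.argsort(x, kind="stable")
        arr = arr[order]
        x = arr[:, 0]
        logger.info("%s: sorted %d rows by abscissa", path, len(arr))
    if np.any(np.diff(x) == 0):
        raise DuplicateAbscissaError(f"{path}: duplicate abscissa values")

    y = arr[:, 1]
    dy = arr[:, 2] if arr.shape[1] >= 3 else None
    cls = ScatteringCurve if as_scattering else XYCurve
    return cls(x=x, y=y, dy=dy, meta=meta)


def write_xy_table(curve: XYCurve, path: str | Path) -> None:
    """Write a curve as a whitespace-delimited table.

    ``meta`` entries become ``# key: value`` header lines. Values are printed
    with 17 significant digits so a read/write round trip is the identity to
    well beyond 10 significant digits.
    """
    path = Path(path)
    cols = [curve.x, curve.y] + ([curve.dy] if curve.dy is not None else [])
    with open(path, "w") as fh:
        for key, val in curve.meta.items():
            fh.write(f"# {key}: {val}\n")
        for row in zip(*cols):
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
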