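"""Loading, normalization and grid alignment of unequally spaced time series.

Measurements of signaling molecules (minutes) and gene expression (hours to
a day) arrive as long-format tables with *different* time-point sets per
molecule.  This module turns them into a single equally spaced representation
with per-series observation masks: unequally spaced data are treated as
equally spaced data with missing time points, which is what the downstream
low-rank signal recovery operates on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "GriddedSet",
    "SchemaError",
    "ParseError",
    "GridError",
    "DegenerateScaleError",
    "load_csv",
    "normalize",
    "to_grid",
    "initial_fill",
]


class SchemaError(ValueError):
    """Input table lacks a required column."""


class ParseError(ValueError):
    """A time or value cell could not be read as a number."""


class GridError(ValueError):
    """An observed time does not fall on the requested grid."""


class DegenerateScaleError(ValueError):
    """A molecule is constant across all conditions and cannot be scaled."""


@dataclass(frozen=True)
class Trace:
    """One molecule under one stimulation condition, unequally sampled.

    ``times`` are minutes since stimulation, strictly increasing; ``values``
    are measurements in arbitrary (pre-normalization) units.
    """

    molecule: str
    condition: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or len(times) != len(values):
            raise ValueError("times and values must be 1-D and equal length")
        if len(times) == 0:
            raise ValueError(f"empty trace for {self.molecule}/{self.condition}")
        if np.any(times < 0):
            raise ValueError("times must be non-negative minutes")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class GriddedSet:
    """All series aligned to a common grid of step ``dt`` with ``n_steps`` points.

    ``series[(molecule, condition)]`` holds length-``n_steps`` value arrays and
    ``mask`` marks the grid indices where an actual observation exists (the
    index sets over which recovery constraints and residuals are evaluated).
    ``scale`` maps molecule -> (min, max) used in min-max normalization.
    """

    dt: float
    n_steps: int
    series: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    mask: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    scale: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    def molecules(self) -> list[str]:
        seen: dict[str, None] = {}
        for mol, _ in self.series:
            seen.setdefault(mol)
        return list(seen)

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, cond in self.series:
            seen.setdefault(cond)
        return list(seen)

    def subset_conditions(self, conditions: list[str]) -> "GriddedSet":
        """A view-like copy restricted to the given conditions."""
        out = GriddedSet(dt=self.dt, n_steps=self.n_steps, scale=dict(self.scale))
        for (mol, cond), vals in self.series.items():
            if cond in conditions:
                out.series[(mol, cond)] = vals.copy()
                out.mask[(mol, cond)] = self.mask[(mol, cond)].copy()
        return out

    def to_wide_frame(self) -> pd.DataFrame:
        """Wide CSV-ready table: rows = grid times, columns = molecule@condition.

        Unobserved entries are blank (NaN) so the sampling design is visible.
        """
        data = {}
        for (mol, cond), vals in sorted(self.series.items()):
            col = vals.astype(float).copy()
            col[~self.mask[(mol, cond)]] = np.nan
            data[f"{mol}@{cond}"] = col
        return pd.DataFrame(data, index=pd.Index(self.times, name="time_min"))


_REQUIRED = ("molecule", "condition", "time_min", "value")


def load_csv(path, schema: dict[str, str] | None = None) -> list[Trace]:
    """Read a long-format CSV into one :class:`Trace` per (molecule, condition).

    ``schema`` maps the canonical column names (``molecule``, ``condition``,
    ``time_min``, ``value``) to the file's actual headers.  Rows are sorted by
    time and duplicate (molecule, condition, time) rows are averaged, matching
    how replicate measurements enter as means.
    """
    colmap = {name: name for name in _REQUIRED}
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, dtype=str)
    missing = [colmap[c] for c in _REQUIRED if colmap[c] not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.rename(columns={v: k for k, v in colmap.items()})

    for col in ("time_min", "value"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric {col} at data row {row + 1}: {df[col].iloc[row]!r}"
            )
        df[col] = parsed
    if df["time_min"].isna().any() or df["value"].isna().any():
        row = int(df[["time_min", "value"]].isna().any(axis=1).idxmax())
        raise ParseError(f"empty time/value cell at data row {row + 1}")

    traces = []
    grouped = df.groupby(["molecule", "condition"], sort=True)
    for (mol, cond), sub in grouped:
        agg = sub.groupby("time_min", sort=True)["value"].mean()
        traces.append(
            Trace(
                molecule=str(mol),
                condition=str(cond),
                times=agg.index.to_numpy(dtype=float),
                values=agg.to_numpy(dtype=float),
            )
        )
    return traces


def normalize(
    traces: list[Trace],
) -> tuple[list[Trace], dict[str, tuple[float, float]]]:
    """Min-max scale each molecule to [0, 1] using its pooled range.

    The minimum and maximum are pooled across *all* conditions of a molecule so
    that relative amplitudes between stimulation conditions are preserved —
    the gain analysis depends on those ratios.  Returns the scaled traces and
    the molecule -> (min, max) map needed to invert the transform.
    """
    pooled: dict[str, list[np.ndarray]] = {}
    for tr in traces:
        pooled.setdefault(tr.molecule, []).append(tr.values)
    scale: dict[str, tuple[float, float]] = {}
    for mol, chunks in pooled.items():
        allv = np.concatenate(chunks)
        lo, hi = float(allv.min()), float(allv.max())
        if hi <= lo:
            raise DegenerateScaleError(
                f"molecule {mol!r} is constant ({lo}); cannot min-max scale"
            )
        scale[mol] = (lo, hi)
    out = []
    for tr in traces:
        lo, hi = scale[tr.molecule]
        out.append(
            Trace(tr.molecule, tr.condition, tr.times, (tr.values - lo) / (hi - lo))
        )
    return out, scale


def _gcd_minutes(times: np.ndarray) -> float:
    ints = np.rint(times).astype(np.int64)
    if not np.allclose(times, ints, atol=1e-9):
        raise GridError("auto grid step requires integer minute time stamps")
    g = 0
    for t in ints:
        g = math.gcd(g, int(t))
    if g == 0:
        raise GridError("cannot infer a grid step from a single time point at 0")
    return float(g)


def to_grid(traces: list[Trace], dt: float | str = "auto") -> GriddedSet:
    """Align traces onto a common equally spaced grid.

    With ``dt="auto"`` the step is the greatest common divisor of all observed
    times (the smallest grid on which every observation lands exactly).  Grid
    length is set by the latest observation across all traces.  Unobserved
    entries are initialized to 0; call :func:`initial_fill` before recovery.
    """
    if not traces:
        raise ValueError("no traces to grid")
    all_times = np.concatenate([tr.times for tr in traces])
    if dt == "auto":
        step = _gcd_minutes(all_times)
    else:
        step = float(dt)
        if step <= 0:
            raise GridError("dt must be positive")
    t_max = float(all_times.max())
    n_steps = int(round(t_max / step)) + 1
    grid = GriddedSet(dt=step, n_steps=n_steps)
    for tr in traces:
        idx_f = tr.times / step
        idx = np.rint(idx_f).astype(int)
        off = np.abs(idx_f - idx)
        if np.any(off > 1e-6):
            bad = tr.times[np.argmax(off)]
            raise GridError(
                f"time {bad} min of {tr.molecule}/{tr.condition} is not on the "
                f"dt={step} grid"
            )
        vals = np.zeros(n_steps)
        mask = np.zeros(n_steps, dtype=bool)
        vals[idx] = tr.values
        mask[idx] = True
        grid.series[(tr.molecule, tr.condition)] = vals
        grid.mask[(tr.molecule, tr.condition)] = mask
    return grid


def locf_fill(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Last-observation-carried-forward fill of one masked series.

    Entries before the first observation are back-filled with it (the
    pre-stimulus baseline is taken as the first measurement).
    """
    if not mask.any():
        raise ValueError("series has no observations")
    obs_idx = np.flatnonzero(mask)
    # index of most recent observation at or before each grid point
    pos = np.searchsorted(obs_idx, np.arange(len(values)), side="right") - 1
    pos = np.clip(pos, 0, None)
    return values[obs_idx[pos]]


def initial_fill(grid: GriddedSet) -> GriddedSet:
    """Fill every unobserved entry by carrying the previous observation forward.

    This is the initialization of the signal-recovery iteration, not an
    interpolation of record: masked-true entries are never altered.
    """
    out = GriddedSet(dt=grid.dt, n_steps=grid.n_steps, scale=dict(grid.scale))
    for key, vals in grid.series.items():
        mask = grid.mask[key]
        out.series[key] = locf_fill(vals, mask)
        out.mask[key] = mask.copy()
    return out
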