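"""Spectrum containers, file I/O, background subtraction and feature windows.

An ED-XRF acquisition is a histogram of photon counts over a uniform energy
grid.  The instrument also reports a per-channel background estimate (the
continuum under the peaks); net counts are ``total - background``.  Model
inputs are the net counts inside a small set of energy windows around the
emission lines of interest, concatenated into one feature vector per
replicate spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from xrfquant.errors import (
    EmptyWindowError,
    FormatError,
    GridError,
    ValidationError,
)

# Columns of the long-format spectrum CSV dialect (one row per channel).
SPECTRUM_COLUMNS = [
    "standard_id", "pellet_id", "repeat_id",
    "energy_keV", "total_counts", "background_counts", "live_time_s",
]

#: Tolerance for non-uniform energy steps when inferring a grid (keV).
GRID_STEP_TOL = 1e-9


@dataclass(frozen=True)
class EnergyGrid:
    """Uniform energy axis: channel ``i`` sits at ``start_keV + i*step_keV``."""

    start_keV: float
    step_keV: float
    n_channels: int

    def __post_init__(self) -> None:
        if self.step_keV <= 0:
            raise GridError(f"step_keV must be > 0, got {self.step_keV}")
        if self.n_channels < 1:
            raise GridError(f"n_channels must be >= 1, got {self.n_channels}")

    @property
    def energies(self) -> np.ndarray:
        """Channel-center energies in keV, strictly increasing."""
        return self.start_keV + self.step_keV * np.arange(self.n_channels)

    def isclose(self, other: "EnergyGrid", tol: float = GRID_STEP_TOL) -> bool:
        return (
            self.n_channels == other.n_channels
            and abs(self.start_keV - other.start_keV) <= tol
            and abs(self.step_keV - other.step_keV) <= tol
        )


@dataclass(frozen=True)
class Spectrum:
    """One acquisition: total and background counts on a shared grid.

    ``total_counts`` may hold net (background-subtracted) values after
    :func:`subtract_background`, in which case entries can be negative;
    raw acquisitions must be non-negative.
    """

    grid: EnergyGrid
    total_counts: np.ndarray
    background_counts: np.ndarray
    live_time_s: float = 120.0
    standard_id: str = ""
    pellet_id: str = ""
    repeat_id: str = ""
    is_net: bool = False

    def __post_init__(self) -> None:
        tc = np.asarray(self.total_counts, dtype=float)
        bc = np.asarray(self.background_counts, dtype=float)
        object.__setattr__(self, "total_counts", tc)
        object.__setattr__(self, "background_counts", bc)
        if tc.shape != (self.grid.n_channels,):
            raise ValidationError(
                f"total_counts length {tc.shape} != n_channels "
                f"{self.grid.n_channels}"
            )
        if bc.shape != (self.grid.n_channels,):
            raise ValidationError(
                f"background_counts length {bc.shape} != n_channels "
                f"{self.grid.n_channels}"
            )
        if not self.is_net and np.any(tc < 0):
            raise ValidationError("raw total_counts must be non-negative")
        if np.any(bc < 0):
            raise ValidationError("background_counts must be non-negative")
        if self.live_time_s <= 0:
            raise ValidationError(f"live_time_s must be > 0, got {self.live_time_s}")


@dataclass
class Standard:
    """A calibration standard: known totals plus its replicate spectra.

    Concentrations are totals (gravimetric spike + intrinsic matrix
    contamination), in µg kg⁻¹.
    """

    standard_id: str
    as_conc: float
    pb_conc: float
    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.as_conc < 0 or self.pb_conc < 0:
            raise ValidationError("concentrations must be non-negative")
        grids = [s.grid for s in self.spectra]
        if grids and not all(g.isclose(grids[0]) for g in grids):
            raise GridError(f"standard {self.standard_id!r} mixes energy grids")

    @property
    def n_replicates(self) -> int:
        return len(self.spectra)


@dataclass(frozen=True)
class RegionSpec:
    """Sorted, non-overlapping energy windows (closed intervals, keV)."""

    windows: tuple[tuple[float, float], ...]

    def __init__(self, windows: Iterable[Sequence[float]]):
        ws = tuple((float(lo), float(hi)) for lo, hi in windows)
        for lo, hi in ws:
            if not lo < hi:
                raise ValidationError(f"window ({lo}, {hi}) must satisfy lo < hi")
        for (_, hi), (lo2, _) in zip(ws, ws[1:]):
            if lo2 <= hi:
                raise ValidationError("windows must be sorted and non-overlapping")
        object.__setattr__(self, "windows", ws)


#: The published windows: the As Kα / Pb Lα overlap region and the Pb Lβ region.
DEFAULT_REGIONS = RegionSpec([(10.35, 10.70), (12.40, 12.85)])


@dataclass
class FeatureTable:
    """One feature row per replicate spectrum, with its (As, Pb) targets.

    ``X`` is ``(n_rows, n_features)`` net counts, ``y`` is ``(n_rows, 2)``
    concentrations in µg kg⁻¹ (columns As, Pb), ``groups`` is the
    standard_id of each row.  Targets are constant within a group.
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.X.ndim != 2:
            raise ValidationError("X must be 2-D")
        if self.y.shape != (self.X.shape[0], 2):
            raise ValidationError("y must be (n_rows, 2)")
        if self.groups.shape != (self.X.shape[0],):
            raise ValidationError("groups must be (n_rows,)")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_spectra(path: str | Path, dialect: str = "long-csv") -> list[Spectrum]:
    """Read spectra from the long-format CSV dialect.

    One row per channel; spectra are grouped by (standard_id, pellet_id,
    repeat_id) and the grid is inferred from the energy column, which must
    advance by a constant step (to within ``GRID_STEP_TOL``).
    """
    if dialect != "long-csv":
        raise FormatError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"standard_id": str, "pellet_id": str,
                                  "repeat_id": str},
                     float_precision="round_trip")
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if (df["total_counts"] < 0).any() or (df["background_counts"] < 0).any():
        raise ValidationError(f"{path}: negative counts")
    spectra: list[Spectrum] = []
    keys = ["standard_id", "pellet_id", "repeat_id"]
    for (sid, pid, rid), g in df.groupby(keys, sort=False):
        e = g["energy_keV"].to_numpy(dtype=float)
        if len(e) > 1:
            steps = np.diff(e)
            step = steps[0]
            if np.any(np.abs(steps - step) > GRID_STEP_TOL) or step <= 0:
                raise GridError(
                    f"{path}: non-uniform energy step for spectrum "
                    f"({sid}, {pid}, {rid})"
                )
        else:
            step = 0.01  # single-channel spectrum: step is arbitrary
        grid = EnergyGrid(start_keV=float(e[0]), step_keV=float(step),
                          n_channels=len(e))
        spectra.append(Spectrum(
            grid=grid,
            total_counts=g["total_counts"].to_numpy(dtype=float),
            background_counts=g["background_counts"].to_numpy(dtype=float),
            live_time_s=float(g["live_time_s"].iloc[0]),
            standard_id=str(sid), pellet_id=str(pid), repeat_id=str(rid),
        ))
    return spectra


def save_spectra(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra to the long-format CSV dialect (lossless round-trip)."""
    frames = []
    for s in spectra:
        frames.append(pd.DataFrame({
            "standard_id": s.standard_id,
            "pellet_id": s.pellet_id,
            "repeat_id": s.repeat_id,
            "energy_keV": s.grid.energies,
            "total_counts": s.total_counts,
            "background_counts": s.background_counts,
            "live_time_s": s.live_time_s,
        }))
    if not frames:
        raise ValidationError("no spectra to write")
    # default float formatting is shortest-round-trip, so the file is lossless
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def save_standards(standards: Iterable[Standard], path: str | Path,
                   role: str = "train") -> None:
    """Write the standards table (known concentrations plus a role tag)."""
    rows = [{"standard_id": st.standard_id, "as_ug_kg": st.as_conc,
             "pb_ug_kg": st.pb_conc, "role": role} for st in standards]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def load_standards(spectra_path: str | Path,
                   standards_path: str | Path,
                   role: str | None = None) -> list[Standard]:
    """Assemble Standard objects from the spectrum and standards CSVs."""
    table = pd.read_csv(standards_path, dtype={"standard_id": str})
    for col in ("standard_id", "as_ug_kg", "pb_ug_kg"):
        if col not in table.columns:
            raise FormatError(f"{standards_path}: missing column {col!r}")
    if role is not None:
        if "role" not in table.columns:
            raise FormatError(f"{standards_path}: missing column 'role'")
        table = table[table["role"] == role]
    spectra = load_spectra(spectra_path)
    by_std: dict[str, list[Spectrum]] = {}
    for s in spectra:
        by_std.setdefault(s.standard_id, []).append(s)
    out = []
    for _, row in table.iterrows():
        sid = str(row["standard_id"])
        out.append(Standard(
            standard_id=sid,
            as_conc=float(row["as_ug_kg"]),
            pb_conc=float(row["pb_ug_kg"]),
            spectra=by_std.get(sid, []),
        ))
    return out


# ---------------------------------------------------------------------------
# Processing
# ---------------------------------------------------------------------------

def subtract_background(s: Spectrum) -> Spectrum:
    """Channelwise net counts = total − background.

    The background field is retained for audit and net values are NOT
    clamped at zero: clamping would bias the low-signal windows the
    calibration model has to learn from.
    """
    net = s.total_counts - s.background_counts
    return replace(s, total_counts=net, is_net=True)


def extract_features(s: Spectrum, r: RegionSpec) -> np.ndarray:
    """Concatenate counts at all channels inside each closed window.

    A channel at energy ``e`` belongs to window ``(lo, hi)`` iff
    ``lo <= e <= hi`` (with a half-step-scaled float tolerance so that
    window edges landing exactly on channel centers are included).
    """
    e = s.grid.energies
    tol = 1e-9 * max(1.0, abs(e[-1]))
    parts = []
    for lo, hi in r.windows:
        sel = (e >= lo - tol) & (e <= hi + tol)
        if not sel.any():
            raise EmptyWindowError(f"window ({lo}, {hi}) contains no channel")
        parts.append(s.total_counts[sel])
    return np.concatenate(parts)


def assemble_dataset(standards: Sequence[Standard], r: RegionSpec) -> FeatureTable:
    """Background-subtract and window every replicate spectrum.

    One row per spectrum, in deterministic (standard, pellet, repeat)
    order; each row carries its standard's (As, Pb) totals.  Replicates
    are deliberately NOT averaged, so the model trains on within-standard
    variability as well as between-standard differences.
    """
    grids = [st.spectra[0].grid for st in standards if st.spectra]
    if grids and not all(g.isclose(grids[0]) for g in grids):
        raise GridError("standards mix energy grids")
    rows, targets, groups = [], [], []
    for st in standards:
        ordered = sorted(st.spectra, key=lambda s: (s.pellet_id, s.repeat_id))
        for s in ordered:
            rows.append(extract_features(subtract_background(s), r))
            targets.append((st.as_conc, st.pb_conc))
            groups.append(st.standard_id)
    if not rows:
        raise ValidationError("no spectra in any standard")
    return FeatureTable(X=np.vstack(rows), y=np.array(targets),
                        groups=np.array(groups))


def summarize_replicates(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (divisor n−1; 0 when n = 1)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("empty replicate list")
    mean = float(v.mean())
    sd = 0.0 if v.size == 1 else float(v.std(ddof=1))
    return mean, sd
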