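"""Spectral preprocessing: spectrum I/O, fixed-width binning with exclusion
windows, percent-total-area normalization, and assembly of the samples x bins
matrix that all downstream chemometrics consume.

The binning convention follows standard metabolomics bucketing: contiguous
left-closed/right-open intervals of fixed width laid from the low edge of the
analysis range; any bucket overlapping an excluded region (residual water,
noise-only stretches) is dropped whole. Each retained bucket holds the
trapezoidal integral of the intensity over its chemical-shift interval, and
every sample is normalized so its buckets sum to 100 (percent of total
integrated area), removing overall dilution differences between sera.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "BinGrid",
    "BinnedSample",
    "BinMatrix",
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "write_manifest",
    "integrate_window",
    "build_bin_grid",
    "bin_spectrum",
    "normalize_percent",
    "assemble_bin_matrix",
]

_AXIS_RTOL = 1e-9


class SpectrumFormatError(ValueError):
    """Raised for malformed spectrum files (bad rows, bad axis, length mismatch)."""


@dataclass
class Spectrum:
    """One subject's 1D frequency-domain trace on a uniform ascending ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    group: str | None = None
    reversed_on_read: bool = False

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumFormatError("ppm and intensity must be 1-D")
        if self.ppm.size != self.intensity.size:
            raise SpectrumFormatError(
                f"length mismatch: {self.ppm.size} ppm values vs "
                f"{self.intensity.size} intensities"
            )
        if self.ppm.size < 2:
            raise SpectrumFormatError("spectrum needs at least 2 points")
        steps = np.diff(self.ppm)
        if np.any(steps <= 0):
            raise SpectrumFormatError("non-monotone ppm axis")
        h = steps.mean()
        if np.any(np.abs(steps - h) > _AXIS_RTOL * max(abs(h), 1.0) + 1e-15):
            raise SpectrumFormatError("non-uniform axis")

    @property
    def step(self) -> float:
        return float(self.ppm[1] - self.ppm[0])

    def covers(self, lo: float, hi: float) -> bool:
        return self.ppm[0] <= lo and self.ppm[-1] >= hi


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text ``ppm<TAB>intensity`` with a
    comment header carrying sample id and group."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sample_id: {spectrum.sample_id}\n")
        if spectrum.group is not None:
            fh.write(f"# group: {spectrum.group}\n")
        for x, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{x:.12e}\t{y:.12e}\n")


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column spectrum file.

    A descending ppm column is reversed to ascending (and flagged on the
    returned object); a duplicated or otherwise non-uniform axis is rejected.
    """
    path = Path(path)
    sample_id, group = "", None
    xs: list[float] = []
    ys: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("sample_id:"):
                    sample_id = body.split(":", 1)[1].strip()
                elif body.startswith("group:"):
                    group = body.split(":", 1)[1].strip() or None
                continue
            parts = line.split()
            if len(parts) != 2:
                raise SpectrumFormatError(f"{path}:{lineno}: malformed row {line!r}")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: non-numeric value in {line!r}"
                ) from exc
    ppm = np.array(xs)
    intensity = np.array(ys)
    flipped = False
    if ppm.size >= 2 and ppm[0] > ppm[-1]:
        ppm = ppm[::-1].copy()
        intensity = intensity[::-1].copy()
        flipped = True
    return Spectrum(ppm, intensity, sample_id=sample_id, group=group,
                    reversed_on_read=flipped)


def write_manifest(rows: list[tuple[str, str, str]], path: str | Path) -> None:
    """Write a cohort manifest: ``sample_id  group  path`` per line."""
    with Path(path).open("w") as fh:
        fh.write("sample_id\tgroup\tpath\n")
        for sid, grp, p in rows:
            fh.write(f"{sid}\t{grp}\t{p}\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["sample_id", "group", "path"]
    if list(df.columns) != expected:
        raise SpectrumFormatError(f"manifest must have columns {expected}")
    return df


def integrate_window(ppm: np.ndarray, intensity: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of intensity over [lo, hi], with linear
    interpolation at window edges falling between grid points."""
    if lo >= hi:
        return 0.0
    if lo < ppm[0] - 1e-12 or hi > ppm[-1] + 1e-12:
        raise ValueError(
            f"window [{lo}, {hi}] outside spectrum range [{ppm[0]}, {ppm[-1]}]"
        )
    i0 = int(np.searchsorted(ppm, lo, side="left"))
    i1 = int(np.searchsorted(ppm, hi, side="right")) - 1
    y_lo = float(np.interp(lo, ppm, intensity))
    y_hi = float(np.interp(hi, ppm, intensity))
    if i0 > i1:
        # both edges inside a single grid interval
        return 0.5 * (y_lo + y_hi) * (hi - lo)
    total = float(np.trapezoid(intensity[i0 : i1 + 1], ppm[i0 : i1 + 1]))
    if ppm[i0] > lo:
        total += 0.5 * (y_lo + intensity[i0]) * (ppm[i0] - lo)
    if ppm[i1] < hi:
        total += 0.5 * (intensity[i1] + y_hi) * (hi - ppm[i1])
    return total


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    merged = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


@dataclass
class BinGrid:
    """Fixed-width bucket grid over an analysis range, minus excluded regions."""

    lo: float
    hi: float
    width: float
    exclusions: list[tuple[float, float]] = field(default_factory=list)
    edges: list[tuple[float, float]] = field(default_factory=list)  # retained bins

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    @property
    def centers(self) -> np.ndarray:
        return np.array([(a + b) / 2 for a, b in self.edges])

    def column_names(self) -> list[str]:
        return [f"{c:.4f}" for c in self.centers]


def build_bin_grid(
    lo: float,
    hi: float,
    width: float,
    exclusions: list[tuple[float, float]] | None = None,
) -> BinGrid:
    """Lay [left, right) bins of the given width from ``lo``; drop any bin whose
    interval overlaps an exclusion interval. Overlapping exclusions are merged.
    The last bin is clipped at ``hi`` if the range is not an exact multiple of
    the width.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    if width <= 0:
        raise ValueError("need width > 0")
    excl = _merge_intervals(list(exclusions or []))
    edges: list[tuple[float, float]] = []
    # small tolerance so float edge arithmetic does not create sliver overlaps
    eps = 1e-9 * width
    k = 0
    while True:
        left = lo + k * width
        if left >= hi - eps:
            break
        right = min(lo + (k + 1) * width, hi)
        k += 1
        if any(left < b - eps and a < right - eps for a, b in excl):
            continue
        edges.append((left, right))
    return BinGrid(lo=lo, hi=hi, width=width, exclusions=excl, edges=edges)


@dataclass
class BinnedSample:
    sample_id: str
    group: str | None
    values: np.ndarray
    grid: BinGrid
    normalized: bool = False


def bin_spectrum(spectrum: Spectrum, grid: BinGrid) -> BinnedSample:
    """Integrate a spectrum over each retained bin of the grid (unnormalized)."""
    if not spectrum.covers(grid.lo, grid.hi):
        raise ValueError(
            f"spectrum [{spectrum.ppm[0]:.3f}, {spectrum.ppm[-1]:.3f}] does not "
            f"cover analysis range [{grid.lo}, {grid.hi}]"
        )
    vals = np.array(
        [integrate_window(spectrum.ppm, spectrum.intensity, a, b) for a, b in grid.edges]
    )
    return BinnedSample(spectrum.sample_id, spectrum.group, vals, grid, normalized=False)


def normalize_percent(binned: BinnedSample) -> BinnedSample:
    """Scale bin areas to percent of total area. A non-positive total marks the
    sample unusable (raises, no silent clipping)."""
    total = float(binned.values.sum())
    if total <= 0:
        raise ValueError(
            f"sample {binned.sample_id!r}: non-positive total area ({total:g})"
        )
    return BinnedSample(
        binned.sample_id,
        binned.group,
        100.0 * binned.values / total,
        binned.grid,
        normalized=True,
    )


@dataclass
class BinMatrix:
    """Samples x retained-bins matrix of percent-normalized areas."""

    grid: BinGrid
    sample_ids: list[str]
    groups: list[str | None]
    values: np.ndarray  # (n_samples, n_bins)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.grid.column_names())
        df.insert(0, "group", self.groups)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str | Path, grid: BinGrid | None = None) -> "BinMatrix":
        df = pd.read_csv(path, sep="\t")
        bin_cols = [c for c in df.columns if c not in ("sample_id", "group")]
        if grid is None:
            # reconstruct a nominal grid from the bin-center column names
            centers = np.array([float(c) for c in bin_cols])
            w = float(np.median(np.diff(centers))) if len(centers) > 1 else 0.04
            edges = [(c - w / 2, c + w / 2) for c in centers]
            grid = BinGrid(lo=edges[0][0], hi=edges[-1][1], width=w, edges=edges)
        return cls(
            grid=grid,
            sample_ids=df["sample_id"].astype(str).tolist(),
            groups=[None if pd.isna(g) else str(g) for g in df["group"]],
            values=df[bin_cols].to_numpy(dtype=float),
        )

    def subset(self, classes: tuple[str, str]) -> "BinMatrix":
        """Rows belonging to either of two classes, in original order."""
        keep = [i for i, g in enumerate(self.groups) if g in classes]
        return BinMatrix(
            grid=self.grid,
            sample_ids=[self.sample_ids[i] for i in keep],
            groups=[self.groups[i] for i in keep],
            values=self.values[keep],
        )


def assemble_bin_matrix(samples: list[BinnedSample], grid: BinGrid) -> BinMatrix:
    """Stack normalized samples (input order preserved) into a BinMatrix."""
    if not samples:
        raise ValueError("no samples to assemble")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    for s in samples:
        if not s.normalized:
            raise ValueError(f"sample {s.sample_id!r} is not normalized")
        if s.grid.edges != grid.edges:
            raise ValueError(f"sample {s.sample_id!r} binned on a different grid")
    return BinMatrix(
        grid=grid,
        sample_ids=ids,
        groups=[s.group for s in samples],
        values=np.vstack([s.values for s in samples]),
    )
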