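"""Multicomponent resolution of transient absorption spectra.

A pulse-radiolysis experiment records optical density OD(λ, t) for a
known absorbed dose per pulse and optical path.  Dividing out dose and
path converts each time slice to Gε(λ) units (µmol J⁻¹ · M⁻¹ cm⁻¹),
which is then resolved into per-species radiation-chemical yields by
linear regression on the reference-spectrum basis:

    Gε(λ_i) = Σ_j ε_j(λ_i) · G_j

The regression is solved by non-negative least squares, since the
coefficients are yields; an unconstrained mode is available for
diagnostics.  Bookkeeping helpers compute the percentage contribution
of each species to the radical pool and the material balance against
the expected scavengeable HO• yield.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .profiles import YieldProfile
from .spectra import SpectrumLibrary, _as_grid

__all__ = [
    "TransientSpectrumSeries",
    "SliceFit",
    "IllConditionedBasisWarning",
    "od_to_geps",
    "resolve_slice",
    "resolve_series",
    "percentage_contributions",
    "material_balance",
]

#: Condition number above which a collinearity warning is issued.
_COND_WARN = 1e8


class IllConditionedBasisWarning(UserWarning):
    """The reference-spectrum basis is (nearly) collinear."""


@dataclass
class TransientSpectrumSeries:
    """OD(λ, t) matrix with dose and path metadata.

    ``od`` is (n_times × n_wavelengths), dimensionless absorbance.  Noise
    may push individual entries slightly negative; the per-time mean must
    stay within 3 standard deviations of zero from below.
    """

    grid: np.ndarray
    times: np.ndarray
    od: np.ndarray
    dose: float
    path: float
    density: float = 1.0

    def __post_init__(self) -> None:
        self.grid = _as_grid(self.grid)
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) < 0):
            raise ValueError("times must be a 1-D ascending array")
        if self.od.shape != (self.times.size, self.grid.size):
            raise ValueError(
                f"od has shape {self.od.shape}, expected "
                f"({self.times.size}, {self.grid.size})"
            )
        if not self.dose > 0:
            raise ValueError("dose must be > 0")
        if not self.path > 0:
            raise ValueError("path must be > 0")
        sd = self.od.std()
        if sd > 0 and self.od.mean() < -3.0 * sd:
            raise ValueError("mean OD baseline below -3 sigma: not noise-like")

    # -- persistence: long CSV (time_s, wavelength_nm, od) + JSON sidecar --

    def to_csv(self, path, meta_path=None) -> None:
        path = Path(path)
        tt, ww = np.meshgrid(self.times, self.grid, indexing="ij")
        pd.DataFrame(
            {"time_s": tt.ravel(), "wavelength_nm": ww.ravel(), "od": self.od.ravel()}
        ).to_csv(path, index=False)
        meta = {
            "schema_version": 1,
            "dose_gy": self.dose,
            "path_cm": self.path,
            "density_kg_per_l": self.density,
        }
        meta_path = Path(meta_path) if meta_path else path.with_suffix(".json")
        meta_path.write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path, meta_path=None) -> "TransientSpectrumSeries":
        path = Path(path)
        frame = pd.read_csv(path)
        required = {"time_s", "wavelength_nm", "od"}
        if not required <= set(frame.columns):
            raise ValueError(f"series CSV needs columns {sorted(required)}")
        meta_path = Path(meta_path) if meta_path else path.with_suffix(".json")
        meta = json.loads(meta_path.read_text())
        wide = frame.pivot(index="time_s", columns="wavelength_nm", values="od")
        wide = wide.sort_index().sort_index(axis=1)
        return cls(
            grid=wide.columns.to_numpy(float),
            times=wide.index.to_numpy(float),
            od=wide.to_numpy(),
            dose=float(meta["dose_gy"]),
            path=float(meta["path_cm"]),
            density=float(meta.get("density_kg_per_l", 1.0)),
        )


def od_to_geps(series: TransientSpectrumSeries) -> np.ndarray:
    """Transform OD(λ, t) to Gε(λ, t) = OD·10⁶ / (dose·path·ρ)."""
    if series.dose <= 0:
        raise ValueError("dose must be > 0 to transform OD to Geps")
    return series.od * 1e6 / (series.dose * series.path * series.density)


@dataclass
class SliceFit:
    """Result of resolving one time slice."""

    g: dict[str, float]
    residual_rms: float
    condition_number: float


def resolve_slice(geps: np.ndarray, library: SpectrumLibrary,
                  allowed: Sequence[str], nonnegative: bool = True) -> SliceFit:
    """Resolve one Gε(λ) slice into per-species yields.

    Solves Gε(λ_i) = Σ_j ε_j(λ_i)·G_j over the species in ``allowed`` by
    non-negative least squares (or an unconstrained solve when
    ``nonnegative`` is false).  Species outside ``allowed`` are absent
    from the result (their yield is pinned at zero).
    """
    allowed = list(allowed)
    if not allowed:
        raise ValueError("allowed species set must be non-empty")
    y = np.asarray(geps, dtype=float)
    if y.shape != library.grid.shape:
        raise ValueError("geps must be sampled on the library grid")
    if y.size < 2 * len(allowed):
        raise ValueError(
            f"need >= {2 * len(allowed)} grid points for {len(allowed)} species"
        )
    basis = library.design_matrix(allowed)
    cond = float(np.linalg.cond(basis))
    if cond > _COND_WARN:
        warnings.warn(
            f"reference basis nearly collinear (condition number {cond:.3g}); "
            "solution returned but individual yields may be unidentifiable",
            IllConditionedBasisWarning,
            stacklevel=2,
        )
    if nonnegative:
        coef, _ = nnls(basis, y)
    else:
        coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    resid = y - basis @ coef
    return SliceFit(
        g=dict(zip(allowed, map(float, coef))),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        condition_number=cond,
    )


def resolve_series(series: TransientSpectrumSeries, library: SpectrumLibrary,
                   allowed: Sequence[str], times=None,
                   nonnegative: bool = True) -> YieldProfile:
    """Resolve every time slice of a series into a :class:`YieldProfile`.

    ``times`` restricts the resolution to the slices nearest the requested
    delays; by default every recorded slice is resolved.  The library is
    interpolated onto the series grid if the grids differ (never the
    reverse).
    """
    allowed = list(allowed)
    if not allowed:
        raise ValueError("allowed species set must be non-empty")
    lib = library
    if lib.grid.shape != series.grid.shape or not np.array_equal(lib.grid, series.grid):
        lib = library.interpolated_to(series.grid)
    geps = od_to_geps(series)
    if times is None:
        idx = np.arange(series.times.size)
    else:
        idx = np.unique(
            [int(np.argmin(np.abs(series.times - t))) for t in np.atleast_1d(times)]
        )
    g = np.empty((idx.size, len(allowed)))
    residual = np.empty(idx.size)
    for row, i in enumerate(idx):
        fit = resolve_slice(geps[i], lib, allowed, nonnegative=nonnegative)
        g[row] = [fit.g[s] for s in allowed]
        residual[row] = fit.residual_rms
    return YieldProfile(series.times[idx], tuple(allowed), g, residual_rms=residual)


def _as_mapping(g_row) -> dict[str, float]:
    if isinstance(g_row, Mapping):
        return {str(k): float(v) for k, v in g_row.items()}
    values = np.asarray(g_row, dtype=float).ravel()
    return {str(i): float(v) for i, v in enumerate(values)}


def percentage_contributions(g_row) -> tuple[dict[str, int], dict[str, float]]:
    """Percentage of the radical pool contributed by each species.

    Accepts a mapping species → G or a plain sequence of yields.  Returns
    integer-rounded percentages (presentation form) alongside the raw
    fractional percentages.
    """
    g = _as_mapping(g_row)
    total = sum(g.values())
    if total <= 0:
        raise ValueError("percentage contributions undefined for a non-positive total")
    raw = {k: 100.0 * v / total for k, v in g.items()}
    rounded = {k: int(round(v)) for k, v in raw.items()}
    return rounded, raw


def material_balance(g_row, expected_g: float) -> dict[str, float]:
    """Total radical yield and its ratio to the expected scavenged yield."""
    if expected_g <= 0:
        raise ValueError("expected_g must be > 0")
    g = _as_mapping(g_row)
    total = float(sum(g.values()))
    return {"total": total, "ratio": total / expected_g}
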