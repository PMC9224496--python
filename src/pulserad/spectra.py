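"""Reference absorption spectra of the sulfur-radical transients.

One-electron oxidation of a thioether dipeptide by HO• passes through a
small set of well-characterised transients: the hydroxysulfuranyl adduct
(``HOS``), backbone and side-chain carbon radicals (``aC1``, ``aC2``),
the α-(alkylthio)alkyl radical (``aS``), the intermolecular two-centre
three-electron S∴S dimer cation (``SS``), and the intramolecular S∴N and
S∴O cyclic species (``SN``, ``SO``).  Each is represented here by a molar
absorption coefficient curve ε(λ) built from one or two Gaussian bands
anchored at the literature (λmax, εmax) pairs.  These curves form the
regression basis used by :mod:`pulserad.resolution` to unmix transient
absorption spectra into per-species radiation-chemical yields.

Band widths are parametric: the anchor points fix peak position and
height, while the FWHM of each band is a configurable stand-in for the
true curve shape.  Tabulated curves may be supplied instead and take
precedence over the parametric form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES_IDS",
    "DEFAULT_BANDS",
    "Band",
    "ReferenceSpectrum",
    "SpectrumLibrary",
    "InvalidGridError",
    "SpectrumSchemaError",
    "sample_band",
    "default_library",
    "default_grid",
    "save_library",
    "load_library",
]

#: Canonical species identifiers, in conventional reporting order.
SPECIES_IDS = ("HOS", "aC1", "aC2", "aS", "SS", "SN", "SO")

_LN2 = float(np.log(2.0))

#: Default band parametrisation: (lambda_max [nm], eps_max [M^-1 cm^-1], fwhm [nm]).
#: Peak positions and heights are the literature values for these transients;
#: widths are package defaults chosen for realism and mutual identifiability
#: of the regression basis (HOS and aC2 share a 340 nm peak and are told
#: apart by band width: broad adduct band vs narrow C-radical band).
DEFAULT_BANDS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "HOS": ((340.0, 3400.0, 90.0),),
    "aC1": ((270.0, 6200.0, 50.0), (370.0, 1800.0, 100.0)),
    "aC2": ((340.0, 2000.0, 40.0),),
    "aS": ((290.0, 3000.0, 60.0),),
    "SS": ((480.0, 6880.0, 100.0),),
    "SN": ((390.0, 4500.0, 80.0),),
    "SO": ((400.0, 3000.0, 90.0),),
}


class InvalidGridError(ValueError):
    """Wavelength grid is not one-dimensional and strictly ascending."""


class SpectrumSchemaError(ValueError):
    """Library file violates the documented schema."""


def _as_grid(grid) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size < 2:
        raise InvalidGridError("wavelength grid must be a 1-D array with >= 2 points")
    if not np.all(np.diff(g) > 0):
        raise InvalidGridError("wavelength grid must be strictly ascending")
    return g


def default_grid(start: float = 270.0, stop: float = 700.0, step: float = 2.0) -> np.ndarray:
    """Observation-window wavelength grid in nm (270–700 nm, 2 nm step)."""
    return np.arange(start, stop + 0.5 * step, step, dtype=float)


@dataclass(frozen=True)
class Band:
    """A single Gaussian absorption band.

    Parameters
    ----------
    lambda_max
        Band centre in nm.
    eps_max
        Peak molar absorption coefficient in M⁻¹ cm⁻¹.
    fwhm
        Full width at half maximum in nm.
    """

    lambda_max: float
    eps_max: float
    fwhm: float = 70.0

    def __post_init__(self) -> None:
        if not self.lambda_max > 0:
            raise ValueError(f"lambda_max must be > 0, got {self.lambda_max}")
        if not self.eps_max >= 0:
            raise ValueError(f"eps_max must be >= 0, got {self.eps_max}")
        if not self.fwhm > 0:
            raise ValueError(f"fwhm must be > 0, got {self.fwhm}")


def sample_band(band: Band, grid) -> np.ndarray:
    """Sample one Gaussian band on a wavelength grid.

    ε(λ) = εmax · exp(−4·ln2·(λ−λmax)²/FWHM²); exactly εmax at the centre
    and εmax/2 at λmax ± FWHM/2.
    """
    g = _as_grid(grid)
    z = (g - band.lambda_max) / band.fwhm
    return band.eps_max * np.exp(-4.0 * _LN2 * z * z)


@dataclass
class ReferenceSpectrum:
    """Molar absorption coefficient curve ε(λ) of one transient species."""

    species_id: str
    bands: tuple[Band, ...]
    grid: np.ndarray
    eps: np.ndarray
    tabulated: bool = False

    def __post_init__(self) -> None:
        self.grid = _as_grid(self.grid)
        self.eps = np.asarray(self.eps, dtype=float)
        if self.eps.shape != self.grid.shape:
            raise ValueError("eps and grid must have identical shapes")
        if np.any(self.eps < 0):
            raise ValueError(f"{self.species_id}: negative molar absorption coefficient")
        if not self.tabulated and not self.bands:
            raise ValueError(f"{self.species_id}: a parametric spectrum needs >= 1 band")

    @classmethod
    def from_bands(cls, species_id: str, bands: Iterable[Band], grid) -> "ReferenceSpectrum":
        g = _as_grid(grid)
        bands = tuple(bands)
        eps = np.zeros_like(g)
        for b in bands:
            eps = eps + sample_band(b, g)
        return cls(species_id=species_id, bands=bands, grid=g, eps=eps)

    @classmethod
    def from_table(cls, species_id: str, wavelengths, eps, grid) -> "ReferenceSpectrum":
        """Tabulated curve, linearly interpolated onto ``grid``; ε = 0 outside
        the tabulated range."""
        g = _as_grid(grid)
        wl = np.asarray(wavelengths, dtype=float)
        ev = np.asarray(eps, dtype=float)
        order = np.argsort(wl)
        wl, ev = wl[order], ev[order]
        if np.any(ev < 0):
            raise ValueError(f"{species_id}: negative molar absorption coefficient")
        out = np.interp(g, wl, ev, left=0.0, right=0.0)
        return cls(species_id=species_id, bands=(), grid=g, eps=out, tabulated=True)

    def interpolated_to(self, grid) -> "ReferenceSpectrum":
        g = _as_grid(grid)
        if self.tabulated:
            eps = np.interp(g, self.grid, self.eps, left=0.0, right=0.0)
            return ReferenceSpectrum(self.species_id, (), g, eps, tabulated=True)
        return ReferenceSpectrum.from_bands(self.species_id, self.bands, g)

    @property
    def lambda_peak(self) -> float:
        """Wavelength of maximum ε on the grid."""
        return float(self.grid[int(np.argmax(self.eps))])


@dataclass
class SpectrumLibrary:
    """A set of reference spectra sharing one wavelength grid."""

    entries: dict[str, ReferenceSpectrum] = field(default_factory=dict)
    grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.grid is not None:
            self.grid = _as_grid(self.grid)
        for sid, spec in self.entries.items():
            if sid != spec.species_id:
                raise ValueError(f"entry key {sid!r} != species_id {spec.species_id!r}")
            if self.grid is None:
                self.grid = spec.grid
            elif not np.array_equal(spec.grid, self.grid):
                raise ValueError(f"{sid}: spectrum grid differs from library grid")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.entries

    def __getitem__(self, species_id: str) -> ReferenceSpectrum:
        return self.entries[species_id]

    def design_matrix(self, allowed: Sequence[str]) -> np.ndarray:
        """ε_j(λ_i) as a (n_grid × n_species) matrix, columns ordered as ``allowed``."""
        missing = [s for s in allowed if s not in self.entries]
        if missing:
            raise KeyError(f"species not in library: {missing}")
        return np.column_stack([self.entries[s].eps for s in allowed])

    def interpolated_to(self, grid) -> "SpectrumLibrary":
        g = _as_grid(grid)
        return SpectrumLibrary(
            entries={s: spec.interpolated_to(g) for s, spec in self.entries.items()},
            grid=g,
        )

    def subset(self, species: Sequence[str]) -> "SpectrumLibrary":
        return SpectrumLibrary(
            entries={s: self.entries[s] for s in species}, grid=self.grid
        )


def default_library(grid=None,
                    fwhm_overrides: Mapping[str, float] | None = None) -> SpectrumLibrary:
    """The seven-species default library on ``grid`` (default 270–700 nm, 2 nm).

    The grid must cover the 270–700 nm observation window.  ``fwhm_overrides``
    maps species_id to a replacement FWHM applied to every band of that
    species.
    """
    g = _as_grid(default_grid() if grid is None else grid)
    if g[0] > 270.0 or g[-1] < 700.0:
        raise InvalidGridError(
            f"grid [{g[0]}, {g[-1]}] nm does not cover the 270-700 nm window"
        )
    overrides = dict(fwhm_overrides or {})
    entries: dict[str, ReferenceSpectrum] = {}
    for sid, band_params in DEFAULT_BANDS.items():
        bands = [
            Band(lm, em, overrides.get(sid, fw)) for lm, em, fw in band_params
        ]
        entries[sid] = ReferenceSpectrum.from_bands(sid, bands, g)
    return SpectrumLibrary(entries=entries, grid=g)


# ---------------------------------------------------------------------------
# Persistence.  Two dialects:
#   * JSON: {"species": {id: [{"lambda_max":..,"eps_max":..,"fwhm":..},...]}}
#   * long CSV with header species,lambda_max,eps_max,fwhm
# plus a tabulated CSV alternative (species,wavelength_nm,eps) loaded via
# ReferenceSpectrum.from_table.

def save_library(library: SpectrumLibrary, path) -> None:
    path = Path(path)
    if any(spec.tabulated for spec in library.entries.values()):
        raise ValueError("tabulated spectra are saved in their own CSV dialect")
    if path.suffix.lower() == ".json":
        payload = {
            "schema_version": 1,
            "species": {
                sid: [
                    {"lambda_max": b.lambda_max, "eps_max": b.eps_max, "fwhm": b.fwhm}
                    for b in spec.bands
                ]
                for sid, spec in library.entries.items()
            },
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        rows = [
            (sid, b.lambda_max, b.eps_max, b.fwhm)
            for sid, spec in library.entries.items()
            for b in spec.bands
        ]
        pd.DataFrame(rows, columns=["species", "lambda_max", "eps_max", "fwhm"]).to_csv(
            path, index=False
        )


def _bands_from_records(records) -> list[Band]:
    try:
        return [
            Band(float(r["lambda_max"]), float(r["eps_max"]), float(r["fwhm"]))
            for r in records
        ]
    except (KeyError, TypeError) as exc:
        raise SpectrumSchemaError(f"malformed band record: {exc}") from exc


def load_library(path, grid=None) -> SpectrumLibrary:
    """Load a band-parametrised or tabulated library file.

    A subset of the seven species is allowed (e.g. no SO for a compound-1
    analysis); unknown species identifiers are rejected.
    """
    path = Path(path)
    g = _as_grid(default_grid() if grid is None else grid)
    per_species: dict[str, list[Band]] = {}
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        species_map = payload.get("species")
        if not isinstance(species_map, dict):
            raise SpectrumSchemaError("JSON library must contain a 'species' mapping")
        for sid, records in species_map.items():
            per_species[sid] = _bands_from_records(records)
    else:
        frame = pd.read_csv(path)
        cols = set(frame.columns)
        if {"species", "wavelength_nm", "eps"} <= cols:
            entries = {}
            for sid, sub in frame.groupby("species", sort=False):
                if sid not in SPECIES_IDS:
                    raise SpectrumSchemaError(f"unknown species_id {sid!r}")
                entries[str(sid)] = ReferenceSpectrum.from_table(
                    str(sid), sub["wavelength_nm"].to_numpy(), sub["eps"].to_numpy(), g
                )
            return SpectrumLibrary(entries=entries, grid=g)
        if not {"species", "lambda_max", "eps_max", "fwhm"} <= cols:
            raise SpectrumSchemaError(
                "CSV library needs columns species,lambda_max,eps_max,fwhm "
                "or species,wavelength_nm,eps"
            )
        for sid, sub in frame.groupby("species", sort=False):
            per_species[str(sid)] = _bands_from_records(sub.to_dict("records"))
    entries = {}
    for sid, bands in per_species.items():
        if sid not in SPECIES_IDS:
            raise SpectrumSchemaError(f"unknown species_id {sid!r}")
        entries[sid] = ReferenceSpectrum.from_bands(sid, bands, g)
    return SpectrumLibrary(entries=entries, grid=g)
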