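"""Synthetic pulse-radiolysis datasets and LC–MS peak lists.

The generator reproduces the forward model that the analysis inverts:
the default kinetic scheme of a compound is integrated, the resulting
concentration trajectories are converted to G-values, and the optical
series is synthesised through Beer–Lambert:

    OD(λ, t) = Σ_j ε_j(λ) · G_j(t) · 10⁻⁶ · dose · path  +  N(0, σ_OD)

Defaults mirror the experimental conditions the pipeline targets:
0.2 mM substrate, 11 Gy per pulse, 1 cm path, a 270–700 nm grid and
log-spaced delays from 0.2 µs to 170 µs.  Detector noise is additive
Gaussian on OD (σ = 5×10⁻⁴ absorbance by default); every noisy output
requires a seed and one named generator is used per dataset.  Ground
truth is always returned (and serialised) alongside the noisy data.

Synthetic LC–MS peak lists place CH₃S-adduct and dimer peaks at their
exact MH⁺ with intensities proportional to prescribed radical ratios
under multiplicative log-normal noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import kinetics, products
from .profiles import YieldProfile
from .resolution import TransientSpectrumSeries
from .spectra import SpectrumLibrary, default_grid, default_library

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "synthesize_series",
    "make_dataset",
    "synth_peaklist",
    "write_dataset",
]

#: Species resolvable per compound (what the optical analysis may fit).
ALLOWED_SPECIES = {
    1: ("HOS", "aC1", "aC2", "aS", "SS", "SN"),
    2: ("HOS", "aC2", "aS", "SS", "SO"),
}


def default_times(n: int = 60) -> np.ndarray:
    """Log-spaced pulse-probe delays, 0.2 µs to 170 µs."""
    return np.geomspace(2e-7, 1.7e-4, n)


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of one synthetic pulse-radiolysis experiment."""

    compound: int = 1
    dose: float = 11.0
    path: float = 1.0
    substrate_conc: float = 2e-4
    grid: np.ndarray = field(default_factory=default_grid)
    times: np.ndarray = field(default_factory=default_times)
    noise_sd_od: float = 5e-4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.compound not in (1, 2):
            raise ValueError("compound must be 1 or 2")
        for name in ("dose", "path", "substrate_conc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd_od < 0:
            raise ValueError("noise_sd_od must be >= 0")
        if self.noise_sd_od > 0 and self.seed is None:
            raise ValueError("a seed is mandatory for noisy output")


@dataclass
class SyntheticDataset:
    """A noisy series together with its generating ground truth."""

    series: TransientSpectrumSeries
    true_profile: YieldProfile
    scheme: kinetics.ReactionScheme
    spec: SyntheticSpec


def synthesize_series(spec: SyntheticSpec, profile: YieldProfile,
                      library: SpectrumLibrary) -> TransientSpectrumSeries:
    """Forward-synthesise an OD series from a yield profile.

    Every profile species must exist in the library; the library is
    interpolated onto the requested grid.
    """
    missing = [s for s in profile.species if s not in library]
    if missing:
        raise KeyError(f"profile species missing from library: {missing}")
    lib = library.interpolated_to(spec.grid)
    basis = lib.design_matrix(profile.species)  # (n_grid, n_species)
    od = profile.g @ basis.T * 1e-6 * spec.dose * spec.path
    if spec.noise_sd_od > 0:
        rng = np.random.default_rng(spec.seed)
        od = od + rng.normal(0.0, spec.noise_sd_od, size=od.shape)
    times = profile.times
    return TransientSpectrumSeries(
        grid=lib.grid, times=times, od=od, dose=spec.dose, path=spec.path
    )


def make_dataset(spec: SyntheticSpec,
                 library: SpectrumLibrary | None = None,
                 rate_overrides: Mapping[str, float] | None = None) -> SyntheticDataset:
    """End-to-end synthetic experiment: kinetics → yields → noisy OD series.

    Integrates the compound's default scheme at the spec's dose and
    substrate concentration, keeps the optically tracked species, and
    synthesises the series.  Ground truth rides along.
    """
    build = kinetics.scheme_compound1 if spec.compound == 1 else kinetics.scheme_compound2
    scheme = build(rate_overrides, dose=spec.dose, substrate_conc=spec.substrate_conc)
    trace = kinetics.simulate(scheme, spec.times)
    profile = kinetics.trace_to_yields(
        trace, spec.dose, species=ALLOWED_SPECIES[spec.compound]
    )
    lib = library if library is not None else default_library(spec.grid)
    series = synthesize_series(spec, profile, lib)
    return SyntheticDataset(series=series, true_profile=profile, scheme=scheme, spec=spec)


def synth_peaklist(compound: int, radical_ratios: Mapping[str, float],
                   seed: int | None, *, sigma: float = 0.05,
                   base_intensity: float = 1000.0,
                   include_dimer: bool = True) -> pd.DataFrame:
    """Synthetic LC–MS peak list (columns mz,intensity).

    One CH₃S-adduct peak per radical at its exact MH⁺ with intensity
    proportional to the prescribed ratio, under multiplicative
    log-normal noise (σ of log-intensity), plus one peak at the shared
    isobaric dimer mass.  ``sigma=0`` gives the noiseless ratios back
    exactly.  A ground-truth ``species`` column rides along (in a real
    measurement the isobaric adducts are told apart by retention time,
    which is not modelled).
    """
    if any(v <= 0 for v in radical_ratios.values()):
        raise ValueError("radical ratios must be strictly positive")
    if sigma > 0 and seed is None:
        raise ValueError("a seed is mandatory for noisy output")
    halves = {h.name: h for h in products.compound_radicals(compound)}
    unknown = set(radical_ratios) - set(halves)
    if unknown:
        raise ValueError(f"unknown radicals for compound {compound}: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for name, ratio in radical_ratios.items():
        intensity = base_intensity * ratio
        if sigma > 0:
            intensity *= float(np.exp(rng.normal(0.0, sigma)))
        rows.append(
            {
                "mz": products.adduct_mh(halves[name]),
                "intensity": intensity,
                "species": name,
            }
        )
    if include_dimer:
        any_two = list(halves.values())[:1] * 2
        rows.append(
            {
                "mz": products.dimer_mh(any_two[0], any_two[1]),
                "intensity": base_intensity * sum(radical_ratios.values()),
                "species": "dimer",
            }
        )
    return pd.DataFrame(rows)


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Serialise a dataset (series CSV + sidecar, truth CSV, scheme YAML)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "series": out / "series.csv",
        "meta": out / "series.json",
        "truth": out / "true_profile.csv",
        "scheme": out / "scheme.yaml",
    }
    dataset.series.to_csv(paths["series"], paths["meta"])
    # record the generator seed in the sidecar for provenance
    meta = json.loads(paths["meta"].read_text())
    meta["seed"] = dataset.spec.seed
    meta["compound"] = dataset.spec.compound
    paths["meta"].write_text(json.dumps(meta, indent=2))
    dataset.true_profile.to_csv(paths["truth"])
    dataset.scheme.to_yaml(paths["scheme"])
    return paths
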