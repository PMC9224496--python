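"""Time-resolved per-species yield profiles G_j(t).

The central exchange object of the pipeline: kinetic simulations produce
one, spectral resolution recovers one, and the synthetic-data generator
consumes one.  Yields are in µmol J⁻¹ on an ascending time grid in
seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["YieldProfile", "species_tmax"]


@dataclass
class YieldProfile:
    """Per-species radiation-chemical yields over time.

    ``g`` is a (n_times × n_species) matrix in µmol J⁻¹; ``residual_rms``
    (optional, Gε units) carries per-time fit residuals when the profile
    comes from spectral resolution.
    """

    times: np.ndarray
    species: tuple[str, ...]
    g: np.ndarray
    residual_rms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.species = tuple(self.species)
        self.g = np.asarray(self.g, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) < 0):
            raise ValueError("times must be a 1-D ascending array")
        if self.g.shape != (self.times.size, len(self.species)):
            raise ValueError(
                f"g has shape {self.g.shape}, expected "
                f"({self.times.size}, {len(self.species)})"
            )
        if self.residual_rms is not None:
            self.residual_rms = np.asarray(self.residual_rms, dtype=float)
            if self.residual_rms.shape != self.times.shape:
                raise ValueError("residual_rms must align with times")

    def g_of(self, species: str) -> np.ndarray:
        try:
            j = self.species.index(species)
        except ValueError:
            raise KeyError(f"species {species!r} not in profile {self.species}") from None
        return self.g[:, j]

    def subset(self, species: Sequence[str]) -> "YieldProfile":
        idx = [self.species.index(s) for s in species]
        return YieldProfile(self.times, tuple(species), self.g[:, idx])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.g, columns=list(self.species))
        frame.insert(0, "time_s", self.times)
        if self.residual_rms is not None:
            frame["residual_rms"] = self.residual_rms
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)

    @classmethod
    def from_csv(cls, path) -> "YieldProfile":
        frame = pd.read_csv(path)
        times = frame.pop("time_s").to_numpy()
        residual = None
        if "residual_rms" in frame.columns:
            residual = frame.pop("residual_rms").to_numpy()
        return cls(times, tuple(frame.columns), frame.to_numpy(), residual)


def species_tmax(profile: YieldProfile, species: str) -> float:
    """Time (s) at which a species reaches its maximum yield.

    Ties resolve to the earliest time; a perfectly flat trace triggers a
    warning (the argmax is then just the first point).
    """
    trace = profile.g_of(species)
    if trace.size and np.all(trace == trace[0]):
        warnings.warn(
            f"{species}: flat trace, tmax is the first time point", stacklevel=2
        )
    return float(profile.times[int(np.argmax(trace))])
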