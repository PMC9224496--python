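"""Radiation-chemical yields and dosimetry.

Radiolysis of neutral water produces e⁻(aq), HO• and H• with primary
yields (G-values) of 0.28, 0.28 and 0.06 µmol J⁻¹, together with H⁺
(0.28) and H₂O₂ (0.07).  Under N₂O saturation the hydrated electron is
converted quantitatively to HO•, so G(HO•) = 0.56 µmol J⁻¹ and HO•/H•
account for 90%/10% of the reactive radicals.

The scavenging-capacity dependence of the total radical yield follows
the empirical Schuler formula

    G(S•) = g0 + g1·√(a[S]) / (1 + √(a[S]))

with g0 = 0.539 µmol J⁻¹, g1 = 0.307 µmol J⁻¹ and a = 19.6 M⁻¹.
Dosimetry helpers convert between absorbed dose (Gy), transient
concentration (M) and G-value for the thiocyanate dosimeter
((SCN)₂•⁻: ε(472 nm) = 7580 M⁻¹ cm⁻¹, G = 0.635 µmol J⁻¹) and expose
the Fricke constant G(Fe³⁺) = 1.61 µmol J⁻¹.

Unit conventions at every API boundary: concentrations in M, doses in
Gy, G-values in µmol J⁻¹, optical path in cm, density in kg L⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PrimaryYields",
    "SchulerParams",
    "DoseSpec",
    "FRICKE_G_FE3",
    "SCN_EPS_472",
    "SCN_G",
    "schuler_g",
    "n2o_ho_yield",
    "reactive_fractions",
    "g_to_concentration",
    "concentration_to_g",
    "scn_dosimetry_dose",
    "gamma_conversion_bound",
    "irradiation_time_min",
]

#: Fricke dosimeter constant, G(Fe3+) in µmol J⁻¹.
FRICKE_G_FE3 = 1.61

#: (SCN)2•− molar absorption coefficient at 472 nm, M⁻¹ cm⁻¹.
SCN_EPS_472 = 7580.0

#: (SCN)2•− radiation-chemical yield at 10 mM KSCN, µmol J⁻¹ (the rounded
#: literature dosimetry value; the Schuler formula itself gives 0.6332).
SCN_G = 0.635


@dataclass(frozen=True)
class PrimaryYields:
    """Primary yields of water radiolysis, µmol J⁻¹."""

    g_eaq: float = 0.28
    g_ho: float = 0.28
    g_h: float = 0.06
    g_hplus: float = 0.28
    g_h2o2: float = 0.07

    def __post_init__(self) -> None:
        for name in ("g_eaq", "g_ho", "g_h", "g_hplus", "g_h2o2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SchulerParams:
    """Constants of the Schuler scavenging formula."""

    g0: float = 0.539
    g1: float = 0.307
    a: float = 19.6

    def __post_init__(self) -> None:
        if not (self.g0 > 0 and self.g1 > 0 and self.a > 0):
            raise ValueError("Schuler constants must be positive")


@dataclass(frozen=True)
class DoseSpec:
    """Absorbed dose and optical geometry of one irradiation."""

    dose: float
    path_length: float = 1.0
    dose_rate: float | None = None  # Gy min^-1
    density: float = 1.0  # kg L^-1

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValueError("dose must be > 0")
        if not self.path_length > 0:
            raise ValueError("path_length must be > 0")


def schuler_g(scavenger_conc, params: SchulerParams = SchulerParams()):
    """Total scavengeable radical yield G(S•) in µmol J⁻¹.

    Strictly increasing in [S], from g0 at zero scavenger to g0+g1 in the
    high-concentration limit.  Accepts scalars or arrays.
    """
    c = np.asarray(scavenger_conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("scavenger concentration must be >= 0")
    root = np.sqrt(params.a * c)
    out = params.g0 + params.g1 * root / (1.0 + root)
    return float(out) if np.isscalar(scavenger_conc) else out


def n2o_ho_yield(primary: PrimaryYields = PrimaryYields()) -> float:
    """G(HO•) under N₂O saturation: g(e⁻aq) + g(HO•), complete conversion."""
    return primary.g_eaq + primary.g_ho


def reactive_fractions(primary: PrimaryYields = PrimaryYields()) -> tuple[float, float]:
    """Fractions of reactive radicals that are HO• vs H• under N₂O."""
    g_ho = n2o_ho_yield(primary)
    total = g_ho + primary.g_h
    return g_ho / total, primary.g_h / total


def g_to_concentration(g: float, dose: float, density: float = 1.0) -> float:
    """Concentration (M) produced by yield ``g`` (µmol J⁻¹) at ``dose`` Gy.

    c = G·10⁻⁶ · dose · ρ  (1 Gy = 1 J kg⁻¹; ρ in kg L⁻¹).
    """
    if g < 0 or dose < 0 or density < 0:
        raise ValueError("g, dose and density must be >= 0")
    return g * 1e-6 * dose * density


def concentration_to_g(conc: float, dose: float, density: float = 1.0) -> float:
    """Inverse of :func:`g_to_concentration`."""
    if dose <= 0 or density <= 0:
        raise ValueError("dose and density must be > 0")
    return conc / (1e-6 * dose * density)


def scn_dosimetry_dose(od_472: float, path: float = 1.0) -> float:
    """Absorbed dose (Gy) from the (SCN)₂•⁻ absorbance at 472 nm.

    Beer–Lambert with ε = 7580 M⁻¹ cm⁻¹ and G = 0.635 µmol J⁻¹:
    dose = OD·10⁶ / (ε·G·path).
    """
    if od_472 < 0:
        raise ValueError("absorbance must be >= 0")
    if path <= 0:
        raise ValueError("path must be > 0")
    return od_472 * 1e6 / (SCN_EPS_472 * SCN_G * path)


def gamma_conversion_bound(substrate_conc: float, dose: float,
                           g_ho: float = 0.56) -> float:
    """Upper bound on the substrate fraction consumable by HO• at ``dose``.

    G_HO·10⁻⁶·dose / [substrate], clipped to 1 (each HO• consumes at most
    one substrate molecule).
    """
    if substrate_conc <= 0:
        raise ValueError("substrate concentration must be > 0")
    if dose < 0 or g_ho < 0:
        raise ValueError("dose and g_ho must be >= 0")
    return min(1.0, g_ho * 1e-6 * dose / substrate_conc)


def irradiation_time_min(dose: float, dose_rate: float) -> float:
    """Irradiation time in minutes for ``dose`` Gy at ``dose_rate`` Gy min⁻¹."""
    if dose < 0 or dose_rate <= 0:
        raise ValueError("dose >= 0 and dose_rate > 0 required")
    return dose / dose_rate
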