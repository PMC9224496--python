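"""Stable-product accounting: coupling dimers, CH₃S• adducts, stereochemistry.

After the transient chemistry is over, the surviving carbon-centred
radicals terminate pairwise.  For a parent CH₃C(O)NHCHXC(O)NHCH₃ with
X = CH₂CH₂SCH₃ (methionine-type, "compound 1") or X = CH₂SCH₃
(S-methyl-cysteine-type, "compound 2"), every carbon radical is the
parent minus one hydrogen, so all C–C dimers of one parent are
isobaric: MH⁺ 407.1781 for compound 1 and 379.1468 for compound 2.
CH₃S• (from H•-induced desulfurisation) couples with each carbon
radical to give methylthio adducts whose LC–MS intensities act as a
footprint of the relative radical concentrations.

Stereochemistry bookkeeping: each radical half retains 0 or 1 parent
stereocentre (fixed S configuration) and may create a new R/S centre at
the radical carbon on coupling.  Diastereoisomer counting enumerates
R/S assignments of the new centres, identifying half-swapped copies of
homodimers and, optionally, global mirror images when no fixed centre
remains (achiral LC cannot separate enantiomers).

Registry of radical halves (per parent):

========  =============================================  =====  =====
name      radical site                                   fixed  new
========  =============================================  =====  =====
aS1       primary •CH₂–S (side-chain terminus)             1     no
aS2       secondary C–H alpha to S on the side chain       1     yes
aC1       backbone Cα (parent centre destroyed/re-made)    0     yes
aC2       primary •CH₂ on the N-methyl amide               1     no
CH3S      methylthiyl (no stereocentre)                    0     no
========  =============================================  =====  =====
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ISOTOPE_MASS",
    "PROTON_MASS",
    "Formula",
    "RadicalHalf",
    "CouplingProduct",
    "CH3S",
    "parent_formula",
    "compound_radicals",
    "monoisotopic_mass",
    "dimer_mh",
    "adduct_mh",
    "count_diastereomers",
    "enumerate_products",
    "normalize_footprint",
    "match_peaks",
]

#: Monoisotopic isotope masses (IUPAC 2021), Da.
ISOTOPE_MASS: dict[str, float] = {
    "H": 1.00782503,
    "C": 12.0,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207069,
}

#: Mass of the proton, Da (MH⁺ uses the proton, not the H atom).
PROTON_MASS = 1.00727646

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """An elemental composition over C, H, N, O, S.

    Supports element-wise addition and subtraction (subtraction below
    zero is an error) and parsing from strings like ``"C8H15N2O2S"``.
    """

    counts: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for el, n in self.counts:
            if el not in ISOTOPE_MASS:
                raise ValueError(f"unknown element {el!r}")
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {el} must be a non-negative integer")
            if n:
                seen[el] = seen.get(el, 0) + n
        object.__setattr__(
            self, "counts", tuple(sorted(seen.items()))
        )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "Formula":
        return cls(tuple(mapping.items()))

    @classmethod
    def parse(cls, text: str) -> "Formula":
        pos, counts = 0, {}
        for m in _FORMULA_TOKEN.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            el, n = m.group(1), int(m.group(2) or 1)
            counts[el] = counts.get(el, 0) + n
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls.from_mapping(counts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "Formula") -> "Formula":
        out = self.as_dict()
        for el, n in other.counts:
            out[el] = out.get(el, 0) + n
        return Formula.from_mapping(out)

    def __sub__(self, other: "Formula") -> "Formula":
        out = self.as_dict()
        for el, n in other.counts:
            out[el] = out.get(el, 0) - n
            if out[el] < 0:
                raise ValueError(f"subtraction gives negative count for {el}")
        return Formula.from_mapping(out)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = {"C": 0, "H": 1}
        parts = sorted(self.counts, key=lambda kv: (order.get(kv[0], 2), kv[0]))
        return "".join(f"{el}{n if n > 1 else ''}" for el, n in parts)


def monoisotopic_mass(formula: Formula) -> float:
    """Monoisotopic mass in Da from the hard-coded isotope table."""
    return sum(n * ISOTOPE_MASS[el] for el, n in formula.counts)


@dataclass(frozen=True)
class RadicalHalf:
    """One carbon-centred (or thiyl) radical that couples into a product.

    ``fixed_centers`` counts retained parent stereocentres (S
    configuration); ``gains_center`` says whether the radical carbon
    becomes a new R/S centre on coupling.
    """

    name: str
    formula: Formula
    fixed_centers: int
    gains_center: bool
    parent: int | None = None  # 1, 2, or None for CH3S

    def __post_init__(self) -> None:
        if self.fixed_centers not in (0, 1):
            raise ValueError("fixed_centers must be 0 or 1")


#: The methylthiyl radical, CH₃S•.
CH3S = RadicalHalf("CH3S", Formula.parse("CH3S"), 0, False, None)

_PARENT = {1: Formula.parse("C8H16N2O2S"), 2: Formula.parse("C7H14N2O2S")}
_H = Formula.parse("H")

# (name, fixed_centers, gains_center); C-radicals are parent minus one H.
_REGISTRY = {
    "aS1": (1, False),
    "aS2": (1, True),
    "aC1": (0, True),
    "aC2": (1, False),
}


def parent_formula(compound: int) -> Formula:
    """Molecular formula of the intact parent dipeptide model."""
    try:
        return _PARENT[compound]
    except KeyError:
        raise ValueError("compound must be 1 or 2") from None


def compound_radicals(compound: int, include_thiyl: bool = False) -> list[RadicalHalf]:
    """Carbon radicals observed for a compound (αC1 is absent for compound 2)."""
    names = ["aS2", "aS1", "aC1", "aC2"] if compound == 1 else ["aS2", "aS1", "aC2"]
    radical = parent_formula(compound) - _H
    halves = [
        RadicalHalf(n, radical, *_REGISTRY[n], parent=compound) for n in names
    ]
    if include_thiyl:
        halves.append(CH3S)
    return halves


def _check_same_parent(a: RadicalHalf, b: RadicalHalf) -> None:
    if a.parent is None or b.parent is None:
        raise ValueError("both halves must be C-radicals of a parent compound")
    if a.parent != b.parent:
        raise ValueError(
            f"cross-parent coupling not modelled ({a.name}: {a.parent}, "
            f"{b.name}: {b.parent})"
        )


def dimer_mh(half_a: RadicalHalf, half_b: RadicalHalf) -> float:
    """Protonated monoisotopic m/z of the C–C coupling dimer (symmetric)."""
    _check_same_parent(half_a, half_b)
    return (
        monoisotopic_mass(half_a.formula)
        + monoisotopic_mass(half_b.formula)
        + PROTON_MASS
    )


def adduct_mh(half: RadicalHalf) -> float:
    """Protonated monoisotopic m/z of the CH₃S adduct of a C-radical."""
    if half.parent is None:
        raise ValueError("adducts form on C-radicals of a parent compound")
    return monoisotopic_mass(half.formula) + monoisotopic_mass(CH3S.formula) + PROTON_MASS


def _half_configs(half: RadicalHalf, new: str) -> tuple[str, ...]:
    cfg = ("S",) * half.fixed_centers
    if half.gains_center:
        cfg = cfg + (new,)
    return cfg


_MIRROR = {"R": "S", "S": "R"}


def count_diastereomers(half_a: RadicalHalf, half_b: RadicalHalf,
                        merge_enantiomers: bool = True) -> int:
    """Number of distinct stereoisomer classes of a coupling product.

    Enumerates every R/S assignment of the newly created centres (parent
    centres stay locked at S).  Two assignments describe the same
    product when they differ by swapping the two halves of a homodimer
    ("identical halves" means same radical name), or — if
    ``merge_enantiomers`` is set and the product retains no fixed centre
    — by a global mirror inversion.
    """
    homodimer = half_a.name == half_b.name
    no_fixed = half_a.fixed_centers + half_b.fixed_centers == 0
    new_slots = [h for h in (half_a, half_b) if h.gains_center]
    classes: set[tuple] = set()
    for assignment in itertools.product("RS", repeat=len(new_slots)):
        it = iter(assignment)
        cfg_a = _half_configs(half_a, next(it) if half_a.gains_center else "")
        cfg_b = _half_configs(half_b, next(it) if half_b.gains_center else "")
        variants = [(cfg_a, cfg_b)]
        if homodimer:
            variants.append((cfg_b, cfg_a))
        if merge_enantiomers and no_fixed:
            for va, vb in list(variants):
                variants.append(
                    (tuple(_MIRROR[c] for c in va), tuple(_MIRROR[c] for c in vb))
                )
        classes.add(min(variants))
    return len(classes)


@dataclass(frozen=True)
class CouplingProduct:
    """A stable radical–radical coupling product (dimer or CH₃S adduct)."""

    halves: tuple[str, str]
    formula: Formula
    mh: float
    n_diastereomers: int
    homodimer: bool
    kind: str  # "dimer" | "adduct"

    @property
    def pair(self) -> str:
        return f"{self.halves[0]}-{self.halves[1]}"


def enumerate_products(radicals: Sequence[RadicalHalf],
                       include_adducts: bool = False,
                       merge_enantiomers: bool = True) -> list[CouplingProduct]:
    """All unordered radical pairs (with repetition) and optional CH₃S adducts.

    ``n`` radicals give n·(n+1)/2 dimers plus, if requested, one adduct
    per radical.
    """
    radicals = list(radicals)
    if not radicals:
        raise ValueError("need at least one radical")
    out: list[CouplingProduct] = []
    for i, a in enumerate(radicals):
        for b in radicals[i:]:
            out.append(
                CouplingProduct(
                    halves=(a.name, b.name),
                    formula=a.formula + b.formula,
                    mh=dimer_mh(a, b),
                    n_diastereomers=count_diastereomers(a, b, merge_enantiomers),
                    homodimer=a.name == b.name,
                    kind="dimer",
                )
            )
    if include_adducts:
        for a in radicals:
            out.append(
                CouplingProduct(
                    halves=(a.name, CH3S.name),
                    formula=a.formula + CH3S.formula,
                    mh=adduct_mh(a),
                    n_diastereomers=count_diastereomers(a, CH3S, merge_enantiomers),
                    homodimer=False,
                    kind="adduct",
                )
            )
    return out


def products_frame(products: Iterable[CouplingProduct]) -> pd.DataFrame:
    """Tabular export: pair, formula, mh, n_diastereomers, homodimer, kind."""
    return pd.DataFrame(
        [
            {
                "pair": p.pair,
                "formula": str(p.formula),
                "mh": p.mh,
                "n_diastereomers": p.n_diastereomers,
                "homodimer": p.homodimer,
                "kind": p.kind,
            }
            for p in products
        ]
    )


def normalize_footprint(intensities: Mapping[str, float]) -> dict[str, float]:
    """Scale adduct intensities so the smallest becomes 1.0 (order-preserving)."""
    if not intensities:
        raise ValueError("empty intensity mapping")
    values = list(intensities.values())
    if min(values) <= 0:
        raise ValueError("intensities must be strictly positive")
    lo = min(values)
    return {k: v / lo for k, v in intensities.items()}


def match_peaks(peaklist: pd.DataFrame, products: Sequence[CouplingProduct],
                tol_ppm: float = 5.0) -> pd.DataFrame:
    """Annotate LC–MS peaks with all products within a ppm window.

    Input needs columns ``mz`` and ``intensity``.  Output adds
    ``matches`` (list of pair labels), ``n_matches``, and ``ambiguous``
    (more than one product fits — e.g. isobaric dimers, or the
    aS1/aS2 methylthio adducts that share one formula).
    """
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be >= 0")
    if not {"mz", "intensity"} <= set(peaklist.columns):
        raise ValueError("peak list needs columns mz,intensity")
    rows = []
    for _, peak in peaklist.iterrows():
        mz = float(peak["mz"])
        if tol_ppm == 0:
            hits = [p for p in products if p.mh == mz]
        else:
            hits = [p for p in products if abs(p.mh - mz) <= mz * tol_ppm * 1e-6]
        rows.append(
            {
                "mz": mz,
                "intensity": float(peak["intensity"]),
                "matches": [p.pair for p in hits],
                "n_matches": len(hits),
                "ambiguous": len(hits) > 1,
            }
        )
    return pd.DataFrame(rows)
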