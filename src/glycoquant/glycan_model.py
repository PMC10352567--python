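"""Glycan composition grammar, derivatization-aware mass chemistry, and the
theoretical light/heavy mass library.

Compositions are written in the compact serum-glycomics notation used for
linkage-specific sialic acid derivatization, e.g. ``H5N4F1Ge2Ac1``:

========  ==================================================================
symbol    residue
========  ==================================================================
``H``     hexose (mannose/galactose)
``N``     HexNAc (GlcNAc)
``F``     deoxyhexose (fucose)
``E``     ethyl-esterified Neu5Ac  (marks an alpha2,6 linkage, +C2H4)
``L``     lactonized Neu5Ac        (marks an alpha2,3 linkage, -H2O)
``Ge``    ethyl-esterified Neu5Gc  (alpha2,6)
``Gl``    lactonized Neu5Gc        (alpha2,3)
``Ac``    O-acetyl group riding on a sialic acid (+C2H2O)
========  ==================================================================

Released N-glycans are detected by MALDI-TOF in positive mode as sodium
adducts ``[M+Na]+``.  The per-glycan internal standard is the same glycome
reduced with sodium borodeuteride: the reducing-end aldehyde becomes an
alditol gaining one H and one D, a constant +3.0219 Da ("+3 Da") shift that
creates a resolvable heavy twin for every light analyte peak.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# --- atomic monoisotopic masses (Da) ---------------------------------------
_H = 1.00782503207
_D = 2.01410177812
_C = 12.0
_N_ATOM = 14.0030740048
_O = 15.9949146196
_NA = 22.9897692809
_ELECTRON = 0.00054857991

WATER = 2 * _H + _O                 # 18.010565
#: electron-corrected Na+ adduct mass for [M+Na]+
SODIUM_CATION = _NA - _ELECTRON     # 22.989221
#: alditol formed by NaBD4 reduction: the aldehyde gains one H and one D
HEAVY_LABEL = _H + _D               # 3.021927
#: O-acetylation of a sialic acid hydroxyl (+C2H2O)
ACETYL = 2 * _C + 2 * _H + _O       # 42.010565
#: ethyl esterification of a sialic acid carboxyl (+C2H4, alpha2,6 linkage)
ETHYL_ESTER = 2 * _C + 4 * _H       # 28.031300

_HEX = 6 * _C + 10 * _H + 5 * _O            # 162.052824
_HEXNAC = 8 * _C + 13 * _H + _N_ATOM + 5 * _O   # 203.079373
_DEOXYHEX = 6 * _C + 10 * _H + 4 * _O       # 146.057909
_NEU5AC = 11 * _C + 17 * _H + _N_ATOM + 8 * _O  # 291.095417
_NEU5GC = _NEU5AC + _O                      # 307.090331

#: monoisotopic residue masses (Da) of the derivatized building blocks
RESIDUE_MASSES: dict[str, float] = {
    "H": _HEX,
    "N": _HEXNAC,
    "F": _DEOXYHEX,
    "E": _NEU5AC + ETHYL_ESTER,   # alpha2,6 Neu5Ac ethyl ester
    "L": _NEU5AC - WATER,         # alpha2,3 Neu5Ac lactone
    "Ge": _NEU5GC + ETHYL_ESTER,  # alpha2,6 Neu5Gc ethyl ester
    "Gl": _NEU5GC - WATER,        # alpha2,3 Neu5Gc lactone
}

#: canonical symbol order for composition names
SYMBOL_ORDER = ("H", "N", "F", "E", "L", "Ge", "Gl", "Ac")

#: instrument acquisition window (m/z)
MZ_WINDOW = (700.0, 3500.0)

#: compositions used for external mass calibration of each spectrum
CALIBRANT_PANEL = (
    "H4N4F1",
    "H4N4Ge1",
    "H5N4F1Ge2",
    "H5N4Ge1",
    "H5N4Ge1Gl1",
    "H5N4Ge2",
    "H5N4Ge2Gl1",
)

# Default quantitation panel: the calibrants, the four O-acetylated
# sialoglycans, the named fucosylated sialoglycans, plus a plausible mouse
# serum extension (high-mannose series, hybrids, neutral complex glycans,
# Neu5Ac/Neu5Gc sialoforms, triantennary species, one disialylated antenna).
DEFAULT_PANEL = (
    # calibrants and named sialoglycans
    "H4N4F1", "H4N4Ge1", "H5N4F1Ge2", "H5N4Ge1", "H5N4Ge1Gl1",
    "H5N4Ge2", "H5N4Ge2Gl1",
    "H5N4Ge2Ac1", "H5N4Ge2Ac2", "H5N4Ge1Gl1Ac1", "H6N5Ge1Gl2Ac1",
    "H5N4F1Ge1Gl1", "H6N5Ge1Gl2",
    # high mannose
    "H5N2", "H6N2", "H7N2", "H8N2", "H9N2",
    # hybrid
    "H5N3", "H6N3", "H5N3Ge1",
    # neutral complex
    "H3N3", "H4N3", "H3N4", "H3N4F1", "H4N4", "H5N4", "H5N4F1", "H6N5",
    # Neu5Ac sialylated
    "H5N4E1", "H5N4E2", "H5N4L1", "H5N4L2", "H5N4E1L1", "H5N4F1E1",
    # Neu5Gc alpha2,3 / mixed fucosylated
    "H5N4Gl1", "H5N4Gl2", "H5N4F1Ge1", "H5N4F1Gl1",
    # triantennary
    "H6N5F1", "H6N5Ge1", "H6N5Ge2", "H6N5Ge3", "H6N5F1Ge2",
    # disialylated antenna (branched sialic acid)
    "H5N4Ge3",
)


class CompositionError(ValueError):
    """A composition string could not be parsed or violates an invariant."""


_TOKEN = re.compile(r"(Ge|Gl|Ac|[HNFEL])([0-9]+)")


@dataclass(frozen=True)
class GlycanComposition:
    """Counts of derivatized monosaccharide residues plus O-acetyl groups.

    The composition is the complete identity of a glycan at MS1 level:
    linkage isomers of sialic acid are mass-distinguished by derivatization
    (``E``/``Ge`` vs ``L``/``Gl``), but topology (branch placement,
    bisecting GlcNAc) is not resolved.
    """

    H: int = 0
    N: int = 0
    F: int = 0
    E: int = 0
    L: int = 0
    Ge: int = 0
    Gl: int = 0
    Ac: int = 0

    def __post_init__(self) -> None:
        for sym in SYMBOL_ORDER:
            if getattr(self, sym) < 0:
                raise CompositionError(f"negative count for {sym!r}")
        if self.Ac > self.sialic:
            raise CompositionError(
                f"Ac count {self.Ac} exceeds sialic acid count {self.sialic}; "
                "O-acetyl groups ride on sialic acids"
            )

    @property
    def sialic(self) -> int:
        """Total sialic acid residue count (E + L + Ge + Gl)."""
        return self.E + self.L + self.Ge + self.Gl

    @property
    def name(self) -> str:
        """Canonical name: symbols in fixed order, zero counts omitted."""
        return "".join(
            f"{sym}{getattr(self, sym)}" for sym in SYMBOL_ORDER if getattr(self, sym)
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def parse_composition(name: str) -> GlycanComposition:
    """Parse a composition string such as ``"H5N4Ge2Ac1"``.

    Tokenization is longest-match: ``Ge``/``Gl``/``Ac`` are consumed before
    the single-letter symbols, so no bare ``G`` ambiguity can arise.  Each
    symbol must be followed by a positive integer and may appear only once.

    Raises
    ------
    CompositionError
        On an unknown symbol, a missing/zero count, a repeated symbol, or
        an acetyl count exceeding the sialic acid count.  The message names
        the offending position.
    """
    if isinstance(name, GlycanComposition):
        return name
    if not name:
        raise CompositionError("empty composition name")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(name):
        m = _TOKEN.match(name, pos)
        if m is None:
            raise CompositionError(
                f"unrecognized token at position {pos} in {name!r}"
            )
        sym, cnt = m.group(1), int(m.group(2))
        if cnt == 0:
            raise CompositionError(
                f"zero count for {sym!r} at position {pos} in {name!r}"
            )
        if sym in counts:
            raise CompositionError(
                f"repeated symbol {sym!r} at position {pos} in {name!r}"
            )
        counts[sym] = cnt
        pos = m.end()
    return GlycanComposition(**counts)


def neutral_mass(comp: GlycanComposition | str) -> float:
    """Monoisotopic neutral mass: sum of residue masses + one water.

    O-acetyl groups contribute +42.010565 Da each; they are modeled as a
    composition-level modification because MS1 cannot localize them to a
    specific sialic acid.
    """
    comp = parse_composition(comp)
    mass = WATER + comp.Ac * ACETYL
    for sym, residue in RESIDUE_MASSES.items():
        mass += getattr(comp, sym) * residue
    return mass


def sodiated_mz(comp: GlycanComposition | str) -> float:
    """m/z of the singly sodiated cation ``[M+Na]+`` (electron-corrected)."""
    return neutral_mass(comp) + SODIUM_CATION


def internal_standard_mz(comp: GlycanComposition | str) -> float:
    """m/z of the deuteride-reduced (heavy) internal standard ``[M+Na]+``.

    Reduction of the reducing-end aldehyde with NaBD4 yields an alditol
    carrying one extra H and one extra D: a constant +3.0219 Da shift
    (nominally "+3 Da") for every composition.
    """
    return sodiated_mz(comp) + HEAVY_LABEL


@dataclass(frozen=True)
class StructuralClass:
    """Composition-derived structural annotation of one glycan.

    ``label`` is one of ``high_mannose``, ``hybrid``, ``complex`` or
    ``other`` (paucimannose etc.).  Antennarity is inferred as HexNAc count
    minus the two core GlcNAcs; antenna isomers and bisecting GlcNAc are not
    distinguishable from composition alone.
    """

    label: str
    antennae: int
    galactoses: int
    sialic: int
    branched: bool
    fucosylated: bool
    acetylated: bool
    a23: int
    a26: int
    neu5ac: int
    neu5gc: int


def classify_structure(comp: GlycanComposition | str) -> StructuralClass:
    """Assign a structural class from composition.

    Rules (composition-only, N = HexNAc count, H = hexose count):

    * high-mannose: N == 2, H >= 5, no fucose, no sialic acid
    * hybrid:       N == 3 and H >= 5
    * complex:      N >= 4, or N == 3 and H <= 4
    * other:        remaining N == 2 species (paucimannose etc.)

    Antennae = N - 2 for hybrid/complex.  Galactose count is bounded both by
    spare hexoses beyond the core (3 for complex, 5 for hybrid) and by the
    antenna count.  A glycan carries "branched" (disialylated-antenna)
    sialic acid when it has more sialic acids than antennae.
    """
    comp = parse_composition(comp)
    if comp.N < 2:
        raise CompositionError(
            f"{comp.name!r}: HexNAc count {comp.N} < 2, not an N-glycan core"
        )
    sialic = comp.sialic
    if comp.N == 2 and comp.H >= 5 and comp.F == 0 and sialic == 0:
        label = "high_mannose"
    elif comp.N == 3 and comp.H >= 5:
        label = "hybrid"
    elif comp.N >= 4 or (comp.N == 3 and comp.H <= 4):
        label = "complex"
    else:
        label = "other"

    if label in ("hybrid", "complex"):
        antennae = comp.N - 2
        core_hex = 3 if label == "complex" else 5
        galactoses = min(max(comp.H - core_hex, 0), antennae)
    else:
        antennae = 0
        galactoses = 0

    return StructuralClass(
        label=label,
        antennae=antennae,
        galactoses=galactoses,
        sialic=sialic,
        branched=sialic > antennae > 0,
        fucosylated=comp.F >= 1,
        acetylated=comp.Ac >= 1,
        a23=comp.L + comp.Gl,
        a26=comp.E + comp.Ge,
        neu5ac=comp.E + comp.L,
        neu5gc=comp.Ge + comp.Gl,
    )


@dataclass(frozen=True)
class LibraryEntry:
    composition: GlycanComposition
    structure: StructuralClass
    light_mz: float
    heavy_mz: float

    @property
    def name(self) -> str:
        return self.composition.name


@dataclass
class TheoreticalLibrary:
    """Sorted per-glycan light/heavy m/z table with structural annotations.

    ``collisions`` lists pairs of library m/z values (light or heavy,
    cross-compared) closer than ``tol_ppm``; such pairs cannot be resolved
    by matching and should prompt a panel revision.  ``excluded`` lists
    panel entries whose light or heavy m/z fell outside the instrument
    window.
    """

    entries: list[LibraryEntry]
    tol_ppm: float
    collisions: list[tuple[str, str, str, str, float]] = field(default_factory=list)
    excluded: list[tuple[str, float]] = field(default_factory=list)
    window: tuple[float, float] = MZ_WINDOW

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LibraryEntry]:
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def light_mz(self) -> np.ndarray:
        return np.array([e.light_mz for e in self.entries])

    @property
    def heavy_mz(self) -> np.ndarray:
        return np.array([e.heavy_mz for e in self.entries])

    def all_mz(self) -> np.ndarray:
        """All light and heavy m/z values, sorted ascending."""
        return np.sort(np.concatenate([self.light_mz, self.heavy_mz]))

    def get(self, name: str) -> LibraryEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            s = e.structure
            rows.append(
                {
                    "name": e.name,
                    "light_mz": e.light_mz,
                    "heavy_mz": e.heavy_mz,
                    "class": s.label,
                    "antennae": s.antennae,
                    "galactoses": s.galactoses,
                    "sialic_23": s.a23,
                    "sialic_26": s.a26,
                    "neu5ac": s.neu5ac,
                    "neu5gc": s.neu5gc,
                    "acetylated": s.acetylated,
                    "fucosylated": s.fucosylated,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def build_library(
    panel: Iterable[GlycanComposition | str],
    tol_ppm: float = 10.0,
    window: tuple[float, float] = MZ_WINDOW,
) -> TheoreticalLibrary:
    """Build the theoretical light/heavy library for a glycan panel.

    Entries are sorted by light m/z.  Duplicate compositions are rejected;
    compositions whose light or heavy m/z falls outside ``window`` are
    excluded with a warning and recorded in ``excluded``.
    """
    comps = [parse_composition(p) for p in panel]
    if not comps:
        raise ValueError("empty panel")
    seen: set[str] = set()
    for c in comps:
        if c.name in seen:
            raise ValueError(f"duplicate composition in panel: {c.name!r}")
        seen.add(c.name)

    entries: list[LibraryEntry] = []
    excluded: list[tuple[str, float]] = []
    lo, hi = window
    for c in comps:
        light = sodiated_mz(c)
        heavy = light + HEAVY_LABEL
        if light < lo or heavy > hi:
            logger.warning(
                "panel glycan %s (m/z %.4f) outside window [%g, %g]; excluded",
                c.name, light, lo, hi,
            )
            excluded.append((c.name, light))
            continue
        entries.append(
            LibraryEntry(
                composition=c,
                structure=classify_structure(c),
                light_mz=light,
                heavy_mz=heavy,
            )
        )
    entries.sort(key=lambda e: e.light_mz)

    # collision scan over the pooled light+heavy m/z values
    points: list[tuple[float, str, str]] = []
    for e in entries:
        points.append((e.light_mz, e.name, "light"))
        points.append((e.heavy_mz, e.name, "heavy"))
    points.sort()
    collisions: list[tuple[str, str, str, str, float]] = []
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            mz_i, name_i, ch_i = points[i]
            mz_j, name_j, ch_j = points[j]
            ppm = (mz_j - mz_i) / mz_i * 1e6
            if ppm > tol_ppm:
                break
            collisions.append((name_i, ch_i, name_j, ch_j, ppm))

    return TheoreticalLibrary(
        entries=entries,
        tol_ppm=tol_ppm,
        collisions=collisions,
        excluded=excluded,
        window=window,
    )


def load_panel(path: str | Path) -> list[str]:
    """Read a panel file: one composition per line, ``#`` comments allowed."""
    names: list[str] = []
    for line in Path(path).read_text().splitlines():
        s = line.split("#", 1)[0].strip()
        if s:
            names.append(parse_composition(s).name)
    if not names:
        raise ValueError(f"panel file {path} contains no compositions")
    return names
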