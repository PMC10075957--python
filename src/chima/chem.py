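"""Monoisotopic mass bookkeeping, modification definitions, and combinatorial
enumeration of modified peptide forms.

All masses are monoisotopic and in daltons. Residue masses are compiled at
import time from elemental compositions so that a single table of atomic
masses is the only numeric authority in the package.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "RESIDUE_MASSES",
    "ModificationSpec",
    "ModificationTable",
    "PeptideForm",
    "ChimaError",
    "InvalidSequenceError",
    "InvalidModificationError",
    "CapacityError",
    "formula_mass",
    "neutral_mass",
    "enumerate_forms",
    "default_modifications",
]


class ChimaError(Exception):
    """Base class for package errors."""


class InvalidSequenceError(ChimaError):
    """A peptide sequence contains a letter outside the 20-residue alphabet."""


class InvalidModificationError(ChimaError):
    """A modification is placed on a residue it does not target."""


class CapacityError(ChimaError):
    """Combinatorial form enumeration would exceed the configured ceiling."""


# Monoisotopic atomic masses (IUPAC 2021 values, truncated to 1e-7 Da).
ELEMENT_MASSES: Mapping[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.9720707,
    "P": 30.97376151,
}

PROTON_MASS = 1.00727646688
WATER_MASS = 2 * ELEMENT_MASSES["H"] + ELEMENT_MASSES["O"]
#: spacing between isotope peaks of a singly charged ion (C13 - C12 averaged
#: over typical peptide elemental makeup)
ISOTOPE_SPACING = 1.00335

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")

# Residue (i.e. amino acid minus water) elemental compositions.
RESIDUE_FORMULAS: Mapping[str, str] = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental formula such as ``C2H2O``.

    Negative counts (``H-2``) are allowed so loss-type deltas can be written.
    """
    mass = 0.0
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if not match.group(0):
            continue
        if match.start() != pos:
            raise ValueError(f"unparseable formula: {formula!r}")
        pos = match.end()
        element, count = match.group(1), match.group(2)
        if element not in ELEMENT_MASSES:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
        mass += ELEMENT_MASSES[element] * int(count or 1)
    if pos != len(formula):
        raise ValueError(f"unparseable formula: {formula!r}")
    return mass


RESIDUE_MASSES: Mapping[str, float] = {
    aa: formula_mass(f) for aa, f in RESIDUE_FORMULAS.items()
}


@dataclass(frozen=True)
class ModificationSpec:
    """A named monoisotopic mass delta with its residue targets.

    role is ``"target"`` for the PTM under study (e.g. lactylation when
    hunting Kla marks) and ``"background"`` for co-occurring mods carried
    along as extra variable modifications.
    """

    name: str
    targets: frozenset
    delta_mass: float
    composition: Optional[str] = None
    role: str = "background"

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", frozenset(self.targets))
        if self.composition is not None:
            computed = formula_mass(self.composition)
            if abs(computed - self.delta_mass) >= 1e-5:
                raise ValueError(
                    f"modification {self.name!r}: delta_mass {self.delta_mass} "
                    f"disagrees with composition {self.composition} "
                    f"({computed:.6f})"
                )

    def applies_to(self, residue: str) -> bool:
        return residue in self.targets


class ModificationTable:
    """Registry of modification specs, unique by name."""

    def __init__(self, specs: Iterable[ModificationSpec] = ()):
        self._by_name: dict[str, ModificationSpec] = {}
        for spec in specs:
            self.add(spec)

    def add(self, spec: ModificationSpec) -> None:
        if spec.name in self._by_name:
            raise ValueError(f"duplicate modification name {spec.name!r}")
        self._by_name[spec.name] = spec

    def __getitem__(self, name: str) -> ModificationSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown modification {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def get_all(self, names: Iterable[str]) -> list[ModificationSpec]:
        return [self[n] for n in names]

    @classmethod
    def from_tsv(cls, path_or_buffer) -> "ModificationTable":
        """Load a TSV with columns name, targets, composition, delta_mass, role.

        ``composition`` or ``delta_mass`` may be blank (not both); when both
        are present they must agree to 1e-5 Da.
        """
        import pandas as pd

        df = pd.read_csv(path_or_buffer, sep="\t", dtype=str).fillna("")
        table = cls()
        for row in df.itertuples(index=False):
            composition = row.composition.strip() or None
            delta_raw = str(row.delta_mass).strip()
            if delta_raw:
                delta = float(delta_raw)
            elif composition:
                delta = formula_mass(composition)
            else:
                raise ValueError(
                    f"modification {row.name!r}: need composition or delta_mass"
                )
            table.add(
                ModificationSpec(
                    name=row.name.strip(),
                    targets=frozenset(t.strip() for t in row.targets.split(",") if t.strip()),
                    delta_mass=delta,
                    composition=composition,
                    role=(row.role.strip() or "background"),
                )
            )
        return table


def default_modifications() -> ModificationTable:
    """The shipped modification table.

    Houses the lysine acylations (ac, la, cr, hib, bz), the methylations
    (me1/2/3 on K, rme1/2 on R) and cysteine carbamidomethylation.
    """
    with resources.files("chima.data").joinpath("modifications.tsv").open() as fh:
        return ModificationTable.from_tsv(fh)


@dataclass(frozen=True)
class PeptideForm:
    """A base peptide sequence plus a site -> modification assignment.

    ``mods`` maps 1-based residue index to a ModificationSpec; it is stored
    as a sorted tuple of (index, spec) pairs so forms are hashable.
    ``protein_refs`` is a tuple of (protein id, start, end) with 1-based
    inclusive protein coordinates.
    """

    sequence: str
    mods: tuple = ()
    protein_refs: tuple = ()
    is_decoy: bool = False

    def __post_init__(self) -> None:
        mods = tuple(sorted(self.mods, key=lambda im: im[0]))
        object.__setattr__(self, "mods", mods)
        seen = set()
        for idx, spec in mods:
            if not 1 <= idx <= len(self.sequence):
                raise InvalidModificationError(
                    f"mod index {idx} outside peptide {self.sequence!r}"
                )
            if idx in seen:
                raise InvalidModificationError(
                    f"more than one modification at index {idx} of {self.sequence!r}"
                )
            seen.add(idx)
            residue = self.sequence[idx - 1]
            if not spec.applies_to(residue):
                raise InvalidModificationError(
                    f"mod {spec.name!r} does not target residue {residue!r} "
                    f"at index {idx} of {self.sequence!r}"
                )

    @property
    def mods_by_index(self) -> dict:
        return dict(self.mods)

    @property
    def mod_multiset(self) -> tuple:
        """Sorted tuple of mod names, ignoring positions (isomer identity)."""
        return tuple(sorted(spec.name for _, spec in self.mods))

    @property
    def neutral_mass(self) -> float:
        return neutral_mass(self)

    def key(self) -> tuple:
        """Canonical sort/identity key: sequence then (index, name) pairs."""
        return (self.sequence, tuple((i, s.name) for i, s in self.mods))

    def annotated(self) -> str:
        """Flat notation such as ``K(la)STGGK(ac)APR``."""
        out = []
        mods = self.mods_by_index
        for i, residue in enumerate(self.sequence, start=1):
            out.append(residue)
            if i in mods:
                out.append(f"({mods[i].name})")
        return "".join(out)

    def is_isomer_of(self, other: "PeptideForm") -> bool:
        """Same sequence and same modification multiset (positions may differ)."""
        return (
            self.sequence == other.sequence
            and self.mod_multiset == other.mod_multiset
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.annotated()


def neutral_mass(form: PeptideForm) -> float:
    """Monoisotopic neutral mass: residue masses + water + mod deltas."""
    if not form.sequence:
        raise InvalidSequenceError("empty peptide sequence")
    mass = WATER_MASS
    for residue in form.sequence:
        try:
            mass += RESIDUE_MASSES[residue]
        except KeyError:
            raise InvalidSequenceError(
                f"unknown residue {residue!r} in {form.sequence!r}"
            ) from None
    for _, spec in form.mods:
        mass += spec.delta_mass
    return mass


def enumerate_forms(
    sequence: str,
    target_mods: Sequence[ModificationSpec],
    background_mods: Sequence[ModificationSpec],
    max_background: int = 3,
    *,
    fixed_mods: Optional[Mapping[int, ModificationSpec]] = None,
    allowed_sites: Optional[Mapping[str, Iterable[int]]] = None,
    ceiling: int = 10_000,
    protein_refs: tuple = (),
    is_decoy: bool = False,
) -> list[PeptideForm]:
    """Enumerate all modified forms of a peptide.

    Every eligible site independently carries at most one modification.
    Target mods may occupy any number of eligible sites; background mods are
    limited to ``max_background`` per peptide in total. The unmodified form
    (or the fixed-mods-only form) is always included.

    Parameters
    ----------
    fixed_mods
        Site assignments locked in every emitted form (e.g. a known mark, or
        a static carbamidomethyl-C applied upstream).
    allowed_sites
        Optional restriction, mod name -> permitted 1-based indices. Sites
        not listed are ineligible for that mod.
    ceiling
        Combinatorial guard; exceeding it raises :class:`CapacityError`
        naming the peptide.
    """
    if max_background < 0:
        raise ValueError("max_background must be >= 0")
    fixed = dict(fixed_mods or {})
    for idx, spec in fixed.items():
        if not spec.applies_to(sequence[idx - 1]):
            raise InvalidModificationError(
                f"fixed mod {spec.name!r} does not target "
                f"{sequence[idx - 1]!r} at index {idx}"
            )

    def eligible(spec: ModificationSpec) -> list[int]:
        sites = [
            i
            for i in range(1, len(sequence) + 1)
            if i not in fixed and spec.applies_to(sequence[i - 1])
        ]
        if allowed_sites and spec.name in allowed_sites:
            permitted = set(allowed_sites[spec.name])
            sites = [i for i in sites if i in permitted]
        return sites

    # Per-site option lists: None (no mod) plus every mod eligible there.
    site_options: dict[int, list] = {}
    for spec in list(target_mods) + list(background_mods):
        for i in eligible(spec):
            site_options.setdefault(i, []).append(spec)
    background_names = {s.name for s in background_mods}

    sites = sorted(site_options)
    forms: list[PeptideForm] = []
    base_mods = tuple(fixed.items())

    def recurse(pos: int, chosen: list, n_background: int) -> None:
        if len(forms) > ceiling:
            raise CapacityError(
                f"peptide {sequence!r}: more than {ceiling} modified forms"
            )
        if pos == len(sites):
            forms.append(
                PeptideForm(
                    sequence=sequence,
                    mods=base_mods + tuple(chosen),
                    protein_refs=protein_refs,
                    is_decoy=is_decoy,
                )
            )
            return
        site = sites[pos]
        recurse(pos + 1, chosen, n_background)
        for spec in site_options[site]:
            nb = n_background + (spec.name in background_names)
            if nb > max_background:
                continue
            chosen.append((site, spec))
            recurse(pos + 1, chosen, nb)
            chosen.pop()

    recurse(0, [], 0)
    if len(forms) > ceiling:
        raise CapacityError(
            f"peptide {sequence!r}: more than {ceiling} modified forms"
        )
    # Canonical order: by mod count, then positions, then mod names.
    forms.sort(key=lambda f: (len(f.mods), tuple(i for i, _ in f.mods),
                              tuple(s.name for _, s in f.mods)))
    # Dedupe (possible when a mod appears in both target and background lists).
    unique: dict[tuple, PeptideForm] = {}
    for f in forms:
        unique.setdefault(f.key(), f)
    return list(unique.values())
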