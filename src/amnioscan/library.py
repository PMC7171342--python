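"""Targeted lipid catalogue for amniotic-fluid lipidomics.

The assay quantifies a fixed panel of polar lipids (phosphatidylcholines,
phosphatidylethanolamines, sphingomyelins, ceramides and optionally
phosphatidylglycerols) against a curated library of known species.  Each
library entry carries the shorthand lipid name, its monoisotopic neutral
mass, the adduct it is detected as, and an expected chromatographic
retention time.  Two derived flags drive the downstream lecithin /
sphingomyelin (L/S) maturity ratio:

* ``is_lecithin`` — diacyl phosphatidylcholines only.  "Lecithin" denotes
  diacyl PC; ether-linked (O-, P-) and lyso PCs are excluded from the
  ratio numerator.
* ``is_sphingomyelin`` — every SM species (the ratio denominator).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "PROTON_MASS",
    "LIPID_CLASSES",
    "LINKAGES",
    "ADDUCTS",
    "LipidNameError",
    "LibraryError",
    "LipidSpecies",
    "LipidLibrary",
    "annotate_species",
    "load_library",
    "save_library",
    "default_library",
    "mz_for_adduct",
    "neutral_mass_from_mz",
]

#: Mass of a proton in Da, used for [M+H]+ / [M-H]- adduct arithmetic.
PROTON_MASS = 1.007276466

LIPID_CLASSES = ("PC", "PE", "SM", "Cer", "PG")
LINKAGES = ("diacyl", "ether_O", "ether_P", "lyso", "n_acyl")
ADDUCTS = ("[M+H]+", "[M-H]-")

# Shorthand lipid names in the wild mix hyphen-minus, the Unicode hyphen,
# en-dashes and the minus sign in O-/P- prefixes; treat them all as '-'.
_DASH_VARIANTS = {"‐": "-", "‑": "-", "‒": "-", "–": "-", "−": "-"}

_NAME_RE = re.compile(r"^(?P<cls>[A-Za-z]+)\((?P<c1>[^/()]+)/(?P<c2>[^/()]+)\)$")
_CHAIN_RE = re.compile(r"^(?P<prefix>O-|P-|d|t)?(?P<carbons>\d+):(?P<dbl>\d+)$")

_SPHINGOID_CLASSES = frozenset({"SM", "Cer"})


class LipidNameError(ValueError):
    """A shorthand lipid name could not be parsed."""


class LibraryError(ValueError):
    """A lipid library violated its schema or invariants."""


def _canonical(name: str) -> str:
    for bad, good in _DASH_VARIANTS.items():
        name = name.replace(bad, good)
    return name.strip()


def annotate_species(name: str) -> tuple[str, str, bool, bool]:
    """Annotate a shorthand lipid name.

    Parses ``Class(chain1/chain2)`` nomenclature such as ``PC(20:4/14:0)``,
    ``PC(O-16:0/18:1)``, ``PC(20:4/0:0)`` or ``SM(d16:1/17:0)`` and returns
    ``(lipid_class, linkage, is_lecithin, is_sphingomyelin)``.

    Linkage rules: sphingolipids (SM, Cer) are N-acyl; a ``0:0`` chain marks
    a lyso species; an ``O-`` (``P-``) prefix marks an ether (plasmalogen)
    linkage; otherwise the species is diacyl.  Lecithins are exactly the
    diacyl PCs.

    Raises
    ------
    LipidNameError
        If the name or one of its chains does not parse; the message names
        the offending token.
    """
    canon = _canonical(name)
    m = _NAME_RE.match(canon)
    if m is None:
        raise LipidNameError(f"unparseable lipid name: {name!r}")
    cls = m.group("cls")
    if cls not in LIPID_CLASSES:
        raise LipidNameError(f"unknown lipid class token {cls!r} in {name!r}")

    chains = []
    for token in (m.group("c1"), m.group("c2")):
        cm = _CHAIN_RE.match(token)
        if cm is None:
            raise LipidNameError(f"unparseable chain token {token!r} in {name!r}")
        chains.append(cm)

    if cls in _SPHINGOID_CLASSES:
        linkage = "n_acyl"
    elif any(c.group("carbons") == "0" and c.group("dbl") == "0" for c in chains):
        linkage = "lyso"
    elif any(c.group("prefix") == "O-" for c in chains):
        linkage = "ether_O"
    elif any(c.group("prefix") == "P-" for c in chains):
        linkage = "ether_P"
    else:
        linkage = "diacyl"

    is_lecithin = cls == "PC" and linkage == "diacyl"
    is_sphingomyelin = cls == "SM"
    return cls, linkage, is_lecithin, is_sphingomyelin


def mz_for_adduct(neutral_mass: float, adduct: str) -> float:
    """m/z of a singly charged adduct: [M+H]+ adds, [M-H]- subtracts a proton."""
    if not neutral_mass > 0:
        raise ValueError(f"neutral_mass must be positive, got {neutral_mass}")
    canon = _canonical(adduct)
    if canon == "[M+H]+":
        return neutral_mass + PROTON_MASS
    if canon == "[M-H]-":
        return neutral_mass - PROTON_MASS
    raise ValueError(f"unsupported adduct label: {adduct!r}")


def neutral_mass_from_mz(mz: float, adduct: str) -> float:
    """Inverse of :func:`mz_for_adduct`."""
    canon = _canonical(adduct)
    if canon == "[M+H]+":
        return mz - PROTON_MASS
    if canon == "[M-H]-":
        return mz + PROTON_MASS
    raise ValueError(f"unsupported adduct label: {adduct!r}")


@dataclass(frozen=True)
class LipidSpecies:
    """One targeted lipid: identity, adduct and expected retention time."""

    name: str
    lipid_class: str
    linkage: str
    neutral_mass: float
    adduct: str
    expected_rt: float
    is_lecithin: bool
    is_sphingomyelin: bool

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise LibraryError(f"{self.name}: unknown lipid class {self.lipid_class!r}")
        if self.linkage not in LINKAGES:
            raise LibraryError(f"{self.name}: unknown linkage {self.linkage!r}")
        if not self.neutral_mass > 0:
            raise LibraryError(f"{self.name}: neutral_mass must be > 0")
        if self.expected_rt < 0:
            raise LibraryError(f"{self.name}: expected_rt must be >= 0")
        if _canonical(self.adduct) not in ADDUCTS:
            raise LibraryError(f"{self.name}: unsupported adduct {self.adduct!r}")
        if self.is_lecithin and not (self.lipid_class == "PC" and self.linkage == "diacyl"):
            raise LibraryError(f"{self.name}: lecithin flag requires a diacyl PC")
        if self.is_sphingomyelin != (self.lipid_class == "SM"):
            raise LibraryError(f"{self.name}: sphingomyelin flag must mirror class SM")

    @classmethod
    def from_name(
        cls, name: str, neutral_mass: float, adduct: str, expected_rt: float
    ) -> "LipidSpecies":
        """Build a species, deriving class/linkage/flags from the name."""
        lipid_class, linkage, is_lec, is_sm = annotate_species(name)
        return cls(
            name=name,
            lipid_class=lipid_class,
            linkage=linkage,
            neutral_mass=float(neutral_mass),
            adduct=_canonical(adduct),
            expected_rt=float(expected_rt),
            is_lecithin=is_lec,
            is_sphingomyelin=is_sm,
        )

    @property
    def mz(self) -> float:
        """Library target m/z under the species' adduct."""
        return mz_for_adduct(self.neutral_mass, self.adduct)


@dataclass
class LipidLibrary:
    """Ordered collection of :class:`LipidSpecies` with unique names."""

    species: list[LipidSpecies] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise LibraryError(f"duplicate species names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self) -> Iterator[LipidSpecies]:
        return iter(self.species)

    def __getitem__(self, name: str) -> LipidSpecies:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def counts_by_class(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for s in self.species:
            tally[s.lipid_class] = tally.get(s.lipid_class, 0) + 1
        return tally

    @property
    def n_lecithin(self) -> int:
        return sum(s.is_lecithin for s in self.species)

    @property
    def n_sphingomyelin(self) -> int:
        return sum(s.is_sphingomyelin for s in self.species)

    def lecithin_names(self) -> list[str]:
        return [s.name for s in self.species if s.is_lecithin]

    def sphingomyelin_names(self) -> list[str]:
        return [s.name for s in self.species if s.is_sphingomyelin]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [s.name for s in self.species],
                "class": [s.lipid_class for s in self.species],
                "linkage": [s.linkage for s in self.species],
                "neutral_mass": [s.neutral_mass for s in self.species],
                "adduct": [s.adduct for s in self.species],
                "expected_rt": [s.expected_rt for s in self.species],
            }
        )


_REQUIRED_COLUMNS = ["name", "class", "linkage", "neutral_mass", "adduct", "expected_rt"]


def load_library(path: str | Path) -> LipidLibrary:
    """Load a lipid library from CSV.

    Expected header: ``name,class,linkage,neutral_mass,adduct,expected_rt``
    (UTF-8, dot decimal separator).  Row order is preserved; lecithin and
    sphingomyelin flags are derived from class and linkage.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise LibraryError(f"{path}: empty library file") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise LibraryError(f"{path}: missing required column(s) {missing}")
    if frame.empty:
        raise LibraryError(f"{path}: library file has no species rows")

    species = []
    for row in frame.to_dict("records"):
        cls = str(row["class"])
        linkage = str(row["linkage"])
        species.append(
            LipidSpecies(
                name=str(row["name"]),
                lipid_class=cls,
                linkage=linkage,
                neutral_mass=float(row["neutral_mass"]),
                adduct=_canonical(str(row["adduct"])),
                expected_rt=float(row["expected_rt"]),
                is_lecithin=cls == "PC" and linkage == "diacyl",
                is_sphingomyelin=cls == "SM",
            )
        )
    return LipidLibrary(species=species)


def save_library(library: LipidLibrary, path: str | Path) -> None:
    """Write a library to CSV (round-trips with :func:`load_library`)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# proton mass constant: {PROTON_MASS} Da\n")
        library.to_dataframe().to_csv(fh, index=False, float_format="%.6f")


def default_library() -> LipidLibrary:
    """The bundled default panel: 151 synthetic species (88 PC, 27 PE, 23 SM,
    13 Cer; 64 lecithins), generated deterministically."""
    from .simulate import generate_library

    return generate_library(seed=0)
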