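"""Compound library: the rule base for defense-compound annotation.

A :class:`CompoundLibrary` holds cardenolide genins (steroid + lactone cores),
sugar residues expressed as anhydro neutral-loss masses, the acetylation mass
shift, target glucosinolates, and the negative-mode diagnostic fragment list
used to flag unknown glucosinolate candidates.

The default library covers the nine genins reported for *Erysimum* leaf
cardenolides (digitoxigenin, dihydroxy-digitoxigenin, cannogenol, cannogenin,
strophanthidin, nigrescigenin, and the formyl/acetyl variants), four glycoside
residue masses (glucose, deoxyhexose, dideoxyhexose/digitoxose, xylose), and
the glucosinolates named for the genus. Dihydroxy-digitoxigenin (C23H34O6)
cannot be resolved between bipindogenin and strophanthidol by exact mass and
is stored by formula only; the nigrescigenin formula (C23H32O7) is likewise a
by-exact-mass assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .masses import ACETYL_MASS, monoisotopic_mass

#: |formula mass - stated mass| above this is treated as an inconsistency (Da).
MASS_CONSISTENCY_TOL = 0.0005


@dataclass(frozen=True)
class Genin:
    """A cardenolide aglycone: name, elemental formula, neutral mass (Da)."""

    name: str
    formula: Optional[str] = None
    mass: Optional[float] = None

    def __post_init__(self):
        if self.formula is None and self.mass is None:
            raise ValueError(f"genin {self.name!r}: need a formula or a mass")
        if self.formula is not None:
            fm = monoisotopic_mass(self.formula)
            if self.mass is None:
                object.__setattr__(self, "mass", fm)
            elif abs(fm - self.mass) >= MASS_CONSISTENCY_TOL:
                raise ValueError(
                    f"genin {self.name!r}: stated mass {self.mass} inconsistent "
                    f"with formula {self.formula} ({fm:.4f})"
                )
        if self.mass <= 0:
            raise ValueError(f"genin {self.name!r}: non-positive mass")


@dataclass(frozen=True)
class Sugar:
    """A glycoside residue as its anhydro neutral-loss mass (Da)."""

    name: str
    formula: Optional[str] = None
    loss_mass: Optional[float] = None

    def __post_init__(self):
        if self.formula is None and self.loss_mass is None:
            raise ValueError(f"sugar {self.name!r}: need a formula or a loss mass")
        if self.formula is not None:
            fm = monoisotopic_mass(self.formula)
            if self.loss_mass is None:
                object.__setattr__(self, "loss_mass", fm)
            elif abs(fm - self.loss_mass) >= MASS_CONSISTENCY_TOL:
                raise ValueError(
                    f"sugar {self.name!r}: loss mass {self.loss_mass} inconsistent "
                    f"with formula {self.formula} ({fm:.4f})"
                )
        if self.loss_mass <= 0:
            raise ValueError(f"sugar {self.name!r}: non-positive loss mass")


@dataclass(frozen=True)
class GlucosinolateTarget:
    """A target glucosinolate: neutral formula/mass plus a side-chain class."""

    name: str
    formula: Optional[str] = None
    mass: Optional[float] = None
    gls_class: str = "other"

    def __post_init__(self):
        if self.formula is None and self.mass is None:
            raise ValueError(f"glucosinolate {self.name!r}: need formula or mass")
        if self.formula is not None:
            fm = monoisotopic_mass(self.formula)
            if self.mass is None:
                object.__setattr__(self, "mass", fm)
            elif abs(fm - self.mass) >= MASS_CONSISTENCY_TOL:
                raise ValueError(
                    f"glucosinolate {self.name!r}: mass {self.mass} inconsistent "
                    f"with formula {self.formula} ({fm:.4f})"
                )
        if self.mass <= 0:
            raise ValueError(f"glucosinolate {self.name!r}: non-positive mass")


#: Negative-mode fragments diagnostic of the glucosinolate core (sulfate and
#: thioglucose-related ions). Configurable; these are conventional defaults.
DEFAULT_DIAGNOSTIC_FRAGMENTS_NEG = (96.9601, 95.9528, 74.9915, 259.0129, 241.0024)


@dataclass
class CompoundLibrary:
    """Rule base for cardenolide and glucosinolate annotation."""

    genins: list = field(default_factory=list)
    sugars: list = field(default_factory=list)
    glucosinolates: list = field(default_factory=list)
    acetyl_mass: float = ACETYL_MASS
    diagnostic_fragments_neg: tuple = DEFAULT_DIAGNOSTIC_FRAGMENTS_NEG

    def __post_init__(self):
        names = [g.name for g in self.genins]
        if len(set(names)) != len(names):
            raise ValueError("genin names must be unique")
        if self.acetyl_mass <= 0:
            raise ValueError("acetyl mass must be positive")
        if any(m <= 0 for m in self.diagnostic_fragments_neg):
            raise ValueError("diagnostic fragment m/z values must be positive")

    def genin_by_name(self, name: str) -> Genin:
        for g in self.genins:
            if g.name == name:
                return g
        raise KeyError(f"genin {name!r} not in library")

    def sugar_by_name(self, name: str) -> Sugar:
        for s in self.sugars:
            if s.name == name:
                return s
        raise KeyError(f"sugar {name!r} not in library")

    def glucosinolate_by_name(self, name: str) -> GlucosinolateTarget:
        for g in self.glucosinolates:
            if g.name == name:
                return g
        raise KeyError(f"glucosinolate {name!r} not in library")

    # ---- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "genins": [asdict(g) for g in self.genins],
            "sugars": [asdict(s) for s in self.sugars],
            "glucosinolates": [asdict(g) for g in self.glucosinolates],
            "acetyl_mass": self.acetyl_mass,
            "diagnostic_fragments_neg": list(self.diagnostic_fragments_neg),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CompoundLibrary":
        return cls(
            genins=[Genin(**g) for g in data.get("genins", [])],
            sugars=[Sugar(**s) for s in data.get("sugars", [])],
            glucosinolates=[
                GlucosinolateTarget(**g) for g in data.get("glucosinolates", [])
            ],
            acetyl_mass=data.get("acetyl_mass", ACETYL_MASS),
            diagnostic_fragments_neg=tuple(
                data.get("diagnostic_fragments_neg", DEFAULT_DIAGNOSTIC_FRAGMENTS_NEG)
            ),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CompoundLibrary":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "CompoundLibrary":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_library() -> CompoundLibrary:
    """The shipped rule base for *Erysimum*-style leaf defense chemistry."""
    genins = [
        Genin("digitoxigenin", "C23H34O4"),
        # bipindogenin vs strophanthidol unresolved by exact mass; kept by formula
        Genin("dihydroxy-digitoxigenin", "C23H34O6"),
        Genin("cannogenol", "C23H34O5"),
        Genin("cannogenin", "C23H32O5"),
        Genin("strophanthidin", "C23H32O6"),
        Genin("nigrescigenin", "C23H32O7"),  # tentative, by exact mass
        Genin("formyl-cannogenol", "C24H34O6"),
        Genin("acetyl-cannogenol", "C25H36O6"),
        Genin("formyl-nigrescigenin", "C24H32O8"),
    ]
    sugars = [
        Sugar("hexose", "C6H10O5"),        # glucose: 162.0528
        Sugar("deoxyhexose", "C6H10O4"),   # rhamnose/fucose/gulomethylose: 146.0579
        Sugar("dideoxyhexose", "C6H10O3"), # digitoxose: 130.0630
        Sugar("pentose", "C5H8O4"),        # xylose: 132.0423
    ]
    glucosinolates = [
        GlucosinolateTarget("glucoiberin", "C11H21NO10S3", gls_class="MSI"),
        GlucosinolateTarget("glucocheirolin", "C11H21NO11S3", gls_class="MSO"),
        GlucosinolateTarget("sinigrin", "C10H17NO9S2", gls_class="ALK"),
        GlucosinolateTarget("gluconapin", "C11H19NO9S2", gls_class="ALK"),
        GlucosinolateTarget("glucoraphanin", "C12H23NO10S3", gls_class="MSI"),
        GlucosinolateTarget("glucoalyssin", "C13H25NO10S3", gls_class="MSI"),
        GlucosinolateTarget("glucoerypestrin", "C12H21NO11S2", gls_class="CARB"),
        GlucosinolateTarget(
            "2-hydroxypropyl glucosinolate", "C10H19NO10S2", gls_class="OH"
        ),
        GlucosinolateTarget("glucobrassicin", "C16H20N2O9S2", gls_class="IND"),
    ]
    return CompoundLibrary(genins=genins, sugars=sugars, glucosinolates=glucosinolates)
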