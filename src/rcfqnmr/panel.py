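"""Compound panel: resonance assignments for RCF-oil aromatic monomers.

The default panel encodes the twelve compounds relevant to poplar RCF oil:
the four primary monomers (4-propyl- and 4-(3-hydroxypropyl)-syringol and
-guaiacol), the minor 4-ethyl and 4-propenyl analogues, the p-hydroxybenzoate
derivatives (p-hydroxybenzoic acid and methyl paraben), phenol, and the
internal standard 1,3,5-tri-tert-butylbenzene (TTB).

Each compound carries its assigned resonances: chemical-shift center,
first-order multiplicity, couplings, proton count, the ppm integration
window, and whether the resonance is used for quantification, as a
side-chain diagnostic, or is a known interference.  Panels are plain YAML
files so that new substrates (e.g. switchgrass hydroxycinnamates) can be
added without code changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from typing import Iterable

import yaml

__all__ = [
    "Resonance",
    "Compound",
    "Panel",
    "default_panel",
    "get_compound",
    "overlap_pairs",
    "molar_mass_from_formula",
    "PanelError",
    "UnknownCompoundError",
]

# Standard atomic weights (IUPAC 2021, conventional values).
ATOMIC_WEIGHTS = {
    "C": 12.011,
    "H": 1.008,
    "O": 15.999,
    "N": 14.007,
    "S": 32.06,
}

MULTIPLICITIES = ("singlet", "doublet", "dd", "multiplet")
ROLES = ("quantification", "diagnostic", "interference")
CLASSES = ("S", "G", "H", "phenol", "internal_standard")
SIDE_CHAINS = ("propyl", "hydroxypropyl", "ethyl", "propenyl", "none")

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class PanelError(ValueError):
    """Invalid panel, compound or resonance definition."""


class UnknownCompoundError(KeyError):
    """Requested abbreviation is not present in the panel."""


def molar_mass_from_formula(formula: str) -> float:
    """Molar mass (g/mol) from a molecular formula like ``C11H16O3``."""
    pos = 0
    mass = 0.0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise PanelError(f"cannot parse molecular formula {formula!r}")
        if not m.group(0):
            break
        sym, count = m.group(1), int(m.group(2) or 1)
        if sym not in ATOMIC_WEIGHTS:
            raise PanelError(f"unknown element {sym!r} in formula {formula!r}")
        mass += ATOMIC_WEIGHTS[sym] * count
        pos = m.end()
    if pos != len(formula) or mass == 0.0:
        raise PanelError(f"cannot parse molecular formula {formula!r}")
    return mass


@dataclass(frozen=True)
class Resonance:
    """One assigned multiplet of a compound.

    ``window`` is the closed ppm interval integrated for this resonance;
    ``envelope_fwhm_ppm`` is the Gaussian envelope width used for
    ``multiplet`` resonances, which are simulated (and corrected) as
    unresolved envelopes rather than explicit line patterns.
    """

    label: str
    center_ppm: float
    multiplicity: str
    j_hz: tuple[float, ...]
    n_protons: int
    window: tuple[float, float]
    role: str
    primary: bool = False
    envelope_fwhm_ppm: float = 0.04

    def __post_init__(self):
        lo, hi = self.window
        if not lo < hi:
            raise PanelError(f"{self.label}: window must satisfy low < high, got {self.window}")
        if self.multiplicity not in MULTIPLICITIES:
            raise PanelError(f"{self.label}: bad multiplicity {self.multiplicity!r}")
        if self.role not in ROLES:
            raise PanelError(f"{self.label}: bad role {self.role!r}")
        if self.n_protons < 1:
            raise PanelError(f"{self.label}: n_protons must be >= 1")
        if self.multiplicity == "singlet" and self.j_hz:
            raise PanelError(f"{self.label}: singlet must have empty j_hz")
        if self.role == "quantification" and not (lo <= self.center_ppm <= hi):
            raise PanelError(
                f"{self.label}: quantification center {self.center_ppm} outside window {self.window}"
            )


@dataclass(frozen=True)
class Compound:
    abbrev: str
    name: str
    molecular_formula: str
    cls: str
    resonances: tuple[Resonance, ...]
    side_chain: str = "none"

    def __post_init__(self):
        if self.cls not in CLASSES:
            raise PanelError(f"{self.abbrev}: bad class {self.cls!r}")
        if self.side_chain not in SIDE_CHAINS:
            raise PanelError(f"{self.abbrev}: bad side_chain {self.side_chain!r}")
        n_primary = sum(1 for r in self.resonances if r.primary)
        if n_primary != 1:
            raise PanelError(
                f"{self.abbrev}: exactly one primary quantification resonance required, got {n_primary}"
            )
        prim = self.primary_resonance
        if prim.role != "quantification":
            raise PanelError(f"{self.abbrev}: primary resonance must have quantification role")

    @property
    def molar_mass(self) -> float:
        return molar_mass_from_formula(self.molecular_formula)

    @property
    def primary_resonance(self) -> Resonance:
        return next(r for r in self.resonances if r.primary)


@dataclass
class Panel:
    compounds: list[Compound]
    version: str = "poplar-1"
    # Annotated overlap pairs: (abbrev_a, abbrev_b, note).  Windows of
    # distinct compounds may only collide where such an annotation exists.
    overlaps: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self):
        abbrevs = [c.abbrev for c in self.compounds]
        if len(abbrevs) != len(set(abbrevs)):
            raise PanelError("compound abbreviations must be unique within a panel")

    def abbrevs(self) -> list[str]:
        return [c.abbrev for c in self.compounds]

    def __contains__(self, abbrev: str) -> bool:
        return abbrev in self.abbrevs()

    def get(self, abbrev: str) -> Compound:
        for c in self.compounds:
            if c.abbrev == abbrev:
                return c
        raise UnknownCompoundError(
            f"unknown compound {abbrev!r}; available: {', '.join(self.abbrevs())}"
        )

    @property
    def internal_standard(self) -> Compound:
        for c in self.compounds:
            if c.cls == "internal_standard":
                return c
        raise PanelError("panel has no internal standard")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def res_dict(r: Resonance) -> dict:
            d = asdict(r)
            d["j_hz"] = list(r.j_hz)
            d["window"] = list(r.window)
            return d

        return {
            "version": self.version,
            "overlaps": [list(o) for o in self.overlaps],
            "compounds": [
                {
                    "abbrev": c.abbrev,
                    "name": c.name,
                    "molecular_formula": c.molecular_formula,
                    "cls": c.cls,
                    "side_chain": c.side_chain,
                    "resonances": [res_dict(r) for r in c.resonances],
                }
                for c in self.compounds
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Panel":
        compounds = []
        for cd in d["compounds"]:
            resonances = tuple(
                Resonance(
                    label=rd["label"],
                    center_ppm=float(rd["center_ppm"]),
                    multiplicity=rd["multiplicity"],
                    j_hz=tuple(float(j) for j in rd.get("j_hz", [])),
                    n_protons=int(rd["n_protons"]),
                    window=(float(rd["window"][0]), float(rd["window"][1])),
                    role=rd["role"],
                    primary=bool(rd.get("primary", False)),
                    envelope_fwhm_ppm=float(rd.get("envelope_fwhm_ppm", 0.04)),
                )
                for rd in cd["resonances"]
            )
            compounds.append(
                Compound(
                    abbrev=cd["abbrev"],
                    name=cd["name"],
                    molecular_formula=cd["molecular_formula"],
                    cls=cd["cls"],
                    resonances=resonances,
                    side_chain=cd.get("side_chain", "none"),
                )
            )
        return cls(
            compounds=compounds,
            version=d.get("version", "custom"),
            overlaps=[tuple(o) for o in d.get("overlaps", [])],
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Panel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> list[str]:
        """Return a list of problems (empty if the panel is consistent)."""
        problems = []
        annotated = {frozenset((a, b)) for a, b, _ in self.overlaps}
        quant = [
            (c.abbrev, r)
            for c in self.compounds
            for r in c.resonances
            if r.role == "quantification"
        ]
        for i, (a, ra) in enumerate(quant):
            for b, rb in quant[i + 1 :]:
                if a == b:
                    continue
                lo = max(ra.window[0], rb.window[0])
                hi = min(ra.window[1], rb.window[1])
                if lo < hi and frozenset((a, b)) not in annotated:
                    problems.append(
                        f"unannotated quantification-window overlap {a}/{ra.label} vs {b}/{rb.label}"
                    )
        return problems


# ---------------------------------------------------------------------------
# Default poplar panel
# ---------------------------------------------------------------------------

def _s(label, center, nH, window, role="diagnostic", primary=False, env=0.04):
    return Resonance(label, center, "singlet", (), nH, window, role, primary, env)


def _d(label, center, j, nH, window, role="diagnostic", primary=False):
    return Resonance(label, center, "doublet", (j,), nH, window, role, primary)


def _dd(label, center, j1, j2, nH, window, role="diagnostic", primary=False):
    return Resonance(label, center, "dd", (j1, j2), nH, window, role, primary)


def _m(label, center, nH, window, role="diagnostic", primary=False, env=0.04):
    return Resonance(label, center, "multiplet", (), nH, window, role, primary, env)


# Aliphatic side-chain windows are shared between S- and G-type compounds
# carrying the same chain; shifts depend on the chain, not the ring.
_PROPYL = lambda: (
    _m("propyl-gamma", 0.895, 3, (0.86, 0.93)),
    _m("propyl-beta", 1.585, 2, (1.53, 1.64), env=0.05),
    _m("propyl-alpha", 2.50, 2, (2.45, 2.55), env=0.05),
)
_HYDROXYPROPYL = lambda: (
    _m("hydroxypropyl-gamma", 3.515, 2, (3.45, 3.58)),
    # beta overlaps the propenyl gamma-CH3; alpha overlaps the ethyl alpha.
    _m("hydroxypropyl-beta", 1.82, 2, (1.77, 1.87), role="interference", env=0.05),
    _m("hydroxypropyl-alpha", 2.58, 2, (2.53, 2.63), role="interference", env=0.05),
)
_ETHYL = lambda: (
    _m("ethyl-beta", 1.165, 3, (1.13, 1.20)),
    _m("ethyl-alpha", 2.555, 2, (2.51, 2.60), role="interference", env=0.05),
)
_PROPENYL = lambda: (
    _d("alkene-alpha", 6.315, 15.8, 1, (6.28, 6.35)),
    _m("alkene-beta", 6.105, 1, (6.06, 6.15), env=0.05),
    _d("propenyl-gamma", 1.84, 6.6, 3, (1.80, 1.88)),
)
_OME_S = lambda: (_m("OMe", 3.82, 6, (3.78, 3.86), env=0.03),)
_OME_G = lambda: (_m("OMe", 3.86, 3, (3.82, 3.90), env=0.03),)


def default_panel() -> Panel:
    """The 12-compound poplar panel with all default windows populated.

    Exact shifts inside the 6.46-6.50 ppm S-band and the TTB aromatic shift
    (set at 7.30 ppm by convention) are defaults and can be overridden by
    loading an edited panel file.
    """
    compounds = [
        Compound(
            "PS", "4-propylsyringol", "C11H16O3", "S",
            (_s("S2/6", 6.462, 2, (6.450, 6.470), role="quantification", primary=True),)
            + _PROPYL() + _OME_S(),
            side_chain="propyl",
        ),
        Compound(
            "PSOH", "4-(3-hydroxypropyl)syringol", "C11H16O4", "S",
            (_s("S2/6", 6.475, 2, (6.470, 6.480), role="quantification", primary=True),)
            + _HYDROXYPROPYL() + _OME_S(),
            side_chain="hydroxypropyl",
        ),
        Compound(
            "ES", "4-ethylsyringol", "C10H14O3", "S",
            (_s("S2/6", 6.490, 2, (6.480, 6.500), role="quantification", primary=True),)
            + _ETHYL() + _OME_S(),
            side_chain="ethyl",
        ),
        Compound(
            "PES", "4-propenylsyringol", "C11H14O3", "S",
            (_s("S2/6", 6.660, 2, (6.645, 6.675), role="quantification", primary=True),)
            + _PROPENYL() + _OME_S(),
            side_chain="propenyl",
        ),
        Compound(
            "PG", "4-propylguaiacol", "C10H14O2", "G",
            (
                _s("G2", 6.780, 1, (6.768, 6.792), role="quantification", primary=True),
                _m("G5", 6.870, 1, (6.84, 6.90), role="interference", env=0.03),
                _m("G6", 6.720, 1, (6.69, 6.75), role="interference", env=0.03),
            )
            + _PROPYL() + _OME_G(),
            side_chain="propyl",
        ),
        Compound(
            "PGOH", "4-(3-hydroxypropyl)guaiacol", "C10H14O3", "G",
            (
                _s("G2", 6.806, 1, (6.792, 6.820), role="quantification", primary=True),
                _m("G5", 6.875, 1, (6.845, 6.905), role="interference", env=0.03),
                _m("G6", 6.725, 1, (6.695, 6.755), role="interference", env=0.03),
            )
            + _HYDROXYPROPYL() + _OME_G(),
            side_chain="hydroxypropyl",
        ),
        Compound(
            "EG", "4-ethylguaiacol", "C9H12O2", "G",
            (
                # Overlaps the PGOH G2 window: never integrated directly.
                _s("G2", 6.800, 1, (6.792, 6.820), role="quantification", primary=True),
                _m("G5", 6.865, 1, (6.835, 6.895), role="interference", env=0.03),
                _m("G6", 6.715, 1, (6.685, 6.745), role="interference", env=0.03),
            )
            + _ETHYL() + _OME_G(),
            side_chain="ethyl",
        ),
        Compound(
            "PEG", "4-propenylguaiacol (isoeugenol)", "C10H12O2", "G",
            (
                _s("G2", 6.990, 1, (6.978, 7.002), role="quantification", primary=True),
                # Broad dd straddling the lower edge of the PG G2 window;
                # roughly half its area falls inside, hence the 50 % rule.
                _dd("G5", 6.768, 8.2, 1.9, 1, (6.74, 6.80), role="interference"),
            )
            + _PROPENYL() + _OME_G(),
            side_chain="propenyl",
        ),
        Compound(
            "PHBA", "p-hydroxybenzoic acid", "C7H6O3", "H",
            (
                _d("H2/6", 7.900, 8.7, 2, (7.87, 7.93), role="quantification", primary=True),
                _d("H3/5", 6.915, 8.7, 2, (6.89, 6.94)),
            ),
        ),
        Compound(
            "MP", "methyl paraben", "C8H8O3", "H",
            (
                # Shares both printed windows with PHBA; reported as a sum.
                _d("H2/6", 7.905, 8.8, 2, (7.87, 7.93), role="quantification", primary=True),
                _d("H3/5", 6.920, 8.8, 2, (6.89, 6.94)),
                _m("OMe", 3.84, 3, (3.80, 3.88), env=0.03),
            ),
        ),
        Compound(
            "PHENOL", "phenol", "C6H6O", "phenol",
            (
                _m("H3/5", 7.180, 2, (7.14, 7.22), role="quantification", primary=True),
                _m("H2/6+H4", 6.810, 3, (6.77, 6.85), role="interference", env=0.05),
            ),
        ),
        Compound(
            "TTB", "1,3,5-tri-tert-butylbenzene", "C18H30", "internal_standard",
            (
                _s("aromatic", 7.300, 3, (7.28, 7.32), role="quantification", primary=True),
                _s("tert-butyl", 1.320, 27, (1.29, 1.35)),
            ),
        ),
    ]
    overlaps = [
        ("PG", "PEG", "PEG G5 (broad dd) partially overlaps the PG G2 window; 50% of the PEG G2 integral is subtracted"),
        ("PGOH", "EG", "EG G2 (6.80 ppm) falls inside the PGOH G2 window; EG is never integrated directly"),
        ("PG", "PHENOL", "phenol 6.77-6.85 multiplet overlaps the G2 region; high phenol precludes G2 use"),
        ("PGOH", "PHENOL", "phenol 6.77-6.85 multiplet overlaps the G2 region; high phenol precludes G2 use"),
        ("ES", "PS", "ES S2/6 sits close to the PS/PSOH singlets; ES reported only when a distinct maximum is found"),
        ("ES", "PSOH", "ES S2/6 sits close to the PS/PSOH singlets; ES reported only when a distinct maximum is found"),
        ("PHBA", "MP", "H2/6 and H3/5 windows are shared; the H2/6 window is reported as their sum"),
    ]
    return Panel(compounds=compounds, version="poplar-1", overlaps=overlaps)


# ---------------------------------------------------------------------------
# Flat operation surface
# ---------------------------------------------------------------------------

def get_compound(panel: Panel, abbrev: str) -> Compound:
    """Look up a compound by abbreviation; raise listing valid names if absent."""
    return panel.get(abbrev)


def overlap_pairs(panel: Panel) -> list[tuple[Compound, Compound, str]]:
    """All annotated overlap pairs as (compound, compound, note) triples."""
    return [(panel.get(a), panel.get(b), note) for a, b, note in panel.overlaps]


# The S-band group resolved jointly by the quantifier.
S_BAND_GROUP = ("PS", "PSOH", "ES")
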