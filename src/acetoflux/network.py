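"""Species/reaction data model for acetogen central-metabolism schemes.

The model is deliberately small: one cytoplasmic compartment plus a
membrane proton tally.  Electron carriers (ferredoxin, NAD(P)H) are
abstract conjugate pairs whose reduced member carries exactly two
electrons, recorded as the pseudo-element ``e`` in its formula; their
protein/nucleotide scaffolds are never expanded atomically.  Free
protons are omitted from individual reactions (they are tracked only as
charge bookkeeping and as the translocated-proton tally), so hydrogen is
balanced *modulo* free H+ while carbon, oxygen and electrons must close
exactly.  All stoichiometric coefficients are exact rationals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = [
    "Species",
    "Reaction",
    "MetabolicNetwork",
    "StoichMatrix",
    "NetworkValidationError",
    "UnknownSpeciesError",
    "ROLES",
    "degree_of_reduction",
    "available_electrons",
    "check_element_balance",
    "build_stoichiometric_matrix",
    "load_network",
    "save_network",
    "bundled_network_path",
]

ROLES = ("feed", "product", "external", "carrier", "intermediate")

#: elements accepted in species formulas (plus the carrier pseudo-element "e")
ELEMENTS = ("C", "H", "O", "N", "S", "P", "Fe")

#: electrons made available per atom when fully oxidized to CO2/H2O/NH3/SO4/PO4
_GAMMA_WEIGHTS = {"C": 4, "H": 1, "O": -2, "N": -3, "S": 6, "P": 5, "Fe": 0}


class NetworkValidationError(ValueError):
    """A network document violates a structural invariant; message carries the field path."""


class UnknownSpeciesError(KeyError):
    """A reaction references a species id that is not defined in the network."""


def _as_fraction(value: Union[int, str, Fraction]) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, str):
        return Fraction(value)
    if isinstance(value, float) and value == int(value):
        return Fraction(int(value))
    raise NetworkValidationError(
        f"stoichiometric coefficient {value!r} is not an exact rational; "
        "write integers or strings like '1/2'"
    )


@dataclass
class Species:
    """A chemical or carrier entity of the network.

    ``formula`` maps element symbol -> non-negative integer count; the
    pseudo-element ``e`` records electrons carried by a reduced carrier
    (2 per Fd_red/NADH/NADPH unit).  ``carrier_pair`` names the conjugate
    partner of a redox pair (oxidized <-> reduced) and is required for
    (and only for) ``role == "carrier"``.
    """

    id: str
    name: str
    formula: dict[str, int] = field(default_factory=dict)
    charge: int = 0
    role: str = "intermediate"
    carrier_pair: Optional[str] = None

    def validate(self) -> None:
        if self.role not in ROLES:
            raise NetworkValidationError(
                f"species[{self.id}].role: {self.role!r} not one of {ROLES}"
            )
        for elem, count in self.formula.items():
            if elem != "e" and elem not in ELEMENTS:
                raise NetworkValidationError(
                    f"species[{self.id}].formula: unknown element {elem!r}"
                )
            if not isinstance(count, int) or count < 0:
                raise NetworkValidationError(
                    f"species[{self.id}].formula[{elem}]: counts must be "
                    f"non-negative integers, got {count!r}"
                )
        if self.role == "carrier" and self.carrier_pair is None:
            raise NetworkValidationError(
                f"species[{self.id}]: role 'carrier' requires a carrier_pair"
            )


@dataclass
class Reaction:
    """Signed stoichiometry over species plus a translocated-proton count.

    ``stoich`` maps species id -> signed rational coefficient (negative =
    consumed).  ``protons_translocated`` is the number of protons exported
    across the membrane per unit flux (positive = exported; e.g. the Rnf
    complex) and is independent of the cytoplasmic free protons omitted
    from ``stoich``.
    """

    id: str
    enzyme: str
    stoich: dict[str, Fraction]
    protons_translocated: Fraction = Fraction(0)
    reversible: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        self.stoich = {sp: _as_fraction(c) for sp, c in self.stoich.items()}
        self.protons_translocated = _as_fraction(self.protons_translocated)

    def validate(self) -> None:
        if not self.stoich:
            raise NetworkValidationError(f"reaction[{self.id}].stoich: must be non-empty")


@dataclass
class MetabolicNetwork:
    """A named set of species and reactions over them."""

    name: str
    species: list[Species]
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        self._index = {sp.id: sp for sp in self.species}

    def validate(self) -> None:
        seen: set[str] = set()
        for sp in self.species:
            sp.validate()
            if sp.id in seen:
                raise NetworkValidationError(f"species[{sp.id}]: duplicate id")
            seen.add(sp.id)
        for sp in self.species:
            if sp.role == "carrier":
                partner = self._index.get(sp.carrier_pair)
                if partner is None:
                    raise NetworkValidationError(
                        f"species[{sp.id}].carrier_pair: unknown species "
                        f"{sp.carrier_pair!r}"
                    )
                if partner.carrier_pair != sp.id:
                    raise NetworkValidationError(
                        f"species[{sp.id}]: carrier pairing with {partner.id!r} "
                        "is not symmetric"
                    )
        rseen: set[str] = set()
        for rxn in self.reactions:
            rxn.validate()
            if rxn.id in rseen:
                raise NetworkValidationError(f"reaction[{rxn.id}]: duplicate id")
            rseen.add(rxn.id)
            for sp_id in rxn.stoich:
                if sp_id not in self._index:
                    raise UnknownSpeciesError(
                        f"reaction[{rxn.id}]: unknown species {sp_id!r}"
                    )

    def species_by_id(self, sp_id: str) -> Species:
        try:
            return self._index[sp_id]
        except KeyError:
            raise UnknownSpeciesError(f"unknown species {sp_id!r}") from None

    def reaction_by_id(self, rxn_id: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rxn_id:
                return rxn
        raise KeyError(f"unknown reaction {rxn_id!r}")


def degree_of_reduction(species: Species) -> int:
    """Available electrons gamma of a species from its elemental formula.

    gamma = 4 C + H - 2 O - 3 N + 6 S + 5 P - charge, i.e. the electrons
    released on complete oxidation to CO2/H2O (with N, S, P at their
    standard reference states).  The charge term makes gamma the count
    for the ionic form actually written (acetate- carries 8, H+ carries
    0), so gamma-weighted sums close for reactions written modulo free
    protons.  Always an integer.
    """
    gamma = sum(
        _GAMMA_WEIGHTS[elem] * count
        for elem, count in species.formula.items()
        if elem != "e"
    )
    return gamma - species.charge


def available_electrons(species: Species) -> int:
    """Degree of reduction plus electrons carried on a reduced carrier."""
    return degree_of_reduction(species) + species.formula.get("e", 0)


def check_element_balance(
    reaction: Reaction, network: MetabolicNetwork
) -> dict[str, Fraction]:
    """Per-element residual (products minus reactants) of one reaction.

    Returns residuals for every element appearing in the participating
    formulas plus the pseudo-element ``"e"`` (the gamma-weighted electron
    balance, in which reduced carriers count their carried electrons) and
    ``"charge"``.  A reaction is element-consistent when C, O, N, S, P and
    "e" residuals are zero; the H residual measures the free protons the
    scheme omits and is reported for charge bookkeeping, not enforced.
    """
    residuals: dict[str, Fraction] = {"e": Fraction(0), "charge": Fraction(0)}
    for sp_id, coeff in reaction.stoich.items():
        sp = network.species_by_id(sp_id)
        for elem, count in sp.formula.items():
            if elem == "e":
                continue
            residuals[elem] = residuals.get(elem, Fraction(0)) + coeff * count
        residuals["e"] += coeff * available_electrons(sp)
        residuals["charge"] += coeff * sp.charge
    return residuals


@dataclass
class StoichMatrix:
    """Exact-rational stoichiometric matrix, species x reactions.

    ``entries[i][j]`` is reaction j's coefficient for species i; a
    separate ``proton_row`` tallies translocated protons per reaction.
    """

    species_ids: list[str]
    reaction_ids: list[str]
    entries: list[list[Fraction]]
    proton_row: list[Fraction]

    def apply(self, flux: dict[str, Fraction]) -> dict[str, Fraction]:
        """Net species production for a flux vector (matrix-vector product)."""
        v = [flux.get(rid, Fraction(0)) for rid in self.reaction_ids]
        out: dict[str, Fraction] = {}
        for sp_id, row in zip(self.species_ids, self.entries):
            net = sum((c * f for c, f in zip(row, v)), Fraction(0))
            if net:
                out[sp_id] = net
        return out


def build_stoichiometric_matrix(network: MetabolicNetwork) -> StoichMatrix:
    network.validate()
    species_ids = [sp.id for sp in network.species]
    index = {sp_id: i for i, sp_id in enumerate(species_ids)}
    reaction_ids = [rxn.id for rxn in network.reactions]
    entries = [[Fraction(0)] * len(reaction_ids) for _ in species_ids]
    proton_row = [Fraction(0)] * len(reaction_ids)
    for j, rxn in enumerate(network.reactions):
        for sp_id, coeff in rxn.stoich.items():
            entries[index[sp_id]][j] = coeff
        proton_row[j] = rxn.protons_translocated
    return StoichMatrix(species_ids, reaction_ids, entries, proton_row)


# ---------------------------------------------------------------------------
# structured-text (YAML) serialization


def _species_to_doc(sp: Species) -> dict:
    doc: dict = {"id": sp.id, "name": sp.name, "formula": dict(sp.formula),
                 "charge": sp.charge, "role": sp.role}
    if sp.carrier_pair is not None:
        doc["carrier_pair"] = sp.carrier_pair
    return doc


def _reaction_to_doc(rxn: Reaction) -> dict:
    return {
        "id": rxn.id,
        "enzyme": rxn.enzyme,
        "stoich": {sp: str(c) for sp, c in rxn.stoich.items()},
        "protons_translocated": str(rxn.protons_translocated),
        "reversible": rxn.reversible,
        "note": rxn.note,
    }


def save_network(network: MetabolicNetwork, path: Union[str, Path]) -> None:
    doc = {
        "name": network.name,
        "species": [_species_to_doc(sp) for sp in network.species],
        "reactions": [_reaction_to_doc(rxn) for rxn in network.reactions],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_network(path: Union[str, Path]) -> MetabolicNetwork:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise NetworkValidationError("network document must be a mapping")
    for key in ("name", "species", "reactions"):
        if key not in doc:
            raise NetworkValidationError(f"missing top-level key {key!r}")
    species = []
    for i, sdoc in enumerate(doc["species"]):
        try:
            species.append(
                Species(
                    id=sdoc["id"],
                    name=sdoc.get("name", sdoc["id"]),
                    formula=dict(sdoc.get("formula") or {}),
                    charge=int(sdoc.get("charge", 0)),
                    role=sdoc.get("role", "intermediate"),
                    carrier_pair=sdoc.get("carrier_pair"),
                )
            )
        except KeyError as exc:
            raise NetworkValidationError(f"species[{i}]: missing field {exc}") from None
    reactions = []
    for i, rdoc in enumerate(doc["reactions"]):
        try:
            reactions.append(
                Reaction(
                    id=rdoc["id"],
                    enzyme=rdoc.get("enzyme", ""),
                    stoich={sp: _as_fraction(c) for sp, c in rdoc["stoich"].items()},
                    protons_translocated=_as_fraction(rdoc.get("protons_translocated", 0)),
                    reversible=bool(rdoc.get("reversible", False)),
                    note=rdoc.get("note", ""),
                )
            )
        except KeyError as exc:
            raise NetworkValidationError(
                f"reactions[{i}]: missing field {exc}"
            ) from None
    network = MetabolicNetwork(name=doc["name"], species=species, reactions=reactions)
    network.validate()
    return network


def bundled_network_path() -> Path:
    """Path of the bundled C. ljungdahlii core network file."""
    return Path(__file__).parent / "data" / "networks" / "cljungdahlii_core.yaml"


def load_bundled_network() -> MetabolicNetwork:
    return load_network(bundled_network_path())
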