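"""Steady-state flux schemes and chemiosmotic ATP accounting.

A *scheme* fixes a feed gas, a product demand (the normalization basis),
and a set of assumption flags that select which reactions of the bundled
network are active.  The internal steady state (zero net production of
every carrier and intermediate) is solved in exact rational arithmetic;
the net ATP yield is the substrate-level tally plus the protons exported
by the Rnf complex divided by the ATP-synthase H+/ATP ratio.

Assumption flags understood by :func:`solve_scheme`:

``bifurcating-mthfr``
    methylene-THF reductase is the electron-bifurcating enzyme (2 NADH in,
    one pair to the methyl group, one to ferredoxin).
``nadh-mthfr``
    plain NADH-dependent methylene-THF reductase instead.
``ethanol-via-aor``
    ethanol is formed by reducing acetate to acetaldehyde through AOR
    (reductive direction) followed by the NADPH alcohol dehydrogenase
    step; the direct acetyl-CoA route stays inactive.
``ethanol-via-adhe``
    the direct AdhE route (acetyl-CoA -> acetaldehyde -> ethanol).
``acetate-from-acetaldehyde``
    acetate is formed through *both* Pta/Ack and the AdhE -> AOR
    (oxidative) route, with equal flux through the two branches.  Without
    this constraint the two routes form a one-dimensional family of
    steady states that differ in ATP, so the yield would be ill-defined.
``formate-from-h2``
    formate is made by the H2-dependent CO2 reductase instead of the
    NADPH-linked formate dehydrogenase.
``h2-evolution``
    allow net H2 evolution through the Fe-only hydrogenase on a CO feed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

import sympy
import yaml

from .network import (
    MetabolicNetwork,
    Reaction,
    _as_fraction,
)

__all__ = [
    "SchemePreset",
    "FluxDistribution",
    "InfeasibleSchemeError",
    "SchemeDefinitionError",
    "solve_scheme",
    "atp_yield",
    "net_overall_reaction",
    "redox_closure",
    "load_preset",
    "load_bundled_preset",
    "bundled_preset_names",
]

KNOWN_FLAGS = frozenset(
    {
        "bifurcating-mthfr",
        "nadh-mthfr",
        "ethanol-via-aor",
        "ethanol-via-adhe",
        "acetate-from-acetaldehyde",
        "formate-from-h2",
        "h2-evolution",
    }
)

#: reactions active in every scheme (the Wood-Ljungdahl trunk and the
#: chemiosmotic couple); the Table-1 summary rows (net_*) are never active.
_BASE_ACTIVE = (
    "codh", "fhs", "mthfc", "mthfd", "acs", "pta", "ack",
    "pfor", "als", "aldc", "bdh", "rnf", "nfn",
)

#: energy tokens excluded from steady-state balancing and net reactions
_ENERGY_TOKENS = frozenset({"atp", "adp"})


class SchemeDefinitionError(ValueError):
    """Preset is internally inconsistent (unknown flag, bad demand, ...)."""


class InfeasibleSchemeError(RuntimeError):
    """No carrier-balanced flux distribution satisfies the demand."""

    def __init__(self, message: str, unbalanced: Optional[dict] = None):
        super().__init__(message)
        self.unbalanced = unbalanced or {}


@dataclass
class SchemePreset:
    """Feed/product scheme with its assumption flags and chemiosmotic parameters."""

    name: str
    feed: str  # "CO" or "H2_CO2"
    product_demand: dict[str, Fraction]
    assumptions: list[str] = field(default_factory=list)
    rnf_h_per_fd: Fraction = Fraction(2)
    h_per_atp: Fraction = Fraction(4)

    def __post_init__(self) -> None:
        self.product_demand = {k: _as_fraction(v) for k, v in self.product_demand.items()}
        self.rnf_h_per_fd = _as_fraction(self.rnf_h_per_fd)
        self.h_per_atp = _as_fraction(self.h_per_atp)

    def validate(self, network: MetabolicNetwork) -> None:
        if self.feed not in ("CO", "H2_CO2"):
            raise SchemeDefinitionError(f"preset[{self.name}].feed: {self.feed!r}")
        if not self.product_demand:
            raise SchemeDefinitionError(f"preset[{self.name}]: product_demand is empty")
        for sp_id in self.product_demand:
            sp = network.species_by_id(sp_id)
            if sp.role != "product":
                raise SchemeDefinitionError(
                    f"preset[{self.name}]: {sp_id!r} is not a product species"
                )
        unknown = set(self.assumptions) - KNOWN_FLAGS
        if unknown:
            raise SchemeDefinitionError(
                f"preset[{self.name}]: unknown assumption flags {sorted(unknown)}"
            )
        if self.h_per_atp <= 0 or self.rnf_h_per_fd <= 0:
            raise SchemeDefinitionError(
                f"preset[{self.name}]: chemiosmotic parameters must be positive"
            )


@dataclass
class FluxDistribution:
    """Solved per-reaction fluxes on a preset's product basis."""

    preset: SchemePreset
    flux: dict[str, Fraction]
    pumped_protons: Fraction
    substrate_level_atp: Fraction
    net_atp: Fraction
    unique: bool
    network: MetabolicNetwork


def _active_reactions(preset: SchemePreset, network: MetabolicNetwork) -> list[str]:
    flags = set(preset.assumptions)
    active = list(_BASE_ACTIVE)
    if "nadh-mthfr" in flags:
        active.append("mthfr_nadh")
    else:
        active.append("mthfr")  # bifurcating enzyme is the default
    if "formate-from-h2" in flags:
        active.append("hdcr")
    else:
        active.append("fdh")
    if preset.feed == "H2_CO2":
        active.append("hyt")
    if "h2-evolution" in flags:
        active.append("hyd_fe")
    if "ethanol-via-aor" in flags or "acetate-from-acetaldehyde" in flags:
        active.append("aor")
    if "ethanol-via-aor" in flags or "ethanol-via-adhe" in flags:
        active.append("adhe_alc")
    if "ethanol-via-adhe" in flags or "acetate-from-acetaldehyde" in flags:
        active.append("adhe_ald")
    if "lactate" in preset.product_demand and preset.product_demand["lactate"] != 0:
        active.append("ldh")
    known = {r.id for r in network.reactions}
    missing = [r for r in active if r not in known]
    if missing:
        raise SchemeDefinitionError(
            f"preset[{preset.name}]: network lacks reactions {missing}"
        )
    return active


def _balanced_species(preset: SchemePreset, network: MetabolicNetwork) -> list[str]:
    balanced = [
        sp.id
        for sp in network.species
        if sp.role in ("carrier", "intermediate") and sp.id not in _ENERGY_TOKENS
    ]
    # the non-feed gas is internal: CO made by CODH on H2/CO2 must be consumed
    # by ACS; H2 may not appear on a CO feed unless evolution is allowed
    if preset.feed == "H2_CO2":
        balanced.append("co")
    elif "h2-evolution" not in preset.assumptions:
        balanced.append("h2")
    return balanced


def solve_scheme(
    network: MetabolicNetwork,
    preset: SchemePreset,
    exclude_reactions: Optional[set[str]] = None,
) -> FluxDistribution:
    """Solve the internal steady state of a scheme in exact rational arithmetic.

    Raises :class:`InfeasibleSchemeError` (naming the unbalanced carriers)
    when no flux vector satisfies all balances, and flags the distribution
    as non-unique (returning the minimum-norm solution) if the active
    subnetwork retains a nullspace after the preset's constraints.
    ``exclude_reactions`` deactivates reactions for what-if diagnostics
    (e.g. removing the Rnf complex shows the resulting carrier imbalance).
    """
    network.validate()
    preset.validate(network)
    active = _active_reactions(preset, network)
    if exclude_reactions:
        active = [rid for rid in active if rid not in exclude_reactions]
    reactions = {rid: network.reaction_by_id(rid) for rid in active}
    balanced = _balanced_species(preset, network)
    products = [sp.id for sp in network.species if sp.role == "product"]

    rows: list[list[Fraction]] = []
    rhs: list[Fraction] = []
    row_labels: list[str] = []
    for sp_id in balanced + products:
        rows.append([reactions[r].stoich.get(sp_id, Fraction(0)) for r in active])
        rhs.append(preset.product_demand.get(sp_id, Fraction(0)) if sp_id in products else Fraction(0))
        row_labels.append(sp_id)
    if "acetate-from-acetaldehyde" in preset.assumptions:
        # equal flux through Pta/Ack and the AdhE->AOR oxidative branch
        row = [Fraction(0)] * len(active)
        row[active.index("ack")] = Fraction(1)
        row[active.index("aor")] = Fraction(-1)
        rows.append(row)
        rhs.append(Fraction(0))
        row_labels.append("constraint:ack=aor")

    A = sympy.Matrix([[sympy.Rational(c) for c in row] for row in rows])
    b = sympy.Matrix([sympy.Rational(v) for v in rhs])

    try:
        sol, params = A.gauss_jordan_solve(b)
    except ValueError:
        unbalanced = _infeasibility_diagnostics(A, b, row_labels, network)
        raise InfeasibleSchemeError(
            f"preset[{preset.name}]: no carrier-balanced flux distribution; "
            f"unbalanced species: {', '.join(sorted(unbalanced)) or 'unknown'}",
            unbalanced=unbalanced,
        ) from None

    unique = len(params) == 0
    if not unique:
        v0 = sol.subs({p: sympy.Integer(0) for p in params})
        nullspace = A.nullspace()
        N = sympy.Matrix.hstack(*nullspace)
        tau = (N.T * N).solve(-N.T * v0)
        v = v0 + N * tau
    else:
        v = sol

    flux = {rid: Fraction(int(v[i].p), int(v[i].q)) for i, rid in enumerate(active)}
    _check_directions(preset, reactions, flux)

    pumped = Fraction(0)
    slp = Fraction(0)
    for rid, f in flux.items():
        protons = preset.rnf_h_per_fd if rid == "rnf" else reactions[rid].protons_translocated
        pumped += f * protons
        slp += f * reactions[rid].stoich.get("atp", Fraction(0))
    chemiosmotic = pumped / preset.h_per_atp
    flux["atps"] = chemiosmotic  # synthase flux pinned by the proton balance
    return FluxDistribution(
        preset=preset,
        flux=flux,
        pumped_protons=pumped,
        substrate_level_atp=slp,
        net_atp=slp + chemiosmotic,
        unique=unique,
        network=network,
    )


def _check_directions(
    preset: SchemePreset, reactions: dict[str, Reaction], flux: dict[str, Fraction]
) -> None:
    flags = set(preset.assumptions)
    if {"ethanol-via-aor", "acetate-from-acetaldehyde"} <= flags:
        raise SchemeDefinitionError(
            f"preset[{preset.name}]: AOR cannot run oxidatively and reductively "
            "in one scheme (futile cycle)"
        )
    for rid, f in flux.items():
        if not reactions[rid].reversible and f < 0:
            raise InfeasibleSchemeError(
                f"preset[{preset.name}]: irreversible reaction {rid!r} "
                f"requires negative flux {f}"
            )
    if "aor" in flux:
        if "ethanol-via-aor" in flags and flux["aor"] > 0:
            raise InfeasibleSchemeError(
                f"preset[{preset.name}]: AOR constrained reductive but solved "
                f"flux is {flux['aor']}"
            )
        if "acetate-from-acetaldehyde" in flags and flux["aor"] < 0:
            raise InfeasibleSchemeError(
                f"preset[{preset.name}]: AOR constrained oxidative but solved "
                f"flux is {flux['aor']}"
            )


def _infeasibility_diagnostics(A, b, row_labels, network) -> dict[str, Fraction]:
    """Name the balance rows that conflict, via an exact Farkas certificate.

    The system A v = b has no solution iff some y satisfies yT A = 0 with
    yT b != 0; the nonzero entries of the sparsest such certificate are the
    species whose balances cannot simultaneously close.  Carrier pairs are
    reported under a joint ox/red key.
    """
    best: Optional[dict[str, Fraction]] = None
    for y in A.T.nullspace():
        mismatch = (y.T * b)[0]
        if mismatch == 0:
            continue
        rows: dict[str, Fraction] = {}
        for i, label in enumerate(row_labels):
            if y[i] == 0 or label.startswith("constraint:"):
                continue
            sp = network.species_by_id(label)
            key = label
            if sp.role == "carrier":
                key = "/".join(sorted((label, sp.carrier_pair)))
            weight = Fraction(int(y[i].p), int(y[i].q))
            rows[key] = rows.get(key, Fraction(0)) + weight
        carriers = {k: v for k, v in rows.items() if "/" in k}
        if carriers:
            rows = carriers  # the carrier imbalance is the informative part
        if best is None or len(rows) < len(best):
            best = rows
    return best or {}


def atp_yield(dist: FluxDistribution, h_per_atp: Optional[Fraction] = None) -> Fraction:
    """Net ATP on the preset's product basis: substrate-level + pumped/h_per_atp."""
    if h_per_atp is None:
        h_per_atp = dist.preset.h_per_atp
    h_per_atp = _as_fraction(h_per_atp)
    if h_per_atp <= 0:
        raise ValueError(f"h_per_atp must be positive, got {h_per_atp}")
    return dist.substrate_level_atp + dist.pumped_protons / h_per_atp


def net_overall_reaction(dist: FluxDistribution) -> Reaction:
    """Collapse a solved scheme into one net exchange reaction.

    Internal species (carriers, intermediates) cancel at steady state;
    the ATP/ADP tokens are reported through the ATP tally instead.  Free
    protons, omitted from individual reactions, are restored here so the
    net reaction is written in the charged Table-1 style.
    """
    net: dict[str, Fraction] = {}
    for rid, f in dist.flux.items():
        if rid == "atps" or f == 0:
            continue
        for sp_id, coeff in dist.network.reaction_by_id(rid).stoich.items():
            sp = dist.network.species_by_id(sp_id)
            if sp.role in ("carrier", "intermediate") or sp_id in _ENERGY_TOKENS:
                continue
            net[sp_id] = net.get(sp_id, Fraction(0)) + f * coeff
    net = {k: v for k, v in net.items() if v != 0}
    h_residual = sum(
        (coeff * dist.network.species_by_id(sp_id).formula.get("H", 0)
         for sp_id, coeff in net.items()),
        Fraction(0),
    )
    if h_residual != 0:
        net["h_plus"] = net.get("h_plus", Fraction(0)) - h_residual
        if net["h_plus"] == 0:
            del net["h_plus"]
    return Reaction(
        id=f"net_{dist.preset.name}",
        enzyme="overall",
        stoich=net,
        protons_translocated=Fraction(0),
        reversible=False,
        note=f"net exchange of scheme {dist.preset.name}",
    )


def redox_closure(dist: FluxDistribution) -> dict[str, Fraction]:
    """Net production of each carrier pair; all zeros for a valid scheme."""
    out: dict[str, Fraction] = {}
    for sp in dist.network.species:
        if sp.role != "carrier" or "e" not in sp.formula:
            continue  # tally once per pair, on the reduced member
        pair = f"{sp.carrier_pair}/{sp.id}"
        net = Fraction(0)
        for rid, f in dist.flux.items():
            if rid == "atps":
                continue
            net += f * dist.network.reaction_by_id(rid).stoich.get(sp.id, Fraction(0))
        out[pair] = net
    return out


# ---------------------------------------------------------------------------
# preset files


def load_preset(path: Union[str, Path]) -> SchemePreset:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        return SchemePreset(
            name=doc["name"],
            feed=doc["feed"],
            product_demand={k: _as_fraction(v) for k, v in doc["product_demand"].items()},
            assumptions=list(doc.get("assumptions", [])),
            rnf_h_per_fd=_as_fraction(doc.get("rnf_h_per_fd", 2)),
            h_per_atp=_as_fraction(doc.get("h_per_atp", 4)),
        )
    except KeyError as exc:
        raise SchemeDefinitionError(f"preset file {path}: missing field {exc}") from None


def _preset_dir() -> Path:
    return Path(__file__).parent / "data" / "presets"


def bundled_preset_names() -> list[str]:
    return sorted(p.stem.upper() for p in _preset_dir().glob("*.yaml"))


def load_bundled_preset(name: str) -> SchemePreset:
    path = _preset_dir() / f"{name.lower()}.yaml"
    if not path.exists():
        raise SchemeDefinitionError(
            f"no bundled preset {name!r}; available: {bundled_preset_names()}"
        )
    return load_preset(path)
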