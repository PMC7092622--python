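"""End-to-end analysis runs: schemes, thermodynamic validation, synthetic
fermentation and ratio summaries, written as plain-text reports plus one
machine-readable JSON summary that is byte-identical for identical
config + seed."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

from . import __version__
from .fermentation import (
    DEFAULT_HORIZONS,
    default_params,
    end_product_ratios,
    growth_summary,
    simulate_fermentation,
    write_timecourse,
)
from .fluxes import (
    FluxDistribution,
    load_bundled_preset,
    load_preset,
    net_overall_reaction,
    redox_closure,
    solve_scheme,
)
from .network import MetabolicNetwork, Reaction, load_bundled_network, load_network
from .thermo import load_bundled_thermo_table, load_thermo_table, validate_table1

__all__ = ["RunConfig", "run_full_analysis", "StageError", "format_reaction",
           "format_scheme_report"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Configuration of one reproducible analysis run."""

    network_path: Optional[str] = None  # None -> bundled network
    preset_names: list[str] = field(
        default_factory=lambda: ["H2_ACETATE", "CO_ACETATE", "CO_ACETATE_BDO", "CO_FULL"]
    )
    thermo_path: Optional[str] = None  # None -> bundled table
    rnf_h_per_fd: Optional[str] = None  # chemiosmotic overrides, exact rationals
    h_per_atp: Optional[str] = None
    condition: str = "CO"
    seed: int = 0
    out_dir: str = "acetoflux_report"
    tolerance_kj: float = 5.0

    def canonical(self) -> str:
        doc = {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)}
        return json.dumps(doc, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def format_reaction(rxn: Reaction) -> str:
    """Human-readable `a A + b B -> c C` rendering of a reaction."""
    lhs, rhs = [], []
    for sp_id, coeff in sorted(rxn.stoich.items()):
        mag = -coeff if coeff < 0 else coeff
        term = sp_id if mag == 1 else f"{mag} {sp_id}"
        (lhs if coeff < 0 else rhs).append(term)
    return f"{' + '.join(lhs) or '(nothing)'} -> {' + '.join(rhs) or '(nothing)'}"


def format_scheme_report(dist: FluxDistribution) -> str:
    preset = dist.preset
    lines = [
        f"scheme {preset.name} (feed {preset.feed})",
        "product basis: "
        + ", ".join(f"{sp} = {d}" for sp, d in sorted(preset.product_demand.items())),
        f"assumptions: {', '.join(preset.assumptions) or 'none'}",
        f"chemiosmosis: Rnf {preset.rnf_h_per_fd} H+/Fd_red, "
        f"ATP synthase {preset.h_per_atp} H+/ATP",
        "",
        "fluxes (per product basis):",
    ]
    for rid in sorted(dist.flux):
        if dist.flux[rid] != 0:
            lines.append(f"  {rid:12s} {dist.flux[rid]}")
    net = net_overall_reaction(dist)
    lines += [
        "",
        f"net reaction: {format_reaction(net)}",
        f"substrate-level ATP: {dist.substrate_level_atp}",
        f"protons exported: {dist.pumped_protons}",
        f"net ATP: {dist.net_atp} ({float(dist.net_atp):g})",
        f"unique solution: {dist.unique}",
    ]
    return "\n".join(lines) + "\n"


def _load_inputs(config: RunConfig):
    network = (
        load_network(config.network_path) if config.network_path else load_bundled_network()
    )
    table = (
        load_thermo_table(config.thermo_path) if config.thermo_path
        else load_bundled_thermo_table()
    )
    return network, table


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "schemes": {},
        "table1": {},
        "fermentation": {},
    }

    try:
        network, table = _load_inputs(config)
    except Exception as exc:
        raise StageError(f"stage 'load inputs' failed: {exc}") from exc

    for name in config.preset_names:
        try:
            preset = load_bundled_preset(name) if not Path(name).exists() else load_preset(name)
            if config.rnf_h_per_fd is not None:
                preset.rnf_h_per_fd = Fraction(config.rnf_h_per_fd)
            if config.h_per_atp is not None:
                preset.h_per_atp = Fraction(config.h_per_atp)
            dist = solve_scheme(network, preset)
            (out / f"scheme_{preset.name}.txt").write_text(format_scheme_report(dist))
            summary["schemes"][preset.name] = {
                "net_atp": str(dist.net_atp),
                "net_atp_float": float(dist.net_atp),
                "substrate_level_atp": str(dist.substrate_level_atp),
                "pumped_protons": str(dist.pumped_protons),
                "net_reaction": format_reaction(net_overall_reaction(dist)),
                "redox_closure_ok": all(v == 0 for v in redox_closure(dist).values()),
                "unique": dist.unique,
            }
        except Exception as exc:
            raise StageError(f"stage 'scheme {name}' failed: {exc}") from exc

    try:
        rows = validate_table1(network, table, tolerance=config.tolerance_kj)
        lines = [f"{'row':8s} {'computed':>10s} {'printed':>9s} {'dev':>7s} pass"]
        for row in rows:
            lines.append(
                f"{row.reaction_id:8s} {row.computed:10.1f} {row.expected:9.1f} "
                f"{row.deviation:7.1f} {'yes' if row.passed else 'NO'}"
            )
            summary["table1"][row.reaction_id] = {
                "computed_kj": round(row.computed, 2),
                "printed_kj": row.expected,
                "passed": row.passed,
            }
        (out / "table1_validation.txt").write_text("\n".join(lines) + "\n")
    except Exception as exc:
        raise StageError(f"stage 'thermodynamic validation' failed: {exc}") from exc

    try:
        params = default_params(config.condition, seed=config.seed)
        tc = simulate_fermentation(params, DEFAULT_HORIZONS[config.condition])
        write_timecourse(tc, out / f"timecourse_{config.condition}.csv")
        reference = "acetate"
        ratios = end_product_ratios(tc, reference)
        summary["fermentation"] = {
            "condition": config.condition,
            "growth": {k: round(v, 4) for k, v in growth_summary(tc).items()},
            "reference": reference,
            "ratios": {
                p: {"ratio": round(r["ratio"], 4), "rounded": r["rounded"]}
                for p, r in sorted(ratios.items())
            },
        }
    except Exception as exc:
        raise StageError(f"stage 'fermentation simulation' failed: {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2) + "\n"
    )
    return summary
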