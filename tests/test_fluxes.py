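"""Scheme solving, ATP accounting and redox closure."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from acetoflux.fluxes import (
    InfeasibleSchemeError,
    SchemePreset,
    atp_yield,
    load_bundled_preset,
    net_overall_reaction,
    redox_closure,
    solve_scheme,
)
from acetoflux.network import available_electrons


def test_h2_scheme_carrier_rows_close_exactly(network, solved):
    dist = solved("H2_ACETATE")
    closure = redox_closure(dist)
    assert set(closure) == {"fd_ox/fd_red", "nad/nadh", "nadp/nadph"}
    assert all(v == 0 for v in closure.values())


def test_h2_acetate_yields_three_quarters_atp(solved):
    """One mole of acetate from H2/CO2 nets exactly 0.75 ATP."""
    dist = solved("H2_ACETATE")
    assert dist.unique
    assert dist.net_atp == Fraction(3, 4)
    assert atp_yield(dist) == Fraction(3, 4)


def test_co_full_scheme_yields_ten_atp(solved):
    """1 acetate + 1 butanediol + 4 ethanol from CO nets exactly 10 ATP."""
    dist = solved("CO_FULL")
    assert dist.unique
    assert dist.net_atp == Fraction(10)


def test_co_beats_h2_per_acetate_equivalent(solved):
    assert solved("CO_ACETATE").net_atp > solved("H2_ACETATE").net_atp


def test_composite_scheme_is_sum_of_components(network, solved):
    """CO_FULL fluxes and ATP equal CO_ACETATE + CO_BDO + 4 * CO_ETHANOL."""
    full = solved("CO_FULL")
    parts = [(solved("CO_ACETATE"), 1), (solved("CO_BDO"), 1), (solved("CO_ETHANOL"), 4)]
    combined: dict[str, Fraction] = {}
    for dist, weight in parts:
        for rid, f in dist.flux.items():
            combined[rid] = combined.get(rid, Fraction(0)) + weight * f
    for rid, f in full.flux.items():
        assert combined.get(rid, Fraction(0)) == f, rid
    assert sum(d.net_atp * w for d, w in parts) == full.net_atp == 10


@settings(max_examples=10, deadline=None, derandomize=True)
@given(st.fractions(min_value="1/3", max_value=5))
def test_homogeneity_in_product_demand(k):
    """Scaling the demand by k scales every flux and the ATP tally by k."""
    from acetoflux.network import load_bundled_network

    network = load_bundled_network()
    base = solve_scheme(network, load_bundled_preset("H2_ACETATE"))
    scaled_preset = load_bundled_preset("H2_ACETATE")
    scaled_preset.product_demand = {"acetate": k}
    scaled = solve_scheme(network, scaled_preset)
    assert scaled.net_atp == k * base.net_atp
    for rid, f in base.flux.items():
        assert scaled.flux[rid] == k * f


@pytest.mark.parametrize(
    "preset_name, expected",
    [
        ("H2_ACETATE", {"h2": -4, "co2": -2, "acetate": 1, "h_plus": 1, "h2o": 2}),
        ("CO_ACETATE", {"co": -4, "h2o": -2, "acetate": 1, "h_plus": 1, "co2": 2}),
        ("CO_ETHANOL", {"co": -6, "h2o": -3, "ethanol": 1, "co2": 4}),
        ("CO_BDO", {"co": -11, "h2o": -5, "butanediol": 1, "co2": 7}),
    ],
)
def test_net_overall_reactions_match_printed_stoichiometries(solved, preset_name, expected):
    net = net_overall_reaction(solved(preset_name))
    assert net.stoich == {k: Fraction(v) for k, v in expected.items()}


def test_net_overall_reaction_conserves_electrons(network, solved):
    for name in ("H2_ACETATE", "CO_ACETATE", "CO_FULL"):
        net = net_overall_reaction(solved(name))
        total = sum(
            coeff * available_electrons(network.species_by_id(sp))
            for sp, coeff in net.stoich.items()
        )
        assert total == 0, name


def test_removing_rnf_reports_carrier_imbalance(network):
    preset = load_bundled_preset("H2_ACETATE")
    with pytest.raises(InfeasibleSchemeError) as err:
        solve_scheme(network, preset, exclude_reactions={"rnf"})
    assert "fd_ox/fd_red" in err.value.unbalanced
    assert "nad/nadh" in err.value.unbalanced


def test_removing_nfn_reports_nadph_imbalance(network):
    """On CO, Nfn is the only NADPH source; dropping it isolates that pair."""
    preset = load_bundled_preset("CO_FULL")
    with pytest.raises(InfeasibleSchemeError) as err:
        solve_scheme(network, preset, exclude_reactions={"nfn"})
    assert set(err.value.unbalanced) == {"nadp/nadph"}


def test_redox_closure_is_homogeneous(network, solved):
    dist = solved("CO_FULL")
    doubled = solve_scheme(
        network,
        SchemePreset(
            name="CO_FULL_X2",
            feed="CO",
            product_demand={k: 2 * v for k, v in dist.preset.product_demand.items()},
            assumptions=list(dist.preset.assumptions),
        ),
    )
    assert all(v == 0 for v in redox_closure(doubled).values())
    assert doubled.net_atp == 2 * dist.net_atp


def test_atp_yield_with_explicit_h_per_atp(solved):
    dist = solved("H2_ACETATE")
    # pumped 5 H+ and SLP -1/2; at 2 H+/ATP the yield doubles the gradient term
    assert atp_yield(dist, Fraction(2)) == Fraction(-1, 2) + Fraction(5, 2)
    with pytest.raises(ValueError, match="positive"):
        atp_yield(dist, 0)


def test_zero_demand_gives_zero_fluxes_and_empty_net_reaction(network):
    preset = SchemePreset(
        name="NOTHING", feed="CO", product_demand={"acetate": Fraction(0)},
        assumptions=["bifurcating-mthfr"],
    )
    dist = solve_scheme(network, preset)
    assert all(f == 0 for f in dist.flux.values())
    assert dist.net_atp == 0
    assert net_overall_reaction(dist).stoich == {}


def test_futile_aor_cycle_rejected(network):
    preset = load_bundled_preset("CO_FULL")
    preset.assumptions.append("acetate-from-acetaldehyde")
    with pytest.raises(Exception, match="futile"):
        solve_scheme(network, preset)


def test_h2_scheme_splits_acetate_between_ack_and_aor(solved):
    """The acetate flux is carried half by acetate kinase, half by the
    aldehyde-oxidizing AOR branch, as the scheme's constraint demands."""
    dist = solved("H2_ACETATE")
    assert dist.flux["ack"] == dist.flux["aor"] == Fraction(1, 2)
    assert dist.flux["rnf"] == Fraction(5, 2)
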