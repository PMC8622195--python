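"""In-silico library: masses, formulas, enumeration, shorthand parsing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics.mass import calculate_mass

from gslscreen.library import (
    GLYCAN_CLASSES,
    MONOMERS,
    PROTON_MASS,
    CeramideComposition,
    ShorthandError,
    default_charge_states,
    enumerate_library,
    enumerate_species,
    find_anchor_species,
    formula_mass,
    headgroup,
    hill_formula,
    ion_mz,
    library_table,
    make_species,
    parse_shorthand,
    residue_mass,
)

# Frozen expected values computed with the atomic-mass summation oracle
# (independently cross-checked against pyteomics below).
RESIDUE_EXPECTED = {
    "Hex": 162.05282,
    "HexNAc": 203.07937,
    "NeuAc": 291.09542,
    "OAc": 42.01057,
    "SO3": 79.95681,
}


@pytest.mark.parametrize("name,expected", sorted(RESIDUE_EXPECTED.items()))
def test_residue_masses(name, expected):
    assert residue_mass(name) == pytest.approx(expected, abs=1e-5)
    # independent oracle: pyteomics elemental mass calculator
    assert residue_mass(name) == pytest.approx(
        calculate_mass(composition=dict(MONOMERS[name].formula)), abs=1e-5
    )


def test_unknown_monomer_is_named_in_error():
    with pytest.raises(ValueError, match="Pentose"):
        residue_mass("Pentose")


@pytest.mark.parametrize(
    "base,carbons,db,mass,formula",
    [
        ("d", 36, 1, 565.54339, "C36H71NO3"),
        ("d", 42, 1, 649.63730, "C42H83NO3"),  # LIPID MAPS Cer 42:1;O2
        ("t", 36, 1, 581.53831, "C36H71NO4"),
    ],
)
def test_ceramide_mass_and_formula(base, carbons, db, mass, formula):
    cer = CeramideComposition(base, carbons, db)
    assert cer.mass == pytest.approx(mass, abs=1e-5)
    assert hill_formula(cer.formula) == formula
    assert cer.mass == pytest.approx(calculate_mass(composition=dict(cer.formula)), abs=1e-5)


def test_t_vs_d_series_differ_by_one_oxygen():
    d = CeramideComposition("d", 36, 0)
    t = CeramideComposition("t", 36, 0)
    assert t.mass - d.mass == pytest.approx(15.99491, abs=1e-5)


def test_excess_double_bonds_rejected():
    with pytest.raises(ValueError, match="double bond"):
        CeramideComposition("d", 4, 5)


@pytest.mark.parametrize(
    "shorthand,mass",
    [
        ("GM3 d36:1", 1180.74446),
        ("GT1b d36:1", 2128.06749),
        ("GT1b-Ac2 d38:1", 2240.11992),
        ("GQ1b-Ac2 d38:1", 2531.21533),
    ],
)
def test_species_neutral_masses(shorthand, mass):
    sp = parse_shorthand(shorthand)
    assert sp.neutral_mass == pytest.approx(mass, abs=1e-5)


def test_double_acetylation_adds_exactly_two_acetyls():
    plain = parse_shorthand("GT1b d36:1")
    ac2 = parse_shorthand("GT1b-Ac2 d36:1")
    assert ac2.neutral_mass - plain.neutral_mass == pytest.approx(84.02113, abs=1e-5)


def test_oac_mass_additivity_across_all_acetylated_classes():
    pairs = [("GT1b", "GT1b-Ac"), ("GT1b-Ac", "GT1b-Ac2"), ("GQ1b", "GQ1b-Ac"),
             ("GQ1b-Ac", "GQ1b-Ac2")]
    for plain, ac in pairs:
        a = make_species(plain, "d", 36, 1).neutral_mass
        b = make_species(ac, "d", 36, 1).neutral_mass
        assert b - a == pytest.approx(residue_mass("OAc"), abs=1e-9)
        assert b - a == pytest.approx(42.01057, abs=1e-5)


def test_composition_identical_isomers_share_mass():
    for group in (("GM1a", "GM1b"), ("GD1a", "GD1b"), ("GT1a", "GT1b", "GT1c"),
                  ("GQ1b", "GQ1c")):
        masses = {make_species(c, "d", 36, 1).neutral_mass for c in group}
        assert len(masses) == 1


@pytest.mark.parametrize(
    "shorthand,charge,mz",
    [
        ("GT1b-Ac2 d38:1", 2, 1119.053),  # printed 1119.1
        ("GQ1b-Ac2 d38:1", 3, 842.731),  # printed 842.7
        ("ST d42:1", 1, 890.63966),
    ],
)
def test_deprotonated_ion_mz(shorthand, charge, mz):
    assert ion_mz(parse_shorthand(shorthand), charge) == pytest.approx(mz, abs=1e-3)


def test_ion_mz_rejects_nonpositive_charge():
    with pytest.raises(ValueError, match="charge"):
        ion_mz(parse_shorthand("GM3 d36:1"), 0)


def test_charge_arithmetic_inverts_exactly():
    sp = parse_shorthand("GT1b-Ac2 d38:1")
    mz = ion_mz(sp, 2)
    assert mz * 2 + 2 * PROTON_MASS == pytest.approx(sp.neutral_mass, rel=1e-9)


def test_anchor_search_recovers_d38_1_for_both_new_subclasses():
    """The figure-caption m/z values pin the ceramide composition uniquely
    over the d-series ganglioside grid."""
    hits1 = find_anchor_species("GT1b-Ac2", 1119.1, charge=2)
    assert [h.species.shorthand for h in hits1] == ["GT1b-Ac2 d38:1"]
    hits2 = find_anchor_species("GQ1b-Ac2", 842.7, charge=3)
    assert [h.species.shorthand for h in hits2] == ["GQ1b-Ac2 d38:1"]


def test_singleton_enumeration():
    ions = enumerate_library(classes=["GM3"], carbons=[36], double_bonds=[1], base_types=["d"])
    assert {i.species.shorthand for i in ions} == {"GM3 d36:1"}
    assert {i.charge for i in ions} == {1, 2}


def test_enumeration_grid_count():
    species = enumerate_species(classes=["GT1b-Ac2"], carbons=range(34, 45),
                                double_bonds=[1, 2], base_types=["d"])
    assert len(species) == 22


def test_enumeration_sorted_deduplicated_and_self_consistent():
    ions = enumerate_library(classes=["GM3", "GD1a", "ST"], carbons=range(34, 40))
    keys = [
        (i.species.headgroup.class_name, i.species.ceramide.base_type,
         i.species.ceramide.carbons, i.species.ceramide.double_bonds, i.charge)
        for i in ions
    ]
    assert keys == sorted(keys)
    assert len(keys) == len(set(keys))
    for ion in ions:
        assert ion.theo_mz == pytest.approx(ion_mz(ion.species, ion.charge), rel=1e-12)
        assert 300 <= ion.theo_mz <= 2000


def test_empty_ranges_yield_empty_library():
    assert enumerate_library(classes=["GM3"], carbons=[]) == []


def test_charge_state_policy_by_sialylation():
    assert default_charge_states(headgroup("GM3")) == (1, 2)
    assert default_charge_states(headgroup("ST")) == (1, 2)
    assert default_charge_states(headgroup("GD1a")) == (2,)
    assert default_charge_states(headgroup("GT1b")) == (2, 3)
    assert default_charge_states(headgroup("GQ1b-Ac2")) == (2, 3)


def test_library_table_columns_and_rows():
    ions = enumerate_library(classes=["GM3"], carbons=[36], double_bonds=[1], base_types=["d"])
    table = library_table(ions)
    assert list(table.columns) == [
        "class", "isomer_label", "base_type", "carbons", "db",
        "shorthand", "formula", "neutral_mass", "charge", "theo_mz",
    ]
    assert len(table) == 2
    assert table["formula"].iloc[0] == "C59H108N2O21"


@pytest.mark.parametrize("shorthand", ["GM1a d42:2", "ST t36:1", "dihexST d38:1"])
def test_parse_shorthand_examples(shorthand):
    sp = parse_shorthand(shorthand)
    assert sp.shorthand == shorthand


def test_parse_shorthand_round_trips_for_every_library_class():
    for cls in GLYCAN_CLASSES:
        text = f"{cls} d36:1"
        assert parse_shorthand(text).shorthand == text


@pytest.mark.parametrize("bad", ["GM3d36:1", "gm3 d36:1", "GM3 x36:1", "GM99 d36:1"])
def test_parse_shorthand_rejects_malformed(bad):
    with pytest.raises(ShorthandError):
        parse_shorthand(bad)


@settings(max_examples=50, deadline=None)
@given(
    cls=st.sampled_from(sorted(GLYCAN_CLASSES)),
    base=st.sampled_from(["d", "t"]),
    carbons=st.integers(28, 48),
    db=st.integers(0, 4),
)
def test_residue_sum_equals_formula_sum(cls, base, carbons, db):
    """Oracle equivalence: mass assembled from residue masses equals the mass
    recomputed from the summed elemental formula."""
    sp = make_species(cls, base, carbons, db)
    assert sp.neutral_mass == pytest.approx(sp.mass_from_formula, abs=1e-6)
    assert sp.neutral_mass == pytest.approx(
        calculate_mass(composition=dict(sp.formula)), abs=2e-4
    )
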