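"""Unit-cell geometry, CIF ingestion, symmetry expansion, lattice sums."""

from __future__ import annotations

import math
import textwrap

import numpy as np
import pytest

from nmrxtal import (
    SiteGroup,
    SyntheticSpec,
    UnitCell,
    enumerate_distances,
    expand_to_p1,
    frac_to_cartesian,
    make_structure,
    read_cif,
)
from nmrxtal.crystal import CifFormatError, SymOp

from conftest import random_p1_structure, supercell_distances

MINIMAL_P1_CIF = textwrap.dedent("""\
    data_minimal
    _cell_length_a 20.0
    _cell_length_b 20.0
    _cell_length_c 20.0
    _cell_angle_alpha 90
    _cell_angle_beta 90
    _cell_angle_gamma 90
    loop_
    _atom_site_label
    _atom_site_type_symbol
    _atom_site_fract_x
    _atom_site_fract_y
    _atom_site_fract_z
    P1 P 0.0 0.0 0.0
    H1 H 0.125 0.0 0.0
    """)


def _write(tmp_path, text, name="test.cif"):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestUnitCell:
    def test_orthorhombic_volume_is_edge_product(self):
        cell = UnitCell(7.737, 10.167, 9.136)
        assert cell.volume == pytest.approx(7.737 * 10.167 * 9.136, rel=1e-12)

    @pytest.mark.parametrize("bad", [(0, 1, 1, 90, 90, 90), (1, 1, 1, 0, 90, 90), (1, 1, 1, 90, 180, 90)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            UnitCell(*bad)

    def test_frac_to_cartesian_orthorhombic(self):
        cell = UnitCell(7.737, 10.167, 9.136)
        np.testing.assert_allclose(frac_to_cartesian(cell, (0.5, 0, 0)), [7.737 / 2, 0, 0])
        np.testing.assert_allclose(frac_to_cartesian(cell, (0, 0, 0)), [0, 0, 0])

    def test_frac_to_cartesian_monoclinic_c_axis(self):
        # monoclinic cell of the calcium phosphoserine salt
        cell = UnitCell(5.534, 12.759, 5.740, 90.0, 104.77, 90.0)
        vec = frac_to_cartesian(cell, (0.0, 0.0, 1.0))
        beta = math.radians(104.77)
        assert vec[0] == pytest.approx(5.740 * math.cos(beta), rel=1e-12)
        assert np.linalg.norm(vec) == pytest.approx(5.740, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        cell = UnitCell(*rng.uniform(5, 12, 3), *rng.uniform(70, 110, 3))
        frac = rng.uniform(0, 1, size=(4, 3))
        back = frac_to_cartesian(cell, frac) @ np.linalg.inv(cell.matrix).T
        np.testing.assert_allclose(back, frac, rtol=1e-10, atol=1e-12)


class TestReadCif:
    def test_minimal_p1(self, tmp_path):
        st = read_cif(_write(tmp_path, MINIMAL_P1_CIF))
        assert len(st.sites) == 2
        assert st.is_p1
        assert st.site("H1").spin_species == "1H"
        assert st.site("P1").spin_species == "31P"

    def test_cell_volume_from_file(self, tmp_path):
        cif = MINIMAL_P1_CIF.replace("20.0\n_cell_length_b 20.0\n_cell_length_c 20.0",
                                     "7.737\n_cell_length_b 10.167\n_cell_length_c 9.136")
        st = read_cif(_write(tmp_path, cif))
        assert st.cell.volume == pytest.approx(718.66, abs=0.01)

    def test_missing_cell_block_errors(self, tmp_path):
        body = "\n".join(l for l in MINIMAL_P1_CIF.splitlines() if "_cell_length" not in l)
        with pytest.raises(CifFormatError, match="_cell"):
            read_cif(_write(tmp_path, body))

    def test_partial_occupancy_rejected(self, tmp_path):
        cif = MINIMAL_P1_CIF.replace(
            "_atom_site_fract_z\n", "_atom_site_fract_z\n_atom_site_occupancy\n"
        ).replace("P1 P 0.0 0.0 0.0", "P1 P 0.0 0.0 0.0 0.5").replace(
            "H1 H 0.125 0.0 0.0", "H1 H 0.125 0.0 0.0 1.0"
        )
        with pytest.raises(CifFormatError, match="occupancy"):
            read_cif(_write(tmp_path, cif))

    def test_spacegroup_symbol_parsed(self, tmp_path):
        cif = MINIMAL_P1_CIF.replace(
            "loop_", "_space_group_name_H-M_alt 'P 21 21 21'\nloop_", 1
        )
        st = read_cif(_write(tmp_path, cif))
        assert len(st.symmetry_ops) == 4


class TestExpandToP1:
    def test_p1_unchanged(self, two_spin_structure):
        assert expand_to_p1(two_spin_structure) is two_spin_structure

    def test_general_position_multiplies_by_group_order(self):
        ops = [SymOp.identity()] + [
            SymOp.from_triplet(t)
            for t in ("-x+1/2,-y,z+1/2", "x+1/2,-y+1/2,-z", "-x,y+1/2,-z+1/2")
        ]
        st = make_structure(
            SyntheticSpec(cell=UnitCell(8, 9, 10), coords={"H1": ("1H", (0.13, 0.22, 0.31))})
        )
        st.symmetry_ops = ops
        p1 = expand_to_p1(st)
        assert len(p1.sites) == 4
        assert p1.is_p1
        # the expanded group follows its member's images
        assert len(p1.groups["H1"].member_labels) == 4

    def test_special_position_images_merged(self):
        # inversion centre: an atom at the origin maps onto itself
        st = make_structure(
            SyntheticSpec(cell=UnitCell(8, 8, 8), coords={"H1": ("1H", (0.0, 0.0, 0.0))})
        )
        st.symmetry_ops = [SymOp.identity(), SymOp.from_triplet("-x,-y,-z")]
        p1 = expand_to_p1(st)
        assert len(p1.sites) == 1


class TestEnumerateDistances:
    def test_isolated_pair(self, two_spin_structure):
        dl = enumerate_distances(two_spin_structure, "P1", "H1", cutoff_pm=1000)
        assert len(dl) == 1
        assert dl.entries[0].r_pm == pytest.approx(250.0, abs=1e-9)
        assert dl.entries[0].image == (0, 0, 0)

    def test_periodic_images_appear_beyond_cell(self, two_spin_structure):
        dl = enumerate_distances(two_spin_structure, "P1", "H1", cutoff_pm=2100)
        r = dl.r
        assert r[0] == pytest.approx(250.0)
        assert r[1] == pytest.approx(1750.0)  # image of H along -a
        oracle = supercell_distances(two_spin_structure, "P1", "H1", 2100)
        np.testing.assert_allclose(r, oracle, atol=1e-9)

    def test_self_pair_counts_unordered_once_no_zero(self):
        st = make_structure(
            SyntheticSpec(
                cell=UnitCell(20, 20, 20),
                coords={"H1": ("1H", (0.0, 0.0, 0.0)), "H2": ("1H", (0.1, 0.0, 0.0))},
            )
        )
        groups = dict(st.groups)
        groups["HH"] = SiteGroup(id="HH", member_labels=("H1", "H2"), species="1H")
        st = st.with_groups(groups.values())
        dl = enumerate_distances(st, "HH", "HH", cutoff_pm=1000)
        assert all(e.r_pm > 0 for e in dl.entries)
        assert len(dl) == 1  # only the 200 pm intra-cell contact within 1 nm
        assert dl.entries[0].r_pm == pytest.approx(200.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_supercell_oracle(self, seed):
        st = random_p1_structure(seed, n_h=3, cell_angstrom=6.5)
        p = next(g.id for g in st.groups.values() if g.species == "31P")
        hs = [g.id for g in st.groups.values() if g.species == "1H"]
        for gk in hs:
            dl = enumerate_distances(st, p, gk, cutoff_pm=1400)
            np.testing.assert_allclose(
                dl.r, supercell_distances(st, p, gk, 1400), atol=1e-9
            )

    @pytest.mark.parametrize("seed", range(4))
    def test_homonuclear_matches_supercell_oracle(self, seed):
        st = random_p1_structure(seed, n_h=3, cell_angstrom=6.5)
        hs = [g.id for g in st.groups.values() if g.species == "1H"]
        merged = st.with_groups(
            list(st.groups.values())
            + [SiteGroup(id="allH", member_labels=tuple(hs), species="1H")]
        )
        dl = enumerate_distances(merged, "allH", "allH", cutoff_pm=1200)
        np.testing.assert_allclose(
            dl.r, supercell_distances(merged, "allH", "allH", 1200), atol=1e-9
        )

    def test_translation_invariance(self):
        st = random_p1_structure(3)
        p = next(g.id for g in st.groups.values() if g.species == "31P")
        h = next(g.id for g in st.groups.values() if g.species == "1H")
        before = enumerate_distances(st, p, h, cutoff_pm=1500).r
        shift = np.array([0.37, 0.81, 0.55])
        shifted = make_structure(
            SyntheticSpec(
                cell=st.cell,
                coords={
                    s.label: (s.spin_species, tuple((np.array(s.frac) + shift) % 1.0))
                    for s in st.sites
                },
            )
        )
        after = enumerate_distances(shifted, p, h, cutoff_pm=1500).r
        np.testing.assert_allclose(after, before, atol=1e-6)

    def test_symmetry_description_equals_expanded(self, tmp_path):
        cif = textwrap.dedent("""\
            data_sym
            _cell_length_a 7.737
            _cell_length_b 10.167
            _cell_length_c 9.136
            _cell_angle_alpha 90
            _cell_angle_beta 90
            _cell_angle_gamma 90
            _space_group_name_H-M_alt 'P 21 21 21'
            loop_
            _atom_site_label
            _atom_site_type_symbol
            _atom_site_fract_x
            _atom_site_fract_y
            _atom_site_fract_z
            P1 P 0.11 0.21 0.33
            H1 H 0.29 0.41 0.17
            """)
        path = tmp_path / "sym.cif"
        path.write_text(cif)
        st = read_cif(str(path))
        # groups defined on the asymmetric unit follow their members' images
        sym = st.with_groups(
            [
                SiteGroup(id="P", member_labels=("P1",), species="31P"),
                SiteGroup(id="H", member_labels=("H1",), species="1H"),
            ]
        )
        # enumerate from the symmetric description (auto-expansion) and the
        # pre-expanded P1 description; distances must agree
        pre = expand_to_p1(sym)
        assert len(pre.sites) == 8
        np.testing.assert_allclose(
            enumerate_distances(sym, "P", "H", cutoff_pm=900).r,
            enumerate_distances(pre, "P", "H", cutoff_pm=900).r,
            atol=1e-9,
        )

    def test_cutoff_monotonicity_prefix(self):
        st = random_p1_structure(7)
        p = next(g.id for g in st.groups.values() if g.species == "31P")
        h = next(g.id for g in st.groups.values() if g.species == "1H")
        short = enumerate_distances(st, p, h, cutoff_pm=900).r
        long = enumerate_distances(st, p, h, cutoff_pm=1800).r
        assert len(long) >= len(short)
        np.testing.assert_allclose(long[: len(short)], short, atol=1e-12)

    def test_unknown_group_errors(self, two_spin_structure):
        with pytest.raises(KeyError, match="nope"):
            enumerate_distances(two_spin_structure, "nope", "H1")

    def test_empty_list_warns(self, two_spin_structure):
        with pytest.warns(UserWarning, match="no P1-H1 contacts"):
            dl = enumerate_distances(two_spin_structure, "P1", "H1", cutoff_pm=100)
        assert len(dl) == 0
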