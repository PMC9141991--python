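"""Reactivity indices, torsion geometry and the donating-ability map."""
import logging
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from anthoredox import (
    EhDamaPoint,
    ReactivityProfile,
    adiabatic_ip,
    bde,
    build_eh_dama,
    conceptual_dft_indices,
    preferred_homolysis_site,
    ring_dihedral,
)
from anthoredox.exceptions import ConsistencyError, GeometryError, ValidationError
from anthoredox.reactivity import signed_ring_dihedral

finite = st.floats(min_value=-2000, max_value=2000, allow_nan=False)


class TestBde:
    def test_constructed_homolysis(self):
        assert bde(-1000.0, -930.3, 0.5) == pytest.approx(70.2)

    def test_zero_when_cycle_closes(self):
        assert bde(-500.0, -500.0 - 0.5, 0.5) == 0.0

    @given(parent=finite, radical=finite, h=finite)
    def test_matches_extended_precision_resummation(self, parent, radical, h):
        import decimal

        expected = float(
            decimal.Decimal(repr(radical))
            + decimal.Decimal(repr(h))
            - decimal.Decimal(repr(parent))
        )
        assert bde(parent, radical, h) == pytest.approx(expected, abs=1e-9)

    def test_mixed_solvent_inputs_rejected(self):
        with pytest.raises(ConsistencyError):
            bde(-1000.0, -930.0, 0.5, parent_solvent="water",
                radical_solvent="pentyl_ethanoate")


class TestAdiabaticIp:
    def test_constructed_pair(self):
        assert adiabatic_ip(-1000.0, -903.4) == pytest.approx(96.6)

    def test_antisymmetric(self):
        assert adiabatic_ip(-10.0, -4.0) == -adiabatic_ip(-4.0, -10.0)
        assert adiabatic_ip(-7.0, -7.0) == 0.0


class TestConceptualDft:
    def test_hand_arithmetic(self):
        mu, eta, omega = conceptual_dft_indices(150.0, 30.0)
        assert (mu, eta, omega) == (-90.0, 60.0, 67.5)

    def test_symmetric_gap_gives_zero_electrophilicity(self):
        mu, eta, omega = conceptual_dft_indices(80.0, -80.0)
        assert mu == 0.0 and omega == 0.0

    def test_degenerate_hardness_rejected(self):
        with pytest.raises(ValidationError):
            conceptual_dft_indices(100.0, 100.0)

    @given(
        vip=st.floats(min_value=-500, max_value=500),
        gap=st.floats(min_value=1e-3, max_value=500),
        c=st.floats(min_value=-100, max_value=100),
    )
    def test_shift_identity(self, vip, gap, c):
        """omega(vIP+c, vEA+c) = (mu - c)^2 / (2 eta): a rigid shift of
        both vertical energies moves mu but not eta."""
        vea = vip - gap
        mu, eta, _ = conceptual_dft_indices(vip, vea)
        _, eta2, omega2 = conceptual_dft_indices(vip + c, vea + c)
        assert eta2 == pytest.approx(eta, rel=1e-12, abs=1e-12)
        assert omega2 == pytest.approx((mu - c) ** 2 / (2 * eta), rel=1e-9, abs=1e-9)

    @given(vip=finite, vea=finite)
    def test_electrophilicity_nonnegative(self, vip, vea):
        if not vip > vea:
            vip, vea = vea, vip - 1.0
        _, _, omega = conceptual_dft_indices(vip, vea)
        assert omega >= 0.0


class TestRingDihedral:
    def test_trans_planar_is_180(self):
        assert ring_dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == pytest.approx(0.0)
        assert ring_dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)) == pytest.approx(180.0)

    def test_constructed_right_angle(self):
        assert ring_dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)) == pytest.approx(90.0)

    def test_collinear_rejected(self):
        with pytest.raises(GeometryError):
            ring_dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    @given(
        angles=st.tuples(*[st.floats(0, 2 * math.pi) for _ in range(3)]),
        shift=st.tuples(*[st.floats(-5, 5) for _ in range(3)]),
    )
    def test_invariant_under_isometry(self, angles, shift):
        pts = [np.array(p, dtype=float) for p in
               [(0, 0, 0), (1.3, 0, 0), (1.3, 1.1, 0), (2.0, 1.4, 0.9)]]
        a, b, c = angles
        rz = np.array([[math.cos(a), -math.sin(a), 0],
                       [math.sin(a), math.cos(a), 0], [0, 0, 1]])
        rx = np.array([[1, 0, 0], [0, math.cos(b), -math.sin(b)],
                       [0, math.sin(b), math.cos(b)]])
        ry = np.array([[math.cos(c), 0, math.sin(c)], [0, 1, 0],
                       [-math.sin(c), 0, math.cos(c)]])
        rot = rz @ rx @ ry
        moved = [rot @ p + np.asarray(shift) for p in pts]
        assert ring_dihedral(*moved) == pytest.approx(ring_dihedral(*pts), abs=1e-7)

    def test_signed_torsion_symmetries(self):
        """The signed torsion is invariant under point-order reversal and
        flips sign under mirror reflection (an improper isometry); the
        unsigned angle is blind to both."""
        pts = [(0, 0, 0), (1.3, 0, 0), (1.3, 1.1, 0), (2.0, 1.4, 0.9)]
        mirrored = [(x, y, -z) for x, y, z in pts]
        phi = signed_ring_dihedral(*pts)
        assert signed_ring_dihedral(*reversed(pts)) == pytest.approx(phi, abs=1e-9)
        assert signed_ring_dihedral(*mirrored) == pytest.approx(-phi, abs=1e-9)
        assert ring_dihedral(*mirrored) == pytest.approx(abs(phi), abs=1e-9)


class TestPreferredSite:
    def test_delphinidin_neutral_water_prefers_c3(self, fixtures):
        bde_map = fixtures.bde_map("Dp", "0")
        assert preferred_homolysis_site(bde_map) == "C3"

    def test_equal_minima_break_to_canonical_order(self):
        assert preferred_homolysis_site({"C7": 70.0, "C4p": 70.0, "C5": 75.0}) == "C4p"

    def test_empty_map_rejected(self):
        with pytest.raises(ValidationError):
            preferred_homolysis_site({})


def make_profile(label, bde_map, omega):
    return ReactivityProfile(
        species=None, label=label, bde_by_site=bde_map, electrophilicity=omega
    )


class TestEhDama:
    def test_dominating_species_ranks_first(self):
        a = make_profile("A", {"C3": 70.0}, 10.0)
        b = make_profile("B", {"C3": 80.0}, 20.0)
        _, ranking = build_eh_dama([b, a])
        assert ranking == ["A", "B"]

    def test_missing_vertical_energies_skipped_with_warning(self, caplog):
        good = make_profile("ok", {"C3": 70.0}, 10.0)
        bad = make_profile("no-omega", {"C3": 60.0}, None)
        blocked = make_profile("all-blocked", {}, 5.0)
        with caplog.at_level(logging.WARNING):
            points, ranking = build_eh_dama([good, bad, blocked])
        assert [p.label for p in points] == ["ok"]
        assert "no-omega" in caplog.text and "all-blocked" in caplog.text

    def test_reference_points_flagged_and_ranked(self):
        species = [make_profile(f"s{i}", {"C3": 70.0 + i}, 5.0 + i) for i in range(3)]
        refs = [EhDamaPoint("trolox", min_bde=78.0, electrophilicity=30.0,
                            is_reference=True)]
        points, ranking = build_eh_dama(species, refs)
        assert sum(p.is_reference for p in points) == 1
        assert ranking[-1] == "trolox"  # dominated on both axes

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValidationError):
            EhDamaPoint("x", min_bde=float("nan"), electrophilicity=1.0)
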