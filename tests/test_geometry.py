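"""Backbone construction, dihedral measurement and superposition."""

import math

import numpy as np
import pytest
import biotite.structure as struc
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from alphasheet.config import BackboneGeometry
from alphasheet.geometry import (
    DihedralTriple,
    bond_angle,
    build_backbone,
    ca_rmsd,
    measure_dihedrals,
    place_amide_hydrogens,
    place_atom,
    superpose,
    torsion_angle,
)

from conftest import random_chain, random_dihedrals


# ---------------------------------------------------------------------------
# independent oracles


def oracle_place(a, b, c, bond, angle, torsion):
    """Rotation-matrix internal-coordinate placement, convention-checked
    against biotite's dihedral rather than against the library's own code."""
    u = c - b
    u = u / np.linalg.norm(u)
    n = np.cross(b - a, u)
    n = n / np.linalg.norm(n)
    for sense1 in (1.0, -1.0):
        dir_cis = Rotation.from_rotvec(sense1 * math.radians(180.0 - angle) * n).apply(u)
        # cis candidate must eclipse a
        a_perp = (a - b) - np.dot(a - b, u) * u
        if np.dot(dir_cis, a_perp) < 0:
            continue
        for sense2 in (1.0, -1.0):
            d = c + bond * Rotation.from_rotvec(sense2 * math.radians(torsion) * u).apply(dir_cis)
            measured = math.degrees(struc.dihedral(a, b, c, d))
            if abs((measured - torsion + 180.0) % 360.0 - 180.0) < 1e-3:
                return d
    raise AssertionError("oracle failed to realize the requested torsion")


def oracle_build(sequence, dihedrals, geom):
    """Naive sequential chain construction using oracle_place only."""
    n = len(sequence)
    N = [None] * n
    CA = [None] * n
    C = [None] * n
    N[0] = np.zeros(3)
    CA[0] = np.array([geom.bond_n_ca, 0.0, 0.0])
    th = math.radians(180.0 - geom.angle_n_ca_c)
    C[0] = CA[0] + geom.bond_ca_c * np.array([math.cos(th), math.sin(th), 0.0])
    for i in range(1, n):
        N[i] = oracle_place(N[i - 1], CA[i - 1], C[i - 1], geom.bond_c_n,
                            geom.angle_ca_c_n, dihedrals[i - 1].psi)
        omega = dihedrals[i - 1].omega if dihedrals[i - 1].omega is not None else 180.0
        CA[i] = oracle_place(CA[i - 1], C[i - 1], N[i], geom.bond_n_ca,
                             geom.angle_c_n_ca, omega)
        C[i] = oracle_place(C[i - 1], N[i], CA[i], geom.bond_ca_c,
                            geom.angle_n_ca_c, dihedrals[i].phi)
    return N, CA, C


# ---------------------------------------------------------------------------
# dihedral measurement


def test_torsion_matches_reference_formula():
    """Torsions agree with biotite's signed-plane-angle implementation."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        p = rng.normal(size=(4, 3)) * 4
        # biotite evaluates in single precision; compare at its resolution
        assert torsion_angle(*p) == pytest.approx(
            math.degrees(struc.dihedral(*p)), abs=1e-4
        )


@pytest.mark.parametrize("n", [5, 9, 16])
def test_build_measure_round_trip(n):
    """measure_dihedrals inverts build_backbone to well below 1e-6 degrees."""
    rng = np.random.default_rng(n)
    for _ in range(20):
        dih = random_dihedrals(rng, n, omega_trans=False)
        chain = random_chain(rng, n)
        chain = build_backbone(chain.sequence, dih)
        for d, m in zip(dih, measure_dihedrals(chain)):
            for name in ("phi", "psi", "omega"):
                want = getattr(d, name)
                if want is not None:
                    assert getattr(m, name) == pytest.approx(want, abs=1e-6)


def test_coordinates_match_sequential_placement_oracle():
    """Built coordinates equal an independent step-by-step placement."""
    rng = np.random.default_rng(42)
    n = 10
    dih = random_dihedrals(rng, n)
    chain = build_backbone("A" * n, dih, with_cb=False, with_hydrogens=False)
    N, CA, C = oracle_build("A" * n, dih, BackboneGeometry())
    for i, res in enumerate(chain.residues):
        assert np.linalg.norm(res["N"] - N[i]) < 1e-9
        assert np.linalg.norm(res["CA"] - CA[i]) < 1e-9
        assert np.linalg.norm(res["C"] - C[i]) < 1e-9


def test_bond_lengths_canonical():
    geom = BackboneGeometry()
    rng = np.random.default_rng(3)
    chain = random_chain(rng, 7)
    for i, res in enumerate(chain.residues):
        assert np.linalg.norm(res["CA"] - res["N"]) == pytest.approx(geom.bond_n_ca, abs=1e-9)
        assert np.linalg.norm(res["C"] - res["CA"]) == pytest.approx(geom.bond_ca_c, abs=1e-9)
        assert np.linalg.norm(res["O"] - res["C"]) == pytest.approx(geom.bond_c_o, abs=1e-9)
        if i + 1 < len(chain):
            nxt = chain.residues[i + 1]
            assert np.linalg.norm(nxt["N"] - res["C"]) == pytest.approx(geom.bond_c_n, abs=1e-9)


def test_terminal_dihedrals_undefined():
    rng = np.random.default_rng(5)
    chain = random_chain(rng, 6)
    meas = measure_dihedrals(chain)
    assert meas[0].phi is None
    assert meas[-1].psi is None and meas[-1].omega is None
    assert all(m.phi is not None for m in meas[1:])


def test_mirrored_coordinates_negate_phi_psi():
    """Point inversion of all coordinates negates every torsion."""
    rng = np.random.default_rng(8)
    chain = random_chain(rng, 6)
    mirrored = chain.copy()
    for res in mirrored.residues:
        for k in res.atoms:
            res.atoms[k] = -res.atoms[k]
    for m, mm in zip(measure_dihedrals(chain), measure_dihedrals(mirrored)):
        for name in ("phi", "psi"):
            a, b = getattr(m, name), getattr(mm, name)
            if a is not None:
                assert b == pytest.approx(-a, abs=1e-9)


def test_chirality_flip_builds_exact_mirror_image():
    """Flipping chirality and negating dihedrals yields the point-inverted
    molecule (including CB and protons), to well below 1e-6 Å RMSD."""
    rng = np.random.default_rng(13)
    for trial in range(5):
        n = int(rng.integers(5, 12))
        chain = random_chain(rng, n)
        dih = measure_dihedrals(chain)
        flipped_seq = chain.sequence.swapcase()
        neg = [
            DihedralTriple(
                phi=None if d.phi is None else -d.phi,
                psi=None if d.psi is None else -d.psi,
                omega=None if d.omega is None else -d.omega,
            )
            for d in dih
        ]
        mirror = build_backbone(flipped_seq, neg)
        names = [sorted(r.atoms) for r in chain.residues]
        a = np.vstack([[mirror.residues[i][k] for k in nm] for i, nm in enumerate(names)])
        b = np.vstack([[-chain.residues[i][k] for k in nm] for i, nm in enumerate(names)])
        _, _, rmsd = superpose(a, b)
        assert rmsd < 1e-6


def test_alternating_alpha_chain_is_extended():
    """Alternating αL/αR dihedrals give a longer end-to-end chain than the
    uniformly αR (helical) chain of the same length."""
    aR, aL = (-60.0, -45.0), (60.0, 45.0)

    def make(pairs):
        n = len(pairs)
        dih = [
            DihedralTriple(None if i == 0 else pairs[i][0],
                           None if i == n - 1 else pairs[i][1], 180.0)
            for i in range(n)
        ]
        return build_backbone("A" * n, dih)

    alt = make([aR if i % 2 == 0 else aL for i in range(6)])
    helical = make([aR] * 6)

    def end_to_end(c):
        return np.linalg.norm(c.residues[-1]["CA"] - c.residues[0]["CA"])

    assert end_to_end(alt) > end_to_end(helical)


# ---------------------------------------------------------------------------
# amide hydrogens


def test_amide_hydrogen_geometry():
    rng = np.random.default_rng(17)
    chain = random_chain(rng, 6)
    geom = BackboneGeometry()
    for i in range(1, len(chain)):
        prev, res = chain.residues[i - 1], chain.residues[i]
        assert bond_angle(prev["C"], res["N"], res["H"]) == pytest.approx(
            geom.angle_c_n_h, abs=1e-6
        )
        # in the peptide plane, trans to the preceding carbonyl O
        assert abs(torsion_angle(prev["O"], prev["C"], res["N"], res["H"])) == pytest.approx(
            180.0, abs=1e-6
        )
        assert np.linalg.norm(res["H"] - res["N"]) == pytest.approx(geom.bond_n_h, abs=1e-9)


def test_place_amide_hydrogens_is_noop_without_overwrite():
    rng = np.random.default_rng(19)
    chain = random_chain(rng, 5)
    before = {i: r.atoms["H"].copy() for i, r in enumerate(chain.residues) if "H" in r}
    out = place_amide_hydrogens(chain)
    for i, h in before.items():
        assert np.array_equal(out.residues[i]["H"], h)


def test_amide_hydrogen_matches_constraint_solving_oracle():
    """H equals the solution of {|NH| = b, ∠(C,N,H) = θ, in-plane, trans-O}
    obtained by explicit rotation of the N→C direction in the peptide plane."""
    rng = np.random.default_rng(23)
    chain = random_chain(rng, 5)
    geom = BackboneGeometry()
    for i in range(1, len(chain)):
        prev, res = chain.residues[i - 1], chain.residues[i]
        n_axis = np.cross(prev["C"] - res["N"], prev["O"] - prev["C"])
        n_axis /= np.linalg.norm(n_axis)
        v = prev["C"] - res["N"]
        v /= np.linalg.norm(v)
        best = None
        for sense in (1.0, -1.0):
            h = res["N"] + geom.bond_n_h * Rotation.from_rotvec(
                sense * math.radians(geom.angle_c_n_h) * n_axis
            ).apply(v)
            tor = abs(torsion_angle(prev["O"], prev["C"], res["N"], h))
            if best is None or abs(tor - 180.0) < best[0]:
                best = (abs(tor - 180.0), h)
        assert np.linalg.norm(res["H"] - best[1]) < 1e-9


# ---------------------------------------------------------------------------
# RMSD


def test_ca_rmsd_is_pseudometric():
    rng = np.random.default_rng(29)
    a = random_chain(rng, 8)
    b = random_chain(rng, 8, seq=a.sequence)
    assert ca_rmsd(a, a) == pytest.approx(0.0, abs=1e-9)
    assert ca_rmsd(a, b) == pytest.approx(ca_rmsd(b, a), abs=1e-9)
    assert ca_rmsd(a, b) >= 0.0


def test_ca_rmsd_invariant_under_rigid_motion():
    rng = np.random.default_rng(31)
    chain = random_chain(rng, 9)
    rot = Rotation.random(random_state=5).as_matrix()
    moved = chain.transformed(rot, np.array([3.0, -2.0, 7.0]))
    assert ca_rmsd(chain, moved) < 1e-9


def test_ca_rmsd_matches_rotation_search_oracle():
    """Kabsch result equals a coarse rotation-grid search refined by a local
    optimizer over Euler angles, to 1e-4 Å."""
    rng = np.random.default_rng(37)
    chain = random_chain(rng, 7)
    bumped = chain.copy()
    bumped.residues[3].atoms["CA"] = bumped.residues[3]["CA"] + np.array([0.9, -0.4, 0.3])
    x = chain.coords("CA") - chain.coords("CA").mean(axis=0)
    y = bumped.coords("CA") - bumped.coords("CA").mean(axis=0)

    def cost(euler):
        r = Rotation.from_euler("xyz", euler).as_matrix()
        return np.sqrt(np.mean(np.sum((x - y @ r.T) ** 2, axis=1)))

    grid = np.linspace(-math.pi, math.pi, 9)
    best = min(
        ((cost((e1, e2, e3)), (e1, e2, e3)) for e1 in grid for e2 in grid for e3 in grid),
        key=lambda t: t[0],
    )
    refined = minimize(cost, best[1], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
    assert ca_rmsd(bumped, chain) == pytest.approx(refined.fun, abs=1e-4)


def test_ca_rmsd_rejects_tiny_or_mismatched_chains():
    rng = np.random.default_rng(41)
    a = random_chain(rng, 5)
    b = random_chain(rng, 6)
    with pytest.raises(ValueError):
        ca_rmsd(a, b)
    two = build_backbone("AA", [DihedralTriple(None, 130.0, 180.0),
                                DihedralTriple(-120.0, None, None)])
    with pytest.raises(ValueError):
        ca_rmsd(two, two)


def test_build_rejects_bad_input():
    with pytest.raises(ValueError):
        build_backbone("AXA", [DihedralTriple(None, 1.0, 180.0)] * 3)
    with pytest.raises(ValueError):
        build_backbone("AAA", [DihedralTriple(None, 1.0, 180.0)] * 2)
    with pytest.raises(ValueError):
        DihedralTriple(float("nan"), 0.0, 180.0)
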