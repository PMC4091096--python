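"""Peptide backbone geometry: internal ↔ Cartesian conversion and RMSD.

The unit of work is :class:`BackboneChain` — an ordered list of residues each
carrying a name → coordinate map for its backbone atoms (N, H, CA, HA, C, O
and optionally CB).  Chains are built from (φ, ψ, ω) dihedrals by sequential
internal-coordinate placement (the NeRF construction), so a chain's measured
dihedrals reproduce the inputs exactly up to floating-point error.

Chirality is carried two ways, deliberately redundantly: as an ``L``/``D``
flag on each residue (glycine is achiral and carries ``None``) and implicitly
in the sign of the dihedrals themselves.  The backbone build is
chirality-agnostic; only CB/HA placement consults the flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .config import BackboneGeometry

__all__ = [
    "DihedralTriple",
    "ResidueUnit",
    "BackboneChain",
    "ConformationalEnsemble",
    "torsion_angle",
    "bond_angle",
    "place_atom",
    "build_backbone",
    "measure_dihedrals",
    "place_amide_hydrogens",
    "place_alpha_hydrogens",
    "ca_rmsd",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


def wrap_angle(a: float) -> float:
    """Wrap an angle in degrees into (−180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class DihedralTriple:
    """Backbone (φ, ψ, ω) for one residue, degrees in (−180, 180].

    ``None`` marks an undefined terminal angle (φ of the first residue,
    ψ/ω of the last in a linear chain); it is never silently defaulted
    when measuring, only when building (ω → 180°, trans).
    """

    phi: Optional[float]
    psi: Optional[float]
    omega: Optional[float] = 180.0

    def __post_init__(self):
        for name in ("phi", "psi", "omega"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"non-finite {name}: {v!r}")


@dataclass
class ResidueUnit:
    """One residue: 1-based index, one-letter code, chirality, atom map."""

    index: int
    code: str
    chirality: Optional[str]  # 'L', 'D', or None for Gly
    atoms: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.code not in AMINO_ACIDS:
            raise ValueError(f"unknown residue code {self.code!r}")
        if self.code == "G":
            self.chirality = None
        elif self.chirality not in ("L", "D"):
            raise ValueError(f"residue {self.index}: chirality must be L or D")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.atoms[name]

    def __contains__(self, name: str) -> bool:
        return name in self.atoms


@dataclass
class BackboneChain:
    """Ordered residues plus a cyclic flag and free-form metadata."""

    residues: list
    cyclic: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, res in enumerate(self.residues, start=1):
            if res.index != k:
                raise ValueError("residue indices must be contiguous from 1")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def __getitem__(self, i: int) -> ResidueUnit:
        return self.residues[i]

    @property
    def sequence(self) -> str:
        """One-letter string, lowercase for D residues."""
        return "".join(
            r.code.lower() if r.chirality == "D" else r.code for r in self.residues
        )

    def coords(self, atom: str = "CA") -> np.ndarray:
        """(n, 3) array of the named atom over all residues."""
        return np.array([r.atoms[atom] for r in self.residues])

    def closure_gap(self) -> Optional[float]:
        """C(last)→N(first) distance in Å for cyclic chains, else None."""
        if not self.cyclic:
            return None
        return float(
            np.linalg.norm(self.residues[0].atoms["N"] - self.residues[-1].atoms["C"])
        )

    def copy(self) -> "BackboneChain":
        return BackboneChain(
            residues=[
                ResidueUnit(r.index, r.code, r.chirality,
                            {k: v.copy() for k, v in r.atoms.items()})
                for r in self.residues
            ],
            cyclic=self.cyclic,
            metadata=dict(self.metadata),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneChain":
        out = self.copy()
        for res in out.residues:
            for name in res.atoms:
                res.atoms[name] = rotation @ res.atoms[name] + translation
        return out


@dataclass
class ConformationalEnsemble:
    """Frames sharing one topology, with nonnegative weights summing to 1."""

    frames: list
    weights: Optional[np.ndarray] = None

    def __post_init__(self):
        if not self.frames:
            raise ValueError("ensemble needs at least one frame")
        seq0 = self.frames[0].sequence
        for f in self.frames[1:]:
            if f.sequence != seq0 or f.cyclic != self.frames[0].cyclic:
                raise ValueError("all frames must share sequence and topology")
        self.is_uniform = self.weights is None
        if self.weights is None:
            self.weights = np.full(len(self.frames), 1.0 / len(self.frames))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.frames):
                raise ValueError("one weight per frame required")
            if np.any(self.weights < 0):
                raise ValueError("weights must be nonnegative")
            total = self.weights.sum()
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                if total <= 0:
                    raise ValueError("weights must sum to a positive value")
                self.weights = self.weights / total

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# primitive geometry


def torsion_angle(p0, p1, p2, p3) -> float:
    """Signed IUPAC torsion p0–p1–p2–p3 in degrees, (−180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return wrap_angle(math.degrees(math.atan2(y, x)))


def bond_angle(p0, p1, p2) -> float:
    """Angle p0–p1–p2 at the middle atom, degrees in [0, 180]."""
    v1 = np.asarray(p0, float) - np.asarray(p1, float)
    v2 = np.asarray(p2, float) - np.asarray(p1, float)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D bonded to C so that |CD| = bond, ∠(B,C,D) = angle and
    the torsion A–B–C–D equals ``torsion`` (degrees, IUPAC sign)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle)
    tor = math.radians(torsion)
    e1 = c - b
    e1 = e1 / np.linalg.norm(e1)
    ba = a - b
    perp = ba - np.dot(ba, e1) * e1
    e2 = perp / np.linalg.norm(perp)  # τ = 0 eclipses atom A (cis)
    e3 = np.cross(e1, e2)
    return c + bond * (
        -math.cos(ang) * e1
        + math.sin(ang) * (math.cos(tor) * e2 + math.sin(tor) * e3)
    )


def _solve_two_cone(u1: np.ndarray, u2: np.ndarray, angle1: float, angle2: float,
                    sign: float) -> np.ndarray:
    """Unit vector making ``angle1`` with u1 and ``angle2`` with u2 (degrees);
    ``sign`` picks which side of the u1/u2 plane (along u1×u2)."""
    c12 = float(np.dot(u1, u2))
    t1 = math.cos(math.radians(angle1))
    t2 = math.cos(math.radians(angle2))
    det = 1.0 - c12 * c12
    p = (t1 - t2 * c12) / det
    q = (t2 - t1 * c12) / det
    v = p * u1 + q * u2
    rsq = 1.0 - float(np.dot(v, v))
    if rsq < 0:
        raise ValueError("inconsistent cone angles (no real solution)")
    w = np.cross(u1, u2)
    w = w / np.linalg.norm(w)
    return v + sign * math.sqrt(rsq) * w


# ---------------------------------------------------------------------------
# chain construction

# sign of the out-of-plane CB component (along N̂×Ĉ from CA) for L residues;
# checked against ideal CCD alanine coordinates
_CB_SIGN_L = 1.0


def _chirality_sign(chirality: Optional[str]) -> float:
    return _CB_SIGN_L if chirality != "D" else -_CB_SIGN_L


def _place_cb(res: ResidueUnit, geom: BackboneGeometry) -> None:
    n, ca, c = res.atoms["N"], res.atoms["CA"], res.atoms["C"]
    u1 = (n - ca) / np.linalg.norm(n - ca)
    u2 = (c - ca) / np.linalg.norm(c - ca)
    d = _solve_two_cone(u1, u2, geom.angle_n_ca_cb, geom.angle_c_ca_cb,
                        _chirality_sign(res.chirality))
    res.atoms["CB"] = ca + geom.bond_ca_cb * d


def build_backbone(
    sequence: Union[str, Sequence],
    dihedrals: Sequence[DihedralTriple],
    geometry: Optional[BackboneGeometry] = None,
    cyclic: bool = False,
    with_cb: bool = True,
    with_hydrogens: bool = True,
) -> BackboneChain:
    """Build an idealized chain from per-residue (φ, ψ, ω) dihedrals.

    ``sequence`` is a chirality-annotated one-letter string (lowercase = D)
    or any iterable of (code, chirality) pairs.  ω defaults to 180° (trans)
    when missing.  CB is mirrored for D residues; amide and α hydrogens are
    added unless disabled.
    """
    geom = geometry or BackboneGeometry()
    if isinstance(sequence, str):
        residues_spec = [
            (ch.upper(), None if ch.upper() == "G" else ("D" if ch.islower() else "L"))
            for ch in sequence
        ]
    else:
        residues_spec = [(c.upper(), chir) for c, chir in sequence]
    n_res = len(residues_spec)
    if n_res == 0:
        raise ValueError("empty sequence")
    if len(dihedrals) != n_res:
        raise ValueError(
            f"sequence length {n_res} != dihedral count {len(dihedrals)}"
        )

    residues = []
    for k, (code, chir) in enumerate(residues_spec, start=1):
        residues.append(ResidueUnit(index=k, code=code, chirality=chir))

    # initial frame: N1 at origin, CA1 on +x, C1 in the xy-plane
    residues[0].atoms["N"] = np.zeros(3)
    residues[0].atoms["CA"] = np.array([geom.bond_n_ca, 0.0, 0.0])
    theta = math.radians(180.0 - geom.angle_n_ca_c)
    residues[0].atoms["C"] = residues[0].atoms["CA"] + geom.bond_ca_c * np.array(
        [math.cos(theta), math.sin(theta), 0.0]
    )

    for i in range(1, n_res):
        prev, cur = residues[i - 1], residues[i]
        d_prev, d_cur = dihedrals[i - 1], dihedrals[i]
        psi = d_prev.psi
        if psi is None:
            raise ValueError(f"residue {i}: interior psi undefined")
        omega = 180.0 if d_prev.omega is None else d_prev.omega
        phi = d_cur.phi
        if phi is None:
            raise ValueError(f"residue {i + 1}: interior phi undefined")
        cur.atoms["N"] = place_atom(
            prev.atoms["N"], prev.atoms["CA"], prev.atoms["C"],
            geom.bond_c_n, geom.angle_ca_c_n, psi,
        )
        cur.atoms["CA"] = place_atom(
            prev.atoms["CA"], prev.atoms["C"], cur.atoms["N"],
            geom.bond_n_ca, geom.angle_c_n_ca, omega,
        )
        cur.atoms["C"] = place_atom(
            prev.atoms["C"], cur.atoms["N"], cur.atoms["CA"],
            geom.bond_ca_c, geom.angle_n_ca_c, phi,
        )

    # carbonyl O: in-plane, anti to the next amide N (torsion N-CA-C-O = ψ+180)
    for i, res in enumerate(residues):
        psi = dihedrals[i].psi
        t_o = wrap_angle((psi if psi is not None else 180.0) + 180.0)
        res.atoms["O"] = place_atom(
            res.atoms["N"], res.atoms["CA"], res.atoms["C"],
            geom.bond_c_o, geom.angle_ca_c_o, t_o,
        )

    chain = BackboneChain(residues=residues, cyclic=cyclic)
    if with_cb:
        for res in residues:
            if res.code != "G":
                _place_cb(res, geom)
    if with_hydrogens:
        place_amide_hydrogens(chain, geometry=geom, in_place=True)
        place_alpha_hydrogens(chain, geometry=geom, in_place=True)
    return chain


def measure_dihedrals(chain: BackboneChain) -> list:
    """Per-residue (φ, ψ, ω); terminal angles are None unless cyclic."""
    n = len(chain)
    out = []
    for i in range(n):
        res = chain.residues[i]
        for name in ("N", "CA", "C"):
            if name not in res:
                raise ValueError(f"residue {i + 1}: missing backbone atom {name}")
        prev_res = chain.residues[i - 1] if (i > 0 or chain.cyclic) else None
        next_res = chain.residues[(i + 1) % n] if (i < n - 1 or chain.cyclic) else None
        phi = psi = omega = None
        if prev_res is not None:
            phi = torsion_angle(prev_res["C"], res["N"], res["CA"], res["C"])
        if next_res is not None:
            psi = torsion_angle(res["N"], res["CA"], res["C"], next_res["N"])
            omega = torsion_angle(res["CA"], res["C"], next_res["N"], next_res["CA"])
        out.append(DihedralTriple(phi=phi, psi=psi, omega=omega))
    return out


def place_amide_hydrogens(
    chain: BackboneChain,
    geometry: Optional[BackboneGeometry] = None,
    overwrite: bool = False,
    in_place: bool = False,
) -> BackboneChain:
    """Add the backbone amide H to every residue with a preceding carbonyl.

    H sits in the peptide plane at the configured N–H length and C(prev)–N–H
    angle, trans to the preceding carbonyl O.  Residue 1 of a linear chain has
    no preceding C and is skipped; prolines have no amide H.
    """
    geom = geometry or BackboneGeometry()
    out = chain if in_place else chain.copy()
    n = len(out)
    for i, res in enumerate(out.residues):
        if res.code == "P":
            continue
        if i == 0 and not out.cyclic:
            continue
        if "H" in res and not overwrite:
            continue
        prev = out.residues[i - 1]
        if "O" not in prev:
            continue
        res.atoms["H"] = place_atom(
            prev["O"], prev["C"], res["N"],
            geom.bond_n_h, geom.angle_c_n_h, 180.0,
        )
    return out


def place_alpha_hydrogens(
    chain: BackboneChain,
    geometry: Optional[BackboneGeometry] = None,
    overwrite: bool = False,
    in_place: bool = False,
) -> BackboneChain:
    """Add Hα to each CA (two, HA2/HA3, for glycine).

    Non-glycine residues get the tetrahedral position on the opposite side of
    the N/CA/C plane from CB; glycine gets both completions.
    """
    geom = geometry or BackboneGeometry()
    out = chain if in_place else chain.copy()
    for res in out.residues:
        n, ca, c = res["N"], res["CA"], res["C"]
        u1 = (n - ca) / np.linalg.norm(n - ca)
        u2 = (c - ca) / np.linalg.norm(c - ca)
        if res.code == "G":
            if ("HA2" in res or "HA3" in res) and not overwrite:
                continue
            for name, sign in (("HA2", _CB_SIGN_L), ("HA3", -_CB_SIGN_L)):
                d = _solve_two_cone(u1, u2, geom.angle_n_ca_ha, geom.angle_c_ca_ha, sign)
                res.atoms[name] = ca + geom.bond_ca_ha * d
        else:
            if "HA" in res and not overwrite:
                continue
            d = _solve_two_cone(
                u1, u2, geom.angle_n_ca_ha, geom.angle_c_ca_ha,
                -_chirality_sign(res.chirality),
            )
            res.atoms["HA"] = ca + geom.bond_ca_ha * d
    return out


# ---------------------------------------------------------------------------
# superposition


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Optimal proper rotation + translation of ``mobile`` onto ``target``.

    Returns (rotation matrix, translation vector, rmsd).  Standard Kabsch:
    SVD of the covariance with a determinant correction so reflections are
    never applied.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape:
        raise ValueError("coordinate sets must have identical shape")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a defined superposition")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    p = mobile - mc
    q = target - tc
    u, _, vt = np.linalg.svd(p.T @ q)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    rmsd = math.sqrt(float(np.mean(np.sum(((r @ p.T).T - q) ** 2, axis=1))))
    t = tc - r @ mc
    return r, t, rmsd


def ca_rmsd(chain: BackboneChain, reference: BackboneChain) -> float:
    """Cα RMSD (Å) after optimal rigid superposition."""
    if len(chain) != len(reference):
        raise ValueError("chains must have equal residue counts")
    _, _, rmsd = superpose(chain.coords("CA"), reference.coords("CA"))
    return rmsd
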