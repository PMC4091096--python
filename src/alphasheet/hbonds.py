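"""Backbone hydrogen-bond detection and fraction-of-time occupancy scoring.

A design's stability score is the mean, over the hydrogen bonds present in
its idealized template, of the fraction of ensemble frames (weight) in which
each bond still satisfies the geometric criteria — plus the mean Cα RMSD of
the frames to the template as a qualitative tie-breaker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .config import HBondDefaults
from .geometry import (
    BackboneChain,
    ConformationalEnsemble,
    bond_angle,
    ca_rmsd,
)

__all__ = [
    "HBondCriteria",
    "HBondOccupancy",
    "DesignScore",
    "find_hbonds",
    "hbond_occupancy",
    "score_design",
    "write_occupancy_report",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criteria; ``mode`` picks which test applies.

    angle mode: H···O ≤ max_ho_dist and ∠(N–H···O) ≥ min_nho_angle.
    distance mode: N···O ≤ max_no_dist (for structures without protons).
    """

    max_ho_dist: float = HBondDefaults.max_ho_dist
    max_no_dist: float = HBondDefaults.max_no_dist
    min_nho_angle: float = HBondDefaults.min_nho_angle
    mode: str = HBondDefaults.mode

    def __post_init__(self):
        if self.max_ho_dist <= 0 or self.max_no_dist <= 0:
            raise ValueError("distance cutoffs must be positive")
        if not 0.0 <= self.min_nho_angle <= 180.0:
            raise ValueError("angle cutoff must be in [0, 180]")
        if self.mode not in ("angle", "distance"):
            raise ValueError("mode must be 'angle' or 'distance'")


BondPair = tuple  # ((donor_res_index, donor_atom), (acceptor_res_index, acceptor_atom))


def _satisfied(frame: BackboneChain, donor_i: int, acceptor_j: int,
               criteria: HBondCriteria) -> bool:
    donor = frame.residues[donor_i - 1]
    acceptor = frame.residues[acceptor_j - 1]
    if "O" not in acceptor:
        return False
    o = acceptor["O"]
    if criteria.mode == "distance":
        return float(np.linalg.norm(donor["N"] - o)) <= criteria.max_no_dist
    if "H" not in donor:
        raise ValueError(
            f"residue {donor_i} has no amide H; run place_amide_hydrogens "
            "or use distance-mode criteria"
        )
    h = donor["H"]
    if float(np.linalg.norm(h - o)) > criteria.max_ho_dist:
        return False
    return bond_angle(donor["N"], h, o) >= criteria.min_nho_angle


def find_hbonds(
    frame: BackboneChain,
    criteria: Optional[HBondCriteria] = None,
    min_sequence_sep: int = 2,
) -> list:
    """All backbone N–H → O=C pairs satisfying the criteria in one frame.

    Pairs with |i − j| < min_sequence_sep are excluded (no self or adjacent
    bonds).  Output is sorted by (donor index, acceptor index).
    """
    criteria = criteria or HBondCriteria()
    n = len(frame)
    pairs = []
    for i in range(1, n + 1):
        donor = frame.residues[i - 1]
        if donor.code == "P":
            continue
        if criteria.mode == "angle" and "H" not in donor:
            if i == 1 and not frame.cyclic:
                continue  # no amide proton at a free N-terminus
            raise ValueError(
                f"residue {i} has no amide H; run place_amide_hydrogens "
                "or use distance-mode criteria"
            )
        for j in range(1, n + 1):
            sep = abs(i - j)
            if frame.cyclic:
                sep = min(sep, n - sep)
            if sep < min_sequence_sep:
                continue
            if _satisfied(frame, i, j, criteria):
                pairs.append(((i, "N"), (j, "O")))
    return pairs


@dataclass(frozen=True)
class HBondOccupancy:
    donor: tuple
    acceptor: tuple
    fraction: float

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0 + 1e-12:
            raise ValueError("fraction must lie in [0, 1]")
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor must differ")


def hbond_occupancy(
    ensemble: ConformationalEnsemble,
    pairs: Sequence,
    criteria: Optional[HBondCriteria] = None,
) -> list:
    """Weighted fraction of frames in which each pair is hydrogen bonded."""
    criteria = criteria or HBondCriteria()
    out = []
    uniform = getattr(ensemble, "is_uniform", False)
    for (di, _), (aj, _) in pairs:
        if uniform:  # exact integer counting
            count = sum(
                _satisfied(frame, di, aj, criteria) for frame in ensemble.frames
            )
            frac = count / len(ensemble.frames)
        else:
            frac = min(
                float(sum(w for frame, w in zip(ensemble.frames, ensemble.weights)
                          if _satisfied(frame, di, aj, criteria))),
                1.0,
            )
        out.append(HBondOccupancy(donor=(di, "N"), acceptor=(aj, "O"), fraction=frac))
    return out


@dataclass
class DesignScore:
    """Mean template-bond occupancy plus mean Cα RMSD to the template."""

    mean_template_occupancy: float
    mean_ca_rmsd: float
    per_bond: list = field(default_factory=list)

    def sort_key(self) -> tuple:
        """Higher occupancy first; lower RMSD breaks ties."""
        return (-self.mean_template_occupancy, self.mean_ca_rmsd)


def score_design(
    ensemble: ConformationalEnsemble,
    template: BackboneChain,
    criteria: Optional[HBondCriteria] = None,
) -> DesignScore:
    """Score an ensemble against its idealized template.

    The template's own hydrogen bonds define the bond list; their mean
    occupancy over the ensemble and the weighted mean per-frame Cα RMSD to
    the template make up the score.
    """
    criteria = criteria or HBondCriteria()
    if len(template) != len(ensemble.frames[0]):
        raise ValueError("template and ensemble must share topology")
    bonds = find_hbonds(template, criteria)
    if not bonds:
        raise ValueError("template has no detected hydrogen bonds; nothing to score")
    occ = hbond_occupancy(ensemble, bonds, criteria)
    mean_occ = float(np.mean([o.fraction for o in occ]))
    mean_rmsd = float(
        sum(w * ca_rmsd(frame, template)
            for frame, w in zip(ensemble.frames, ensemble.weights))
    )
    return DesignScore(mean_template_occupancy=mean_occ,
                       mean_ca_rmsd=mean_rmsd, per_bond=occ)


def write_occupancy_report(occupancies: Sequence, path: Union[str, Path]) -> None:
    """Tab-separated occupancy report: donor, acceptor, fraction."""
    lines = ["donor\tacceptor\tfraction"]
    for o in occupancies:
        lines.append(f"{o.donor[0]}:{o.donor[1]}\t{o.acceptor[0]}:{o.acceptor[1]}\t"
                     f"{o.fraction:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
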