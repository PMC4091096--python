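"""Ramachandran classification, α-strand detection and propensity tables.

The α-sheet signature is a backbone that alternates strictly between the
right-handed (αR, lower-left quadrant) and left-handed (αL, upper-right
quadrant) helical regions of the Ramachandran map, which aligns all carbonyls
on one face of the strand and all amide N–H groups on the other.  Default
region boundaries are the pure sign quadrants, half-open at 0°; polygonal
regions can be supplied for finer work.

D-amino acids have point-inverted (φ, ψ) preferences relative to their L
forms, so a D-propensity table is obtained from an L table by swapping
αR ↔ αL and β ↔ mirror-β (`mirror_propensities`).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .geometry import BackboneChain, ConformationalEnsemble, measure_dihedrals

__all__ = [
    "RamachandranRegion",
    "StrandSegment",
    "AlignmentScore",
    "PropensityTable",
    "classify_region",
    "classify_chain",
    "detect_alpha_strands",
    "carbonyl_alignment",
    "propensity_from_samples",
    "mirror_propensities",
]


class RamachandranRegion(enum.Enum):
    """Quadrant labels; the declaration order is the modal tie-break order."""

    ALPHA_R = "ALPHA_R"
    ALPHA_L = "ALPHA_L"
    BETA = "BETA"
    MIRROR_BETA = "MIRROR_BETA"
    UNDEFINED = "UNDEFINED"


REGION_ORDER = list(RamachandranRegion)

_MIRROR = {
    RamachandranRegion.ALPHA_R: RamachandranRegion.ALPHA_L,
    RamachandranRegion.ALPHA_L: RamachandranRegion.ALPHA_R,
    RamachandranRegion.BETA: RamachandranRegion.MIRROR_BETA,
    RamachandranRegion.MIRROR_BETA: RamachandranRegion.BETA,
    RamachandranRegion.UNDEFINED: RamachandranRegion.UNDEFINED,
}


def mirror_region(region: RamachandranRegion) -> RamachandranRegion:
    """Region of (−φ, −ψ) given the region of (φ, ψ)."""
    return _MIRROR[region]


def classify_region(
    phi: Optional[float],
    psi: Optional[float],
    regions: Optional[Sequence] = None,
) -> RamachandranRegion:
    """Map one (φ, ψ) point to its Ramachandran region.

    Default partition (half-open at 0°): β φ<0, ψ≥0; αR φ<0, ψ<0;
    αL φ≥0, ψ≥0; mirror-β φ≥0, ψ<0.  ``regions`` may instead be a list of
    (label, polygon-vertex-array) pairs tested in order; points outside all
    polygons fall back to UNDEFINED.  Undefined/non-finite inputs yield
    UNDEFINED, never an exception.
    """
    if phi is None or psi is None:
        return RamachandranRegion.UNDEFINED
    if not (math.isfinite(phi) and math.isfinite(psi)):
        return RamachandranRegion.UNDEFINED
    if regions is not None:
        from matplotlib.path import Path as MplPath

        for label, polygon in regions:
            if MplPath(np.asarray(polygon)).contains_point((phi, psi)):
                return label
        return RamachandranRegion.UNDEFINED
    if phi < 0:
        return RamachandranRegion.ALPHA_R if psi < 0 else RamachandranRegion.BETA
    return RamachandranRegion.MIRROR_BETA if psi < 0 else RamachandranRegion.ALPHA_L


@dataclass
class ResidueClassification:
    """Per-residue modal label plus region occupancies over an ensemble."""

    index: int
    modal: RamachandranRegion
    occupancy: dict


def classify_chain(
    structure: Union[BackboneChain, ConformationalEnsemble],
    regions: Optional[Sequence] = None,
) -> list:
    """Classify every residue of a chain or ensemble.

    For an ensemble the per-region occupancies are frame-weight sums and the
    modal label is the occupancy argmax (ties broken by the declaration order
    αR < αL < β < mirror-β < undefined).
    """
    if isinstance(structure, BackboneChain):
        ensemble = ConformationalEnsemble(frames=[structure])
    else:
        ensemble = structure
    n = len(ensemble.frames[0])
    uniform = getattr(ensemble, "is_uniform", False)
    increment = 1 if uniform else None
    occ = [{r: 0.0 for r in REGION_ORDER} for _ in range(n)]
    for frame, w in zip(ensemble.frames, ensemble.weights):
        for i, d in enumerate(measure_dihedrals(frame)):
            occ[i][classify_region(d.phi, d.psi, regions=regions)] += (
                increment if uniform else w
            )
    if uniform:  # exact counting: divide integer counts once
        occ = [{r: v / len(ensemble.frames) for r, v in row.items()} for row in occ]
    out = []
    for i in range(n):
        modal = max(REGION_ORDER, key=lambda r: (occ[i][r], -REGION_ORDER.index(r)))
        out.append(ResidueClassification(index=i + 1, modal=modal, occupancy=occ[i]))
    return out


@dataclass(frozen=True)
class StrandSegment:
    """Maximal alternating αL/αR run, 1-based inclusive indices."""

    start: int
    end: int
    pattern_phase: RamachandranRegion  # label of the first residue

    def __len__(self) -> int:
        return self.end - self.start + 1


_ALPHA = (RamachandranRegion.ALPHA_R, RamachandranRegion.ALPHA_L)


def detect_alpha_strands(labels: Sequence, min_len: int = 4) -> list:
    """Find maximal non-overlapping runs alternating strictly αL/αR.

    ``labels`` is a list of RamachandranRegion (or ResidueClassification,
    whose modal labels are used).  Runs shorter than ``min_len`` are dropped;
    output is sorted by start index.
    """
    lab = [x.modal if isinstance(x, ResidueClassification) else x for x in labels]
    segments = []
    i = 0
    n = len(lab)
    while i < n:
        if lab[i] not in _ALPHA:
            i += 1
            continue
        j = i
        while j + 1 < n and lab[j + 1] in _ALPHA and lab[j + 1] != lab[j]:
            j += 1
        if j - i + 1 >= min_len:
            segments.append(StrandSegment(start=i + 1, end=j + 1, pattern_phase=lab[i]))
        i = j + 1
    return segments


@dataclass(frozen=True)
class AlignmentScore:
    """Order parameters in [0, 1]: 1 = all vectors parallel, 0 = cancelled."""

    carbonyl_order: float
    amide_order: Optional[float] = None


def carbonyl_alignment(chain: BackboneChain, segment: StrandSegment) -> AlignmentScore:
    """Norm of the mean unit C→O (and N→H) vector over a segment.

    In an ideal α-strand all carbonyls point the same way (score → 1);
    in a β-strand they alternate and cancel (score → 0).  The amide score is
    None when any segment residue lacks its amide H.
    """
    if len(segment) < 2:
        raise ValueError("segment must span at least 2 residues")
    co, nh = [], []
    have_h = True
    for idx in range(segment.start, segment.end + 1):
        res = chain.residues[idx - 1]
        v = res["O"] - res["C"]
        co.append(v / np.linalg.norm(v))
        if "H" in res:
            u = res["H"] - res["N"]
            nh.append(u / np.linalg.norm(u))
        else:
            have_h = False
    carbonyl = float(np.linalg.norm(np.mean(co, axis=0)))
    amide = float(np.linalg.norm(np.mean(nh, axis=0))) if (have_h and nh) else None
    return AlignmentScore(carbonyl_order=carbonyl, amide_order=amide)


# ---------------------------------------------------------------------------
# propensity tables


@dataclass
class PropensityTable:
    """(code, chirality) → probability vector over Ramachandran regions.

    ``entries`` maps (one-letter code, 'L'|'D'|None) to a dict
    {RamachandranRegion: probability}; ``counts`` records sample sizes.
    """

    entries: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def probability(self, code: str, chirality: Optional[str],
                    region: RamachandranRegion) -> float:
        key = (code, None if code == "G" else chirality)
        if key not in self.entries:
            raise KeyError(f"no propensity entry for {key}")
        return self.entries[key].get(region, 0.0)

    def modal_region(self, code: str, chirality: Optional[str]) -> RamachandranRegion:
        key = (code, None if code == "G" else chirality)
        row = self.entries[key]
        return max(REGION_ORDER, key=lambda r: (row.get(r, 0.0), -REGION_ORDER.index(r)))

    def validate(self) -> None:
        for key, row in self.entries.items():
            total = sum(row.values())
            if any(p < 0 for p in row.values()) or abs(total - 1.0) > 1e-9:
                raise ValueError(f"entry {key}: probabilities must be ≥0 and sum to 1")

    # -- TSV round-trip ---------------------------------------------------

    def to_tsv(self, path: Union[str, Path]) -> None:
        rows = []
        for (code, chir), row in sorted(
            self.entries.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
        ):
            rec = {"code": code, "chirality": chir if chir else "-"}
            for region in REGION_ORDER:
                rec[region.value] = row.get(region, 0.0)
            rec["count"] = self.counts.get((code, chir), 0)
            rows.append(rec)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "PropensityTable":
        df = pd.read_csv(path, sep="\t")
        table = cls()
        for _, rec in df.iterrows():
            chir = None if rec["chirality"] in ("-", "", None) else str(rec["chirality"])
            key = (str(rec["code"]), chir)
            table.entries[key] = {r: float(rec[r.value]) for r in REGION_ORDER}
            table.counts[key] = int(rec["count"])
        table.validate()
        return table


def propensity_from_samples(
    samples: dict,
    regions: Optional[Sequence] = None,
) -> PropensityTable:
    """Estimate region probabilities by counting (φ, ψ) observations.

    ``samples`` maps (code, chirality) to an iterable of (φ, ψ) pairs — e.g.
    the per-frame dihedrals of the guest residue in a host–guest (GGXGG-style)
    simulation.  Probabilities are raw counts / total; no smoothing.
    """
    table = PropensityTable()
    for key, pairs in samples.items():
        code, chir = key
        chir = None if code == "G" else chir
        pairs = list(pairs)
        if not pairs:
            raise ValueError(f"empty sample set for {key}")
        counts = {r: 0 for r in REGION_ORDER}
        for phi, psi in pairs:
            counts[classify_region(phi, psi, regions=regions)] += 1
        total = len(pairs)
        table.entries[(code, chir)] = {r: counts[r] / total for r in REGION_ORDER}
        table.counts[(code, chir)] = total
    table.validate()
    return table


def mirror_propensities(table: PropensityTable) -> PropensityTable:
    """Derive D-residue propensities from L entries by region mirroring.

    P_D(code, region) = P_L(code, mirror(region)); glycine is achiral and
    passes through unchanged.  Applying the operation twice restores the
    original table.
    """
    out = PropensityTable()
    for (code, chir), row in table.entries.items():
        if chir is None:  # Gly
            out.entries[(code, None)] = dict(row)
            out.counts[(code, None)] = table.counts.get((code, None), 0)
            continue
        flipped = "D" if chir == "L" else "L"
        out.entries[(code, flipped)] = {
            region: row[mirror_region(region)] for region in REGION_ORDER
        }
        out.counts[(code, flipped)] = table.counts.get((code, chir), 0)
    out.validate()
    return out
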