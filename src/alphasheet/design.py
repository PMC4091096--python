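"""Idealized hairpin templates and propensity-based sequence ranking.

The in-silico loop mirrors how α-sheet hairpins are designed: build an
idealized template (alternating αR/αL strands for α-sheet, extended strands
for β-sheet, joined by a turn), enumerate candidate sequences whose
chirality pattern matches the template (L at αR positions, D at αL
positions), rank them by summed log conformational propensity under a
polar/nonpolar composition constraint, then re-rank survivors by
hydrogen-bond occupancy and Cα RMSD over per-candidate ensembles.
Refinement is deliberately manual: rank → evaluate → edit → re-rank.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .config import BackboneGeometry, IdealDihedrals
from .conformation import RamachandranRegion, PropensityTable
from .geometry import BackboneChain, ConformationalEnsemble, DihedralTriple, build_backbone
from .hbonds import DesignScore, HBondCriteria, score_design

__all__ = [
    "TemplateSpec",
    "DesignCandidate",
    "CompositionConstraint",
    "make_ideal_template",
    "template_dihedrals",
    "strand_positions",
    "rank_sequences",
    "evaluate_candidates",
    "POLAR_RESIDUES",
]

POLAR_RESIDUES = set("STNQDEKRHY")

ALPHA_SHEET = "ALPHA_SHEET"
BETA_SHEET = "BETA_SHEET"

# Artifact turn defaults (the source designs publish no turn types).
# β-hairpins close with a type I′ turn.  The α-sheet turn was chosen by a
# coarse grid search over the mirror-β quadrant for the two-residue turn that
# best closes an idealized α-hairpin (most cross-strand hydrogen bonds,
# most compact strand pairing); see docs/methods.md.
DEFAULT_BETA_TURN = ((60.0, 30.0), (90.0, 0.0))
DEFAULT_ALPHA_TURN = ((50.0, -10.0), (170.0, -10.0))


@dataclass
class TemplateSpec:
    """Geometry recipe for an idealized hairpin."""

    strand_len: int = 6
    turn_len: int = 2
    conformation: str = ALPHA_SHEET
    cyclic: bool = False
    turn_dihedrals: Optional[Sequence] = None  # (φ, ψ) pairs, cycled over the turn
    ideal: IdealDihedrals = field(default_factory=IdealDihedrals)

    def __post_init__(self):
        if self.strand_len < 3:
            raise ValueError("strand_len must be ≥ 3")
        if self.turn_len < 2:
            raise ValueError("turn_len must be ≥ 2")
        if self.conformation not in (ALPHA_SHEET, BETA_SHEET):
            raise ValueError("conformation must be ALPHA_SHEET or BETA_SHEET")
        if self.turn_dihedrals is None:
            self.turn_dihedrals = (
                DEFAULT_ALPHA_TURN if self.conformation == ALPHA_SHEET else DEFAULT_BETA_TURN
            )

    @property
    def n_residues(self) -> int:
        # cyclic hairpins need a second turn to close the backbone
        return 2 * self.strand_len + self.turn_len * (2 if self.cyclic else 1)


def _position_kind(spec: TemplateSpec, pos: int) -> str:
    """'strand' or 'turn' for 1-based position ``pos``."""
    s, t = spec.strand_len, spec.turn_len
    if pos <= s:
        return "strand"
    if pos <= s + t:
        return "turn"
    if pos <= 2 * s + t:
        return "strand"
    return "turn"


def strand_positions(spec: TemplateSpec) -> list:
    """1-based indices of all strand residues."""
    return [p for p in range(1, spec.n_residues + 1) if _position_kind(spec, p) == "strand"]


def target_region(spec: TemplateSpec, pos: int) -> Optional[RamachandranRegion]:
    """Intended Ramachandran region of a strand position (None for turns).

    α-sheet strands alternate αR/αL with a global parity (odd positions αR);
    β-sheet strands are all β.
    """
    if _position_kind(spec, pos) != "strand":
        return None
    if spec.conformation == BETA_SHEET:
        return RamachandranRegion.BETA
    return RamachandranRegion.ALPHA_R if pos % 2 == 1 else RamachandranRegion.ALPHA_L


def template_dihedrals(spec: TemplateSpec) -> list:
    """Per-residue DihedralTriple list realizing the spec."""
    out = []
    n = spec.n_residues
    turn_counter = 0
    for pos in range(1, n + 1):
        if _position_kind(spec, pos) == "turn":
            phi, psi = spec.turn_dihedrals[turn_counter % len(spec.turn_dihedrals)]
            turn_counter += 1
        else:
            region = target_region(spec, pos)
            phi, psi = {
                RamachandranRegion.ALPHA_R: spec.ideal.alpha_r,
                RamachandranRegion.ALPHA_L: spec.ideal.alpha_l,
                RamachandranRegion.BETA: spec.ideal.beta,
            }[region]
        last = pos == n and not spec.cyclic
        out.append(
            DihedralTriple(
                phi=None if pos == 1 and not spec.cyclic else float(phi),
                psi=None if last else float(psi),
                omega=None if last else 180.0,
            )
        )
    return out


def default_template_sequence(spec: TemplateSpec) -> str:
    """Alanine strands (D at αL positions) with glycine turns."""
    seq = []
    for pos in range(1, spec.n_residues + 1):
        region = target_region(spec, pos)
        if region is None:
            seq.append("G")
        elif region == RamachandranRegion.ALPHA_L:
            seq.append("a")
        else:
            seq.append("A")
    return "".join(seq)


def make_ideal_template(
    spec: TemplateSpec,
    sequence: Optional[str] = None,
    geometry: Optional[BackboneGeometry] = None,
) -> BackboneChain:
    """Build the idealized hairpin chain for a template spec.

    A linear hairpin is strand–turn–strand; a cyclic one adds a second turn
    and records (without optimizing) the C-terminal→N-terminal closure gap
    in ``metadata['closure_gap']``.
    """
    seq = sequence if sequence is not None else default_template_sequence(spec)
    if len(seq) != spec.n_residues:
        raise ValueError(
            f"sequence length {len(seq)} != template size {spec.n_residues}"
        )
    chain = build_backbone(
        seq, template_dihedrals(spec), geometry=geometry, cyclic=spec.cyclic
    )
    chain.metadata["template"] = spec.conformation
    if spec.cyclic:
        chain.metadata["closure_gap"] = chain.closure_gap()
    return chain


@dataclass
class CompositionConstraint:
    """Polar-fraction bounds over strand positions."""

    min_polar_fraction: float = 0.4
    max_polar_fraction: float = 0.6
    polar_set: frozenset = frozenset(POLAR_RESIDUES)

    def satisfied(self, strand_codes: Sequence[str]) -> bool:
        if not strand_codes:
            return True
        frac = sum(c in self.polar_set for c in strand_codes) / len(strand_codes)
        return self.min_polar_fraction <= frac <= self.max_polar_fraction


@dataclass
class DesignCandidate:
    """A chirality-annotated sequence with its propensity score."""

    sequence: str  # lowercase = D
    propensity_score: float
    polar_fraction: float
    score: Optional[DesignScore] = None


def _candidate_chirality_ok(spec: TemplateSpec, pos: int, code: str, chir) -> bool:
    region = target_region(spec, pos)
    if code == "G":
        return True
    if region == RamachandranRegion.ALPHA_L:
        return chir == "D"
    if region in (RamachandranRegion.ALPHA_R, RamachandranRegion.BETA):
        return chir == "L"
    return True


def rank_sequences(
    spec: TemplateSpec,
    table: PropensityTable,
    library: dict,
    constraint: Optional[CompositionConstraint] = None,
    fixed: Optional[dict] = None,
) -> list:
    """Enumerate and rank candidate sequences for the strand positions.

    ``library`` maps 1-based strand position → iterable of one-letter codes
    (chirality is imposed by the template: D at αL positions, L elsewhere;
    glycine stays achiral).  Non-library positions take ``fixed`` codes or
    glycine.  Candidates violating the chirality pattern or the composition
    constraint are dropped; survivors are sorted by summed log propensity
    toward each position's target region (descending), ties broken by
    lexicographic sequence order.  Zero-probability entries score −inf and
    rank last.
    """
    constraint = constraint or CompositionConstraint()
    fixed = fixed or {}
    positions = sorted(library.keys())
    if not positions:
        raise ValueError("empty candidate library")
    s_positions = set(strand_positions(spec))

    def chirality_for(pos: int, code: str):
        if code == "G":
            return None
        region = target_region(spec, pos)
        return "D" if region == RamachandranRegion.ALPHA_L else "L"

    candidates = []
    for combo in itertools.product(*(library[p] for p in positions)):
        seq_chars = []
        ok = True
        score = 0.0
        strand_codes = []
        for pos in range(1, spec.n_residues + 1):
            if pos in library:
                code = combo[positions.index(pos)].upper()
            else:
                code = fixed.get(pos, "G").upper()
            chir = chirality_for(pos, code)
            if not _candidate_chirality_ok(spec, pos, code, chir):
                ok = False
                break
            region = target_region(spec, pos)
            if region is not None and pos in library:
                p = table.probability(code, chir, region)
                score += math.log(p) if p > 0 else -math.inf
            if pos in s_positions:
                strand_codes.append(code)
            seq_chars.append(code.lower() if chir == "D" else code)
        if not ok:
            continue
        if not constraint.satisfied(strand_codes):
            continue
        candidates.append(
            DesignCandidate(
                sequence="".join(seq_chars),
                propensity_score=score,
                polar_fraction=(
                    sum(c in constraint.polar_set for c in strand_codes) / len(strand_codes)
                    if strand_codes
                    else 0.0
                ),
            )
        )
    if not candidates:
        raise ValueError("no candidates survive the constraints")
    candidates.sort(key=lambda c: (-c.propensity_score, c.sequence))
    return candidates


def evaluate_candidates(
    candidates: Sequence[DesignCandidate],
    ensembles: Sequence[ConformationalEnsemble],
    spec: TemplateSpec,
    criteria: Optional[HBondCriteria] = None,
    geometry: Optional[BackboneGeometry] = None,
) -> list:
    """Fill each candidate's DesignScore from its ensemble and re-rank.

    Each candidate is scored against its own idealized template (same spec,
    candidate sequence); the final order is higher mean hydrogen-bond
    occupancy first, lower mean Cα RMSD on ties.
    """
    if len(candidates) != len(ensembles):
        raise ValueError("one ensemble per candidate required")
    out = []
    for cand, ens in zip(candidates, ensembles):
        if ens.frames[0].sequence != cand.sequence:
            raise ValueError(
                f"ensemble topology {ens.frames[0].sequence!r} does not match "
                f"candidate {cand.sequence!r}"
            )
        template = make_ideal_template(spec, sequence=cand.sequence, geometry=geometry)
        cand.score = score_design(ens, template, criteria)
        out.append(cand)
    out.sort(key=lambda c: c.score.sort_key() + (c.sequence,))
    return out


def write_candidate_report(candidates: Sequence[DesignCandidate],
                           path: Union[str, Path]) -> None:
    """Tab-separated candidate report."""
    lines = ["sequence\tpropensity_score\tpolar_fraction\tmean_occupancy\tmean_ca_rmsd"]
    for c in candidates:
        occ = f"{c.score.mean_template_occupancy:.6f}" if c.score else "NA"
        rmsd = f"{c.score.mean_ca_rmsd:.6f}" if c.score else "NA"
        lines.append(f"{c.sequence}\t{c.propensity_score:.6f}\t{c.polar_fraction:.3f}\t{occ}\t{rmsd}")
    Path(path).write_text("\n".join(lines) + "\n")
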