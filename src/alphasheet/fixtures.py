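"""Seed-deterministic synthetic inputs: jittered ensembles, kinetics, spectra.

These generators stand in for the physical inputs of the workflow — MD
conformational ensembles, plate-reader aggregation kinetics, FTIR second
derivatives — so every analysis can be exercised end-to-end without data
files.  Jitter is applied in internal coordinates (Gaussian noise on φ/ψ,
chain rebuilt), so every frame remains a valid peptide geometry, which is
the property MD frames would also have; see docs/methods.md for what this
model does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .assays import AssayCurve, Spectrum
from .config import BackboneGeometry
from .design import TemplateSpec, default_template_sequence, template_dihedrals
from .geometry import ConformationalEnsemble, DihedralTriple, build_backbone

__all__ = [
    "JitterSpec",
    "KineticsSpec",
    "generate_ensemble",
    "generate_kinetics",
    "generate_spectrum",
]


@dataclass
class JitterSpec:
    """Gaussian dihedral jitter around an idealized template."""

    template: TemplateSpec
    sigma: float = 10.0   # degrees, sd of the φ/ψ perturbation
    n_frames: int = 50
    seed: int = 0
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be ≥ 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be ≥ 1")


def generate_ensemble(spec: JitterSpec,
                      geometry: Optional[BackboneGeometry] = None) -> ConformationalEnsemble:
    """Rebuild the template n_frames times with independent φ/ψ jitter.

    ω is left at its template value (peptide-bond torsions are far stiffer
    than φ/ψ).  σ = 0 reproduces the template exactly in every frame.
    """
    rng = np.random.default_rng(spec.seed)
    base = template_dihedrals(spec.template)
    seq = spec.sequence or default_template_sequence(spec.template)
    frames = []
    for _ in range(spec.n_frames):
        jittered = []
        for d in base:
            jittered.append(
                DihedralTriple(
                    phi=None if d.phi is None else d.phi + rng.normal(0.0, spec.sigma),
                    psi=None if d.psi is None else d.psi + rng.normal(0.0, spec.sigma),
                    omega=d.omega,
                )
            )
        frames.append(
            build_backbone(seq, jittered, geometry=geometry, cyclic=spec.template.cyclic)
        )
    return ConformationalEnsemble(frames=frames)


@dataclass
class KineticsSpec:
    """Sigmoidal aggregation curve with an injected inhibition fraction."""

    baseline: float = 0.05
    amplitude: float = 1.0
    t50: float = 12.0      # hours
    tau: float = 2.5       # hours
    inhibition: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.amplitude <= 0 or self.tau <= 0:
            raise ValueError("amplitude and tau must be positive")
        if not 0.0 <= self.inhibition <= 1.0:
            raise ValueError("inhibition must be in [0, 1]")


def generate_kinetics(spec: KineticsSpec, times: Sequence[float],
                      condition: str = "", replicate: int = 0) -> AssayCurve:
    """signal(t) = baseline + amplitude·(1 − inhibition)·σ((t − t50)/τ) + noise."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(times, dtype=float)
    signal = spec.baseline + spec.amplitude * (1.0 - spec.inhibition) / (
        1.0 + np.exp(-(t - spec.t50) / spec.tau)
    )
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=t.shape)
    return AssayCurve(times=t, signals=signal, condition=condition, replicate=replicate)


def generate_spectrum(
    bands: Sequence,
    grid: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    kind: str = "FTIR_second_derivative",
) -> Spectrum:
    """Sum of negative Gaussians (second-derivative-like bands) plus noise.

    ``bands`` is a list of (center cm⁻¹, width cm⁻¹, depth) triples; the
    default grid is 1550–1750 cm⁻¹ at 1 cm⁻¹.
    """
    x = np.asarray(grid if grid is not None else np.arange(1550.0, 1750.5, 1.0), float)
    rng = np.random.default_rng(seed)
    y = np.zeros_like(x)
    for center, width, depth in bands:
        if width <= 0:
            raise ValueError("band width must be positive")
        y -= depth * np.exp(-0.5 * ((x - center) / width) ** 2)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    return Spectrum(x=x, y=y, kind=kind)
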