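"""Chirality-annotated sequence notation.

Designs are written in one-letter code with lowercase for D-amino acids
(glycine is achiral), optional ``Ac-``/``-NH2`` terminal modifiers and a
``cyclo(...)`` wrapper for head-to-tail cyclic backbones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from .geometry import AMINO_ACIDS

__all__ = ["AnnotatedSequence", "parse_sequence", "render_sequence"]


@dataclass
class AnnotatedSequence:
    """Residues as (code, chirality) with termini and cyclic flag."""

    residues: list  # (one-letter uppercase code, 'L'|'D'|None)
    n_terminus: str = "free"   # free | acetyl
    c_terminus: str = "free"   # free | amide
    cyclic: bool = False

    def __post_init__(self):
        if self.n_terminus not in ("free", "acetyl"):
            raise ValueError("n_terminus must be 'free' or 'acetyl'")
        if self.c_terminus not in ("free", "amide"):
            raise ValueError("c_terminus must be 'free' or 'amide'")
        if self.cyclic and (self.n_terminus != "free" or self.c_terminus != "free"):
            raise ValueError("a cyclic backbone has no terminal modifiers")
        for code, chir in self.residues:
            if code not in AMINO_ACIDS:
                raise ValueError(f"unknown residue code {code!r}")
            if code == "G" and chir is not None:
                raise ValueError("glycine is achiral")
            if code != "G" and chir not in ("L", "D"):
                raise ValueError(f"residue {code}: chirality must be L or D")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def core(self) -> str:
        """Bare sequence string, lowercase = D."""
        return "".join(c.lower() if ch == "D" else c for c, ch in self.residues)


def parse_sequence(text: str) -> AnnotatedSequence:
    """Parse ``[Ac-]SEQ[-NH2]`` or ``cyclo(SEQ)``; lowercase letters are D."""
    s = text.strip()
    if not s:
        raise ValueError("empty sequence")
    cyclic = False
    n_mod, c_mod = "free", "free"
    if s.lower().startswith("cyclo(") and s.endswith(")"):
        cyclic = True
        s = s[len("cyclo("):-1]
    else:
        if s.startswith("Ac-"):
            n_mod = "acetyl"
            s = s[3:]
        if s.endswith("-NH2"):
            c_mod = "amide"
            s = s[:-4]
    residues = []
    for ch in s:
        code = ch.upper()
        if code not in AMINO_ACIDS:
            raise ValueError(f"unknown residue letter {ch!r} in {text!r}")
        if code == "G":
            if ch == "g":
                warnings.warn("glycine is achiral; lowercase 'g' treated as G")
            residues.append(("G", None))
        else:
            residues.append((code, "D" if ch.islower() else "L"))
    return AnnotatedSequence(residues=residues, n_terminus=n_mod,
                             c_terminus=c_mod, cyclic=cyclic)


def render_sequence(seq: AnnotatedSequence) -> str:
    """Inverse of parse_sequence."""
    core = seq.core
    if seq.cyclic:
        return f"cyclo({core})"
    prefix = "Ac-" if seq.n_terminus == "acetyl" else ""
    suffix = "-NH2" if seq.c_terminus == "amide" else ""
    return f"{prefix}{core}{suffix}"
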