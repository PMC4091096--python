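"""Run-wide configuration: geometry constants, region boundaries, thresholds.

Every tunable in the toolkit lives here with a documented default, so a run
is fully described by one flat key=value file plus a seed.  Geometry constants
are Engh–Huber-style values in Å and degrees.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union


@dataclass
class BackboneGeometry:
    """Canonical backbone bond lengths (Å) and angles (degrees).

    These are library defaults in the Engh–Huber tradition; any of them can
    be overridden when idealized chains are built.
    """

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    bond_c_o: float = 1.231
    bond_n_h: float = 1.010
    bond_ca_cb: float = 1.530
    bond_ca_ha: float = 1.090
    angle_c_n_ca: float = 121.7
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_ca_c_o: float = 120.8
    angle_c_n_h: float = 119.0
    angle_n_ca_cb: float = 110.5
    angle_c_ca_cb: float = 110.1
    angle_n_ca_ha: float = 109.5
    angle_c_ca_ha: float = 109.5


@dataclass
class IdealDihedrals:
    """(φ, ψ) used when building idealized templates, degrees.

    The α-sheet literature reads conformation by Ramachandran quadrant;
    these point values are library defaults chosen inside those quadrants,
    not published constants.
    """

    alpha_r: tuple[float, float] = (-60.0, -45.0)
    alpha_l: tuple[float, float] = (60.0, 45.0)
    beta: tuple[float, float] = (-120.0, 130.0)


@dataclass
class HBondDefaults:
    """Geometric hydrogen-bond criteria (angle mode is the default)."""

    max_ho_dist: float = 2.6       # Å, H···O in angle mode
    max_no_dist: float = 3.5       # Å, N···O in distance-only mode
    min_nho_angle: float = 120.0   # degrees, N–H···O
    mode: str = "angle"            # "angle" | "distance"


@dataclass
class NOEDefaults:
    """Effective-distance bucket edges (Å) and pattern-verdict rule knobs."""

    strong_max: float = 2.7
    medium_max: float = 3.5
    weak_max: float = 5.5
    long_range_min_sep: int = 3
    # verdict rule: see noe.predict_pattern
    alpha_dnn_max: float = 3.0
    beta_dan_max: float = 2.6
    beta_dnn_min: float = 4.0


@dataclass
class AssayConstants:
    """Published assay conversion constants.

    ``cr_denominator_*`` are the Congo red absorbance divisors of the
    rCb = Abs540/25295 − Abs477/46306 relationship; ``epsilon_220`` is the
    Aβ extinction coefficient at 220 nm in cm⁻¹·M⁻¹.
    """

    cr_denominator_540: float = 25295.0
    cr_denominator_477: float = 46306.0
    epsilon_220: float = 50000.0


@dataclass
class RunConfig:
    """Aggregate of all defaults plus the random seed."""

    geometry: BackboneGeometry = field(default_factory=BackboneGeometry)
    ideal: IdealDihedrals = field(default_factory=IdealDihedrals)
    hbond: HBondDefaults = field(default_factory=HBondDefaults)
    noe: NOEDefaults = field(default_factory=NOEDefaults)
    assay: AssayConstants = field(default_factory=AssayConstants)
    min_strand_len: int = 4
    seed: int = 0

    # ---- flat key=value serialization ----------------------------------

    def to_file(self, path: Union[str, Path]) -> None:
        lines = []
        for section_name, section in self._sections():
            for f in dataclasses.fields(section):
                lines.append(f"{section_name}.{f.name} = {getattr(section, f.name)!r}")
        lines.append(f"min_strand_len = {self.min_strand_len!r}")
        lines.append(f"seed = {self.seed!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        cfg = cls()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            cfg._set_flat(key, value, where=f"{path}:{lineno}")
        return cfg

    def _sections(self):
        return [
            ("geometry", self.geometry),
            ("ideal", self.ideal),
            ("hbond", self.hbond),
            ("noe", self.noe),
            ("assay", self.assay),
        ]

    def _set_flat(self, key: str, value: str, where: str = "") -> None:
        import ast

        try:
            parsed = ast.literal_eval(value)
        except (ValueError, SyntaxError):
            parsed = value  # bare string (e.g. hbond mode)
        if "." in key:
            section_name, attr = key.split(".", 1)
            section = dict(self._sections()).get(section_name)
            if section is None or not hasattr(section, attr):
                raise KeyError(f"{where}: unknown config key {key!r}")
            setattr(section, attr, parsed)
        else:
            if not hasattr(self, key) or key in {"geometry", "ideal", "hbond", "noe", "assay"}:
                raise KeyError(f"{where}: unknown config key {key!r}")
            setattr(self, key, parsed)


DEFAULT_CONFIG = RunConfig()
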