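"""PDB reading/writing for backbone chains and multi-model ensembles.

Chains are written with standard L 3-letter residue names plus an optional
chirality sidecar table (maximal reader compatibility); on reading, either
the sidecar or standard PDB D-residue names (DAL, DPN, ...) restore the
chirality flags.  Ensembles round-trip as MODEL/ENDMDL blocks.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .geometry import BackboneChain, ConformationalEnsemble, ResidueUnit

__all__ = ["read_pdb", "write_pdb", "PDBFormatError"]


class PDBFormatError(ValueError):
    pass


ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

# standard PDB chemical-component names for D-amino acids
D_THREE = {
    "DAL": "A", "DAR": "R", "DSG": "N", "DAS": "D", "DCY": "C",
    "DGN": "Q", "DGL": "E", "DHI": "H", "DIL": "I", "DLE": "L",
    "DLY": "K", "MED": "M", "DPN": "F", "DPR": "P", "DSN": "S",
    "DTH": "T", "DTR": "W", "DTY": "Y", "DVA": "V",
}

_ATOM_ORDER = ("N", "H", "CA", "HA", "HA2", "HA3", "CB", "C", "O")


def _element(atom_name: str) -> str:
    return "H" if atom_name.startswith("H") else atom_name[0]


def _chain_to_atom_array(chain: BackboneChain) -> struc.AtomArray:
    names, res_ids, res_names, coords = [], [], [], []
    for res in chain.residues:
        for name in _ATOM_ORDER:
            if name in res.atoms:
                names.append(name)
                res_ids.append(res.index)
                res_names.append(ONE_TO_THREE[res.code])
                coords.append(res.atoms[name])
    arr = struc.AtomArray(len(names))
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = np.array(names)
    arr.res_id = np.array(res_ids)
    arr.res_name = np.array(res_names)
    arr.chain_id = np.full(len(names), "A")
    arr.element = np.array([_element(n) for n in names])
    arr.hetero = np.zeros(len(names), dtype=bool)
    return arr


def write_pdb(
    structure: Union[BackboneChain, ConformationalEnsemble],
    path: Union[str, Path],
    sidecar: Optional[Union[str, Path]] = None,
) -> None:
    """Write a chain (single model) or ensemble (multi-model) PDB file.

    ``sidecar`` optionally names a TSV file receiving per-residue chirality
    flags (index, code, chirality).
    """
    if isinstance(structure, BackboneChain):
        chain0 = structure
        array = _chain_to_atom_array(structure)
    else:
        chain0 = structure.frames[0]
        arrays = [_chain_to_atom_array(f) for f in structure.frames]
        array = struc.stack(arrays)
    if not np.all(np.isfinite(array.coord)):
        raise ValueError("cannot write non-finite coordinates")
    pdb = PDBFile()
    pdb.set_structure(array)
    pdb.write(str(path))
    if sidecar is not None:
        lines = ["index\tcode\tchirality"]
        for res in chain0.residues:
            lines.append(f"{res.index}\t{res.code}\t{res.chirality or '-'}")
        Path(sidecar).write_text("\n".join(lines) + "\n")


def _validate_atom_records(path: Path) -> None:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise PDBFormatError(
                    f"{path}:{lineno}: truncated ATOM record ({len(line)} columns)"
                )
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise PDBFormatError(
                    f"{path}:{lineno}: unparsable coordinate field"
                ) from None


def _array_to_chain(arr: struc.AtomArray, chirality: Optional[dict],
                    cyclic: bool) -> BackboneChain:
    residues = []
    res_ids = np.unique(arr.res_id)
    for new_index, rid in enumerate(sorted(res_ids), start=1):
        mask = arr.res_id == rid
        res_name = str(arr.res_name[mask][0])
        if res_name in THREE_TO_ONE:
            code, chir = THREE_TO_ONE[res_name], "L"
        elif res_name in D_THREE:
            code, chir = D_THREE[res_name], "D"
        else:
            raise PDBFormatError(f"unsupported residue name {res_name!r}")
        if code == "G":
            chir = None
        if chirality and int(rid) in chirality:
            chir = chirality[int(rid)]
        atoms = {
            str(name): coord.astype(float)
            for name, coord in zip(arr.atom_name[mask], arr.coord[mask])
        }
        residues.append(ResidueUnit(index=new_index, code=code,
                                    chirality=chir, atoms=atoms))
    for res in residues:
        missing = {"N", "CA", "C"} - set(res.atoms)
        if missing:
            raise PDBFormatError(
                f"residue {res.index}: missing backbone atoms {sorted(missing)}"
            )
    return BackboneChain(residues=residues, cyclic=cyclic)


def read_pdb(
    path: Union[str, Path],
    sidecar: Optional[Union[str, Path]] = None,
    cyclic: bool = False,
) -> Union[BackboneChain, ConformationalEnsemble]:
    """Read a PDB file; multi-model files yield a ConformationalEnsemble.

    Chirality is restored from the sidecar table when given (or found next
    to the file as ``<name>.chirality.tsv``), else from D-residue names;
    otherwise residues default to L.
    """
    path = Path(path)
    _validate_atom_records(path)
    chirality = None
    sidecar = sidecar or (path.with_suffix(path.suffix + ".chirality.tsv")
                          if path.with_suffix(path.suffix + ".chirality.tsv").exists()
                          else None)
    if sidecar is not None:
        chirality = {}
        for line in Path(sidecar).read_text().splitlines()[1:]:
            idx, _code, chir = line.split("\t")
            chirality[int(idx)] = None if chir == "-" else chir
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    chains = [_array_to_chain(stack[m], chirality, cyclic)
              for m in range(stack.stack_depth())]
    seqs = {c.sequence for c in chains}
    if len(seqs) > 1:
        raise PDBFormatError("models disagree on sequence/topology")
    if len(chains) == 1:
        return chains[0]
    return ConformationalEnsemble(frames=chains)
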