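"""Readers and writers for structures, rank tables, surface areas and annotations.

File dialects
-------------
* structures: PDB format; only Cα ATOM records are consumed, and SEQRES (when
  present) supplies the full sequence length for the truncation-ratio filter.
* ranks: whitespace-separated ``seq_number aa rank`` lines, ``#`` comments.
* accessibility: whitespace-separated ``seq_number area`` lines, ``#`` comments.
* annotations: TSV ``chain_id<TAB>EC[,EC...]`` (second column may be empty).
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .model import (
    AnnotationTable,
    ETRanking,
    ProteinChain,
    SurfaceAnnotation,
    validate_ec,
)

logger = logging.getLogger(__name__)

_ONE_TO_THREE = {one: three for three, one in protein_letters_3to1.items()}
_ONE_TO_THREE["X"] = "UNK"


def _three_to_one(resname: str) -> str:
    return protein_letters_3to1.get(resname.strip().upper(), "X")


def read_pdb_chain(path: str | Path, chain: str) -> ProteinChain:
    """Read one chain's Cα trace from a PDB file.

    Altloc ambiguity is resolved to the highest-occupancy conformer (ties to
    the first by altloc id); insertion-coded residues are skipped with a
    warning. Residues without a CA atom are ignored.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    model = next(structure.get_models())
    available = [c.id for c in model]
    if chain not in [c.id for c in model]:
        raise ValueError(
            f"chain {chain!r} not found in {path.name}; available chains: {available}"
        )
    seq_numbers: list[int] = []
    aas: list[str] = []
    coords: list[np.ndarray] = []
    for residue in model[chain]:
        hetflag, resseq, icode = residue.id
        if hetflag.strip():
            continue
        if icode.strip():
            logger.warning(
                "%s chain %s: skipping insertion-coded residue %s%s",
                path.name, chain, resseq, icode,
            )
            continue
        if "CA" not in residue:
            continue
        atom = residue["CA"]
        if atom.is_disordered():
            children = sorted(
                atom.disordered_get_list(),
                key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
            )
            atom = children[0]
        seq_numbers.append(resseq)
        aas.append(_three_to_one(residue.get_resname()))
        # parser stores float32; re-round to the file's 3-decimal precision
        coords.append(np.round(atom.get_coord().astype(float), 3))
    if not coords:
        raise ValueError(f"{path.name} chain {chain}: no CA atoms found")
    full_length = _read_seqres_length(path, chain)
    return ProteinChain(
        id=f"{path.stem}{chain}" if not path.stem.endswith(chain) else path.stem,
        seq_numbers=np.array(seq_numbers),
        aas=tuple(aas),
        coords=np.array(coords),
        full_sequence_length=full_length,
    )


def _read_seqres_length(path: Path, chain: str) -> int | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("SEQRES") and len(line) > 13 and line[11] == chain:
                try:
                    return int(line[13:17])
                except ValueError:  # malformed SEQRES; treat as absent
                    return None
    return None


def write_ca_pdb(chain: ProteinChain, path: str | Path) -> None:
    """Write a Cα-only PDB file (with SEQRES carrying the full length)."""
    path = Path(path)
    chain_letter = chain.id[-1] if chain.id else "A"
    lines: list[str] = []
    full = chain.full_sequence_length
    if full is not None:
        resnames = [_ONE_TO_THREE.get(a, "UNK") for a in chain.aas]
        resnames += ["UNK"] * (full - len(resnames))
        for i in range(0, len(resnames), 13):
            block = resnames[i : i + 13]
            lines.append(
                f"SEQRES {i // 13 + 1:3d} {chain_letter} {full:4d}  "
                + " ".join(f"{r:>3s}" for r in block)
            )
    for serial, (seq, aa, xyz) in enumerate(
        zip(chain.seq_numbers, chain.aas, chain.coords), start=1
    ):
        resname = _ONE_TO_THREE.get(aa, "UNK")
        lines.append(
            f"ATOM  {serial:5d}  CA  {resname:>3s} {chain_letter}{int(seq):4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"           C"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_et_ranks(path: str | Path, chain_id: str | None = None) -> ETRanking:
    """Read a rank table; percentiles are derived as rank coverage."""
    path = Path(path)
    rank: dict[int, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path.name}:{lineno}: expected 'seq aa rank'")
            try:
                seq = int(fields[0])
                value = float(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: non-numeric field") from exc
            if seq in rank:
                raise ValueError(f"{path.name}:{lineno}: duplicate residue {seq}")
            rank[seq] = value
    return ETRanking.from_ranks(chain_id or path.stem.split(".")[0], rank)


def write_et_ranks(ranking: ETRanking, chain: ProteinChain, path: str | Path) -> None:
    lines = ["# seq aa rank"]
    for seq in sorted(ranking.rank):
        aa = chain.aa_of(seq) if seq in chain else "X"
        lines.append(f"{seq}\t{aa}\t{ranking.rank[seq]:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_accessibility(path: str | Path, chain_id: str | None = None) -> SurfaceAnnotation:
    path = Path(path)
    area: dict[int, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                seq, value = int(fields[0]), float(fields[1])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path.name}:{lineno}: expected 'seq area'") from exc
            if value < 0:
                raise ValueError(f"{path.name}:{lineno}: negative area {value}")
            area[seq] = value
    return SurfaceAnnotation(chain_id or path.stem.split(".")[0], area)


def write_accessibility(surface: SurfaceAnnotation, path: str | Path) -> None:
    lines = ["# seq area"]
    for seq in sorted(surface.area):
        lines.append(f"{seq}\t{surface.area[seq]:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def approximate_accessibility(
    chain: ProteinChain, radius: float = 10.0, quantile: float = 0.6
) -> SurfaceAnnotation:
    """Coarse, non-DSSP surface proxy from Cα neighbor counts.

    A residue is flagged exposed when its count of Cα neighbors within
    ``radius`` lies in the lowest ``quantile`` fraction of neighbor counts;
    exposed residues get a pseudo-area of 3 A^2 (satisfying the > 2 A^2
    convention), buried residues 0. Only used when no DSSP-style table is
    available.
    """
    if len(chain) < 2:
        raise ValueError("accessibility approximation needs at least 2 residues")
    diff = chain.coords[:, None, :] - chain.coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    counts = (dist <= radius).sum(axis=1) - 1
    threshold = np.quantile(counts, quantile)
    area = {
        int(seq): 3.0 if counts[i] <= threshold else 0.0
        for i, seq in enumerate(chain.seq_numbers)
    }
    return SurfaceAnnotation(chain.id, area)


def truncation_ratio(chain: ProteinChain) -> float:
    """Resolved residue count over full sequence length, in [0, 1].

    Callers filter target structures at a ratio *strictly greater* than 0.95.
    """
    if chain.full_sequence_length is None:
        raise ValueError(f"{chain.id}: full sequence length unknown")
    return len(chain) / chain.full_sequence_length


def read_annotations(path: str | Path) -> AnnotationTable:
    table = AnnotationTable()
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            cid = parts[0].strip()
            ecs = [e.strip() for e in parts[1].split(",")] if len(parts) > 1 else []
            table[cid] = frozenset(validate_ec(e) for e in ecs if e)
    return table


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    lines = [f"{cid}\t{','.join(sorted(table[cid]))}" for cid in sorted(table)]
    Path(path).write_text("\n".join(lines) + "\n")
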