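"""Core domain types shared across the annotation pipeline.

Residues are identified by their author sequence number (PDB numbering)
within a chain; every cross-reference between structures, rank tables and
surface-area tables uses that number, never a 0-based index.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Residues with DSSP accessible area above this value (in squared angstrom,
#: strictly greater) are considered solvent exposed.
SURFACE_AREA_THRESHOLD = 2.0


def is_full_ec(ec: str) -> bool:
    """True for a complete four-field numeric EC string, e.g. ``"4.1.1.33"``."""
    parts = ec.split(".")
    return len(parts) == 4 and all(p.isdigit() for p in parts)


def validate_ec(ec: str) -> str:
    parts = ec.split(".")
    if len(parts) != 4 or any(not p for p in parts):
        raise ValueError(f"EC number must have four dot-separated fields: {ec!r}")
    return ec


@dataclass(eq=False)
class ProteinChain:
    """A single protein chain reduced to its Cα trace.

    Parameters
    ----------
    id:
        PDB code plus chain letter, e.g. ``"3f0nA"``.
    seq_numbers:
        Author residue numbers, strictly increasing.
    aas:
        One-letter residue types ('X' for nonstandard residues).
    coords:
        ``(n, 3)`` Cα coordinates in angstrom.
    full_sequence_length:
        Length of the full (possibly partially unresolved) sequence; used by
        the truncation-ratio completeness filter. ``None`` if unknown.
    """

    id: str
    seq_numbers: np.ndarray
    aas: tuple[str, ...]
    coords: np.ndarray
    full_sequence_length: int | None = None

    def __post_init__(self) -> None:
        self.seq_numbers = np.asarray(self.seq_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.aas = tuple(self.aas)
        n = len(self.seq_numbers)
        if len(self.aas) != n or self.coords.shape != (n, 3):
            raise ValueError(
                f"{self.id}: inconsistent residue arrays "
                f"({n} numbers, {len(self.aas)} types, coords {self.coords.shape})"
            )
        if n == 0:
            raise ValueError(f"{self.id}: chain has no residues")
        if np.any(np.diff(self.seq_numbers) <= 0):
            raise ValueError(f"{self.id}: residue numbers must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.id}: non-finite coordinates")
        bad = set(self.aas) - AA_ALPHABET - {"X"}
        if bad:
            raise ValueError(f"{self.id}: unknown residue types {sorted(bad)}")
        if self.full_sequence_length is not None and self.full_sequence_length < n:
            raise ValueError(
                f"{self.id}: full sequence length {self.full_sequence_length} "
                f"smaller than resolved residue count {n}"
            )
        self._index = {int(s): i for i, s in enumerate(self.seq_numbers)}

    def __len__(self) -> int:
        return len(self.seq_numbers)

    def __contains__(self, seq_number: int) -> bool:
        return int(seq_number) in self._index

    @property
    def sequence(self) -> str:
        return "".join(self.aas)

    def index_of(self, seq_number: int) -> int:
        return self._index[int(seq_number)]

    def ca(self, seq_number: int) -> np.ndarray:
        return self.coords[self._index[int(seq_number)]]

    def aa_of(self, seq_number: int) -> str:
        return self.aas[self._index[int(seq_number)]]

    def coords_of(self, seq_numbers: Iterable[int]) -> np.ndarray:
        return np.array([self.ca(s) for s in seq_numbers])


@dataclass(eq=False)
class ETRanking:
    """Per-residue evolutionary-importance ranks (lower = more important).

    ``percentile`` is the right-continuous rank coverage
    ``pct(i) = #{j : rank(j) <= rank(i)} / N`` in (0, 1]; tied ranks share the
    maximal coverage value. It is invariant under strictly monotone transforms
    of the raw ranks.
    """

    chain_id: str
    rank: dict[int, float]
    percentile: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rank = {int(k): float(v) for k, v in self.rank.items()}
        for k, v in self.rank.items():
            if not np.isfinite(v):
                raise ValueError(f"{self.chain_id}: non-finite rank at residue {k}")
        if not self.percentile:
            self.percentile = self._percentiles(self.rank)

    @staticmethod
    def _percentiles(rank: Mapping[int, float]) -> dict[int, float]:
        if not rank:
            return {}
        vals = np.sort(np.array(list(rank.values()), dtype=float))
        n = len(vals)
        return {
            k: float(np.searchsorted(vals, v, side="right")) / n
            for k, v in rank.items()
        }

    @classmethod
    def from_ranks(cls, chain_id: str, rank: Mapping[int, float]) -> "ETRanking":
        return cls(chain_id=chain_id, rank=dict(rank))


@dataclass(eq=False)
class SurfaceAnnotation:
    """Solvent accessible surface areas (squared angstrom) per residue."""

    chain_id: str
    area: dict[int, float]

    def __post_init__(self) -> None:
        self.area = {int(k): float(v) for k, v in self.area.items()}
        for k, v in self.area.items():
            if v < 0:
                raise ValueError(f"{self.chain_id}: negative area at residue {k}")

    @property
    def is_surface(self) -> dict[int, bool]:
        return {k: v > SURFACE_AREA_THRESHOLD for k, v in self.area.items()}

    def surface(self, seq_number: int) -> bool:
        """Whether the residue is solvent exposed (area strictly > 2 A^2).

        Residues absent from the table count as buried.
        """
        return self.area.get(int(seq_number), 0.0) > SURFACE_AREA_THRESHOLD


class AnnotationTable(dict):
    """Mapping chain_id -> frozenset of EC strings (may be empty)."""

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, Iterable[str]]]) -> "AnnotationTable":
        table = cls()
        for cid, ecs in pairs:
            table[cid] = frozenset(validate_ec(e) for e in ecs)
        return table

    def full_ec(self, chain_id: str) -> frozenset[str]:
        """The chain's complete four-field EC annotations (possibly empty)."""
        return frozenset(e for e in self.get(chain_id, ()) if is_full_ec(e))


@dataclass(eq=False)
class ProteinRecord:
    """A chain bundled with its rank and surface tables; the pipeline unit."""

    chain: ProteinChain
    ranks: ETRanking
    surface: SurfaceAnnotation

    @property
    def id(self) -> str:
        return self.chain.id


@dataclass(eq=False)
class Template:
    """An ordered probe of 5 or 6 putative functional residues.

    ``allowed_types[k]`` is the set of residue types acceptable at position k
    when the template is searched in another structure (the native type plus
    alignment-supported variants).
    """

    source_chain: str
    positions: tuple[int, ...]
    coords: np.ndarray
    allowed_types: tuple[frozenset[str], ...]
    mode_tag: str = "6R"
    source_cluster: object = None

    def __post_init__(self) -> None:
        self.positions = tuple(int(p) for p in self.positions)
        self.coords = np.asarray(self.coords, dtype=float)
        self.allowed_types = tuple(frozenset(t) for t in self.allowed_types)
        k = len(self.positions)
        if k not in (5, 6):
            raise ValueError(f"template must have 5 or 6 positions, got {k}")
        if len(set(self.positions)) != k:
            raise ValueError("template positions must be distinct")
        if self.coords.shape != (k, 3):
            raise ValueError(f"template coords shape {self.coords.shape} != ({k}, 3)")
        if len(self.allowed_types) != k or any(not t for t in self.allowed_types):
            raise ValueError("each template position needs a non-empty allowed-type set")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(eq=False)
class TemplateMatch:
    """A residue correspondence between a template and a target chain.

    ``rank_diffs`` are absolute percentile-rank differences per position and
    ``et_score`` is their sum (the total evolutionary dissimilarity of the
    matched sites). Both, like ``rmsd``, are filled by scoring after the
    geometric search.
    """

    query_chain: str
    target_chain: str
    template_positions: tuple[int, ...]
    matched_positions: tuple[int, ...]
    mode_tag: str = "6R"
    rmsd: float | None = None
    rank_diffs: tuple[float, ...] | None = None
    et_score: float | None = None
    direction: str = "query->target"
    significant: bool | None = None

    def __post_init__(self) -> None:
        self.template_positions = tuple(int(p) for p in self.template_positions)
        self.matched_positions = tuple(int(p) for p in self.matched_positions)
        if len(self.template_positions) != len(self.matched_positions):
            raise ValueError("template and matched position lists differ in length")

    def __len__(self) -> int:
        return len(self.template_positions)

    @property
    def is_self_match(self) -> bool:
        return self.query_chain == self.target_chain
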