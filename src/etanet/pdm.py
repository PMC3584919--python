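"""Paired-distance matching of templates into target chains, and RMSD scoring.

The search places template residues one at a time onto type-compatible target
residues, requiring every pairwise Cα distance of the partial placement to
agree with the corresponding template distance within a tolerance (default
2.5 Å). A target residue may fill only one template position per assignment.
Match quality is quantified by least-squares RMSD after optimal rigid
superposition (rotation + translation, no reflection).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .model import ETRanking, ProteinChain, Template, TemplateMatch

DEFAULT_TOLERANCE = 2.5
DEFAULT_NODE_CAP = 100_000


@dataclass(eq=False)
class SearchResult:
    """All complete assignments found, plus enumeration bookkeeping.

    ``partial`` is True when the node cap aborted the enumeration early, in
    which case ``matches`` is a (deterministic) prefix of the full set.
    """

    matches: list[TemplateMatch] = field(default_factory=list)
    partial: bool = False
    nodes: int = 0

    def __iter__(self):
        return iter(self.matches)

    def __len__(self) -> int:
        return len(self.matches)


def pdm_search(
    template: Template,
    target: ProteinChain,
    tol: float = DEFAULT_TOLERANCE,
    cap: int = DEFAULT_NODE_CAP,
) -> SearchResult:
    """Depth-first paired-distance search of ``template`` in ``target``.

    Candidates for position k must have an allowed residue type, be unused in
    the current assignment, and satisfy the all-pairs distance constraint
    against every previously placed position. RMSD is left unset on the
    returned matches; use :func:`score_match`.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    k = len(template)
    if k == 0:
        raise ValueError("empty template")
    candidates = [
        [i for i, aa in enumerate(target.aas) if aa in template.allowed_types[p]]
        for p in range(k)
    ]
    tdist = squareform(pdist(template.coords))
    coords = target.coords
    result = SearchResult()
    chosen: list[int] = []
    used: set[int] = set()

    def dfs(pos: int) -> None:
        if pos == k:
            result.matches.append(
                TemplateMatch(
                    query_chain=template.source_chain,
                    target_chain=target.id,
                    template_positions=template.positions,
                    matched_positions=tuple(
                        int(target.seq_numbers[i]) for i in chosen
                    ),
                    mode_tag=template.mode_tag,
                    direction=f"{template.source_chain}->{target.id}",
                )
            )
            return
        for i in candidates[pos]:
            if result.partial:
                return
            if i in used:
                continue
            result.nodes += 1
            if result.nodes > cap:
                result.partial = True
                return
            if chosen:
                d = np.linalg.norm(coords[i] - coords[chosen], axis=1)
                if np.any(np.abs(d - tdist[pos, : len(chosen)]) > tol):
                    continue
            chosen.append(i)
            used.add(i)
            dfs(pos + 1)
            used.discard(chosen.pop())

    dfs(0)
    return result


def match_rmsd(template_coords: np.ndarray, matched_coords: np.ndarray) -> float:
    """Least-squares RMSD after optimal rigid superposition (Kabsch).

    Reflections are excluded; degenerate (e.g. collinear) point sets still
    return a value.
    """
    a = np.asarray(template_coords, dtype=float)
    b = np.asarray(matched_coords, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate sets must share shape (n, 3); got {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition RMSD")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    cov = a0.T @ b0
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    # applying the optimal rotation explicitly avoids the cancellation error
    # of the E0 - 2*trace closed form for near-congruent sets
    return float(np.sqrt(((a0 @ rot - b0) ** 2).sum() / n))


def score_match(
    match: TemplateMatch,
    template: Template,
    target: ProteinChain,
    query_ranks: ETRanking,
    target_ranks: ETRanking,
) -> TemplateMatch:
    """Fill rmsd, per-position percentile-rank differences and the ETScore.

    The ETScore is the sum over positions of the absolute difference between
    the query and target residues' percentile ranks.
    """
    matched_coords = target.coords_of(match.matched_positions)
    match.rmsd = match_rmsd(template.coords, matched_coords)
    diffs = []
    for qpos, tpos in zip(match.template_positions, match.matched_positions):
        try:
            qp = query_ranks.percentile[qpos]
            tp = target_ranks.percentile[tpos]
        except KeyError as exc:
            raise ValueError(f"missing percentile rank for residue {exc}") from exc
        diffs.append(abs(qp - tp))
    match.rank_diffs = tuple(diffs)
    match.et_score = float(sum(diffs))
    return match
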