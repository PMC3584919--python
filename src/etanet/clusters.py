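"""Ranked surface-residue clusters and functional-site template selection.

The template picker mirrors classic evolutionary-trace practice: the most
important residues of a protein aggregate into spatial clusters on the
surface; the first cluster to collect at least 11 exposed residues (as rank
coverage is swept upward) nominates the putative functional site, and a 5- or
6-residue template is grown greedily from it — best-ranked residue nearest the
cluster center first, then, at each step, the best-ranked remaining member
nearest the midpoint between the selected residues' center of mass and the
cluster's.

Clustering uses single linkage on Cα–Cα distance (default cutoff 8 Å, a Cα
proxy for heavy-atom contact).
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .model import ETRanking, ProteinChain, SurfaceAnnotation, Template

logger = logging.getLogger(__name__)

DEFAULT_LINK_CUTOFF = 8.0
MIN_PRIMARY_SURFACE = 11
COVERAGE_STEP = 0.01


class NoTemplateError(ValueError):
    """Raised when no cluster ever qualifies; the protein yields no templates."""


@dataclass(eq=False)
class ResidueCluster:
    members: frozenset[int]
    formation_threshold: float
    best_rank: float
    cm: np.ndarray

    def surface_members(self, surface: SurfaceAnnotation) -> frozenset[int]:
        return frozenset(m for m in self.members if surface.surface(m))


def _ranked_seqs(chain: ProteinChain, ranks: ETRanking) -> list[int]:
    return sorted(s for s in ranks.rank if s in chain)


def _clusters_from(
    chain: ProteinChain,
    ranks: ETRanking,
    surface: SurfaceAnnotation,
    seqs: list[int],
    dist: np.ndarray,
    important: np.ndarray,
    coverage: float,
    link_cutoff: float,
) -> list[ResidueCluster]:
    idx = np.flatnonzero(important)
    if idx.size == 0:
        return []
    sub = dist[np.ix_(idx, idx)] <= link_cutoff
    _, labels = connected_components(csr_matrix(sub), directed=False)
    clusters = []
    for comp in np.unique(labels):
        comp_idx = idx[labels == comp]
        members = frozenset(int(seqs[i]) for i in comp_idx)
        surf = [m for m in members if surface.surface(m)]
        pool = surf if surf else sorted(members)
        best = min(ranks.rank[m] for m in pool)
        cm = np.mean([chain.ca(s) for s in sorted(members)], axis=0)
        clusters.append(
            ResidueCluster(
                members=members,
                formation_threshold=coverage,
                best_rank=float(best),
                cm=cm,
            )
        )
    clusters.sort(key=lambda c: (c.best_rank, min(c.members)))
    return clusters


def identify_clusters(
    chain: ProteinChain,
    ranks: ETRanking,
    surface: SurfaceAnnotation,
    coverage: float,
    link_cutoff: float = DEFAULT_LINK_CUTOFF,
) -> list[ResidueCluster]:
    """Single-linkage components of the top-``coverage`` ranked residues.

    A residue is "important" when its percentile rank is at most ``coverage``;
    membership therefore grows monotonically with coverage. Clusters are
    sorted most-important-first (ascending best rank).
    """
    if link_cutoff <= 0:
        raise ValueError("link_cutoff must be positive")
    seqs = _ranked_seqs(chain, ranks)
    if not seqs:
        return []
    coords = np.array([chain.ca(s) for s in seqs])
    dist = squareform(pdist(coords)) if len(seqs) > 1 else np.zeros((1, 1))
    important = np.array(
        [ranks.percentile[s] <= coverage + 1e-9 for s in seqs], dtype=bool
    )
    return _clusters_from(chain, ranks, surface, seqs, dist, important, coverage, link_cutoff)


def _sweep(
    chain: ProteinChain,
    ranks: ETRanking,
    surface: SurfaceAnnotation,
    link_cutoff: float,
    step: float,
    start: float = 0.0,
):
    """Yield (coverage, clusters) at increasing coverage, sharing distances."""
    seqs = _ranked_seqs(chain, ranks)
    if not seqs:
        return
    coords = np.array([chain.ca(s) for s in seqs])
    dist = squareform(pdist(coords)) if len(seqs) > 1 else np.zeros((1, 1))
    pct = np.array([ranks.percentile[s] for s in seqs])
    n_steps = int(round(1.0 / step))
    for k in range(1, n_steps + 1):
        coverage = k * step
        if coverage < start - 1e-9:
            continue
        important = pct <= coverage + 1e-9
        yield coverage, _clusters_from(
            chain, ranks, surface, seqs, dist, important, coverage, link_cutoff
        )


def select_primary_cluster(
    chain: ProteinChain,
    ranks: ETRanking,
    surface: SurfaceAnnotation,
    link_cutoff: float = DEFAULT_LINK_CUTOFF,
    min_surface: int = MIN_PRIMARY_SURFACE,
    step: float = COVERAGE_STEP,
) -> ResidueCluster:
    """First cluster to reach ``min_surface`` exposed residues in the sweep.

    Coverage is swept upward in ``step`` increments; at the smallest
    qualifying coverage, ties between simultaneously qualifying clusters are
    broken by best rank, then smallest residue number.
    """
    for coverage, clusters in _sweep(chain, ranks, surface, link_cutoff, step):
        qualifying = [
            c for c in clusters if len(c.surface_members(surface)) >= min_surface
        ]
        if qualifying:
            return min(qualifying, key=lambda c: (c.best_rank, min(c.members)))
    raise NoTemplateError(
        f"{chain.id}: no cluster reaches {min_surface} surface residues at full coverage"
    )


def select_additional_clusters(
    chain: ProteinChain,
    ranks: ETRanking,
    surface: SurfaceAnnotation,
    primary: ResidueCluster,
    link_cutoff: float = DEFAULT_LINK_CUTOFF,
    min_surface: int = 5,
    comparator: str = "median",
    step: float = COVERAGE_STEP,
) -> list[ResidueCluster]:
    """Distinct clusters holding better-ranked surface residues than the primary.

    A cluster qualifies when it (a) shares no member with the primary cluster
    (or any already-accepted additional cluster), (b) contains at least one
    exposed residue whose rank beats the ``comparator`` statistic (best,
    median, or worst) of the primary cluster's exposed ranks, and (c) has at
    least ``min_surface`` exposed residues to support a template. The sweep
    continues from the primary's formation coverage so late-forming secondary
    sites are still found.
    """
    psr = [ranks.rank[m] for m in primary.surface_members(surface)]
    if not psr:
        psr = [ranks.rank[m] for m in primary.members]
    reference = {
        "best": min(psr),
        "median": float(np.median(psr)),
        "worst": max(psr),
    }[comparator]
    taken: list[frozenset[int]] = [primary.members]
    found: list[ResidueCluster] = []
    for _, clusters in _sweep(
        chain, ranks, surface, link_cutoff, step, start=primary.formation_threshold
    ):
        for cl in clusters:
            if any(cl.members & t for t in taken):
                continue
            surf = cl.surface_members(surface)
            if len(surf) < min_surface:
                continue
            if not any(ranks.rank[m] < reference for m in surf - primary.members):
                continue
            taken.append(cl.members)
            found.append(cl)
    found.sort(key=lambda c: (c.best_rank, min(c.members)))
    return found


def pick_template(
    cluster: ResidueCluster,
    chain: ProteinChain,
    ranks: ETRanking,
    size: int,
) -> Template:
    """Greedy template from a cluster.

    Residue 1 is the best-ranked member nearest the cluster center of mass;
    each later residue is, among unselected members in the best remaining
    rank band (exact rank ties), the one nearest the midpoint between the
    selected residues' center of mass and the cluster's. All ties break to
    the smallest residue number, so the pick is deterministic and the
    5-residue template is a prefix of the 6-residue one.
    """
    if size not in (5, 6):
        raise ValueError("template size must be 5 or 6")
    members = sorted(cluster.members)
    if len(members) < size:
        raise ValueError(
            f"cluster of {len(members)} members cannot yield a {size}-residue template"
        )
    remaining = list(members)
    selected: list[int] = []
    while len(selected) < size:
        if selected:
            sel_cm = np.mean([chain.ca(s) for s in selected], axis=0)
            anchor = 0.5 * (sel_cm + cluster.cm)
        else:
            anchor = cluster.cm
        best_rank = min(ranks.rank[m] for m in remaining)
        band = [m for m in remaining if ranks.rank[m] == best_rank]
        choice = min(
            band, key=lambda m: (float(np.linalg.norm(chain.ca(m) - anchor)), m)
        )
        selected.append(choice)
        remaining.remove(choice)
    return Template(
        source_chain=chain.id,
        positions=tuple(selected),
        coords=chain.coords_of(selected),
        allowed_types=tuple(frozenset({chain.aa_of(s)}) for s in selected),
        source_cluster=cluster,
    )


def template_type_variants(template: Template, chain: ProteinChain, msa) -> Template:
    """Fill allowed residue types from a multiple sequence alignment.

    Row 0 of the alignment must be the template's source chain (its ungapped
    sequence equal to the chain sequence). For each template position, the
    allowed set is the native type plus any type appearing there in a row
    pattern that is non-gapped across all template columns and occurs at
    least twice in the alignment.
    """
    rows = [str(getattr(rec, "seq", rec[1] if isinstance(rec, tuple) else rec)) for rec in msa]
    if not rows:
        raise ValueError("empty alignment")
    ungapped0 = rows[0].replace("-", "")
    if ungapped0 != chain.sequence:
        raise ValueError(
            "alignment row 0 must be the template's source chain sequence"
        )
    # chain residue order index -> alignment column
    col_of_index: dict[int, int] = {}
    k = 0
    for col, ch in enumerate(rows[0]):
        if ch != "-":
            col_of_index[k] = col
            k += 1
    try:
        cols = [col_of_index[chain.index_of(p)] for p in template.positions]
    except KeyError as exc:
        raise ValueError(f"template position not mappable to alignment: {exc}") from exc
    patterns = Counter(tuple(row[c] for c in cols) for row in rows)
    allowed = [set(t) for t in template.allowed_types]
    for pattern, count in patterns.items():
        if "-" in pattern or count < 2:
            continue
        for i, ch in enumerate(pattern):
            allowed[i].add(ch)
    return Template(
        source_chain=template.source_chain,
        positions=template.positions,
        coords=template.coords,
        allowed_types=tuple(frozenset(a) for a in allowed),
        mode_tag=template.mode_tag,
        source_cluster=template.source_cluster,
    )


MODES = ("6R", "5R", "M6R", "M5R")


def make_templates(
    chain: ProteinChain,
    ranks: ETRanking,
    surface: SurfaceAnnotation,
    mode: str,
    msa=None,
    link_cutoff: float = DEFAULT_LINK_CUTOFF,
    min_primary_surface: int = MIN_PRIMARY_SURFACE,
    comparator: str = "median",
    step: float = COVERAGE_STEP,
) -> list[Template]:
    """Templates for one protein under a selection mode.

    6R/5R give one template from the primary cluster; M6R/M5R add one template
    per qualifying additional cluster (degenerating to the single-template
    case when none exists). An empty list means the protein yields no
    prediction (no qualifying cluster).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    size = 6 if mode in ("6R", "M6R") else 5
    try:
        primary = select_primary_cluster(
            chain, ranks, surface, link_cutoff, min_primary_surface, step
        )
    except NoTemplateError:
        logger.info("%s: no qualifying cluster, no templates", chain.id)
        return []
    clusters = [primary]
    if mode.startswith("M"):
        clusters += select_additional_clusters(
            chain, ranks, surface, primary, link_cutoff,
            min_surface=size, comparator=comparator, step=step,
        )
    templates = []
    for cluster in clusters:
        if len(cluster.members) < size:
            logger.info("%s: skipping undersized cluster (%d members)",
                        chain.id, len(cluster.members))
            continue
        tpl = pick_template(cluster, chain, ranks, size)
        if msa is not None:
            tpl = template_type_variants(tpl, chain, msa)
        tpl.mode_tag = mode
        templates.append(tpl)
    return templates
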