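"""Function prediction: plurality vote over reciprocal partners, the four
template-selection modes, their iterative combination, and a sequence-identity
baseline.

A query's prediction is the EC number held by a plurality of its *unique*
reciprocal partners: a partner contributes one vote to each of its full EC
annotations no matter how many templates matched it. Ties at the top, or the
absence of reciprocal partners, yield no prediction. The iterative strategy
runs the modes in decreasing order of accuracy (default 6R, 5R, M6R, M5R) and
takes the first mode that produces a label for each query.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .clusters import make_templates
from .filtering import classify, featurize, prefilter, reciprocal_matches
from .model import AnnotationTable, ProteinRecord
from .pdm import DEFAULT_NODE_CAP, DEFAULT_TOLERANCE, pdm_search, score_match

MODE_ORDER = ("6R", "5R", "M6R", "M5R")


@dataclass(eq=False)
class Prediction:
    query: str
    label: str | None
    votes: int
    runner_up_votes: int
    mode_tag: str
    partners: tuple[str, ...] = ()


class MatchEngine:
    """Caches templates and significant matches for a protein set and mode."""

    def __init__(
        self,
        proteins: Mapping[str, ProteinRecord],
        model,
        mode: str,
        tol: float = DEFAULT_TOLERANCE,
        cap: int = DEFAULT_NODE_CAP,
        msas: Mapping[str, object] | None = None,
        site_level: bool = False,
        **template_kwargs,
    ) -> None:
        self.proteins = dict(proteins)
        self.model = model
        self.mode = mode
        self.tol = tol
        self.cap = cap
        self.msas = dict(msas or {})
        self.site_level = site_level
        self.template_kwargs = template_kwargs
        self._templates: dict[str, list] = {}
        self._significant: dict[tuple[str, str], list] = {}

    def templates(self, pid: str) -> list:
        if pid not in self._templates:
            rec = self.proteins[pid]
            self._templates[pid] = make_templates(
                rec.chain,
                rec.ranks,
                rec.surface,
                self.mode,
                msa=self.msas.get(pid),
                **self.template_kwargs,
            )
        return self._templates[pid]

    def significant_matches(self, src: str, dst: str) -> list:
        """Significant matches of src's templates in dst (one best per template)."""
        key = (src, dst)
        if key in self._significant:
            return self._significant[key]
        src_rec, dst_rec = self.proteins[src], self.proteins[dst]
        out = []
        for tpl in self.templates(src):
            result = pdm_search(tpl, dst_rec.chain, tol=self.tol, cap=self.cap)
            scored = [
                score_match(m, tpl, dst_rec.chain, src_rec.ranks, dst_rec.ranks)
                for m in result.matches
            ]
            survivors = []
            for m in prefilter(scored):
                m.significant = classify(self.model, featurize(m))
                if m.significant:
                    survivors.append(m)
            if survivors:
                # one assignment per (template, target): keep the lowest RMSD
                out.append(min(survivors, key=lambda m: m.rmsd))
        self._significant[key] = out
        return out

    def reciprocal_pairs(self, a: str, b: str):
        return reciprocal_matches(
            self.significant_matches(a, b),
            self.significant_matches(b, a),
            site_level=self.site_level,
        )


def plurality_vote(
    query: str,
    reciprocal_partners: Iterable[tuple[str, Iterable[str]]],
    mode_tag: str = "6R",
) -> Prediction:
    """Vote over unique reciprocal partners' full EC numbers.

    Each unique partner contributes one vote per EC it carries; the label with
    a strictly highest vote wins, a tie at the top abstains.
    """
    seen: dict[str, frozenset[str]] = {}
    for pid, ecs in reciprocal_partners:
        seen[pid] = seen.get(pid, frozenset()) | frozenset(ecs)
    votes: Counter[str] = Counter()
    for ecs in seen.values():
        for ec in ecs:
            votes[ec] += 1
    partners = tuple(sorted(seen))
    if not votes:
        return Prediction(query, None, 0, 0, mode_tag, partners)
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    top_label, top = ranked[0]
    runner_up = ranked[1][1] if len(ranked) > 1 else 0
    if runner_up == top:
        return Prediction(query, None, top, top, mode_tag, partners)
    return Prediction(query, top_label, top, runner_up, mode_tag, partners)


def run_mode(
    queries: Mapping[str, ProteinRecord],
    targets: Mapping[str, ProteinRecord],
    mode: str,
    model,
    annotations: AnnotationTable,
    engine: MatchEngine | None = None,
    **engine_kwargs,
) -> dict[str, Prediction]:
    """Full pipeline per query: templates -> search -> filter -> reciprocity -> vote.

    Only targets carrying at least one full four-field EC annotation can vote.
    Queries without templates yield an empty prediction.
    """
    proteins = {**dict(targets), **dict(queries)}
    if engine is None:
        engine = MatchEngine(proteins, model, mode, **engine_kwargs)
    predictions: dict[str, Prediction] = {}
    for q in sorted(queries):
        if not engine.templates(q):
            predictions[q] = Prediction(q, None, 0, 0, mode)
            continue
        partners: list[tuple[str, frozenset[str]]] = []
        for t in sorted(targets):
            if t == q:
                continue
            for pair in engine.reciprocal_pairs(q, t):
                other = pair.partner_of(q)
                ecs = annotations.full_ec(other) if isinstance(
                    annotations, AnnotationTable
                ) else frozenset(annotations.get(other, ()))
                if ecs:
                    partners.append((other, ecs))
        predictions[q] = plurality_vote(q, partners, mode_tag=mode)
    return predictions


def iterative_combine(
    per_mode: Mapping[str, Mapping[str, Prediction]],
    order: Sequence[str] = MODE_ORDER,
) -> dict[str, Prediction]:
    """Per query, the first mode in ``order`` with a label supplies the call."""
    queries = sorted({q for preds in per_mode.values() for q in preds})
    combined: dict[str, Prediction] = {}
    for q in queries:
        chosen = None
        for mode in order:
            pred = per_mode.get(mode, {}).get(q)
            if pred is not None and pred.label is not None:
                chosen = replace(pred, mode_tag="ALL")
                break
        combined[q] = chosen if chosen is not None else Prediction(q, None, 0, 0, "ALL")
    return combined


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def sequence_identity(seq1: str, seq2: str) -> float:
    """Identical aligned residues over aligned (non-gap-pair) positions."""
    aligner = _make_aligner()
    alignment = aligner.align(seq1, seq2)[0]
    a, b = str(alignment[0]), str(alignment[1])
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    return sum(x == y for x, y in pairs) / len(pairs)


def seqid_baseline(
    query: str,
    proteins: Mapping[str, ProteinRecord],
    target_ids: Sequence[str],
    annotations: AnnotationTable,
) -> Prediction:
    """Transfer the annotation of the highest-identity target (tie: smallest id)."""
    targets = [t for t in target_ids if t != query]
    if not targets:
        return Prediction(query, None, 0, 0, "SeqID")
    qseq = proteins[query].chain.sequence
    scored = sorted(
        ((sequence_identity(qseq, proteins[t].chain.sequence), t) for t in targets),
        key=lambda it: (-it[0], it[1]),
    )
    _, best = scored[0]
    ecs = annotations.full_ec(best) if isinstance(annotations, AnnotationTable) else (
        frozenset(annotations.get(best, ()))
    )
    if not ecs:
        return Prediction(query, None, 0, 0, "SeqID", partners=(best,))
    return Prediction(query, min(sorted(ecs)), 1, 0, "SeqID", partners=(best,))
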