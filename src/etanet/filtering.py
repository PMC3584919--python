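"""Match filtering: RMSD/self-match prefilter, SVM significance, reciprocity.

A candidate match survives when it is not a self-match, its superposition
RMSD is at most 2 Å, and a classifier trained to combine geometric and
evolutionary similarity accepts its 7-dimensional feature vector
``[rmsd, r1..r6]``, where ``r_k`` is the absolute percentile-rank difference
at position k. Five-residue matches reuse the six-residue feature contract by
appending a virtual sixth residue equal to the mean of the other five.
Finally, only protein pairs matching significantly in *both* directions
(reciprocal matches) feed function transfer.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .model import TemplateMatch

RMSD_CUTOFF = 2.0


def prefilter(matches: Iterable[TemplateMatch]) -> list[TemplateMatch]:
    """Drop self-matches and matches with RMSD strictly greater than 2 Å."""
    kept = []
    for m in matches:
        if m.rmsd is None:
            raise ValueError("prefilter requires rmsd to be set on every match")
        if m.is_self_match or m.rmsd > RMSD_CUTOFF:
            continue
        kept.append(m)
    return kept


def features_from(rmsd: float, rank_diffs: Sequence[float]) -> np.ndarray:
    """Build the 7-vector [rmsd, r1..r6] from scored match components."""
    diffs = list(rank_diffs)
    if len(diffs) == 5:
        diffs.append(float(np.mean(diffs)))
    if len(diffs) != 6:
        raise ValueError(f"need 5 or 6 rank differences, got {len(diffs)}")
    vec = np.array([rmsd, *diffs], dtype=float)
    if vec[0] < 0 or np.any(vec[1:] < 0) or np.any(vec[1:] > 1):
        raise ValueError("invalid feature values (rmsd >= 0, diffs in [0, 1])")
    return vec


def featurize(match: TemplateMatch, query_ranks=None, target_ranks=None) -> np.ndarray:
    """Feature vector for a match; computes rank diffs from rankings if unset."""
    if match.rank_diffs is None:
        if query_ranks is None or target_ranks is None:
            raise ValueError("match not scored and no rankings supplied")
        diffs = []
        for qpos, tpos in zip(match.template_positions, match.matched_positions):
            try:
                diffs.append(
                    abs(query_ranks.percentile[qpos] - target_ranks.percentile[tpos])
                )
            except KeyError as exc:
                raise ValueError(f"missing percentile for residue {exc}") from exc
        match.rank_diffs = tuple(diffs)
        match.et_score = float(sum(diffs))
    if match.rmsd is None:
        raise ValueError("match has no rmsd; run score_match first")
    return features_from(match.rmsd, match.rank_diffs)


@dataclass(eq=False)
class SvmModel:
    """A fitted RBF-SVM over match features, with provenance recorded."""

    pipeline: Pipeline
    params: dict
    provenance: str

    def decide(self, features: np.ndarray) -> bool:
        return bool(self.pipeline.predict(np.asarray(features).reshape(1, -1))[0])


@dataclass(eq=False)
class ThresholdClassifier:
    """Transparent fallback rule: accept iff rmsd and mean rank diff are small."""

    max_rmsd: float = 2.0
    max_mean_diff: float = 0.25
    provenance: str = "threshold rule"

    def decide(self, features: np.ndarray) -> bool:
        features = np.asarray(features)
        return bool(
            features[0] <= self.max_rmsd
            and float(np.mean(features[1:])) <= self.max_mean_diff
        )


def train_svm(
    labeled: Sequence[tuple[np.ndarray, bool]],
    seed: int = 0,
    cv: int = 5,
    c_grid: Sequence[float] = (1.0, 10.0, 100.0),
    gamma_grid: Sequence = ("scale", 0.1, 1.0),
) -> SvmModel:
    """Fit an RBF SVM on labeled match features (standardized internally).

    Hyperparameters are chosen by a small grid with stratified cross
    validation; the fit is deterministic for a fixed seed.
    """
    if not labeled:
        raise ValueError("no training data")
    x = np.vstack([np.asarray(f, dtype=float) for f, _ in labeled])
    y = np.array([bool(l) for _, l in labeled])
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))]
    )
    grid = GridSearchCV(
        pipe,
        param_grid={"svc__C": list(c_grid), "svc__gamma": list(gamma_grid)},
        cv=StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    grid.fit(x, y)
    return SvmModel(
        pipeline=grid.best_estimator_,
        params=dict(grid.best_params_),
        provenance=(
            f"RBF SVM trained on {len(y)} synthetic template matches "
            f"({int(y.sum())} true / {int((~y).sum())} false), seed={seed}"
        ),
    )


def classify(model, features: np.ndarray) -> bool:
    """Apply a significance classifier (SvmModel or ThresholdClassifier)."""
    return model.decide(features)


@dataclass(eq=False)
class ReciprocalPair:
    """An unordered protein pair matched significantly in both directions."""

    a: str
    b: str
    matches: list[TemplateMatch] = field(default_factory=list)

    @property
    def best_match(self) -> TemplateMatch:
        return min(self.matches, key=lambda m: m.rmsd)

    def partner_of(self, chain_id: str) -> str:
        return self.b if chain_id == self.a else self.a


def _sites_correspond(fwd: TemplateMatch, rev: TemplateMatch) -> bool:
    return bool(
        set(fwd.template_positions) & set(rev.matched_positions)
        and set(fwd.matched_positions) & set(rev.template_positions)
    )


def reciprocal_matches(
    sig_fwd: Iterable[TemplateMatch],
    sig_rev: Iterable[TemplateMatch],
    site_level: bool = False,
) -> list[ReciprocalPair]:
    """Unordered pairs with significant matches in both directions.

    Protein-level by default: any template of A matching B and any template of
    B matching A suffices. With ``site_level=True`` the two directed matches
    must additionally involve overlapping residue sites. The result is
    independent of how matches are split between the two arguments.
    """
    directed: dict[tuple[str, str], list[TemplateMatch]] = defaultdict(list)
    for m in list(sig_fwd) + list(sig_rev):
        directed[(m.query_chain, m.target_chain)].append(m)
    pairs: list[ReciprocalPair] = []
    for (a, b) in sorted(directed):
        if a >= b or (b, a) not in directed:
            continue
        fwd, rev = directed[(a, b)], directed[(b, a)]
        if site_level and not any(
            _sites_correspond(m1, m2) for m1 in fwd for m2 in rev
        ):
            continue
        pairs.append(ReciprocalPair(a=a, b=b, matches=fwd + rev))
    return pairs
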