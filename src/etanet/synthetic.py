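"""Self-contained toy benchmarks with planted, geometry-shared functional sites.

Each function is assigned a rigid "site motif" — a connected arrangement of
5-6 Cα positions with distinct residue types. Every protein of that function
embeds a rotated, translated and jittered copy of the motif among decoy
residues, and its evolutionary ranks place the site residues at the top, so
the whole annotation pipeline (cluster -> template -> search -> filter ->
vote -> network) can run end to end and be checked against planted truth.

Layout per protein (regions separated by ~60 Å so clusters never bridge):

* site 1 (and optionally site 2) plus "filler" residues 5-7.5 Å away, so the
  site cluster can reach the 11-surface-residue requirement;
* one "false site": a geometric copy of a *different* function's motif whose
  residues carry unimportant ranks — a geometric coincidence with no
  evolutionary support, the canonical false-positive the SVM must reject;
* random decoys with random types and poor ranks.

In two-site fixtures the two sites receive interleaved top ranks (site 1:
1,3,5,...; site 2: 2,4,6,...) so both clusters are genuinely important and
the secondary cluster satisfies the better-rank condition for additional
templates. Setting ``corrupt_primary_fraction`` scrambles site-1 geometry in
that fraction of proteins, removing their primary-template partners while
leaving site 2 intact — the scenario in which multiple templates rescue
sensitivity.

All coordinates are rounded to 3 decimals (PDB precision), so written files
round-trip bit-identically.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import io as io_mod
from .model import (
    AnnotationTable,
    ETRanking,
    ProteinChain,
    ProteinRecord,
    SurfaceAnnotation,
)
from .network import MatchNetwork
from .filtering import features_from
from .pdm import match_rmsd, pdm_search
from .model import Template

TWENTY = "ACDEFGHIKLMNPQRSTVWY"

_SITE_CENTERS = {0: np.array([0.0, 0.0, 0.0]), 1: np.array([60.0, 0.0, 0.0])}
_FALSE_CENTER = np.array([0.0, 60.0, 0.0])
_DECOY_CENTER = np.array([60.0, 60.0, 60.0])
_DECOY_HALF_WIDTH = 20.0


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for a generated benchmark (reproducible by seed)."""

    n_proteins: int = 20
    n_functions: int = 4
    site_size: int = 6
    sites_per_protein: int = 1
    jitter_sigma: float = 0.2
    decoy_residues: int = 18
    n_fillers: int = 8
    rank_noise: float = 0.25
    buried_fraction: float = 0.0
    corrupt_primary_fraction: float = 0.0
    plant_false_site: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.site_size < 5:
            raise ValueError("site_size must be at least 5")
        if self.sites_per_protein not in (1, 2):
            raise ValueError("sites_per_protein must be 1 or 2")
        if self.jitter_sigma < 0 or self.rank_noise < 0:
            raise ValueError("noise levels must be nonnegative")


@dataclass(eq=False)
class PlantedSite:
    function: int
    site_index: int
    positions: tuple[int, ...]  # seq numbers, in motif point order
    corrupted: bool = False


@dataclass(eq=False)
class Benchmark:
    spec: FixtureSpec
    proteins: dict[str, ProteinRecord]
    annotations: AnnotationTable
    sites: dict[str, list[PlantedSite]]
    corrupted: frozenset[str]
    function_of: dict[str, int]
    motifs: dict[tuple[int, int], tuple[np.ndarray, str]]

    def ec_of(self, function: int) -> str:
        return f"1.1.1.{function + 1}"

    def manifest(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "proteins": {
                pid: {
                    "function": self.function_of[pid],
                    "ec": sorted(self.annotations[pid]),
                    "corrupted": pid in self.corrupted,
                    "sites": [
                        {
                            "function": s.function,
                            "site_index": s.site_index,
                            "positions": list(s.positions),
                            "corrupted": s.corrupted,
                        }
                        for s in self.sites[pid]
                    ],
                    "files": {
                        "structure": f"{pid}.pdb",
                        "ranks": f"{pid}.ranks.tsv",
                        "accessibility": f"{pid}.acc.tsv",
                    },
                }
                for pid in sorted(self.proteins)
            },
            "motifs": {
                f"{f}_{s}": {
                    "points": np.round(points, 6).tolist(),
                    "types": types,
                }
                for (f, s), (points, types) in sorted(self.motifs.items())
            },
            "annotation_file": "annotations.tsv",
        }

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for pid in sorted(self.proteins):
            rec = self.proteins[pid]
            io_mod.write_ca_pdb(rec.chain, outdir / f"{pid}.pdb")
            io_mod.write_et_ranks(rec.ranks, rec.chain, outdir / f"{pid}.ranks.tsv")
            io_mod.write_accessibility(rec.surface, outdir / f"{pid}.acc.tsv")
        io_mod.write_annotations(self.annotations, outdir / "annotations.tsv")
        manifest = self.manifest()
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
        return manifest


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _sample_motif(
    rng: np.random.Generator, k: int, min_sep: float = 3.8, max_link: float = 7.0
) -> np.ndarray:
    """Connected rigid motif: each point 3.8-7 Å from an earlier one."""
    pts = [np.zeros(3)]
    tries = 0
    while len(pts) < k:
        tries += 1
        if tries > 5000:
            raise RuntimeError("motif sampling failed; relax separation constraints")
        base = pts[int(rng.integers(len(pts)))]
        cand = base + _unit(rng) * rng.uniform(min_sep, max_link)
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
    arr = np.array(pts)
    return arr - arr.mean(axis=0)


def _linked(points: np.ndarray, cutoff: float) -> bool:
    n = len(points)
    seen = {0}
    frontier = [0]
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    while frontier:
        i = frontier.pop()
        for j in range(n):
            if j not in seen and d[i, j] <= cutoff:
                seen.add(j)
                frontier.append(j)
    return len(seen) == n


def _place_fillers(
    rng: np.random.Generator, site_pts: np.ndarray, n_fillers: int
) -> list[np.ndarray]:
    fillers: list[np.ndarray] = []
    tries = 0
    while len(fillers) < n_fillers:
        tries += 1
        if tries > 20000:
            raise RuntimeError(
                "overcrowded geometry: cannot place filler residues; use a larger box"
            )
        anchor = site_pts[int(rng.integers(len(site_pts)))]
        cand = anchor + _unit(rng) * rng.uniform(5.2, 7.4)
        if min(np.linalg.norm(cand - p) for p in site_pts) < 5.0:
            continue
        if fillers and min(np.linalg.norm(cand - p) for p in fillers) < 3.0:
            continue
        fillers.append(cand)
    return fillers


def _place_decoys(rng: np.random.Generator, n_decoys: int) -> list[np.ndarray]:
    decoys: list[np.ndarray] = []
    tries = 0
    while len(decoys) < n_decoys:
        tries += 1
        if tries > 20000:
            raise RuntimeError(
                "overcrowded geometry: cannot place decoy residues; use a larger box"
            )
        cand = _DECOY_CENTER + rng.uniform(-_DECOY_HALF_WIDTH, _DECOY_HALF_WIDTH, 3)
        if decoys and min(np.linalg.norm(cand - p) for p in decoys) < 3.0:
            continue
        decoys.append(cand)
    return decoys


def generate_benchmark(spec: FixtureSpec, outdir: str | Path | None = None) -> Benchmark:
    """Generate a benchmark; identical specs give bit-identical outputs."""
    rng = np.random.default_rng(spec.seed)
    motifs: dict[tuple[int, int], tuple[np.ndarray, str]] = {}
    for f in range(spec.n_functions):
        for s in range(spec.sites_per_protein):
            points = _sample_motif(rng, spec.site_size)
            types = "".join(rng.permutation(list(TWENTY))[: spec.site_size])
            motifs[(f, s)] = (points, types)

    n_corrupt = int(round(spec.corrupt_primary_fraction * spec.n_proteins))
    corrupt_idx = set(rng.permutation(spec.n_proteins)[:n_corrupt].tolist())

    proteins: dict[str, ProteinRecord] = {}
    annotations = AnnotationTable()
    sites: dict[str, list[PlantedSite]] = {}
    corrupted_ids: set[str] = set()
    function_of: dict[str, int] = {}

    for i in range(spec.n_proteins):
        pid = f"sy{i:02d}A"
        f = i % spec.n_functions
        is_corrupt = i in corrupt_idx
        entries: list[tuple[np.ndarray, str, str, int]] = []  # coord, aa, role, site

        site_points_all: dict[int, np.ndarray] = {}
        for s in range(spec.sites_per_protein):
            motif, types = motifs[(f, s)]
            rot = _rotation(rng)
            pts = motif @ rot.T + _SITE_CENTERS[s]
            pts = pts + rng.normal(0.0, spec.jitter_sigma, pts.shape)
            if is_corrupt and s == 0:
                for _ in range(100):
                    scrambled = pts + rng.normal(0.0, 3.5, pts.shape)
                    d = np.linalg.norm(
                        scrambled[:, None] - scrambled[None, :], axis=2
                    )
                    np.fill_diagonal(d, np.inf)
                    if _linked(scrambled, 8.0) and d.min() >= 2.0:
                        pts = scrambled
                        break
                else:  # pragma: no cover - essentially impossible
                    raise RuntimeError("could not scramble site geometry")
            site_points_all[s] = pts
            for k in range(spec.site_size):
                entries.append((pts[k], types[k], f"site{s}", s))
            for filler in _place_fillers(rng, pts, spec.n_fillers):
                entries.append((filler, rng.choice(list(TWENTY)), f"filler{s}", s))

        if spec.plant_false_site and spec.n_functions > 1:
            fmotif, ftypes = motifs[((f + 1) % spec.n_functions, 0)]
            rot = _rotation(rng)
            pts = fmotif @ rot.T + _FALSE_CENTER
            pts = pts + rng.normal(0.0, spec.jitter_sigma, pts.shape)
            for k in range(spec.site_size):
                entries.append((pts[k], ftypes[k], "false", -1))

        # chain lengths vary (like real proteins), so percentile ranks — and
        # hence ETScores — differ across chains instead of degenerating
        n_decoys = spec.decoy_residues + int(
            rng.integers(0, max(2, spec.decoy_residues // 3))
        )
        for decoy in _place_decoys(rng, n_decoys):
            entries.append((decoy, rng.choice(list(TWENTY)), "decoy", -1))

        # rank assignment: planted sites first (interleaved when two sites),
        # then fillers per site, then everything else shuffled.
        order: list[int] = []
        site_entry_idx = {
            s: [j for j, e in enumerate(entries) if e[2] == f"site{s}"]
            for s in range(spec.sites_per_protein)
        }
        if spec.sites_per_protein == 2:
            for k in range(spec.site_size):
                order.append(site_entry_idx[0][k])
                order.append(site_entry_idx[1][k])
        else:
            order.extend(site_entry_idx[0])
        for s in range(spec.sites_per_protein):
            order.extend(j for j, e in enumerate(entries) if e[2] == f"filler{s}")
        rest = [j for j in range(len(entries)) if j not in set(order)]
        order.extend(rng.permutation(rest).tolist())
        base_rank = {j: r + 1.0 for r, j in enumerate(order)}
        rank_by_entry = {
            j: max(1.0, base_rank[j] + rng.normal(0.0, spec.rank_noise))
            for j in range(len(entries))
        }

        perm = rng.permutation(len(entries))
        seq_of_entry = {int(j): k + 1 for k, j in enumerate(perm)}
        by_seq = sorted(
            (seq_of_entry[j], entries[j], rank_by_entry[j])
            for j in range(len(entries))
        )
        coords = np.round(np.array([e[0] for _, e, _ in by_seq]), 3)
        aas = tuple(e[1] for _, e, _ in by_seq)
        seq_numbers = np.array([s for s, _, _ in by_seq])
        ranks = {int(sn): float(rk) for sn, _e, rk in by_seq}

        # accessibility: everything exposed except a buried fraction of decoys
        area = {int(s): 30.0 for s in seq_numbers}
        decoy_seqs = [sn for sn, e, _ in by_seq if e[2] == "decoy"]
        n_buried = int(round(spec.buried_fraction * len(decoy_seqs)))
        for sn in list(rng.permutation(decoy_seqs))[:n_buried]:
            area[int(sn)] = 0.0

        chain = ProteinChain(
            id=pid,
            seq_numbers=seq_numbers,
            aas=aas,
            coords=coords,
            full_sequence_length=len(seq_numbers),
        )
        proteins[pid] = ProteinRecord(
            chain=chain,
            ranks=ETRanking.from_ranks(pid, ranks),
            surface=SurfaceAnnotation(pid, area),
        )
        annotations[pid] = frozenset({f"1.1.1.{f + 1}"})
        function_of[pid] = f
        sites[pid] = [
            PlantedSite(
                function=f,
                site_index=s,
                positions=tuple(seq_of_entry[j] for j in site_entry_idx[s]),
                corrupted=is_corrupt and s == 0,
            )
            for s in range(spec.sites_per_protein)
        ]
        if is_corrupt:
            corrupted_ids.add(pid)

    bench = Benchmark(
        spec=spec,
        proteins=proteins,
        annotations=annotations,
        sites=sites,
        corrupted=frozenset(corrupted_ids),
        function_of=function_of,
        motifs=motifs,
    )
    if outdir is not None:
        bench.write(outdir)
    return bench


def load_benchmark(outdir: str | Path) -> Benchmark:
    """Reload a benchmark written by :meth:`Benchmark.write`."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    spec = FixtureSpec(**manifest["spec"])
    annotations = io_mod.read_annotations(outdir / manifest["annotation_file"])
    proteins: dict[str, ProteinRecord] = {}
    sites: dict[str, list[PlantedSite]] = {}
    corrupted: set[str] = set()
    function_of: dict[str, int] = {}
    for pid, info in manifest["proteins"].items():
        chain = io_mod.read_pdb_chain(outdir / info["files"]["structure"], pid[-1])
        ranks = io_mod.read_et_ranks(outdir / info["files"]["ranks"], chain_id=pid)
        surface = io_mod.read_accessibility(
            outdir / info["files"]["accessibility"], chain_id=pid
        )
        proteins[pid] = ProteinRecord(chain=chain, ranks=ranks, surface=surface)
        function_of[pid] = info["function"]
        if info["corrupted"]:
            corrupted.add(pid)
        sites[pid] = [
            PlantedSite(
                function=s["function"],
                site_index=s["site_index"],
                positions=tuple(s["positions"]),
                corrupted=s["corrupted"],
            )
            for s in info["sites"]
        ]
    motifs = {
        tuple(int(x) for x in key.split("_")): (np.array(m["points"]), m["types"])
        for key, m in manifest["motifs"].items()
    }
    return Benchmark(
        spec=spec,
        proteins=proteins,
        annotations=annotations,
        sites=sites,
        corrupted=frozenset(corrupted),
        function_of=function_of,
        motifs=motifs,
    )


def _site_template(bench: Benchmark, pid: str, site_index: int) -> Template:
    rec = bench.proteins[pid]
    site = bench.sites[pid][site_index]
    return Template(
        source_chain=pid,
        positions=site.positions,
        coords=rec.chain.coords_of(site.positions),
        allowed_types=tuple(
            frozenset({rec.chain.aa_of(p)}) for p in site.positions
        ),
        mode_tag="6R" if bench.spec.site_size == 6 else "5R",
    )


def generate_svm_training(
    source: FixtureSpec | Benchmark,
    n_true: int = 40,
    n_false: int = 25,
    seed: int = 0,
) -> list[tuple[np.ndarray, bool]]:
    """Labeled match features from planted correspondences and decoy matches.

    True examples pair the planted sites of same-function proteins (low RMSD,
    low rank differences). False examples are paired-distance hits of a
    protein's site template in different-function structures (or non-identity
    hits in its own), i.e. geometric coincidences without evolutionary
    support.
    """
    if n_true < 10 or n_false < 10:
        raise ValueError("need at least 10 examples per class")
    bench = generate_benchmark(source) if isinstance(source, FixtureSpec) else source
    if bench.spec.site_size not in (5, 6):
        raise ValueError("SVM features require site_size 5 or 6")
    rng = np.random.default_rng(seed)
    ids = sorted(bench.proteins)

    true_feats: list[np.ndarray] = []
    for a in ids:
        for b in ids:
            if a == b or bench.function_of[a] != bench.function_of[b]:
                continue
            for s in range(bench.spec.sites_per_protein):
                if bench.sites[a][s].corrupted or bench.sites[b][s].corrupted:
                    continue
                ca = bench.proteins[a].chain.coords_of(bench.sites[a][s].positions)
                cb = bench.proteins[b].chain.coords_of(bench.sites[b][s].positions)
                diffs = [
                    abs(
                        bench.proteins[a].ranks.percentile[pa]
                        - bench.proteins[b].ranks.percentile[pb]
                    )
                    for pa, pb in zip(
                        bench.sites[a][s].positions, bench.sites[b][s].positions
                    )
                ]
                true_feats.append(features_from(match_rmsd(ca, cb), diffs))
    if len(true_feats) < n_true:
        raise ValueError(
            f"only {len(true_feats)} true matches available; "
            "use more proteins per function"
        )

    false_feats: list[np.ndarray] = []
    for a in ids:
        if bench.sites[a][0].corrupted:
            continue
        tpl = _site_template(bench, a, 0)
        planted = dict(zip(tpl.positions, tpl.positions))
        for b in ids:
            if bench.function_of[a] == bench.function_of[b] and a != b:
                continue
            result = pdm_search(tpl, bench.proteins[b].chain, cap=20000)
            for m in result.matches:
                if a == b and m.matched_positions == m.template_positions:
                    continue  # the identity self-match is not a false example
                rmsd = match_rmsd(
                    tpl.coords, bench.proteins[b].chain.coords_of(m.matched_positions)
                )
                diffs = [
                    abs(
                        bench.proteins[a].ranks.percentile[pa]
                        - bench.proteins[b].ranks.percentile[pb]
                    )
                    for pa, pb in zip(m.template_positions, m.matched_positions)
                ]
                false_feats.append(features_from(rmsd, diffs))
    if len(false_feats) < n_false:
        raise ValueError(
            f"only {len(false_feats)} false matches found; increase decoy_residues "
            "or keep plant_false_site enabled"
        )

    t_idx = rng.choice(len(true_feats), size=n_true, replace=False)
    f_idx = rng.choice(len(false_feats), size=n_false, replace=False)
    labeled = [(true_feats[i], True) for i in t_idx] + [
        (false_feats[i], False) for i in f_idx
    ]
    return labeled


def generate_msa(
    chain: ProteinChain,
    n_rows: int = 12,
    substitution_rate: float = 0.2,
    seed: int = 0,
    gap_rate: float = 0.0,
    site_positions: tuple[int, ...] = (),
) -> MultipleSeqAlignment:
    """A toy alignment of mutated copies of the chain sequence.

    Row 0 is the native sequence. Site positions mutate at one tenth of the
    background substitution rate (functional conservation); gaps are inserted
    at ``gap_rate`` per position in non-native rows.
    """
    if not 0 <= substitution_rate < 1:
        raise ValueError("substitution_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    site_set = {int(p) for p in site_positions}
    native = chain.sequence
    rows = [SeqRecord(Seq(native), id=chain.id, description="")]
    letters = list(TWENTY)
    for r in range(1, n_rows):
        out = []
        for idx, aa in enumerate(native):
            seq_number = int(chain.seq_numbers[idx])
            if rng.random() < gap_rate:
                out.append("-")
                continue
            rate = substitution_rate / 10 if seq_number in site_set else substitution_rate
            if rng.random() < rate:
                choices = [c for c in letters if c != aa]
                out.append(choices[int(rng.integers(len(choices)))])
            else:
                out.append(aa)
        rows.append(SeqRecord(Seq("".join(out)), id=f"homolog{r}", description=""))
    return MultipleSeqAlignment(rows)


@dataclass(eq=False)
class TieFixture:
    """A match network where plain voting ties but edge weights discriminate."""

    network: MatchNetwork
    annotations: AnnotationTable
    truth: dict[str, frozenset[str]]
    partners: dict[str, list[tuple[str, frozenset[str]]]]


def generate_tie_network(
    n_per_function: int = 4,
    k_unknown: int = 4,
    seed: int = 0,
    strong: tuple[float, float] = (0.6, 0.3),
    weak: tuple[float, float] = (1.6, 1.1),
    intra: tuple[float, float] = (1.0, 0.7),
    noise: float = 0.05,
    transform: str = "exp",
) -> TieFixture:
    """Two-function network where each unknown node has equally many partners
    of both functions but strictly stronger (lower rmsd/ETScore) edges to its
    true one — the situation in which diffusion breaks a voting tie.
    """
    if k_unknown < 2:
        raise ValueError("need at least 2 unknown nodes for confidence z-scores")
    rng = np.random.default_rng(seed)
    functions = ("1.1.1.1", "1.1.1.2")
    labeled = {
        f"L{fi}{j}": functions[fi]
        for fi in range(2)
        for j in range(n_per_function)
    }
    unknown_truth = {f"U{j:02d}": functions[j % 2] for j in range(k_unknown)}
    edges: dict[tuple[str, str], tuple[float, float]] = {}

    def jitter(base: tuple[float, float]) -> tuple[float, float]:
        return (
            max(0.01, base[0] + rng.normal(0.0, noise)),
            max(0.01, base[1] + rng.normal(0.0, noise)),
        )

    group = {fn: sorted(n for n, f in labeled.items() if f == fn) for fn in functions}
    for fn in functions:
        members = group[fn]
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                edges[(a, b)] = jitter(intra)
    for u, fn_true in unknown_truth.items():
        for ln, fn in labeled.items():
            edges[(u, ln)] = jitter(strong if fn == fn_true else weak)

    nodes = sorted(labeled) + sorted(unknown_truth)
    network = MatchNetwork.from_edges(nodes, edges, transform)
    annotations = AnnotationTable(
        {n: frozenset({fn}) for n, fn in labeled.items()}
        | {u: frozenset() for u in unknown_truth}
    )
    partners = {
        u: [(ln, frozenset({fn})) for ln, fn in sorted(labeled.items())]
        for u in unknown_truth
    }
    return TieFixture(
        network=network,
        annotations=annotations,
        truth={u: frozenset({fn}) for u, fn in unknown_truth.items()},
        partners=partners,
    )
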