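"""Genome rearrangement simulator with known event phylogeny.

Genomes are signed permutations of atomic ancestral segments (default
10 kb each) distributed over chromosomes; nucleotide sequence is never
simulated because breakpoint placement and branch assignment are the
quantities under test.  Events (inversions, translocations, fusions,
fissions) are drawn along a species tree in preorder; every event is
logged.  Leaf assemblies can be fragmented into scaffolds with optional
chimeric joins (ground truth for the QC stage), and alignment anchors
against a designated chromosome-level reference leaf are emitted with
optional anchor dropout and boundary jitter.

Ground-truth EBRs are the reference-genome coordinates of event junctions:
an event contributes one true EBR per junction whose broken-or-created
segment adjacency survives in the final reference genome (junctions later
reworked on the reference lineage are not reference-observable;
fusion/fission junctions falling on reference chromosome ends produce no
breakpoint region and drop out of the same rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .formats import AlignmentAnchor, GenomicInterval
from .phylo import Phylogeny

DEFAULT_SEGMENT_LENGTH = 10_000
DEFAULT_TYPE_WEIGHTS = {
    "inversion": 0.80,
    "translocation": 0.10,
    "fusion": 0.05,
    "fission": 0.05,
}

Adjacency = tuple[int, int]


def _canon(u: int, v: int) -> Adjacency:
    """Orientation-symmetric adjacency key: (u,v) == (-v,-u)."""
    return min((u, v), (-v, -u))


@dataclass
class SegmentGenome:
    chromosomes: list[list[int]]
    names: list[str] = field(default_factory=list)
    segment_length: int = DEFAULT_SEGMENT_LENGTH

    def __post_init__(self) -> None:
        if not self.names:
            self.names = [f"chr{i + 1}" for i in range(len(self.chromosomes))]
        ids = [abs(s) for chrom in self.chromosomes for s in chrom]
        if len(set(ids)) != len(ids):
            raise ValueError("segment ids must be unique genome-wide")

    @classmethod
    def ancestor(
        cls,
        n_segments: int,
        n_chromosomes: int = 1,
        segment_length: int = DEFAULT_SEGMENT_LENGTH,
    ) -> "SegmentGenome":
        if n_segments < n_chromosomes:
            raise ValueError("need at least one segment per chromosome")
        per = n_segments // n_chromosomes
        chroms, nxt = [], 1
        for i in range(n_chromosomes):
            count = per + (1 if i < n_segments % n_chromosomes else 0)
            chroms.append(list(range(nxt, nxt + count)))
            nxt += count
        return cls(chromosomes=chroms, segment_length=segment_length)

    def copy(self) -> "SegmentGenome":
        return SegmentGenome(
            chromosomes=[list(c) for c in self.chromosomes],
            names=list(self.names),
            segment_length=self.segment_length,
        )

    @property
    def n_segments(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def chrom_sizes(self) -> dict[str, int]:
        return {
            name: len(chrom) * self.segment_length
            for name, chrom in zip(self.names, self.chromosomes)
        }

    def segment_multiset(self) -> list[int]:
        return sorted(abs(s) for chrom in self.chromosomes for s in chrom)

    def adjacency_positions(self) -> dict[Adjacency, tuple[str, int]]:
        """Canonical adjacency -> (chromosome, bp position of the junction)."""
        out: dict[Adjacency, tuple[str, int]] = {}
        for name, chrom in zip(self.names, self.chromosomes):
            for i in range(len(chrom) - 1):
                out[_canon(chrom[i], chrom[i + 1])] = (name, (i + 1) * self.segment_length)
        return out


@dataclass(frozen=True)
class SimEvent:
    branch: str  # clade id of the tree edge the event occurred on
    truth_branch: str  # canonical (classification-convention) branch id
    type: str
    broken: tuple[Adjacency, ...]
    created: tuple[Adjacency, ...]
    event_index: int


@dataclass(frozen=True)
class TrueEBR:
    ref: GenomicInterval
    branch: str
    event_index: int
    event_type: str


@dataclass
class SimTruth:
    events: list[SimEvent]
    true_ebrs: list[TrueEBR]
    scaffold_maps: dict[str, dict] = field(default_factory=dict)
    noise_log: dict[str, list] = field(default_factory=dict)
    seed: int | None = None


# ---------------------------------------------------------------------------
# Event mechanics
# ---------------------------------------------------------------------------


def _pick_chrom(rng: np.random.Generator, genome: SegmentGenome, min_len: int) -> int | None:
    sizes = np.array([len(c) for c in genome.chromosomes], dtype=float)
    ok = sizes >= min_len
    if not ok.any():
        return None
    probs = np.where(ok, sizes, 0.0)
    probs /= probs.sum()
    return int(rng.choice(len(sizes), p=probs))


def _inversion(
    rng: np.random.Generator, genome: SegmentGenome, min_segments: int
) -> tuple[tuple[Adjacency, ...], tuple[Adjacency, ...]] | None:
    ci = _pick_chrom(rng, genome, min_segments + 2)
    if ci is None:
        return None
    c = genome.chromosomes[ci]
    n = len(c)
    # internal boundaries 1..n-1, span >= min_segments keeps two junctions
    i = int(rng.integers(1, n - min_segments))
    j = int(rng.integers(i + min_segments, n))
    broken = (_canon(c[i - 1], c[i]), _canon(c[j - 1], c[j]))
    created = (_canon(c[i - 1], -c[j - 1]), _canon(-c[i], c[j]))
    c[i:j] = [-s for s in reversed(c[i:j])]
    return broken, created


def _translocation(
    rng: np.random.Generator, genome: SegmentGenome
) -> tuple[tuple[Adjacency, ...], tuple[Adjacency, ...]] | None:
    if len(genome.chromosomes) < 2:
        return None
    src = _pick_chrom(rng, genome, 3)
    if src is None:
        return None
    others = [k for k in range(len(genome.chromosomes)) if k != src and len(genome.chromosomes[k]) >= 2]
    if not others:
        return None
    dst = int(rng.choice(others))
    cs, cd = genome.chromosomes[src], genome.chromosomes[dst]
    i = int(rng.integers(1, len(cs) - 1))
    j = int(rng.integers(i + 1, len(cs)))
    k = int(rng.integers(1, len(cd)))
    run = cs[i:j]
    broken = [_canon(cs[i - 1], cs[i]), _canon(cd[k - 1], cd[k])]
    if j < len(cs):
        broken.append(_canon(cs[j - 1], cs[j]))
    created = [_canon(cd[k - 1], run[0]), _canon(run[-1], cd[k])]
    if j < len(cs):
        created.append(_canon(cs[i - 1], cs[j]))
    del cs[i:j]
    genome.chromosomes[dst] = cd[:k] + run + cd[k:]
    return tuple(broken), tuple(created)


def _fusion(
    rng: np.random.Generator, genome: SegmentGenome
) -> tuple[tuple[Adjacency, ...], tuple[Adjacency, ...]] | None:
    if len(genome.chromosomes) < 2:
        return None
    a, b = rng.choice(len(genome.chromosomes), size=2, replace=False)
    a, b = int(a), int(b)
    created = (_canon(genome.chromosomes[a][-1], genome.chromosomes[b][0]),)
    genome.chromosomes[a] = genome.chromosomes[a] + genome.chromosomes[b]
    del genome.chromosomes[b]
    genome.names = [f"chr{i + 1}" for i in range(len(genome.chromosomes))]
    return (), created


def _fission(
    rng: np.random.Generator, genome: SegmentGenome
) -> tuple[tuple[Adjacency, ...], tuple[Adjacency, ...]] | None:
    ci = _pick_chrom(rng, genome, 2)
    if ci is None:
        return None
    c = genome.chromosomes[ci]
    i = int(rng.integers(1, len(c)))
    broken = (_canon(c[i - 1], c[i]),)
    genome.chromosomes[ci] = c[:i]
    genome.chromosomes.append(c[i:])
    genome.names = [f"chr{k + 1}" for k in range(len(genome.chromosomes))]
    return broken, ()


_EVENT_FUNCS = {
    "inversion": lambda rng, g, mi: _inversion(rng, g, mi),
    "translocation": lambda rng, g, mi: _translocation(rng, g),
    "fusion": lambda rng, g, mi: _fusion(rng, g),
    "fission": lambda rng, g, mi: _fission(rng, g),
}


def simulate(
    ancestor: SegmentGenome,
    phylo: Phylogeny,
    reference: str,
    events_per_branch: int = 8,
    type_weights: Mapping[str, float] | None = None,
    seed: int | None = None,
    min_inv_segments: int = 2,
) -> tuple[dict[str, SegmentGenome], SimTruth]:
    """Evolve ``ancestor`` along the tree; return leaf genomes and the truth ledger."""
    if ancestor.n_segments == 0:
        raise ValueError("empty ancestor genome")
    if reference not in phylo.leaves:
        raise ValueError(f"reference {reference!r} not a leaf of the tree")
    weights = dict(type_weights or DEFAULT_TYPE_WEIGHTS)
    types = sorted(weights)
    probs = np.array([weights[t] for t in types], dtype=float)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)

    tree = phylo._tree
    genomes: dict[int, SegmentGenome] = {id(tree.seed_node): ancestor.copy()}
    leaf_genomes: dict[str, SegmentGenome] = {}
    events: list[SimEvent] = []
    event_index = 0

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        genome = genomes[id(node.parent_node)].copy()
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        from .phylo import branch_id as _bid

        bid = _bid(clade)
        truth_bid = phylo.classification_branch_id(bid, reference)
        used: set[Adjacency] = set()
        for _ in range(events_per_branch):
            placed = False
            for _attempt in range(200):
                etype = types[int(rng.choice(len(types), p=probs))]
                trial = genome.copy()
                outcome = _EVENT_FUNCS[etype](rng, trial, min_inv_segments)
                if outcome is None:
                    continue
                broken, created = outcome
                if used & (set(broken) | set(created)):
                    continue  # no boundary reuse on one branch
                genome = trial
                used |= set(broken) | set(created)
                events.append(
                    SimEvent(
                        branch=bid,
                        truth_branch=truth_bid,
                        type=etype,
                        broken=broken,
                        created=created,
                        event_index=event_index,
                    )
                )
                event_index += 1
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place an event on branch {bid!r} (genome too fragmented?)"
                )
        genomes[id(node)] = genome
        if node.is_leaf():
            leaf_genomes[node.taxon.label] = genome

    ref_genome = leaf_genomes[reference]
    adj_pos = ref_genome.adjacency_positions()
    true_ebrs: list[TrueEBR] = []
    for ev in events:
        for adj in (*ev.broken, *ev.created):
            hit = adj_pos.get(adj)
            if hit is None:
                continue
            chrom, pos = hit
            true_ebrs.append(
                TrueEBR(
                    ref=GenomicInterval(chrom, pos, pos + 1),
                    branch=ev.truth_branch,
                    event_index=ev.event_index,
                    event_type=ev.type,
                )
            )
    truth = SimTruth(events=events, true_ebrs=true_ebrs, seed=seed)
    return leaf_genomes, truth


# ---------------------------------------------------------------------------
# Scaffold fragmentation
# ---------------------------------------------------------------------------


def _n50(sizes_bp: Sequence[int]) -> int:
    total = sum(sizes_bp)
    acc = 0
    for s in sorted(sizes_bp, reverse=True):
        acc += s
        if acc * 2 >= total:
            return s
    return 0


def fragment(
    genome: SegmentGenome,
    n50_target: int,
    min_scaffold: int = 0,
    seed: int | None = None,
    p_chimera: float = 0.0,
) -> tuple[SegmentGenome, dict]:
    """Cut chromosomes at random segment boundaries until N50 <= target.

    Scaffolds shorter than ``min_scaffold`` bp are dropped (logged).  With
    probability ``p_chimera`` per join attempt, two scaffolds from
    different source chromosomes are concatenated and logged as ground-
    truth chimeric artifacts.
    """
    if n50_target < min_scaffold:
        raise ValueError("n50_target must be >= min_scaffold")
    L = genome.segment_length
    rng = np.random.default_rng(seed)
    scaffolds: list[list[int]] = [list(c) for c in genome.chromosomes]
    origins: list[set[str]] = [{name} for name in genome.names]

    while _n50([len(s) * L for s in scaffolds]) > n50_target:
        cuttable = [i for i, s in enumerate(scaffolds) if len(s) >= 2]
        if not cuttable:
            raise ValueError(f"cannot reach N50 <= {n50_target} with {L} bp segments")
        sizes = np.array([len(scaffolds[i]) for i in cuttable], dtype=float)
        pick = cuttable[int(rng.choice(len(cuttable), p=sizes / sizes.sum()))]
        s = scaffolds[pick]
        cut = int(rng.integers(1, len(s)))
        scaffolds[pick] = s[:cut]
        scaffolds.append(s[cut:])
        origins.append(set(origins[pick]))

    chimeras: list[dict] = []
    for _ in range(max(1, len(scaffolds) // 2)):
        if len(scaffolds) < 2 or rng.random() >= p_chimera:
            continue
        candidates = [
            (i, j)
            for i in range(len(scaffolds))
            for j in range(len(scaffolds))
            if i < j and not (origins[i] & origins[j])
        ]
        if not candidates:
            break
        i, j = candidates[int(rng.integers(len(candidates)))]
        junction_bp = len(scaffolds[i]) * L
        scaffolds[i] = scaffolds[i] + scaffolds[j]
        origins[i] |= origins[j]
        del scaffolds[j], origins[j]
        chimeras.append({"scaffold_index": i, "junction_bp": junction_bp})

    dropped: list[int] = []
    kept, kept_origins = [], []
    for s, o in zip(scaffolds, origins):
        if len(s) * L < min_scaffold:
            dropped.extend(abs(x) for x in s)
        else:
            kept.append(s)
            kept_origins.append(o)
    if not kept:
        raise ValueError("min_scaffold drops every scaffold: empty assembly")

    names = [f"scaf{i + 1:05d}" for i in range(len(kept))]
    out = SegmentGenome(chromosomes=kept, names=names, segment_length=L)
    log = {
        "chimeras": [
            {"scaffold": names[c["scaffold_index"]], "junction_bp": c["junction_bp"]}
            for c in chimeras
        ],
        "dropped_segments": sorted(dropped),
        "origins": {name: sorted(o) for name, o in zip(names, kept_origins)},
    }
    return out, log


# ---------------------------------------------------------------------------
# Anchor emission
# ---------------------------------------------------------------------------


def emit_anchors(
    leaf: SegmentGenome,
    reference: SegmentGenome,
    species: str,
    drop_rate: float = 0.0,
    jitter_bp: int = 0,
    seed: int | None = None,
) -> tuple[list[AlignmentAnchor], list[dict]]:
    """One anchor per maximal run of consecutive shared segments.

    A run extends while target segments map to consecutive reference
    positions on one reference chromosome with constant relative
    orientation.  Anchors are then independently dropped with
    ``drop_rate`` and their boundaries shifted by U(-jitter, +jitter),
    clipped to validity; all noise is logged.
    """
    L = leaf.segment_length
    if reference.segment_length != L:
        raise ValueError("segment_length mismatch between leaf and reference")
    rng = np.random.default_rng(seed)
    ref_pos: dict[int, tuple[str, int, int]] = {}
    ref_len: dict[str, int] = {}
    for name, chrom in zip(reference.names, reference.chromosomes):
        ref_len[name] = len(chrom) * L
        for idx, s in enumerate(chrom):
            ref_pos[abs(s)] = (name, idx, 1 if s > 0 else -1)

    anchors: list[AlignmentAnchor] = []
    log: list[dict] = []
    for sname, segs in zip(leaf.names, leaf.chromosomes):
        tgt_len = len(segs) * L
        runs: list[tuple[int, int, str, int, int, int]] = []  # jstart, jend, chrom, imin, imax, orient
        j = 0
        while j < len(segs):
            info = ref_pos.get(abs(segs[j]))
            if info is None:
                j += 1
                continue
            chrom, idx, rsign = info
            orient = (1 if segs[j] > 0 else -1) * rsign
            jstart, imin, imax = j, idx, idx
            while j + 1 < len(segs):
                nxt = ref_pos.get(abs(segs[j + 1]))
                if nxt is None:
                    break
                nchrom, nidx, nrsign = nxt
                norient = (1 if segs[j + 1] > 0 else -1) * nrsign
                if nchrom != chrom or norient != orient or nidx - (imax if orient > 0 else imin) != orient:
                    break
                j += 1
                imin, imax = min(imin, nidx), max(imax, nidx)
            runs.append((jstart, j, chrom, imin, imax, orient))
            j += 1

        for jstart, jend, chrom, imin, imax, orient in runs:
            ref_iv = [imin * L, (imax + 1) * L]
            tgt_iv = [jstart * L, (jend + 1) * L]
            if drop_rate and rng.random() < drop_rate:
                log.append({"action": "dropped", "scaffold": sname, "ref": tuple(ref_iv)})
                continue
            if jitter_bp:
                deltas = rng.integers(-jitter_bp, jitter_bp + 1, size=4)
                ref_iv[0] = int(np.clip(ref_iv[0] + deltas[0], 0, ref_iv[1] - 1))
                ref_iv[1] = int(np.clip(ref_iv[1] + deltas[1], ref_iv[0] + 1, ref_len[chrom]))
                tgt_iv[0] = int(np.clip(tgt_iv[0] + deltas[2], 0, tgt_iv[1] - 1))
                tgt_iv[1] = int(np.clip(tgt_iv[1] + deltas[3], tgt_iv[0] + 1, tgt_len))
                log.append({"action": "jittered", "scaffold": sname, "deltas": deltas.tolist()})
            anchors.append(
                AlignmentAnchor(
                    ref=GenomicInterval(chrom, ref_iv[0], ref_iv[1]),
                    tgt=GenomicInterval(sname, tgt_iv[0], tgt_iv[1]),
                    orientation="+" if orient > 0 else "-",
                    species=species,
                )
            )
    return anchors, log


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


@dataclass
class RecoveryScores:
    n_truth: int
    n_detections: int
    n_truth_matched: int
    n_detections_matched: int
    recall: float | None
    precision: float | None
    branch_accuracy: float | None
    unmatched_detections: list[GenomicInterval] = field(default_factory=list)


def _gap(truth: GenomicInterval, det: GenomicInterval) -> float:
    if truth.seq_id != det.seq_id:
        return math.inf
    if truth.overlaps(det):
        return 0
    return max(truth.start, det.start) - min(truth.end, det.end)


def evaluate_recovery(
    truth: SimTruth,
    detections: Sequence[tuple[GenomicInterval, str, str]],
    tolerance_bp: int,
    include_uncertain: bool = False,
) -> RecoveryScores:
    """Hit-based matching of detected EBRs against true junctions.

    ``detections`` rows are (reference interval, branch id, status).  A
    truth junction is recovered if some detection lies within
    ``tolerance_bp`` (overlap or gap); branch accuracy is scored on each
    recovered junction against its nearest detection.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance must be >= 0")
    dets = [
        (iv, branch)
        for iv, branch, status in detections
        if status == "EBR" or include_uncertain
    ]
    n_truth = len(truth.true_ebrs)
    matched_truth = 0
    correct = 0
    det_hit = [False] * len(dets)
    for t in truth.true_ebrs:
        best_gap, best_i = math.inf, None
        for i, (iv, _branch) in enumerate(dets):
            g = _gap(t.ref, iv)
            if g < best_gap:
                best_gap, best_i = g, i
        if best_i is not None and best_gap <= tolerance_bp:
            matched_truth += 1
            det_hit[best_i] = True
            if dets[best_i][1] == t.branch:
                correct += 1
    # a detection is a true positive if any truth junction is within tolerance
    for i, (iv, _branch) in enumerate(dets):
        if det_hit[i]:
            continue
        for t in truth.true_ebrs:
            if _gap(t.ref, iv) <= tolerance_bp:
                det_hit[i] = True
                break
    n_det_matched = sum(det_hit)
    return RecoveryScores(
        n_truth=n_truth,
        n_detections=len(dets),
        n_truth_matched=matched_truth,
        n_detections_matched=n_det_matched,
        recall=matched_truth / n_truth if n_truth else None,
        precision=n_det_matched / len(dets) if dets else None,
        branch_accuracy=correct / matched_truth if matched_truth else None,
        unmatched_detections=[iv for (iv, _b), hit in zip(dets, det_hit) if not hit],
    )
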