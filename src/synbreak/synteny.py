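"""Chain alignment anchors into syntenic fragments (SFs).

An SF is a run of anchors that is colinear between the reference and one
target sequence at a given resolution.  Consecutive anchors (sorted by
reference position) extend the growing SF iff they

  (i)   hit the same target sequence,
  (ii)  share orientation,
  (iii) advance on the target side in the direction implied by the
        orientation (increasing for ``+``, decreasing for ``-``), and
  (iv)  leave a gap smaller than the resolution on BOTH genomes.

SFs whose reference span falls short of the resolution are discarded, so a
rearrangement smaller than the resolution cannot create a breakpoint.
Candidate SFs from different target sequences may still overlap on the
reference; overlaps are resolved deterministically in favour of the SF
with more aligned bases (ties: the SF starting first), the other being
trimmed back to the winner's boundary and dropped if it no longer reaches
the resolution.

The same chaining logic, applied to gene *ranks* instead of base
coordinates, screens one-to-one ortholog lists for "singleton" and
"out-of-place" genes whose position disagrees with the surrounding gene
order in the second genome.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

from .formats import AlignmentAnchor, GenomicInterval

DEFAULT_RESOLUTIONS = (100_000, 300_000, 500_000)
DEFAULT_MIN_ANCHOR = 1_000


@dataclass(frozen=True)
class SyntenyFragment:
    species: str
    resolution: int
    ref: GenomicInterval
    tgt: GenomicInterval
    orientation: str
    anchor_count: int
    aligned_bp: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in {"+", "-"}:
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")
        if self.anchor_count < 1:
            raise ValueError("anchor_count must be >= 1")


@dataclass(frozen=True)
class OrthologPair:
    gene_id: str
    ref_position: GenomicInterval
    other_position: GenomicInterval


def _chainable(prev: AlignmentAnchor, nxt: AlignmentAnchor, resolution: int) -> bool:
    if prev.ref.seq_id != nxt.ref.seq_id:
        return False
    if prev.tgt.seq_id != nxt.tgt.seq_id or prev.orientation != nxt.orientation:
        return False
    if nxt.ref.start - prev.ref.end >= resolution:
        return False
    if prev.orientation == "+":
        # target must advance rightward
        if nxt.tgt.start < prev.tgt.start:
            return False
        if nxt.tgt.start - prev.tgt.end >= resolution:
            return False
    else:
        # target must advance leftward
        if nxt.tgt.end > prev.tgt.end:
            return False
        if prev.tgt.start - nxt.tgt.end >= resolution:
            return False
    return True


def _close_chain(chain: list[AlignmentAnchor], resolution: int) -> SyntenyFragment:
    ref = GenomicInterval(
        chain[0].ref.seq_id,
        chain[0].ref.start,
        max(a.ref.end for a in chain),
    )
    tgt = GenomicInterval(
        chain[0].tgt.seq_id,
        min(a.tgt.start for a in chain),
        max(a.tgt.end for a in chain),
    )
    return SyntenyFragment(
        species=chain[0].species,
        resolution=resolution,
        ref=ref,
        tgt=tgt,
        orientation=chain[0].orientation,
        anchor_count=len(chain),
        aligned_bp=sum(a.ref.length for a in chain),
    )


def _resolve_overlaps(sfs: list[SyntenyFragment], resolution: int) -> list[SyntenyFragment]:
    """Make SFs pairwise non-overlapping on the reference, deterministically."""
    out = sorted(sfs, key=lambda s: (s.ref.seq_id, s.ref.start, s.ref.end))
    changed = True
    while changed:
        changed = False
        for i in range(len(out) - 1):
            a, b = out[i], out[i + 1]
            if not a.ref.overlaps(b.ref):
                continue
            # winner: more aligned bp, then earlier start, then listed first
            if (b.aligned_bp, -b.ref.start) > (a.aligned_bp, -a.ref.start):
                winner, loser = b, a
            else:
                winner, loser = a, b
            if winner.ref.contains(loser.ref):
                out.remove(loser)
            else:
                if loser.ref.start < winner.ref.start:
                    new_ref = (loser.ref.start, winner.ref.start)
                else:
                    new_ref = (winner.ref.end, loser.ref.end)
                out.remove(loser)
                if new_ref[1] - new_ref[0] >= resolution:
                    trimmed = dataclasses.replace(
                        loser,
                        ref=GenomicInterval(loser.ref.seq_id, new_ref[0], new_ref[1]),
                    )
                    out.append(trimmed)
            out.sort(key=lambda s: (s.ref.seq_id, s.ref.start, s.ref.end))
            changed = True
            break
    return out


def build_sfs(
    anchors: Iterable[AlignmentAnchor],
    resolution: int,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> list[SyntenyFragment]:
    """Chain one species' anchors into syntenic fragments at ``resolution``."""
    if resolution <= 0:
        raise ValueError(f"resolution must be > 0, got {resolution}")
    anchors = list(anchors)
    if not anchors:
        return []
    species = {a.species for a in anchors}
    if len(species) > 1:
        raise ValueError(f"anchors mix species: {sorted(species)}")

    usable = [a for a in anchors if a.ref.length >= min_anchor]
    usable.sort(key=lambda a: (a.ref.seq_id, a.ref.start, a.ref.end, a.tgt.seq_id, a.tgt.start))

    sfs: list[SyntenyFragment] = []
    chain: list[AlignmentAnchor] = []
    for anchor in usable:
        if chain and _chainable(chain[-1], anchor, resolution):
            chain.append(anchor)
        else:
            if chain:
                sfs.append(_close_chain(chain, resolution))
            chain = [anchor]
    if chain:
        sfs.append(_close_chain(chain, resolution))

    sfs = [sf for sf in sfs if sf.ref.length >= resolution]
    return _resolve_overlaps(sfs, resolution)


# ---------------------------------------------------------------------------
# Ortholog gene-order filter
# ---------------------------------------------------------------------------


def _gene_blocks(pairs: Sequence[OrthologPair], resolution_genes: int) -> list[list[int]]:
    """Decompose genes into colinear blocks on gene ranks.

    Genes act as unit-length anchors: a gene extends a block iff it sits on
    the same chromosome pair, continues the block's direction in the other
    genome, and skips at most ``resolution_genes`` intervening ranks on both
    sides.  A block stays open for attachment only while the current gene is
    within that rank window, which lets strict blocks tunnel past isolated
    interlopers (and lets interleaved runs coexist).
    Returns blocks as lists of indices into ``pairs``.
    """
    n = len(pairs)
    ref_order = sorted(range(n), key=lambda i: (pairs[i].ref_position.seq_id, pairs[i].ref_position.start))
    other_order = sorted(range(n), key=lambda i: (pairs[i].other_position.seq_id, pairs[i].other_position.start))
    ref_rank = {idx: r for r, idx in enumerate(ref_order)}
    other_rank = {idx: r for r, idx in enumerate(other_order)}

    open_blocks: list[dict] = []
    closed: list[list[int]] = []
    for idx in ref_order:
        rr, orr = ref_rank[idx], other_rank[idx]
        still_open = []
        for blk in open_blocks:
            if rr - blk["last_rr"] - 1 > resolution_genes:
                closed.append(blk["members"])
            else:
                still_open.append(blk)
        open_blocks = still_open

        attached = False
        # prefer the most recently extended compatible block
        for blk in sorted(open_blocks, key=lambda b: -b["last_rr"]):
            last = pairs[blk["members"][-1]]
            cur = pairs[idx]
            if last.ref_position.seq_id != cur.ref_position.seq_id:
                continue
            if last.other_position.seq_id != cur.other_position.seq_id:
                continue
            step = orr - blk["last_or"]
            if step == 0:
                continue
            direction = 1 if step > 0 else -1
            if blk["dir"] is not None and direction != blk["dir"]:
                continue
            if abs(step) - 1 > resolution_genes:
                continue
            blk["members"].append(idx)
            blk["last_rr"] = rr
            blk["last_or"] = orr
            if blk["dir"] is None:
                blk["dir"] = direction
            attached = True
            break
        if not attached:
            open_blocks.append({"members": [idx], "last_rr": rr, "last_or": orr, "dir": None})
    closed.extend(blk["members"] for blk in open_blocks)
    return closed


def filter_ortholog_genes(
    pairs: Sequence[OrthologPair],
    resolution_genes: int = 1,
) -> tuple[list[OrthologPair], list[tuple[OrthologPair, str]]]:
    """Partition ortholog pairs into (kept, removed) by gene-order congruence.

    Removed genes are singletons (blocks of size 1) — those falling inside
    the reference span of a kept block are labelled ``out-of-place``, the
    rest ``singleton``.  kept + removed = input, disjoint.
    """
    pairs = list(pairs)
    ids = [p.gene_id for p in pairs]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate gene_id(s): {', '.join(dupes)}")
    if not pairs:
        return [], []

    blocks = _gene_blocks(pairs, resolution_genes)
    kept_idx = sorted(i for blk in blocks if len(blk) >= 2 for i in blk)
    removed_idx = sorted(i for blk in blocks if len(blk) < 2 for i in blk)

    kept = [pairs[i] for i in kept_idx]
    kept_spans = []
    for blk in blocks:
        if len(blk) < 2:
            continue
        chrom = pairs[blk[0]].ref_position.seq_id
        lo = min(pairs[i].ref_position.start for i in blk)
        hi = max(pairs[i].ref_position.end for i in blk)
        kept_spans.append((chrom, lo, hi))

    removed: list[tuple[OrthologPair, str]] = []
    for i in removed_idx:
        p = pairs[i]
        inside = any(
            chrom == p.ref_position.seq_id and lo < p.ref_position.start and p.ref_position.end < hi
            for chrom, lo, hi in kept_spans
        )
        removed.append((p, "out-of-place" if inside else "singleton"))
    return kept, removed
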