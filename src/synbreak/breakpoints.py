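"""Breakpoint regions (BRs): derivation, cross-species grouping, translation.

A BR is the reference-coordinate gap between two adjacent SFs on one
reference chromosome for one species.  Chromosome ends are not BRs.  SFs
that abut exactly still represent a rearrangement junction; such
zero-length gaps are kept as 1 bp point BRs.

BRs from all species are grouped by single-linkage overlap (>= 1 bp shared)
on the reference.  Within a group each species is scored

* ``present``  — it contributes a BR eligible for EBR status: the BR lies
  within one scaffold, or the species is assembled to chromosomes;
* ``unknown``  — its BR spans a scaffold join (unobservable), or it has
  insufficient SF coverage of the group's flanks (missing data);
* ``absent``   — it has SF coverage over the locus but no breakpoint.

The representative interval of a group is the intersection of its member
BRs when non-empty (the conservative shared locus), else their union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .formats import GenomicInterval
from .synteny import SyntenyFragment

DEFAULT_FLANK = 100_000
DEFAULT_MIN_COVERAGE = 0.5


@dataclass(frozen=True)
class BreakpointRegion:
    species: str
    ref: GenomicInterval
    left_sf: SyntenyFragment
    right_sf: SyntenyFragment
    within_scaffold: bool
    resolution: int


@dataclass
class BRGroup:
    group_id: str
    ref: GenomicInterval
    members: dict[str, BreakpointRegion]
    pattern: dict[str, str]  # species -> present | absent | unknown
    representative_type: str = "intersection"  # or "union"
    resolution: int = 0
    notes: str = field(default="")


def derive_brs(
    sfs: Sequence[SyntenyFragment],
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[BreakpointRegion]:
    """One BR per adjacent SF pair on each reference chromosome."""
    if not sfs:
        return []
    species = {sf.species for sf in sfs}
    if len(species) > 1:
        raise ValueError(f"SFs mix species: {sorted(species)}")
    resolution = sfs[0].resolution

    by_chrom: dict[str, list[SyntenyFragment]] = {}
    for sf in sfs:
        by_chrom.setdefault(sf.ref.seq_id, []).append(sf)

    brs: list[BreakpointRegion] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda s: (s.ref.start, s.ref.end))
        for left, right in zip(ordered, ordered[1:]):
            if right.ref.start < left.ref.end:
                raise ValueError(
                    f"overlapping SFs on {chrom}: [{left.ref.start},{left.ref.end}) "
                    f"and [{right.ref.start},{right.ref.end})"
                )
            start, end = left.ref.end, right.ref.start
            if end == start:
                end = start + 1  # point BR for exactly abutting SFs
            brs.append(
                BreakpointRegion(
                    species=left.species,
                    ref=GenomicInterval(chrom, start, end),
                    left_sf=left,
                    right_sf=right,
                    within_scaffold=left.tgt.seq_id == right.tgt.seq_id,
                    resolution=resolution,
                )
            )
    return brs


def _coverage_fraction(
    iv_start: int,
    iv_end: int,
    chrom: str,
    intervals: Sequence[GenomicInterval],
    chrom_size: int | None = None,
) -> float:
    # clip the probe window to the chromosome; absent sequence is no evidence
    iv_start = max(iv_start, 0)
    if chrom_size is not None:
        iv_end = min(iv_end, chrom_size)
    if iv_end <= iv_start:
        return 1.0
    covered = 0
    for iv in intervals:
        if iv.seq_id != chrom:
            continue
        lo, hi = max(iv.start, iv_start), min(iv.end, iv_end)
        if hi > lo:
            covered += hi - lo
    return covered / (iv_end - iv_start)


def group_brs(
    brs_by_species: Mapping[str, Sequence[BreakpointRegion]],
    chromosome_level_species: Iterable[str] = (),
    sf_by_species: Mapping[str, Sequence[GenomicInterval]] | None = None,
    flank: int = DEFAULT_FLANK,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[BRGroup]:
    """Group BRs across species by single-linkage reference overlap."""
    chromosome_level = set(chromosome_level_species)
    all_brs: list[BreakpointRegion] = []
    resolutions = set()
    for sp, brs in brs_by_species.items():
        for br in brs:
            resolutions.add(br.resolution)
            all_brs.append(br)
    if len(resolutions) > 1:
        raise ValueError(f"mixed resolutions: {sorted(resolutions)}")
    resolution = resolutions.pop() if resolutions else 0

    # single-linkage clustering by sweep over sorted intervals
    all_brs.sort(key=lambda b: (b.ref.seq_id, b.ref.start, b.ref.end, b.species))
    clusters: list[list[BreakpointRegion]] = []
    cur: list[BreakpointRegion] = []
    cur_chrom, cur_end = None, -1
    for br in all_brs:
        if cur and br.ref.seq_id == cur_chrom and br.ref.start < cur_end:
            cur.append(br)
            cur_end = max(cur_end, br.ref.end)
        else:
            if cur:
                clusters.append(cur)
            cur = [br]
            cur_chrom, cur_end = br.ref.seq_id, br.ref.end
    if cur:
        clusters.append(cur)

    species_all = sorted(brs_by_species)
    groups: list[BRGroup] = []
    for n, cluster in enumerate(clusters, start=1):
        members: dict[str, BreakpointRegion] = {}
        for br in cluster:
            prev = members.get(br.species)
            # nested/overlapping BRs of one species in a group: keep the smallest
            if prev is None or br.ref.length < prev.ref.length or (
                br.ref.length == prev.ref.length and br.ref.start < prev.ref.start
            ):
                members[br.species] = br

        chrom = cluster[0].ref.seq_id
        inter_lo = max(br.ref.start for br in members.values())
        inter_hi = min(br.ref.end for br in members.values())
        if inter_hi > inter_lo:
            rep = GenomicInterval(chrom, inter_lo, inter_hi)
            rep_type = "intersection"
        else:
            rep = GenomicInterval(
                chrom,
                min(br.ref.start for br in members.values()),
                max(br.ref.end for br in members.values()),
            )
            rep_type = "union"

        pattern: dict[str, str] = {}
        for sp in species_all:
            if sp in members:
                eligible = members[sp].within_scaffold or sp in chromosome_level
                pattern[sp] = "present" if eligible else "unknown"
            else:
                if sf_by_species is None:
                    pattern[sp] = "absent"
                else:
                    ivs = sf_by_species.get(sp, ())
                    size = chrom_sizes.get(chrom) if chrom_sizes else None
                    left_cov = _coverage_fraction(rep.start - flank, rep.start, chrom, ivs, size)
                    right_cov = _coverage_fraction(rep.end, rep.end + flank, chrom, ivs, size)
                    ok = left_cov >= min_coverage and right_cov >= min_coverage
                    pattern[sp] = "absent" if ok else "unknown"

        groups.append(
            BRGroup(
                group_id=f"g{n:05d}",
                ref=rep,
                members=members,
                pattern=pattern,
                representative_type=rep_type,
                resolution=resolution,
            )
        )
    return groups


def translate_ebr(br: BreakpointRegion) -> GenomicInterval:
    """Translate a within-scaffold BR into target-genome coordinates.

    The target-side boundary of each flanking SF depends on its
    orientation: the ``+`` SF's relevant end is ``tgt.end``; the ``-``
    SF's is ``tgt.start`` (left flank), and symmetrically for the right
    flank.  The returned interval is normalised to start < end.
    """
    if not br.within_scaffold:
        raise ValueError(
            f"BR {br.ref} flanked by SFs on different target sequences "
            f"({br.left_sf.tgt.seq_id!r} vs {br.right_sf.tgt.seq_id!r})"
        )
    left = br.left_sf.tgt.end if br.left_sf.orientation == "+" else br.left_sf.tgt.start
    right = br.right_sf.tgt.start if br.right_sf.orientation == "+" else br.right_sf.tgt.end
    lo, hi = min(left, right), max(left, right)
    if hi == lo:
        hi = lo + 1  # abutting target boundaries: point junction
    return GenomicInterval(br.left_sf.tgt.seq_id, lo, hi)
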