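import numpy as np
import pytest

from synbreak.formats import GenomicInterval
from synbreak.synteny import OrthologPair, build_sfs, filter_ortholog_genes
from tests.conftest import make_anchor


def brute_force_sfs(anchors, resolution):
    """Independent chain enumerator for small, reference-disjoint anchor sets.

    Sorts by reference position and splits runs wherever any of the four
    merge conditions (target sequence, orientation, target order, dual gap
    bound) fails; reports reference spans of runs >= resolution.
    """
    out = []
    ordered = sorted(anchors, key=lambda a: (a.ref.seq_id, a.ref.start))
    run = []
    for a in ordered:
        ok = False
        if run:
            p = run[-1]
            same = (
                p.ref.seq_id == a.ref.seq_id
                and p.tgt.seq_id == a.tgt.seq_id
                and p.orientation == a.orientation
            )
            if same and a.ref.start - p.ref.end < resolution:
                if a.orientation == "+":
                    ok = a.tgt.start >= p.tgt.start and a.tgt.start - p.tgt.end < resolution
                else:
                    ok = a.tgt.end <= p.tgt.end and p.tgt.start - a.tgt.end < resolution
        if ok:
            run.append(a)
        else:
            if run:
                out.append(run)
            run = [a]
    if run:
        out.append(run)
    spans = []
    for r in out:
        lo, hi = r[0].ref.start, max(x.ref.end for x in r)
        if hi - lo >= resolution:
            spans.append((r[0].ref.seq_id, lo, hi, r[0].orientation, len(r)))
    return spans


class TestBuildSfs:
    def test_colinear_merge(self):
        anchors = [
            make_anchor("chr1", 0, 50_000, "scafA", 0, 50_000),
            make_anchor("chr1", 50_000, 120_000, "scafA", 50_000, 120_000),
        ]
        (sf,) = build_sfs(anchors, resolution=100_000, min_anchor=1)
        assert (sf.ref.start, sf.ref.end) == (0, 120_000)
        assert sf.orientation == "+" and sf.anchor_count == 2

    def test_orientation_break_splits(self):
        anchors = [
            make_anchor("chr1", 0, 200_000, "scafA", 0, 200_000, "+"),
            make_anchor("chr1", 200_000, 400_000, "scafA", 200_000, 400_000, "-"),
        ]
        sfs = build_sfs(anchors, resolution=100_000, min_anchor=1)
        assert len(sfs) == 2
        assert {sf.orientation for sf in sfs} == {"+", "-"}

    def test_below_resolution_discarded(self):
        anchors = [make_anchor("chr1", 0, 80_000, "scafA", 0, 80_000)]
        assert build_sfs(anchors, resolution=100_000, min_anchor=1) == []

    def test_negative_orientation_chain(self):
        # target decreasing for a "-" block
        anchors = [
            make_anchor("chr1", 0, 60_000, "scafA", 140_000, 200_000, "-"),
            make_anchor("chr1", 60_000, 120_000, "scafA", 80_000, 140_000, "-"),
        ]
        (sf,) = build_sfs(anchors, resolution=100_000, min_anchor=1)
        assert sf.anchor_count == 2 and sf.orientation == "-"
        assert (sf.tgt.start, sf.tgt.end) == (80_000, 200_000)

    def test_target_gap_breaks_chain(self):
        anchors = [
            make_anchor("chr1", 0, 150_000, "scafA", 0, 150_000),
            make_anchor("chr1", 150_000, 300_000, "scafA", 500_000, 650_000),
        ]
        sfs = build_sfs(anchors, resolution=100_000, min_anchor=1)
        assert len(sfs) == 2  # 350 kb target-side jump despite adjacency on reference

    def test_min_anchor_filters_micro_matches(self):
        anchors = [
            make_anchor("chr1", 0, 150_000, "scafA", 0, 150_000),
            make_anchor("chr1", 150_000, 150_500, "scafB", 0, 500),
        ]
        sfs = build_sfs(anchors, resolution=100_000, min_anchor=1_000)
        assert len(sfs) == 1 and sfs[0].tgt.seq_id == "scafA"

    def test_mixed_species_rejected(self):
        anchors = [
            make_anchor("chr1", 0, 150_000, "s", 0, 150_000, species="x"),
            make_anchor("chr1", 200_000, 350_000, "s", 0, 150_000, species="y"),
        ]
        with pytest.raises(ValueError, match="species"):
            build_sfs(anchors, resolution=100_000)
        with pytest.raises(ValueError, match="resolution"):
            build_sfs(anchors[:1], resolution=0)

    def test_input_order_invariance(self, rng):
        anchors = _random_anchors(rng, 40)
        sfs = build_sfs(anchors, resolution=50_000, min_anchor=1)
        for _ in range(5):
            perm = [anchors[i] for i in rng.permutation(len(anchors))]
            assert build_sfs(perm, resolution=50_000, min_anchor=1) == sfs

    def test_non_overlap_invariant(self, rng):
        for _ in range(20):
            sfs = build_sfs(_random_anchors(rng, 60), resolution=30_000, min_anchor=1)
            ordered = sorted(sfs, key=lambda s: (s.ref.seq_id, s.ref.start))
            for a, b in zip(ordered, ordered[1:]):
                assert not a.ref.overlaps(b.ref)
                assert a.ref.length >= 30_000

    def test_resolution_monotonicity(self, rng):
        """Coarse SFs live inside the union of fine-resolution SF intervals.

        Holds whenever anchor gaps stay below the finer resolution (with
        larger gaps a coarse block legitimately bridges sequence that the
        finer scale does not call syntenic)."""
        for _ in range(10):
            anchors = _random_dense_anchors(rng, 80, max_gap=15_000)
            fine = build_sfs(anchors, resolution=20_000, min_anchor=1)
            coarse = build_sfs(anchors, resolution=100_000, min_anchor=1)
            fine_ivs = [sf.ref for sf in fine]
            for sf in coarse:
                covered = sum(
                    min(iv.end, sf.ref.end) - max(iv.start, sf.ref.start)
                    for iv in fine_ivs
                    if iv.seq_id == sf.ref.seq_id and iv.overlaps(sf.ref)
                )
                assert covered == sf.ref.length

    def test_matches_brute_force_on_disjoint_anchors(self, rng):
        for _ in range(30):
            anchors = _random_disjoint_anchors(rng, int(rng.integers(1, 20)))
            got = build_sfs(anchors, resolution=40_000, min_anchor=1)
            want = brute_force_sfs(anchors, resolution=40_000)
            assert [
                (s.ref.seq_id, s.ref.start, s.ref.end, s.orientation, s.anchor_count)
                for s in sorted(got, key=lambda s: (s.ref.seq_id, s.ref.start))
            ] == sorted(want)


def _random_anchors(rng, n):
    anchors = []
    for _ in range(n):
        chrom = f"chr{int(rng.integers(1, 3))}"
        start = int(rng.integers(0, 2_000_000))
        length = int(rng.integers(5_000, 60_000))
        tstart = int(rng.integers(0, 2_000_000))
        anchors.append(
            make_anchor(
                chrom, start, start + length,
                f"scaf{int(rng.integers(1, 4))}", tstart, tstart + length,
                "+" if rng.random() < 0.5 else "-",
            )
        )
    return anchors


def _random_dense_anchors(rng, n, max_gap):
    """Reference-contiguous anchors whose gaps never exceed ``max_gap``."""
    anchors, pos, tpos = [], 0, 0
    for _ in range(n):
        pos += int(rng.integers(0, max_gap))
        length = int(rng.integers(5_000, 60_000))
        # occasional target-side discontinuity, large enough to break
        # chains at every resolution under test
        if rng.random() < 0.3:
            tpos += 150_000 + int(rng.integers(0, 500_000))
        anchors.append(
            make_anchor(
                "chr1", pos, pos + length,
                f"scaf{int(rng.integers(1, 3))}", tpos, tpos + length,
                "+" if rng.random() < 0.7 else "-",
            )
        )
        pos += length
        tpos += length + int(rng.integers(0, max_gap))
    return anchors


def _random_disjoint_anchors(rng, n):
    """Reference-disjoint anchors (no overlap trimming involved)."""
    anchors, pos = [], 0
    for _ in range(n):
        pos += int(rng.integers(1_000, 80_000))
        length = int(rng.integers(5_000, 60_000))
        tstart = int(rng.integers(0, 1_000_000))
        anchors.append(
            make_anchor(
                "chr1", pos, pos + length,
                f"scaf{int(rng.integers(1, 3))}", tstart, tstart + length,
                "+" if rng.random() < 0.5 else "-",
            )
        )
        pos += length
    return anchors


def _pairs(spec):
    """spec rows: (gene, ref_chrom, ref_pos, other_chrom, other_pos)"""
    return [
        OrthologPair(
            g,
            GenomicInterval(rc, rp, rp + 1_000),
            GenomicInterval(oc, op, op + 1_000),
        )
        for g, rc, rp, oc, op in spec
    ]


class TestOrthologFilter:
    def test_perfectly_colinear_keeps_all(self):
        pairs = _pairs([(f"g{i}", "chr1", i * 10_000, "hchr1", i * 10_000) for i in range(5)])
        kept, removed = filter_ortholog_genes(pairs)
        assert len(kept) == 5 and removed == []

    def test_off_chromosome_singleton_removed(self):
        spec = [(f"g{i}", "chr1", i * 10_000, "hchr1", i * 10_000) for i in range(5)]
        spec.insert(3, ("odd", "chr1", 25_000, "hchr9", 500_000))
        kept, removed = filter_ortholog_genes(_pairs(spec))
        assert {p.gene_id for p in kept} == {f"g{i}" for i in range(5)}
        ((gene, reason),) = [removed[0]]
        assert gene.gene_id == "odd" and reason == "out-of-place"

    def test_interleaved_runs_both_kept(self):
        # A1 B1 A2 B2 A3 B3 on the reference; each run colinear in the other genome
        spec = []
        for i in range(3):
            spec.append((f"a{i}", "chr1", (2 * i) * 10_000, "hchr1", i * 10_000))
            spec.append((f"b{i}", "chr1", (2 * i + 1) * 10_000, "hchr2", i * 10_000))
        kept, removed = filter_ortholog_genes(_pairs(spec))
        assert removed == [] and len(kept) == 6

    def test_duplicate_gene_id_rejected(self):
        pairs = _pairs([("g", "chr1", 0, "h", 0), ("g", "chr1", 10_000, "h", 10_000)])
        with pytest.raises(ValueError, match="duplicate"):
            filter_ortholog_genes(pairs)

    def test_partition_is_exact(self, rng):
        spec = [
            (f"g{i}", "chr1", i * 10_000, f"hchr{int(rng.integers(1, 4))}", int(rng.integers(0, 10**6)))
            for i in range(30)
        ]
        pairs = _pairs(spec)
        kept, removed = filter_ortholog_genes(pairs)
        assert len(kept) + len(removed) == len(pairs)
        assert {p.gene_id for p in kept}.isdisjoint({p.gene_id for p, _ in removed})

    def test_reversed_block_kept(self):
        # a run colinear in decreasing other-genome order is still a block
        spec = [(f"g{i}", "chr1", i * 10_000, "hchr1", (10 - i) * 10_000) for i in range(5)]
        kept, removed = filter_ortholog_genes(_pairs(spec))
        assert removed == [] and len(kept) == 5
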