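"""Collinearity chaining against a brute-force oracle, and depth profiles."""

import itertools
import random

import pytest

from tests.conftest import make_genome
from wgdscape.synteny import (
    AnchorPair,
    SyntenicBlock,
    chain_anchors,
    self_synteny,
    syntenic_depth,
)


def A(ra, rb, score=10.0, ca="c1", cb="c2"):
    return AnchorPair(
        gene_a=f"a{ra}", gene_b=f"b{rb}", rank_a=ra, rank_b=rb,
        chrom_a=ca, chrom_b=cb, score=score,
    )


def test_diagonal_chain():
    blocks = chain_anchors([A(1, 1), A(2, 2), A(3, 3)], min_anchors=3)
    assert len(blocks) == 1
    assert blocks[0].orientation == "same"
    assert len(blocks[0]) == 3


def test_inverted_chain():
    blocks = chain_anchors([A(1, 5), A(2, 4), A(3, 3)], min_anchors=3)
    assert len(blocks) == 1
    assert blocks[0].orientation == "inverted"
    assert [a.rank_b for a in blocks[0].anchors] == [5, 4, 3]


def test_min_anchors_discards_short_chains():
    assert chain_anchors([A(1, 1), A(2, 2)], min_anchors=3) == []


def test_max_gap_breaks_chain():
    anchors = [A(1, 1), A(2, 2), A(40, 40), A(41, 41)]
    blocks = chain_anchors(anchors, min_anchors=2, max_gap=5)
    assert {len(b) for b in blocks} == {2}
    assert len(blocks) == 2


def brute_force_best_chain(anchors, max_gap, gap_penalty=1.0):
    """Max-scoring collinear chain by exhaustive subset enumeration."""
    n = len(anchors)
    best = 0.0
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            chain = sorted((anchors[i] for i in combo), key=lambda a: a.rank_a)
            for sign in (1, -1):
                ok = True
                score = chain[0].score
                for prev, cur in zip(chain, chain[1:]):
                    da = cur.rank_a - prev.rank_a
                    db = sign * (cur.rank_b - prev.rank_b)
                    if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                        ok = False
                        break
                    score += cur.score - gap_penalty * ((da - 1) + (db - 1))
                if ok:
                    best = max(best, score)
    return best


@pytest.mark.parametrize("seed", range(6))
def test_chaining_equals_brute_force(seed):
    """DP chain score equals exhaustive enumeration on <=12-anchor instances."""
    rng = random.Random(seed)
    n = rng.randint(6, 12)
    anchors = []
    used = set()
    while len(anchors) < n:
        ra, rb = rng.randint(0, 20), rng.randint(0, 20)
        if (ra, rb) in used:
            continue
        used.add((ra, rb))
        anchors.append(A(ra, rb, score=rng.choice([5.0, 10.0, 20.0])))
    max_gap = rng.choice([5, 10, 25])
    blocks = chain_anchors(anchors, min_anchors=1, max_gap=max_gap)
    top = max((b.chain_score for b in blocks), default=0.0)
    assert top == pytest.approx(brute_force_best_chain(anchors, max_gap))


def test_decoy_does_not_join_chain():
    anchors = [A(i, i) for i in range(1, 13)] + [A(6, 18)]
    blocks = chain_anchors(anchors, min_anchors=3, max_gap=5)
    assert len(blocks[0]) == 12
    assert all(a.rank_a == a.rank_b for a in blocks[0].anchors)


def test_unknown_gene_id_error():
    genome = make_genome([("a1", "c1", 100, 200)])
    with pytest.raises(KeyError, match="a9"):
        chain_anchors([A(9, 9)], genome, genome)


def test_chain_score_invariant_under_relabeling():
    anchors = [A(1, 1), A(2, 2), A(3, 3), A(5, 4)]
    relabeled = [
        AnchorPair(f"x{a.rank_a}", f"y{a.rank_b}", a.rank_a, a.rank_b,
                   a.chrom_a, a.chrom_b, a.score)
        for a in anchors
    ]
    b1 = chain_anchors(anchors, min_anchors=2)
    b2 = chain_anchors(relabeled, min_anchors=2)
    assert [b.chain_score for b in b1] == [b.chain_score for b in b2]


# --------------------------------------------------------------------------
# self-synteny
# --------------------------------------------------------------------------


def _dup_segment_genome(n=10):
    """A chromosome with a perfectly duplicated 10-gene segment."""
    specs = []
    for i in range(2 * n):
        specs.append((f"g{i}", "chr1", 1000 * i + 1, 1000 * i + 500))
    return make_genome(specs)


def test_duplicated_segment_yields_single_block():
    n = 10
    genome = _dup_segment_genome(n)
    anchors = []
    for i in range(n):
        g1, g2 = genome.genes[i], genome.genes[i + n]
        anchors.append(AnchorPair(g1.gene_id, g2.gene_id, g1.rank, g2.rank,
                                  "chr1", "chr1", 50.0))
        # mirror duplicate of the same match
        anchors.append(AnchorPair(g2.gene_id, g1.gene_id, g2.rank, g1.rank,
                                  "chr1", "chr1", 50.0))
    blocks = self_synteny(genome, anchors)
    assert len(blocks) == 1
    assert len(blocks[0]) == n


def test_no_duplication_no_blocks():
    genome = _dup_segment_genome(10)
    assert self_synteny(genome, []) == []


def test_tandem_adjacent_anchors_excluded():
    genome = _dup_segment_genome(10)
    g = genome.genes
    anchors = [AnchorPair(g[i].gene_id, g[i + 1].gene_id, i, i + 1,
                          "chr1", "chr1", 50.0) for i in range(8)]
    assert self_synteny(genome, anchors, min_anchors=2) == []


def test_simulated_blocks_satisfy_invariants(small_sim):
    """Blocks chained from true WGD pairs are collinear and non-mirrored."""
    from wgdscape.synteny import anchors_from_pairs
    from wgdscape.genome_io import HomologyPair

    pairs = [
        HomologyPair(r.gene_a, r.gene_b, 90.0, 1e-50, 100.0, 100)
        for r in small_sim.truth.pairs.itertuples()
        if r.origin.startswith("WGD")
    ]
    blocks = self_synteny(small_sim.genome, pairs)
    assert blocks, "expected at least one self-syntenic block"
    seen_spans = set()
    for b in blocks:
        # constructor re-checks monotonicity; mirror check via canonical span
        key = (b.chrom_a, b.span_a, b.chrom_b, b.span_b)
        mirror = (b.chrom_b, b.span_b, b.chrom_a, b.span_a)
        assert mirror not in seen_spans
        seen_spans.add(key)
        assert (b.chrom_a, b.span_a[0]) <= (b.chrom_b, b.span_b[0])


# --------------------------------------------------------------------------
# syntenic depth
# --------------------------------------------------------------------------


def _block(anchors, block_id="b1"):
    return SyntenicBlock(anchors=tuple(anchors), orientation="same",
                         chain_score=1.0, block_id=block_id)


def test_single_block_depth_one():
    genome_b = make_genome(
        [(f"b{i}", "c2", 1000 * i + 1, 1000 * i + 500) for i in range(1, 11)]
    )
    block = _block([A(1, 1), A(5, 5), A(10, 9)])
    profile = syntenic_depth([block], genome_b, side="b")
    covered = [g for g, d in profile.depth.items() if d == 1]
    assert profile.modal_depth == 1
    assert len(covered) == 9  # ranks 1..9 inclusive


def test_doubling_doubles_modal_depth():
    """A perfect in-silico WGD doubles modal depth against a fixed outgroup."""
    outgroup = make_genome(
        [(f"o{i}", "out1", 1000 * i + 1, 1000 * i + 500) for i in range(20)]
    )
    one_copy = [_block([A(i, i, ca="c1", cb="out1") for i in range(20)], "b1")]
    two_copies = one_copy + [
        _block([AnchorPair(f"d{i}", f"o{i}", i, i, "c1dup", "out1", 10.0)
                for i in range(20)], "b2")
    ]
    d1 = syntenic_depth(one_copy, outgroup, side="b").modal_depth
    d2 = syntenic_depth(two_copies, outgroup, side="b").modal_depth
    assert (d1, d2) == (1, 2)
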