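"""Ka/Ks (NG86) and 4dTv against independent oracles.

The NG86 oracle below is a from-scratch second implementation: its codon
table comes from a hard-coded lookup string and its pathway enumeration is
written independently of the library's cached tables.
"""

import itertools
import math
import random

import pytest

from wgdscape.kaks import KsRecord, block_ks, codon_align, fourdtv, ng86, pair_divergence

# independent genetic code (TCAG order)
_AA64 = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODE = {
    b1 + b2 + b3: _AA64[16 * i + 4 * j + k]
    for i, b1 in enumerate("TCAG")
    for j, b2 in enumerate("TCAG")
    for k, b3 in enumerate("TCAG")
}
NON_STOP = sorted(c for c, aa in CODE.items() if aa != "*")


def oracle_ng86(codon_pairs):
    """Brute-force NG86: per-position site fractions and exhaustive
    enumeration of minimal substitution pathways (stop-avoiding)."""

    def sites(codon):
        s = 0.0
        for pos in range(3):
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1 :]
                if CODE[mut] != "*" and CODE[mut] == CODE[codon]:
                    s += 1 / 3
        return s

    def diffs(c1, c2):
        pos = [i for i in range(3) if c1[i] != c2[i]]
        if not pos:
            return 0.0, 0.0
        paths, all_paths = [], []
        for order in itertools.permutations(pos):
            cur, sd, nd, stop = c1, 0, 0, False
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if CODE[nxt] == "*":
                    stop = True
                    nd += 1
                elif CODE[nxt] == CODE[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            all_paths.append((sd, nd))
            if not stop:
                paths.append((sd, nd))
        use = paths or all_paths
        return (sum(p[0] for p in use) / len(use),
                sum(p[1] for p in use) / len(use))

    S = sum((sites(a) + sites(b)) / 2 for a, b in codon_pairs)
    Sd = sum(diffs(a, b)[0] for a, b in codon_pairs)
    ps = Sd / S if S else None
    if ps is None or ps >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * ps / 3) if ps else 0.0


def random_codons(n, rng):
    return [rng.choice(NON_STOP) for _ in range(n)]


def diverge(codons, n_changes, rng):
    out = list(codons)
    for _ in range(n_changes):
        i = rng.randrange(len(out))
        pos = rng.randrange(3)
        alt = rng.choice([b for b in "ACGT" if b != out[i][pos]])
        cand = out[i][:pos] + alt + out[i][pos + 1 :]
        if CODE[cand] != "*":
            out[i] = cand
    return out


# --------------------------------------------------------------------------
# codon alignment
# --------------------------------------------------------------------------


def test_identical_cds_align_without_gaps():
    cds = "ATGAAATTTGGGCCCAGATTGGGGCAA"
    codons = codon_align(cds, cds)
    assert len(codons) == len(cds) // 3
    assert all(a == b for a, b in codons)


def test_single_codon_deletion_one_gap():
    a = "ATGAAATTTGGGCCCAAATTGCAA"  # 8 codons
    b = a[:12] + a[15:]  # drop codon 5 (CCC)
    codons = codon_align(a, b)
    assert len(codons) == 7
    assert [x for x, _ in codons] == [a[i:i + 3] for i in range(0, 24, 3) if i != 12]


def test_codon_with_n_excluded():
    a = "ATGAAATTTGGG"
    b = "ATGAANTTTGGG"
    codons = codon_align(a, b)
    assert len(codons) == 3
    assert ("AAA", "AAN") not in codons


# --------------------------------------------------------------------------
# NG86
# --------------------------------------------------------------------------


def test_identical_sequences_zero_divergence():
    rng = random.Random(0)
    codons = [(c, c) for c in random_codons(20, rng)]
    r = ng86(codons)
    assert r["ka"] == 0.0 and r["ks"] == 0.0


def test_phe_synonymous_difference_matches_oracle():
    # TTT<->TTC (Phe/Phe) in a context of ten leucine CTG codons
    codons = [("TTT", "TTC")] + [("CTG", "CTG")] * 10
    r = ng86(codons)
    assert r["Sd"] == pytest.approx(1.0)
    assert r["Nd"] == pytest.approx(0.0)
    assert r["ks"] == pytest.approx(oracle_ng86(codons), abs=1e-12)


def test_saturated_ps_undefined_not_zero():
    codons = [("TTT", "TTC")]  # Sd=1 over S=1/3 -> ps = 3
    r = ng86(codons)
    assert r["ks"] is None
    assert "ks saturated" in r["flags"]


@pytest.mark.parametrize("seed", range(8))
def test_ng86_matches_pathway_enumeration_oracle(seed):
    rng = random.Random(seed)
    a = random_codons(30, rng)
    b = diverge(a, rng.randint(1, 12), rng)
    codons = list(zip(a, b))
    got = ng86(codons)["ks"]
    want = oracle_ng86(codons)
    if want is None:
        assert got is None
    else:
        assert got == pytest.approx(want, abs=1e-12)


try:
    from hypothesis import given, settings, strategies as st

    codon_pairs = st.lists(
        st.tuples(st.sampled_from(NON_STOP), st.sampled_from(NON_STOP)),
        min_size=1, max_size=30,
    )

    @given(codon_pairs)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_ng86_symmetry_property(pairs):
        """ng86(a,b) == ng86(b,a) exactly, for arbitrary codon alignments."""
        fwd = ng86(pairs)
        rev = ng86([(b, a) for a, b in pairs])
        assert fwd["ks"] == rev["ks"]
        assert fwd["ka"] == rev["ka"]

    @given(codon_pairs)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_corrected_fourdtv_never_below_raw(pairs):
        r = fourdtv(pairs)
        if r["corrected"] is not None:
            assert r["corrected"] >= r["raw"] - 1e-12

except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


def test_ng86_symmetry_exact():
    rng = random.Random(99)
    a = random_codons(25, rng)
    b = diverge(a, 8, rng)
    fwd = ng86(list(zip(a, b)))
    rev = ng86(list(zip(b, a)))
    assert fwd["ks"] == rev["ks"] and fwd["ka"] == rev["ka"]


def test_jc_correction_inflates():
    rng = random.Random(5)
    a = random_codons(50, rng)
    b = diverge(a, 25, rng)
    r = ng86(list(zip(a, b)))
    if r["ks"] is not None:
        assert r["ks"] >= r["ps"]
    if r["ka"] is not None:
        assert r["ka"] >= r["pn"]


# --------------------------------------------------------------------------
# 4dTv
# --------------------------------------------------------------------------


def test_fourdtv_identical_zero():
    codons = [("GGA", "GGA"), ("GGT", "GGT"), ("CTC", "CTC"), ("GTG", "GTG")]
    r = fourdtv(codons)
    assert r["raw"] == 0.0 and r["corrected"] == 0.0
    assert r["n_4d_sites"] == 4


def test_fourdtv_closed_form_quarter():
    # 8 fourfold sites, 2 transversions, pooled purine fraction exactly 1/2:
    # corrected = -0.5 ln(1 - 0.25/0.5) = -0.5 ln(0.5)
    codons = [
        ("GGA", "GGT"), ("GGT", "GGA"),  # transversions (A/T thirds)
        ("GGG", "GGG"), ("GGG", "GGG"),
        ("GGC", "GGC"), ("GGC", "GGC"),
        ("GGA", "GGA"), ("GGT", "GGT"),
    ]
    r = fourdtv(codons)
    assert r["raw"] == pytest.approx(0.25)
    assert r["corrected"] == pytest.approx(-0.5 * math.log(0.5), abs=1e-12)


def test_fourdtv_saturation_undefined():
    codons = [("GGA", "GGT"), ("GGT", "GGA"), ("GGA", "GGC"), ("GGC", "GGA")]
    r = fourdtv(codons)
    assert r["raw"] == 1.0
    assert r["corrected"] is None


def test_fourdtv_requires_matching_fourfold_prefix():
    # TTT is not fourfold-degenerate; AAA neither
    r = fourdtv([("TTT", "TTC"), ("AAA", "AAG")])
    assert r["n_4d_sites"] == 0
    assert r["raw"] is None


def test_corrected_at_least_raw():
    rng = random.Random(2)
    fams = ["GG", "GC", "CT", "GT", "AC", "TC", "CC", "CG"]
    codons = [
        (p + rng.choice("ACGT"), p + rng.choice("ACGT"))
        for p in (rng.choice(fams) for _ in range(60))
    ]
    r = fourdtv(codons)
    if r["corrected"] is not None:
        assert r["corrected"] >= r["raw"]


# --------------------------------------------------------------------------
# block-level driver
# --------------------------------------------------------------------------


def test_block_median_excludes_undefined(monkeypatch):
    import wgdscape.kaks as kaks_mod

    canned = {
        ("a1", "b1"): 0.1, ("a2", "b2"): 0.1, ("a3", "b3"): 0.2,
        ("a4", "b4"): 0.3, ("a5", "b5"): None,
    }

    def fake_divergence(ga, gb, ca, cb):
        return KsRecord(ga, gb, canned[(ga, gb)], None, None, None, 10, 2)

    monkeypatch.setattr(kaks_mod, "pair_divergence", fake_divergence)

    class Anchor:
        def __init__(self, a, b):
            self.gene_a, self.gene_b = a, b

    class Block:
        block_id = "blk1"
        anchors = [Anchor(f"a{i}", f"b{i}") for i in range(1, 6)]

    cds = {g: "ATG" for pair in canned for g in pair}
    per_pair, per_block = block_ks([Block()], cds)
    assert per_block.loc[0, "median_ks"] == pytest.approx(0.15)
    assert len(per_pair) == 5


def test_block_all_undefined_gives_undefined_summary(monkeypatch):
    import wgdscape.kaks as kaks_mod

    monkeypatch.setattr(
        kaks_mod, "pair_divergence",
        lambda ga, gb, ca, cb: KsRecord(ga, gb, None, None, None, None, 10, 0),
    )

    class Anchor:
        def __init__(self, a, b):
            self.gene_a, self.gene_b = a, b

    class Block:
        block_id = "blk1"
        anchors = [Anchor("a1", "b1"), Anchor("a2", "b2")]

    _pp, per_block = block_ks([Block()], {"a1": "ATG", "b1": "ATG",
                                          "a2": "ATG", "b2": "ATG"})
    assert per_block.loc[0, "median_ks"] is None


def test_missing_cds_counted_as_skipped():
    class Anchor:
        def __init__(self, a, b):
            self.gene_a, self.gene_b = a, b

    class Block:
        block_id = "blk1"
        anchors = [Anchor("x", "y")]

    _pp, per_block = block_ks([Block()], {"x": "ATGAAA"})
    assert per_block.loc[0, "n_skipped"] == 1


# --------------------------------------------------------------------------
# molecular clock (simulation oracle)
# --------------------------------------------------------------------------


def test_ks_tracks_divergence_time():
    """Mean NG86 Ks is close to 2 r t and monotone in t."""
    from wgdscape.simulate import SimConfig, simulate_divergent_pairs

    cfg = SimConfig(seed=3)
    means = []
    for t_mya, n in [(7.6, 120), (29.6, 250)]:
        pairs = simulate_divergent_pairs(n, 300, t_mya, cfg=cfg, seed=1000 + int(t_mya))
        ks = [
            r["ks"]
            for r in (ng86(codon_align(a, b)) for a, b in pairs)
            if r["ks"] is not None
        ]
        mean = sum(ks) / len(ks)
        expected = 2 * cfg.synonymous_rate * t_mya * 1e6
        assert mean == pytest.approx(expected, rel=0.10)
        means.append(mean)
    assert means == sorted(means)
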