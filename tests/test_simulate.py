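"""Forward simulator: determinism, bookkeeping, and the synonymous clock."""

import numpy as np
import pytest

from wgdscape.kaks import codon_align, ng86
from wgdscape.simulate import (
    SimConfig,
    simulate_divergent_pairs,
    simulate_expression_metabolites,
    simulate_genome,
    simulate_reads,
)


def _tiny_cfg(**kw):
    base = dict(seed=5, n_chrom=2, genes_per_chrom=40, codons_per_gene=80)
    base.update(kw)
    return SimConfig(**base)


def test_bit_reproducibility():
    a = simulate_genome(_tiny_cfg())
    b = simulate_genome(_tiny_cfg())
    assert a.genome.cds_map() == b.genome.cds_map()
    assert a.outgroup.cds_map() == b.outgroup.cds_map()
    assert a.truth.pairs.equals(b.truth.pairs)
    assert a.truth.genes.equals(b.truth.genes)


def test_no_events_no_change():
    cfg = _tiny_cfg(wgd_times_mya=(), tandem_rate=0.0, outgroup_split_mya=1e-9)
    res = simulate_genome(cfg)
    assert len(res.genome) == 80
    snap = {g.replace("anc_", ""): s for g, s in res.snapshot.cds_map().items()}
    assert snap == res.genome.cds_map()


def test_full_retention_doubles_gene_count():
    cfg = _tiny_cfg(wgd_times_mya=(10.0,), retention_per_wgd=1.0, tandem_rate=0.0)
    res = simulate_genome(cfg)
    assert len(res.genome) == 160
    wgd_pairs = res.truth.pairs_by_origin("WGD1")
    partnered = set(wgd_pairs["gene_a"]) | set(wgd_pairs["gene_b"])
    assert len(partnered) == 160


def test_retention_bookkeeping():
    """Extant count ~ ancestral x (1 + retention) per WGD."""
    cfg = _tiny_cfg(genes_per_chrom=100, wgd_times_mya=(20.0, 5.0),
                    retention_per_wgd=0.7, tandem_rate=0.0)
    res = simulate_genome(cfg)
    expected = 200 * (1 + 0.7) ** 2
    assert len(res.genome) == pytest.approx(expected, rel=0.12)


def test_truth_covers_every_extant_gene_once():
    res = simulate_genome(_tiny_cfg())
    truth_ids = list(res.truth.genes["gene_id"])
    assert len(truth_ids) == len(set(truth_ids)) == len(res.genome)


def test_infeasible_retention_rejected():
    with pytest.raises(ValueError):
        SimConfig(wgd_times_mya=(10.0,), retention_per_wgd=0.0)


def test_wgd_must_predate_outgroup_split():
    with pytest.raises(ValueError):
        SimConfig(wgd_times_mya=(40.0,), outgroup_split_mya=36.4)


def test_wgd_pair_ks_matches_clock(small_sim):
    """NG86 Ks of direct WGD pairs centres on 2 r t for both events."""
    cfg = small_sim.config
    cds = small_sim.genome.cds_map()
    for origin, t_mya in [("WGD1", 29.6), ("WGD2", 6.9)]:
        pairs = small_sim.truth.pairs_by_origin(origin)
        ks = []
        for r in pairs.itertuples():
            rec = ng86(codon_align(cds[r.gene_a], cds[r.gene_b]))
            if rec["ks"] is not None:
                ks.append(rec["ks"])
        expected = 2 * cfg.synonymous_rate * t_mya * 1e6
        assert np.mean(ks) == pytest.approx(expected, rel=0.10)


def test_ortholog_ks_matches_split_time(small_sim):
    cfg = small_sim.config
    cds = dict(small_sim.genome.cds_map())
    cds.update(small_sim.outgroup.cds_map())
    rng = np.random.default_rng(0)
    pairs = small_sim.truth.pairs_by_origin("ortholog")
    take = pairs.iloc[rng.choice(len(pairs), size=120, replace=False)]
    ks = []
    for r in take.itertuples():
        rec = ng86(codon_align(cds[r.gene_a], cds[r.gene_b]))
        if rec["ks"] is not None:
            ks.append(rec["ks"])
    assert np.mean(ks) == pytest.approx(2 * cfg.synonymous_rate * 36.4e6, rel=0.10)


def test_divergent_pairs_t_zero_identical():
    pairs = simulate_divergent_pairs(5, 50, 0.0, seed=1)
    assert all(a == b for a, b in pairs)


# --------------------------------------------------------------------------
# reads
# --------------------------------------------------------------------------


def _comp(s):
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


def test_error_free_reads_are_substrings():
    import random

    g = "".join(random.Random(3).choice("ACGT") for _ in range(5000))
    reads = simulate_reads({"chr1": g}, coverage=3, read_len=80, seed=3)
    for r in reads[:50]:
        assert r in g or _comp(r) in g


def test_read_base_accounting():
    g = {"chr1": "ACGT" * 2500}
    reads = simulate_reads(g, coverage=10, read_len=100, seed=0)
    total = sum(len(r) for r in reads)
    assert total == pytest.approx(10 * 10_000, abs=100)


def test_planted_het_density():
    import random

    g = "".join(random.Random(4).choice("ACGT") for _ in range(200_000))
    _reads, haps = simulate_reads({"chr1": g}, coverage=0.01, read_len=50,
                                  heterozygosity=0.008, seed=4,
                                  return_haplotypes=True)
    h0, h1 = haps[0][0], haps[1][0]
    density = sum(a != b for a, b in zip(h0, h1)) / len(h0)
    assert density == pytest.approx(0.008, rel=0.05)


def test_read_longer_than_genome_rejected():
    with pytest.raises(ValueError, match="read length"):
        simulate_reads({"c": "ACGT" * 10}, coverage=1, read_len=100)


# --------------------------------------------------------------------------
# expression / metabolites
# --------------------------------------------------------------------------


def test_noise_free_couplings_are_perfect():
    modules = {"flower": ["g1", "g2"], "leaf": ["g3", "g4"]}
    expr, metab, truth = simulate_expression_metabolites(
        modules, tissues=("flower", "leaf"), n_reps=3, noise_sd=0.0,
        couplings=[("attract", "flower", 1), ("repel", "flower", -1)], seed=0,
    )
    log_expr = np.log2(expr.loc["g1"] + 1)
    r_pos = np.corrcoef(log_expr, metab.loc["attract"])[0, 1]
    r_neg = np.corrcoef(log_expr, metab.loc["repel"])[0, 1]
    assert r_pos == pytest.approx(1.0)
    assert r_neg == pytest.approx(-1.0)


def test_unknown_coupling_module_rejected():
    with pytest.raises(ValueError, match="unknown module"):
        simulate_expression_metabolites(
            {"flower": ["g1"]}, couplings=[("m", "nope", 1)]
        )


def test_coupled_pairs_exceed_cutoff():
    """effect 4, noise 0.5, 5 tissues x 3 reps: coupled pairs pass |r|>0.7."""
    modules = {t: [f"{t}_g{i}" for i in range(10)]
               for t in ("root", "stem", "leaf", "flower", "trichome")}
    couplings = [("a1", "flower", 1), ("a2", "trichome", 1),
                 ("r1", "leaf", -1), ("r2", "stem", -1)]
    expr, metab, _ = simulate_expression_metabolites(
        modules, n_reps=3, effect=4.0, noise_sd=0.5, couplings=couplings, seed=2,
    )
    log_expr = np.log2(expr + 1)
    n_pass = n_total = 0
    for met, module, sign in couplings:
        for g in modules[module]:
            r = np.corrcoef(log_expr.loc[g], metab.loc[met])[0, 1]
            n_total += 1
            if sign * r > 0.7:
                n_pass += 1
    assert n_pass / n_total > 0.95
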