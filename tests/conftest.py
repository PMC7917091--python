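import warnings

import pytest

from wgdscape.genome_io import GeneModel, GenomeTable


def make_genome(gene_specs, chrom_len=1_000_000):
    """Build a GenomeTable from (gene_id, chrom, start, end[, cds]) tuples;
    ranks are assigned by start order per chromosome."""
    by_chrom = {}
    for spec in gene_specs:
        by_chrom.setdefault(spec[1], []).append(spec)
    genes = []
    lengths = {}
    for chrom, specs in by_chrom.items():
        specs = sorted(specs, key=lambda s: s[2])
        for rank, spec in enumerate(specs):
            cds = spec[4] if len(spec) > 4 else ""
            genes.append(
                GeneModel(
                    gene_id=spec[0], chrom=chrom, start=spec[2], end=spec[3],
                    strand="+", rank=rank, cds=cds,
                )
            )
        lengths[chrom] = max(chrom_len, max(s[3] for s in specs))
    return GenomeTable(genes=genes, chrom_lengths=lengths)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_sim():
    """One small two-WGD simulation shared across tests (seed-fixed)."""
    from wgdscape.simulate import SimConfig, simulate_genome

    cfg = SimConfig(seed=42, n_chrom=2, genes_per_chrom=80, codons_per_gene=120)
    return simulate_genome(cfg)
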