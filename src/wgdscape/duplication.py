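"""Tandem duplication blocks and terpenoid gene-cluster scanning.

A tandem duplication is read strictly: a homolog pair (passing the identity
and e-value filters) whose two genes sit at *adjacent* ranks on the same
chromosome, with no other gene interspersed.  Adjacent pairs sharing a gene
are merged transitively into maximal tandem blocks.

The gene-cluster scan finds physically linked runs of terpenoid-pathway
genes (terpene synthases and their tailoring enzymes: cytochrome P450s and
BAHD acyltransferases) along a chromosome — at most ``max_intervening``
non-pathway genes between consecutive members and a bounded genomic span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .genome_io import GenomeTable, HomologyPair
from .wgd import fraction_pct

__all__ = [
    "TandemBlock",
    "GeneCluster",
    "find_tandem_blocks",
    "tandem_summary",
    "scan_gene_clusters",
    "PATHWAY_FAMILIES",
]

PATHWAY_FAMILIES = ("TPS", "CYP450", "BAHD")


@dataclass(frozen=True)
class TandemBlock:
    chrom: str
    member_genes: tuple[str, ...]  # ordered by rank, contiguous
    ranks: tuple[int, ...]
    family_label: str = ""

    def __post_init__(self) -> None:
        if len(self.member_genes) < 2:
            raise ValueError("tandem block needs >= 2 genes")
        if list(self.ranks) != list(range(self.ranks[0], self.ranks[0] + len(self.ranks))):
            raise ValueError("tandem block ranks must be a contiguous run")

    def __len__(self) -> int:
        return len(self.member_genes)


@dataclass(frozen=True)
class GeneCluster:
    chrom: str
    members: tuple[tuple[str, str], ...]  # (gene_id, family) pathway members
    span_bp: int
    cluster_type: str  # TPS-TPS | TPS-CYP450 | TPS-BAHD | mixed
    n_intervening: int = 0

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("gene cluster needs >= 2 pathway genes")


def find_tandem_blocks(
    genome: GenomeTable,
    pairs: Iterable[HomologyPair],
    min_identity: float = 50.0,
    max_evalue: float = 1e-20,
) -> list[TandemBlock]:
    """Tandem blocks from homolog pairs under the adjacency rule.

    A pair qualifies iff it passes ``identity >= min_identity`` and
    ``evalue <= max_evalue``, lies on one chromosome, and its genes are
    rank-adjacent (|rank_a - rank_b| = 1).  Qualifying pairs sharing a gene
    merge transitively into maximal blocks.
    """
    by_id = genome.by_id
    # adjacency graph over genes (union-find)
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for p in pairs:
        if p.pct_identity < min_identity or p.evalue > max_evalue:
            continue
        ga, gb = by_id.get(p.query_id), by_id.get(p.subject_id)
        if ga is None:
            raise KeyError(f"gene id {p.query_id} not in genome")
        if gb is None:
            raise KeyError(f"gene id {p.subject_id} not in genome")
        if ga.chrom != gb.chrom or abs(ga.rank - gb.rank) != 1:
            continue
        parent.setdefault(ga.gene_id, ga.gene_id)
        parent.setdefault(gb.gene_id, gb.gene_id)
        union(ga.gene_id, gb.gene_id)

    groups: dict[str, list[str]] = {}
    for g in parent:
        groups.setdefault(find(g), []).append(g)

    blocks = []
    for members in groups.values():
        genes = sorted(members, key=lambda g: by_id[g].rank)
        ranks = tuple(by_id[g].rank for g in genes)
        blocks.append(
            TandemBlock(
                chrom=by_id[genes[0]].chrom,
                member_genes=tuple(genes),
                ranks=ranks,
            )
        )
    blocks.sort(key=lambda b: (b.chrom, b.ranks[0]))
    return blocks


def tandem_summary(blocks: Iterable[TandemBlock], n_genes_total: int) -> dict:
    """Fig.-2d-style summary: block count, gene count, percent of all genes."""
    blocks = list(blocks)
    n_genes = sum(len(b) for b in blocks)
    return dict(
        n_blocks=len(blocks),
        n_genes=n_genes,
        pct_of_genes=fraction_pct(n_genes, n_genes_total),
    )


def _cluster_type(families: list[str]) -> str:
    fam = set(families)
    if len(fam) >= 3:
        return "mixed"
    if "TPS" in fam and "CYP450" in fam:
        return "TPS-CYP450"
    if "TPS" in fam and "BAHD" in fam:
        return "TPS-BAHD"
    if families.count("TPS") >= 2:
        return "TPS-TPS"
    return "mixed"


def scan_gene_clusters(
    genome: GenomeTable,
    family_map: Mapping[str, str],
    max_intervening: int = 10,
    max_span_kb: float = 200.0,
) -> list[GeneCluster]:
    """Sliding scan for physically linked terpenoid-pathway gene clusters.

    ``family_map`` labels genes TPS/CYP450/BAHD (anything else, or absent,
    counts as non-pathway).  Consecutive pathway members may be separated by
    at most ``max_intervening`` non-pathway genes, and a cluster's genomic
    span may not exceed ``max_span_kb``.  Clusters need >= 2 pathway genes.
    """
    max_span = max_span_kb * 1000.0
    clusters: list[GeneCluster] = []
    for chrom, genes in genome.by_chrom.items():
        pathway = [
            g for g in genes if family_map.get(g.gene_id, "other") in PATHWAY_FAMILIES
        ]
        run: list = []
        for g in pathway:
            if run:
                gap = g.rank - run[-1].rank - 1
                span = g.end - run[0].start + 1
                if gap <= max_intervening and span <= max_span:
                    run.append(g)
                    continue
                _close_run(run, family_map, clusters)
                run = []
            run.append(g)
        _close_run(run, family_map, clusters)
    clusters.sort(key=lambda c: (c.chrom, c.members[0][0]))
    return clusters


def _close_run(run: list, family_map: Mapping[str, str], out: list) -> None:
    if len(run) < 2:
        return
    families = [family_map[g.gene_id] for g in run]
    n_intervening = (run[-1].rank - run[0].rank + 1) - len(run)
    out.append(
        GeneCluster(
            chrom=run[0].chrom,
            members=tuple((g.gene_id, f) for g, f in zip(run, families)),
            span_bp=run[-1].end - run[0].start + 1,
            cluster_type=_cluster_type(families),
            n_intervening=n_intervening,
        )
    )
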