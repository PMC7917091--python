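"""Genome I/O: GFF3 / FASTA / BLAST-tabular readers and the gene-order table.

Every downstream stage (synteny chaining, tandem scanning, Ks dating) works
on gene *ranks* — the 0-based order index of a gene along its chromosome —
so this module's main job is to turn annotation files into a
:class:`GenomeTable` with consistent ranks, and to read homology hit tables
with the filtering conventions used throughout the pipeline.

Coordinates are 1-based inclusive internally (the GFF3 convention); BED-style
exports convert to 0-based half-open at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "GeneModel",
    "GenomeTable",
    "HomologyPair",
    "GFF3ParseError",
    "read_gff3",
    "write_gff3",
    "read_fasta",
    "write_fasta",
    "read_blast_tab",
    "write_blast_tab",
]

_VALID_CDS_CHARS = set("ACGTN")

BLAST_OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class GFF3ParseError(ValueError):
    """Malformed GFF3 input; message carries the offending line number."""


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: coordinates, strand, order rank and CDS."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    rank: int  # 0-based order index along the chromosome by start
    cds: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        bad = set(self.cds) - _VALID_CDS_CHARS
        if bad:
            raise ValueError(
                f"gene {self.gene_id}: CDS contains invalid characters {sorted(bad)}"
            )

    @property
    def bed_interval(self) -> tuple[str, int, int]:
        """(chrom, start, end) as 0-based half-open."""
        return (self.chrom, self.start - 1, self.end)


@dataclass
class GenomeTable:
    """An ordered collection of genes plus chromosome lengths.

    Genes are stored sorted by (chrom, rank).  ``by_id`` and ``by_chrom``
    give O(1) / per-chromosome access, which the synteny and tandem stages
    use heavily.
    """

    genes: list[GeneModel] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.chrom, g.rank))
        self._validate()

    def _validate(self) -> None:
        seen: dict[str, list[int]] = {}
        for g in self.genes:
            if g.chrom not in self.chrom_lengths:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > self.chrom_lengths[g.chrom]:
                raise ValueError(
                    f"gene {g.gene_id}: end {g.end} beyond chromosome "
                    f"{g.chrom} length {self.chrom_lengths[g.chrom]}"
                )
            seen.setdefault(g.chrom, []).append(g.rank)
        for chrom, ranks in seen.items():
            if sorted(ranks) != list(range(len(ranks))):
                raise ValueError(f"chromosome {chrom}: ranks are not 0..n-1")

    @property
    def by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    @property
    def by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out

    def __len__(self) -> int:
        return len(self.genes)

    def cds_map(self) -> dict[str, str]:
        return {g.gene_id: g.cds for g in self.genes if g.cds}


@dataclass(frozen=True)
class HomologyPair:
    """A scored protein-protein match (one unordered pair after dedup)."""

    query_id: str
    subject_id: str
    pct_identity: float  # percent, 0-100
    evalue: float
    bitscore: float
    aln_len: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.evalue < 0 or self.bitscore < 0:
            raise ValueError("evalue and bitscore must be non-negative")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _parse_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for item in attr_field.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_gff3(
    path: str | Path,
    genome_fasta: str | Path | Mapping[str, str] | None = None,
) -> GenomeTable:
    """Parse gene/mRNA/CDS features of a GFF3 file into a :class:`GenomeTable`.

    One :class:`GeneModel` per gene; when a gene carries several mRNAs the
    transcript with the longest summed CDS is kept (ties broken by
    lexicographic transcript id).  Ranks are assigned per chromosome by
    ascending start (ties by gene id).  Genes without any CDS get an empty
    ``cds`` and are counted in a single warning.

    CDS sequences are spliced from chromosome sequence when available —
    either from ``genome_fasta`` (path or mapping) or from an embedded
    ``##FASTA`` section — strand-aware, with parts joined in transcript order.
    """
    path = Path(path)
    genes: dict[str, dict] = {}  # gene_id -> {chrom,start,end,strand}
    mrna_parent: dict[str, str] = {}  # mRNA id -> gene id
    cds_len: dict[str, int] = {}  # mRNA id -> summed CDS length
    cds_parts: dict[str, list[tuple[int, int, str]]] = {}
    gene_order: list[str] = []
    embedded_fasta: dict[str, str] = {}

    with open(path) as fh:
        in_fasta = False
        fasta_id: str | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if in_fasta:
                if line.startswith(">"):
                    fasta_id = line[1:].split()[0]
                    embedded_fasta[fasta_id] = ""
                elif fasta_id is not None:
                    embedded_fasta[fasta_id] += line.strip().upper()
                continue
            if line.startswith("##FASTA"):
                in_fasta = True
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3ParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GFF3ParseError(
                    f"{path.name}:{lineno}: non-integer coordinate"
                ) from exc
            a = _parse_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise GFF3ParseError(f"{path.name}:{lineno}: gene without ID")
                genes[gid] = dict(chrom=chrom, start=start, end=end, strand=strand)
                gene_order.append(gid)
            elif ftype == "mRNA":
                tid, parent = a.get("ID"), a.get("Parent")
                if tid is None or parent is None:
                    raise GFF3ParseError(
                        f"{path.name}:{lineno}: mRNA without ID/Parent"
                    )
                mrna_parent[tid] = parent
                cds_len.setdefault(tid, 0)
            elif ftype == "CDS":
                parent = a.get("Parent")
                if parent is None:
                    raise GFF3ParseError(f"{path.name}:{lineno}: CDS without Parent")
                cds_len[parent] = cds_len.get(parent, 0) + (end - start + 1)
                cds_parts.setdefault(parent, []).append((start, end, strand))

    # choose transcript per gene: longest summed CDS, ties by transcript id
    best_tx: dict[str, str] = {}
    for tid, gid in sorted(mrna_parent.items()):
        length = cds_len.get(tid, 0)
        cur = best_tx.get(gid)
        if cur is None:
            best_tx[gid] = tid
            continue
        cur_len = cds_len.get(cur, 0)
        if length > cur_len or (length == cur_len and tid < cur):
            best_tx[gid] = tid

    # chromosome sequence source, if any
    chrom_seq: Mapping[str, str] = {}
    if genome_fasta is not None:
        chrom_seq = (
            genome_fasta if isinstance(genome_fasta, Mapping) else read_fasta(genome_fasta)
        )
    elif embedded_fasta:
        chrom_seq = embedded_fasta

    def splice_cds(tid: str, chrom: str, strand: str) -> str:
        seq = chrom_seq.get(chrom)
        if seq is None or tid not in cds_parts:
            return ""
        parts = sorted(cds_parts[tid], key=lambda p: p[0])
        joined = "".join(seq[s - 1 : e] for s, e, _ in parts)
        return reverse_complement(joined) if strand == "-" else joined

    n_no_cds = 0
    models: list[GeneModel] = []
    chrom_genes: dict[str, list[str]] = {}
    for gid in gene_order:
        chrom_genes.setdefault(genes[gid]["chrom"], []).append(gid)

    chrom_lengths: dict[str, int] = {c: len(s) for c, s in chrom_seq.items()}
    for chrom, gids in chrom_genes.items():
        ordered = sorted(gids, key=lambda g: (genes[g]["start"], g))
        for rank, gid in enumerate(ordered):
            info = genes[gid]
            tid = best_tx.get(gid)
            if tid is None or cds_len.get(tid, 0) == 0:
                n_no_cds += 1
                cds = ""
            else:
                cds = splice_cds(tid, chrom, info["strand"])
            models.append(
                GeneModel(
                    gene_id=gid,
                    chrom=chrom,
                    start=info["start"],
                    end=info["end"],
                    strand=info["strand"],
                    rank=rank,
                    cds=cds,
                )
            )
            chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), info["end"])
    if n_no_cds:
        warnings.warn(f"{n_no_cds} gene(s) without CDS features", stacklevel=2)

    table = GenomeTable(genes=models, chrom_lengths=chrom_lengths)
    table.transcript_cds_lengths = {  # type: ignore[attr-defined]
        gid: cds_len.get(tid, 0) for gid, tid in best_tx.items()
    }
    return table


def write_gff3(table: GenomeTable, path: str | Path) -> None:
    """Write a GenomeTable as minimal gene/mRNA/CDS GFF3 (round-trippable)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in table.genes:
            base = f"{g.chrom}\twgdscape\t"
            fh.write(
                f"{base}gene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{base}mRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            if g.cds:
                fh.write(
                    f"{base}CDS\t{g.start}\t{g.start + len(g.cds) - 1}\t.\t"
                    f"{g.strand}\t0\tID={tid}.cds;Parent={tid}\n"
                )


def attach_cds(table: GenomeTable, sequences: Mapping[str, str]) -> GenomeTable:
    """Return a copy of ``table`` with CDS sequences attached by gene id."""
    genes = [
        replace(g, cds=sequences.get(g.gene_id, g.cds)) for g in table.genes
    ]
    return GenomeTable(genes=genes, chrom_lengths=dict(table.chrom_lengths))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {id: uppercase sequence}; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------


def read_blast_tab(
    path: str | Path,
    max_evalue: float = 1e-20,
    min_identity: float = 50.0,
) -> list[HomologyPair]:
    """Read a 12-column BLAST tabular file into filtered HomologyPairs.

    Self-hits are removed, reciprocal duplicates (A,B)/(B,A) are collapsed
    keeping the better bitscore, and hits are kept only when
    ``pident >= min_identity`` and ``evalue <= max_evalue`` — the retention
    rule used for tandem-duplication calling.
    """
    path = Path(path)
    best: dict[tuple[str, str], HomologyPair] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path.name}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            q, s = fields[0], fields[1]
            if q == s:
                continue
            pident = float(fields[2])
            aln_len = int(fields[3])
            evalue = float(fields[10])
            bitscore = float(fields[11])
            if pident < min_identity or evalue > max_evalue:
                continue
            key = (q, s) if q <= s else (s, q)
            pair = HomologyPair(
                query_id=key[0],
                subject_id=key[1],
                pct_identity=pident,
                evalue=evalue,
                bitscore=bitscore,
                aln_len=aln_len,
            )
            prev = best.get(key)
            if prev is None or pair.bitscore > prev.bitscore:
                best[key] = pair
    return [best[k] for k in sorted(best)]


def write_blast_tab(pairs: Iterable[HomologyPair], path: str | Path) -> None:
    """Write pairs as 12-column outfmt-6 (alignment coordinates zero-filled)."""
    with open(path, "w") as fh:
        for p in pairs:
            mismatches = round(p.aln_len * (1 - p.pct_identity / 100.0))
            fh.write(
                f"{p.query_id}\t{p.subject_id}\t{p.pct_identity:.2f}\t{p.aln_len}"
                f"\t{mismatches}\t0\t1\t{p.aln_len}\t1\t{p.aln_len}"
                f"\t{p.evalue:.3g}\t{p.bitscore:.1f}\n"
            )
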