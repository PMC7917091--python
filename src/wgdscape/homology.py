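"""Internal protein homology search.

Desk-scale stand-in for an all-vs-all BLASTP run: candidate pairs are found
by exact k-mer seeding, each candidate is aligned with an exact
Smith-Waterman local alignment (BLOSUM62, affine gaps 11/1, via Biopython's
C aligner), and an e-value surrogate is derived from the bitscore with fixed
Karlin-Altschul constants.  Output is emitted in the same shape as an
imported outfmt-6 table, so the synteny and tandem stages cannot tell
internal hits from external ones.

E-values here are *not* NCBI-identical (fixed lambda=0.267, K=0.041, simple
m x n search space, no length or composition corrections); the contract is
thresholding behaviour, not absolute e-values.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .genome_io import HomologyPair

__all__ = [
    "translate_cds",
    "all_vs_all",
    "KARLIN_LAMBDA",
    "KARLIN_K",
]

# Karlin-Altschul constants for ungapped BLOSUM62 statistics; recorded in
# output metadata.  Fixed by design: see module docstring.
KARLIN_LAMBDA = 0.267
KARLIN_K = 0.041

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


class InternalStopError(ValueError):
    """CDS translates with an internal stop codon."""

    def __init__(self, codon_index: int, codon: str):
        self.codon_index = codon_index
        super().__init__(f"internal stop codon {codon} at codon index {codon_index}")


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    A trailing stop codon is removed; an internal stop raises
    :class:`InternalStopError` naming the codon index (0-based).  Codons
    containing N translate to 'X'.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    n_codons = len(cds) // 3
    aa = []
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if "N" in codon:
            aa.append("X")
            continue
        if codon in _STANDARD_TABLE.stop_codons:
            if i == n_codons - 1:
                break
            raise InternalStopError(i, codon)
        aa.append(_STANDARD_TABLE.forward_table[codon])
    return "".join(aa)


def _make_aligner(sub_matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(sub_matrix)
    aligner.mode = "local"
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _alignment_identity(alignment) -> tuple[int, int]:
    """(identities, alignment length incl. gaps) of a Bio.Align alignment."""
    counts = alignment.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    return counts.identities, aln_len


def evalue_from_bitscore(bitscore: float, m: int, n: int) -> float:
    """Karlin-Altschul e-value surrogate: E = m * n * 2^-bitscore."""
    return m * n * math.pow(2.0, -bitscore)


def bitscore_from_raw(raw_score: float) -> float:
    return (KARLIN_LAMBDA * raw_score - math.log(KARLIN_K)) / math.log(2.0)


def all_vs_all(
    proteins: Mapping[str, str],
    k_seed: int = 4,
    sub_matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    max_evalue: float | None = None,
    min_identity: float | None = None,
    proteins_b: Mapping[str, str] | None = None,
) -> list[HomologyPair]:
    """All-vs-all (or cross, if ``proteins_b`` given) local protein alignment.

    Only pairs sharing at least one exact ``k_seed``-mer are aligned; each
    aligned pair yields one :class:`HomologyPair` with percent identity over
    the local alignment and a surrogate e-value.  Scores are symmetric by
    construction.  Empty proteins are skipped with a warning.
    """
    if proteins_b is None and len(proteins) < 2:
        raise ValueError("need at least 2 proteins")
    aligner = _make_aligner(sub_matrix, gap_open, gap_extend)

    def clean(d: Mapping[str, str]) -> dict[str, str]:
        out = {}
        for name, seq in d.items():
            if not seq:
                warnings.warn(f"empty protein {name}: skipped", stacklevel=2)
                continue
            out[name] = seq.upper()
        return out

    prot_a = clean(proteins)
    prot_b = clean(proteins_b) if proteins_b is not None else prot_a
    cross = proteins_b is not None

    # seed index: k-mer -> list of ids (over the B side)
    index: dict[str, list[str]] = {}
    for name, seq in prot_b.items():
        for kmer in _kmer_set(seq, k_seed):
            index.setdefault(kmer, []).append(name)

    total_residues = sum(len(s) for s in prot_b.values())
    seen: set[tuple[str, str]] = set()
    pairs: list[HomologyPair] = []
    for qname in sorted(prot_a):
        qseq = prot_a[qname]
        candidates: set[str] = set()
        for kmer in _kmer_set(qseq, k_seed):
            candidates.update(index.get(kmer, ()))
        for sname in sorted(candidates):
            if not cross and sname == qname:
                continue
            key = (qname, sname) if cross or qname <= sname else (sname, qname)
            if key in seen:
                continue
            seen.add(key)
            sseq = prot_b[sname]
            if max_evalue is not None:
                # score-only pass (cheap) to discard sub-threshold pairs
                # before computing a full traceback
                raw = aligner.score(qseq, sseq)
                if (
                    evalue_from_bitscore(bitscore_from_raw(raw), len(qseq), total_residues)
                    > max_evalue
                ):
                    continue
            try:
                aln = aligner.align(qseq, sseq)[0]
            except IndexError:
                continue
            identities, aln_len = _alignment_identity(aln)
            if aln_len == 0:
                continue
            pident = 100.0 * identities / aln_len
            bitscore = bitscore_from_raw(aln.score)
            evalue = evalue_from_bitscore(bitscore, len(qseq), total_residues)
            if max_evalue is not None and evalue > max_evalue:
                continue
            if min_identity is not None and pident < min_identity:
                continue
            pairs.append(
                HomologyPair(
                    query_id=key[0],
                    subject_id=key[1],
                    pct_identity=round(pident, 2),
                    evalue=evalue,
                    bitscore=round(bitscore, 1),
                    aln_len=aln_len,
                )
            )
    pairs.sort(key=lambda p: (p.query_id, p.subject_id))
    return pairs


def proteins_from_cds(cds_map: Mapping[str, str]) -> dict[str, str]:
    """Translate a CDS map, skipping untranslatable entries with a warning."""
    out = {}
    for name, cds in cds_map.items():
        try:
            out[name] = translate_cds(cds)
        except ValueError as exc:
            warnings.warn(f"{name}: {exc}", stacklevel=2)
    return out
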