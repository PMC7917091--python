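"""Pairwise coding-sequence divergence: Ka, Ks and 4dTv.

Ks (synonymous substitutions per synonymous site) is the molecular-clock
proxy used for WGD detection: under a clock with synonymous rate r, a pair
that split t years ago carries Ks ~ 2 r t.  This module estimates Ks/Ka
with the Nei-Gojobori (1986) counting method plus Jukes-Cantor multiple-hit
correction, and the fourfold-degenerate transversion proportion (4dTv) with
a transversion-distance correction using empirical purine/pyrimidine
frequencies — a saturation-resistant corroborating statistic.

Conventions (NG86):
  * synonymous site count of a codon = sum over its three positions of the
    fraction of the three possible changes that are synonymous; changes that
    create a stop codon count as nonsynonymous;
  * for codons differing at several positions, synonymous/nonsynonymous
    differences are averaged over all minimal substitution pathways,
    excluding pathways that pass through a stop codon (all pathways are used
    if every one hits a stop);
  * Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3); p >= 3/4 is reported as
    saturated (undefined), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from math import log
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .homology import translate_cds

__all__ = [
    "KsRecord",
    "codon_align",
    "ng86",
    "fourdtv",
    "block_ks",
    "pair_divergence",
]

_BASES = "ACGT"
_STOPS = frozenset({"TAA", "TAG", "TGA"})
_PURINES = frozenset("AG")

_CODON_AA: dict[str, str] = {}
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _c = _b1 + _b2 + _b3
            if _c not in _STOPS:
                _CODON_AA[_c] = translate_cds(_c + "TAA")  # translate one codon

# fourfold-degenerate codon families: first two bases determine the amino acid
_FOURFOLD_PREFIXES = frozenset(
    p for p in (a + b for a in _BASES for b in _BASES)
    if all(p + c not in _STOPS for c in _BASES)
    and len({_CODON_AA[p + c] for c in _BASES}) == 1
)


def _syn_site_count(codon: str) -> float:
    """NG86 synonymous site count of one codon (0..3)."""
    s = 0.0
    aa = _CODON_AA[codon]
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant not in _STOPS and _CODON_AA[mutant] == aa:
                s += 1.0 / 3.0
    return s


_SYN_SITES: dict[str, float] = {c: _syn_site_count(c) for c in _CODON_AA}


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two codons, averaged over minimal
    substitution pathways that avoid stop codons."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        hits_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                hits_stop = True
            if nxt in _STOPS or _CODON_AA.get(cur) != _CODON_AA.get(nxt):
                nd += 1
            else:
                sd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if not hits_stop:
            valid.append((sd, nd))
    paths = valid if valid else all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


_PAIR_DIFFS: dict[tuple[str, str], tuple[float, float]] = {}


def _pair_diff_cached(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2)
    hit = _PAIR_DIFFS.get(key)
    if hit is None:
        hit = _pathway_diffs(c1, c2)
        _PAIR_DIFFS[key] = hit
        _PAIR_DIFFS[(c2, c1)] = hit
    return hit


@dataclass(frozen=True)
class KsRecord:
    """Divergence estimates for one gene pair.

    Saturated or uncomputable quantities are ``None`` with an explanatory
    flag — never silently 0.
    """

    gene_a: str
    gene_b: str
    ks: float | None
    ka: float | None
    fourdtv_raw: float | None
    fourdtv_corrected: float | None
    n_codons: int
    n_4d_sites: int
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------

_protein_aligner = Align.PairwiseAligner()
_protein_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_protein_aligner.mode = "global"
_protein_aligner.open_gap_score = -11.0
_protein_aligner.extend_gap_score = -1.0


def codon_align(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    """Codon-level alignment of two CDS via global protein alignment.

    The proteins are aligned (Needleman-Wunsch, BLOSUM62, affine gaps) and
    the alignment is back-translated to codons.  Gap columns and columns
    where either codon contains N are dropped pairwise.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    prot_a, prot_b = translate_cds(cds_a), translate_cds(cds_b)
    aln = _protein_aligner.align(prot_a, prot_b)[0]
    a_idx = b_idx = 0
    codons: list[tuple[str, str]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for i, j in zip(range(a_start, a_end), range(b_start, b_end)):
            ca = cds_a[3 * i : 3 * i + 3]
            cb = cds_b[3 * j : 3 * j + 3]
            if "N" in ca or "N" in cb:
                continue
            codons.append((ca, cb))
    return codons


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86(codons: Sequence[tuple[str, str]]) -> dict:
    """Nei-Gojobori (1986) Ka/Ks over an aligned codon list.

    Returns a dict with keys ``ka``, ``ks`` (None when saturated or when the
    corresponding site count is zero), ``pn``, ``ps``, ``S``, ``N``, ``Sd``,
    ``Nd`` and ``flags``.
    """
    if not codons:
        raise ValueError("empty codon alignment")
    S = N = Sd = Nd = 0.0
    for ca, cb in codons:
        if ca in _STOPS or cb in _STOPS:
            raise ValueError(f"stop codon in alignment: {ca}/{cb}")
        sa, sb = _SYN_SITES[ca], _SYN_SITES[cb]
        S += 0.5 * (sa + sb)
        N += 0.5 * ((3.0 - sa) + (3.0 - sb))
        sd, nd = _pair_diff_cached(ca, cb)
        Sd += sd
        Nd += nd
    flags: list[str] = []
    ks = ka = ps = pn = None
    if S <= 0:
        flags.append("no synonymous sites")
    else:
        ps = Sd / S
        ks = _jukes_cantor(ps)
        if ks is None:
            flags.append("ks saturated")
    if N <= 0:
        flags.append("no nonsynonymous sites")
    else:
        pn = Nd / N
        ka = _jukes_cantor(pn)
        if ka is None:
            flags.append("ka saturated")
    return dict(ka=ka, ks=ks, pn=pn, ps=ps, S=S, N=N, Sd=Sd, Nd=Nd, flags=tuple(flags))


# ---------------------------------------------------------------------------
# 4dTv
# ---------------------------------------------------------------------------


def _is_transversion(b1: str, b2: str) -> bool:
    return (b1 in _PURINES) != (b2 in _PURINES)


def fourdtv(codons: Sequence[tuple[str, str]]) -> dict:
    """Transversion proportion at fourfold-degenerate third codon positions.

    A site qualifies when both codons are fourfold-degenerate and share their
    first two bases.  The raw proportion is corrected with the transversion
    component of the HKY/TN93 distance,
    ``c = -2 pR pY ln(1 - raw / (2 pR pY))``, using purine/pyrimidine
    frequencies pooled over the 4d third positions of both sequences.
    Saturation (log argument <= 0) yields ``None``.
    """
    n_4d = 0
    n_tv = 0
    n_purine = 0
    n_pooled = 0
    for ca, cb in codons:
        if ca[:2] != cb[:2] or ca[:2] not in _FOURFOLD_PREFIXES:
            continue
        n_4d += 1
        if _is_transversion(ca[2], cb[2]):
            n_tv += 1
        for b in (ca[2], cb[2]):
            n_pooled += 1
            if b in _PURINES:
                n_purine += 1
    if n_4d == 0:
        return dict(raw=None, corrected=None, n_4d_sites=0, flags=("no 4d sites",))
    raw = n_tv / n_4d
    pi_r = n_purine / n_pooled
    pi_y = 1.0 - pi_r
    denom = 2.0 * pi_r * pi_y
    flags: tuple[str, ...] = ()
    if denom <= 0 or raw >= denom:
        corrected = None
        flags = ("4dtv saturated",)
    else:
        corrected = -denom * log(1.0 - raw / denom)
    return dict(raw=raw, corrected=corrected, n_4d_sites=n_4d, flags=flags)


# ---------------------------------------------------------------------------
# per-pair and per-block drivers
# ---------------------------------------------------------------------------


def pair_divergence(gene_a: str, gene_b: str, cds_a: str, cds_b: str) -> KsRecord:
    """Full divergence record for one gene pair (align + NG86 + 4dTv)."""
    codons = codon_align(cds_a, cds_b)
    if not codons:
        return KsRecord(gene_a, gene_b, None, None, None, None, 0, 0, ("empty alignment",))
    ng = ng86(codons)
    fd = fourdtv(codons)
    return KsRecord(
        gene_a=gene_a,
        gene_b=gene_b,
        ks=ng["ks"],
        ka=ng["ka"],
        fourdtv_raw=fd["raw"],
        fourdtv_corrected=fd["corrected"],
        n_codons=len(codons),
        n_4d_sites=fd["n_4d_sites"],
        flags=ng["flags"] + fd["flags"],
    )


def block_ks(blocks, cds_map: Mapping[str, str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ks/Ka/4dTv for every anchor pair of a block list.

    Returns ``(per_pair, per_block)`` DataFrames.  The per-block summary is
    the median Ks/4dTv of the block's anchors, undefined values excluded;
    anchors whose CDS is missing are skipped and counted in the ``n_skipped``
    column.
    """
    pair_rows = []
    block_rows = []
    for block in blocks:
        ks_values: list[float] = []
        fd_values: list[float] = []
        n_skipped = 0
        for anchor in block.anchors:
            ca, cb = cds_map.get(anchor.gene_a), cds_map.get(anchor.gene_b)
            if not ca or not cb:
                n_skipped += 1
                continue
            rec = pair_divergence(anchor.gene_a, anchor.gene_b, ca, cb)
            pair_rows.append(
                dict(
                    block_id=block.block_id,
                    gene_a=rec.gene_a,
                    gene_b=rec.gene_b,
                    ka=rec.ka,
                    ks=rec.ks,
                    fourdtv_raw=rec.fourdtv_raw,
                    fourdtv_corrected=rec.fourdtv_corrected,
                    n_codons=rec.n_codons,
                    n_4d_sites=rec.n_4d_sites,
                    flags=";".join(rec.flags),
                )
            )
            if rec.ks is not None:
                ks_values.append(rec.ks)
            if rec.fourdtv_corrected is not None:
                fd_values.append(rec.fourdtv_corrected)
        block_rows.append(
            dict(
                block_id=block.block_id,
                n_anchors=len(block.anchors),
                n_skipped=n_skipped,
                median_ks=float(pd.Series(ks_values).median()) if ks_values else None,
                median_4dtv=float(pd.Series(fd_values).median()) if fd_values else None,
            )
        )
    per_pair = pd.DataFrame(
        pair_rows,
        columns=[
            "block_id", "gene_a", "gene_b", "ka", "ks", "fourdtv_raw",
            "fourdtv_corrected", "n_codons", "n_4d_sites", "flags",
        ],
    )
    per_block = pd.DataFrame(
        block_rows,
        columns=["block_id", "n_anchors", "n_skipped", "median_ks", "median_4dtv"],
    )
    return per_pair, per_block
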