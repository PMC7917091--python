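"""k-mer genome survey: spectrum construction and genome-size estimation.

The k-mer spectrum (histogram of per-k-mer read depth, canonical 17-mers by
default) separates sequencing-error k-mers (low depth) from genomic k-mers
peaking at the sequencing coverage; genome size follows as
total k-mers above the error cutoff divided by the homozygous peak depth.
For a heterozygous diploid the spectrum shows a het peak near half the hom
peak; the higher-depth major peak is taken as homozygous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

__all__ = [
    "KmerSpectrum",
    "spectrum",
    "estimate_genome_size",
    "estimate_heterozygosity",
]

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class KmerSpectrum:
    k: int
    histogram: dict[int, int]  # depth -> number of distinct k-mers
    total_kmers: int  # sum depth * count

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.histogram):
            raise ValueError("depths must be >= 1")
        if self.total_kmers != sum(d * c for d, c in self.histogram.items()):
            raise ValueError("total_kmers inconsistent with histogram")

    @property
    def n_distinct(self) -> int:
        return sum(self.histogram.values())

    def write_histo(self, path) -> None:
        """Two-column depth/count text, the common k-mer-counter histo shape."""
        with open(path, "w") as fh:
            for depth in sorted(self.histogram):
                fh.write(f"{depth}\t{self.histogram[depth]}\n")


def _iter_reads(reads: Iterable[str] | str | Path) -> Iterator[str]:
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
        for rec in SeqIO.parse(str(path), fmt):
            yield str(rec.seq)
    else:
        yield from reads


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical integer codes of all valid (N-free) k-mers of one read."""
    b = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if b.size < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(b, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    valid = (windows >= 0).all(axis=1)
    fwd = windows @ powers
    rev = (3 - windows[:, ::-1]) @ powers
    canon = np.minimum(fwd, rev)
    return canon[valid]


def spectrum(reads: Iterable[str] | str | Path, k: int = 17, canonical: bool = True) -> KmerSpectrum:
    """Count canonical k-mers of a read set into a depth histogram.

    ``reads`` may be a FASTA/FASTQ path or an iterable of sequence strings.
    k must be odd (a canonical k-mer is then never its own reverse
    complement); k-mers containing N are skipped; a k longer than every read
    is an error.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if k > 31:
        raise ValueError("k must fit 2 bits/base in int64 (k <= 31)")
    chunks: list[np.ndarray] = []
    max_len = 0
    for seq in _iter_reads(reads):
        max_len = max(max_len, len(seq))
        if canonical:
            codes = _kmer_codes(seq, k)
        else:
            b = _BASE_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
            if b.size < k:
                codes = np.empty(0, dtype=np.int64)
            else:
                w = np.lib.stride_tricks.sliding_window_view(b, k)
                powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
                codes = (w @ powers)[(w >= 0).all(axis=1)]
        if codes.size:
            chunks.append(codes)
    if max_len and k > max_len:
        raise ValueError(f"k={k} exceeds longest read length {max_len}")
    if not chunks:
        return KmerSpectrum(k=k, histogram={}, total_kmers=0)
    allcodes = np.concatenate(chunks)
    _, depth_per_kmer = np.unique(allcodes, return_counts=True)
    depths, counts = np.unique(depth_per_kmer, return_counts=True)
    hist = {int(d): int(c) for d, c in zip(depths, counts)}
    return KmerSpectrum(k=k, histogram=hist, total_kmers=int(allcodes.size))


def _dense_smoothed(hist: dict[int, int], window: int = 5) -> np.ndarray:
    """Histogram as a dense depth-indexed array, moving-average smoothed."""
    max_depth = max(hist)
    dense = np.zeros(max_depth + 1)
    for d, c in hist.items():
        dense[d] = c
    kernel = np.ones(window) / window
    return np.convolve(dense, kernel, mode="same")


def _first_local_minimum(smoothed: np.ndarray) -> int:
    """Depth of the first local minimum of the smoothed histogram."""
    for d in range(2, len(smoothed) - 1):
        if smoothed[d] <= smoothed[d - 1] and smoothed[d] <= smoothed[d + 1]:
            return d
    return 1


def estimate_genome_size(
    spec: KmerSpectrum,
    error_depth_cutoff: int | None = None,
) -> tuple[float, int]:
    """(genome size in bp, homozygous peak depth) from a k-mer spectrum.

    The cutoff defaults to the first local minimum of the histogram.  Among
    peaks above the cutoff, the global maximum is the candidate; when a
    comparably strong peak sits near twice its depth (a het/hom pair), the
    higher-depth one is taken as the homozygous peak.  Size = total k-mers
    above the cutoff / hom peak depth.
    """
    if not spec.histogram:
        raise ValueError("empty spectrum")
    smoothed = _dense_smoothed(spec.histogram)
    if error_depth_cutoff is None:
        # a spectrum with a genuine error peak has a dip after depth 1;
        # an error-free spectrum is unimodal and the cutoff stays at 0
        candidate = _first_local_minimum(smoothed)
        error_depth_cutoff = candidate if candidate < np.argmax(smoothed) else 0
    depths = np.arange(len(smoothed))
    keep = depths > error_depth_cutoff
    if not keep.any() or smoothed[keep].max() <= 0:
        raise ValueError(f"no peak above depth cutoff {error_depth_cutoff}")
    raw = np.zeros(len(smoothed))
    for d, c in spec.histogram.items():
        raw[d] = c

    def refine(center: int) -> int:
        lo = max(int(error_depth_cutoff) + 1, center - 2)
        hi = min(len(raw) - 1, center + 2)
        return lo + int(np.argmax(raw[lo : hi + 1]))

    masked = np.where(keep, smoothed, -1.0)
    major = refine(int(np.argmax(masked)))
    major_count = smoothed[major]
    # het/hom disambiguation: a comparable smoothed peak near 2x the major
    hom_peak = major
    lo, hi = int(1.6 * major), int(2.4 * major) + 1
    if hi < len(smoothed):
        window = smoothed[lo : hi + 1]
        if window.size and window.max() >= 0.2 * major_count:
            hom_peak = refine(lo + int(np.argmax(window)))
    # sub-integer peak depth: count-weighted centroid over the hom-peak
    # region (0.7x-1.5x, asymmetric because a Poisson-like peak carries more
    # mass above its mode; a het half-peak at 0.5x stays excluded)
    lo = max(int(error_depth_cutoff) + 1, int(np.ceil(0.7 * hom_peak)))
    hi = min(len(raw) - 1, int(1.5 * hom_peak))
    weights = raw[lo : hi + 1]
    centroid = (
        float(np.average(np.arange(lo, hi + 1), weights=weights))
        if weights.sum() > 0
        else float(hom_peak)
    )
    total_above = float(
        sum(d * c for d, c in spec.histogram.items() if d > error_depth_cutoff)
    )
    return total_above / centroid, hom_peak


def estimate_heterozygosity(
    spec: KmerSpectrum,
    error_depth_cutoff: int | None = None,
) -> float:
    """Rough areal heterozygosity estimate — experimental.

    h ~ 1 - (1 - a)^(1/k) where a is the fraction of distinct above-cutoff
    k-mers lying in the het-peak region (depth <= 0.75 x hom peak).  A
    formulaic core only; no full spectrum-model fit.
    """
    size, hom_peak = estimate_genome_size(spec, error_depth_cutoff)
    if error_depth_cutoff is None:
        smoothed = _dense_smoothed(spec.histogram)
        candidate = _first_local_minimum(smoothed)
        error_depth_cutoff = candidate if candidate < np.argmax(smoothed) else 0
    above = {d: c for d, c in spec.histogram.items() if d > error_depth_cutoff}
    total = sum(above.values())
    het = sum(c for d, c in above.items() if d <= 0.75 * hom_peak)
    a = het / total if total else 0.0
    if a >= 1.0:
        return 1.0
    return 1.0 - (1.0 - a) ** (1.0 / spec.k)
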