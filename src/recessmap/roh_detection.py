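"""Windowed detection of runs of homozygosity (ROH) per sample.

The scan follows the classic SNP-array windowed algorithm: every marker is
scored by the fraction of overlapping windows of ``window_snps`` consecutive
markers that look homozygous (at most ``window_max_het`` heterozygous and
``window_max_missing`` missing calls). Markers whose hit rate reaches
``hit_rate_threshold`` form candidate runs; candidate runs are broken at
inter-marker gaps larger than ``max_gap_kb`` and at heterozygous calls beyond
``max_het_in_roh``, and surviving maximal stretches are emitted when they
satisfy the minimum SNP count, minimum length and marker-density bounds.

Four scan parameters (500 kb minimum length, 20 contiguous SNPs, 40-SNP
windows, zero heterozygous calls inside a run) are the standard settings for
~1 SNP / 60 kb arrays; the remaining knobs default to the scanning tool's
published defaults and are all exposed on :class:`RohParams`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genotype_io import HET, MISSING, GenotypePanel


@dataclass(frozen=True)
class RohParams:
    min_kb: float = 500.0
    min_snps: int = 20
    window_snps: int = 40
    max_het_in_roh: int = 0
    window_max_het: int = 1
    window_max_missing: int = 5
    hit_rate_threshold: float = 0.05
    max_gap_kb: float = 1000.0
    min_density_kb_per_snp: float = 50.0

    def __post_init__(self) -> None:
        if self.min_kb <= 0:
            raise ValueError("min_kb must be > 0")
        if not 0 < self.hit_rate_threshold <= 1:
            raise ValueError("hit_rate_threshold must be in (0, 1]")
        for name in ("min_snps", "window_snps", "max_het_in_roh",
                     "window_max_het", "window_max_missing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class RohSegment:
    sample: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1e3

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


@dataclass
class RohSummary:
    """Per-sample segment counts/coverage and pooled length statistics (Mb)."""

    n_segments: dict[str, int]
    coverage_mb: dict[str, float]
    mean_length_mb: float | None
    min_length_mb: float | None
    max_length_mb: float | None

    def rendered(self) -> dict[str, object]:
        """Reporting view: lengths in Mb rounded to 1 decimal."""
        rnd = lambda x: None if x is None else round(x, 1)
        return {
            "n_segments": dict(self.n_segments),
            "coverage_mb": {s: rnd(v) for s, v in self.coverage_mb.items()},
            "mean_length_mb": rnd(self.mean_length_mb),
            "min_length_mb": rnd(self.min_length_mb),
            "max_length_mb": rnd(self.max_length_mb),
        }


def window_hit_mask(genotypes: np.ndarray, params: RohParams) -> np.ndarray:
    """Per-marker boolean mask of the windowed homozygosity hit rate.

    ``genotypes`` is one sample's codes along one chromosome, in map order.
    Windows are clamped at chromosome ends: a marker near an end overlaps
    fewer windows and its hit rate uses the actual count. A chromosome
    shorter than the window size is scanned with one truncated window.
    """
    g = np.asarray(genotypes)
    n = g.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    w = min(params.window_snps, n)
    het = (g == HET).astype(np.int64)
    mis = (g == MISSING).astype(np.int64)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    starts = np.arange(0, n - w + 1)
    ok = (
        (chet[starts + w] - chet[starts] <= params.window_max_het)
        & (cmis[starts + w] - cmis[starts] <= params.window_max_missing)
    ).astype(np.int64)
    cok = np.concatenate([[0], np.cumsum(ok)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n - w)
    n_windows = hi - lo + 1
    n_hits = cok[hi + 1] - cok[lo]
    return n_hits / n_windows >= params.hit_rate_threshold


def _maximal_low_het_spans(het: np.ndarray, max_het: int) -> list[tuple[int, int]]:
    """Maximal index spans containing at most ``max_het`` heterozygous calls."""
    n = het.size
    spans: list[tuple[int, int]] = []
    r = -1
    count = 0
    prev_r = -2
    for l in range(n):
        if r < l - 1:
            r = l - 1
            count = 0
        while r + 1 < n and count + het[r + 1] <= max_het:
            r += 1
            count += het[r]
        if r >= l and r > prev_r:
            spans.append((l, r))
            prev_r = r
        if r >= l:
            count -= het[l]
    return spans


def detect_roh(
    panel: GenotypePanel, sample: str, params: RohParams | None = None
) -> list[RohSegment]:
    """Detect runs of homozygosity for one sample across all chromosomes."""
    params = params or RohParams()
    si = panel.sample_index(sample)
    segments: list[RohSegment] = []
    for chrom in panel.chromosomes():
        idx = panel.marker_indices(chrom)
        g = panel.genotypes[si, idx]
        pos = np.array([panel.markers[i].position for i in idx], dtype=np.int64)
        mask = window_hit_mask(g, params)
        segments.extend(
            _segments_from_mask(sample, chrom, g, pos, mask, params)
        )
    return segments


def _segments_from_mask(
    sample: str,
    chrom: str,
    g: np.ndarray,
    pos: np.ndarray,
    mask: np.ndarray,
    params: RohParams,
) -> list[RohSegment]:
    out: list[RohSegment] = []
    n = g.size
    i = 0
    max_gap_bp = params.max_gap_kb * 1e3
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1]:
            j += 1
        # candidate run [i, j]; break at over-long gaps
        pieces: list[tuple[int, int]] = []
        ps = i
        for k in range(i + 1, j + 1):
            if pos[k] - pos[k - 1] > max_gap_bp:
                pieces.append((ps, k - 1))
                ps = k
        pieces.append((ps, j))
        for (a, b) in pieces:
            het = (g[a : b + 1] == HET).astype(np.int64)
            for (l, r) in _maximal_low_het_spans(het, params.max_het_in_roh):
                seg = _finalize(sample, chrom, pos, a + l, a + r, params)
                if seg is not None:
                    out.append(seg)
        i = j + 1
    return out


def _finalize(
    sample: str, chrom: str, pos: np.ndarray, a: int, b: int, params: RohParams
) -> RohSegment | None:
    n_snps = b - a + 1
    length_kb = (pos[b] - pos[a] + 1) / 1e3
    if n_snps < params.min_snps:
        return None
    if length_kb < params.min_kb:
        return None
    if length_kb / n_snps > params.min_density_kb_per_snp:
        return None
    return RohSegment(
        sample=sample, chromosome=chrom,
        start_bp=int(pos[a]), end_bp=int(pos[b]), n_snps=n_snps,
    )


def detect_roh_all(
    panel: GenotypePanel, params: RohParams | None = None,
    samples: Sequence[str] | None = None,
) -> dict[str, list[RohSegment]]:
    return {s: detect_roh(panel, s, params) for s in (samples or panel.samples)}


def summarize_roh(segments: Iterable[RohSegment]) -> RohSummary:
    segs = list(segments)
    n_segments: dict[str, int] = {}
    coverage_mb: dict[str, float] = {}
    for s in segs:
        n_segments[s.sample] = n_segments.get(s.sample, 0) + 1
        coverage_mb[s.sample] = coverage_mb.get(s.sample, 0.0) + s.length_mb
    if segs:
        lengths = np.array([s.length_mb for s in segs])
        mean, lo, hi = float(lengths.mean()), float(lengths.min()), float(lengths.max())
    else:
        mean = lo = hi = None
    return RohSummary(
        n_segments=n_segments, coverage_mb=coverage_mb,
        mean_length_mb=mean, min_length_mb=lo, max_length_mb=hi,
    )
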