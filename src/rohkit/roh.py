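"""Sliding-window runs-of-homozygosity (ROH) detection.

The scan follows the PLINK ``--homozyg`` scheme: a window of ``window_snp``
consecutive SNVs is *homozygous* if it holds at most ``window_het``
heterozygous and at most ``window_missing`` missing calls; each SNV's hit
fraction is the share of windows containing it that are homozygous; a SNV is
eligible when its hit fraction reaches ``hit_threshold`` and its own call is
not heterozygous.  Maximal runs of eligible SNVs, split at large inter-SNV
gaps, become segments when they satisfy the SNV-count, length and density
thresholds.

Heterozygous calls therefore break runs (no called segment starts, ends or
contains a het call); missing calls are counted within windows but do not
break runs — a missing SNV inside a run contributes to the segment span but
not to ``n_snvs``, and segments never start or end on one.

``min_snv_threshold`` is the standard calibration for the minimum number of
SNVs per ROH such that fewer than a fraction ``alpha`` of ROH are expected to
arise by chance given the cohort size, marker count and mean heterozygosity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROHParams:
    """Scanning-window and segment thresholds (PLINK v1.9 defaults except
    where the study set them: 3 het calls per window, 300 kb minimum length).

    ``min_snv=None`` means: calibrate with :func:`min_snv_threshold` at
    alpha=0.05 from the matrix being scanned (the pipeline default).
    """

    window_snp: int = 50
    window_het: int = 3
    window_missing: int = 5
    hit_threshold: float = 0.05
    min_snv: int | None = None
    min_kb: float = 300.0
    max_gap_kb: float = 1000.0
    max_kb_per_snv: float = 50.0

    def __post_init__(self) -> None:
        if self.window_snp <= 0 or self.window_het < 0 or self.window_missing < 0:
            raise ValueError("window parameters must be non-negative (window_snp > 0)")
        if not 0 < self.hit_threshold <= 1:
            raise ValueError("hit_threshold must be in (0, 1]")
        if self.min_snv is not None and self.min_snv <= 0:
            raise ValueError("min_snv must be positive")
        if min(self.min_kb, self.max_gap_kb, self.max_kb_per_snv) <= 0:
            raise ValueError("kb thresholds must be positive")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run in one sample; 1-based inclusive bp coordinates of
    its first and last member SNV."""

    sample: str
    chrom: str
    start: int
    end: int
    n_snvs: int
    n_het: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("segment end < start")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def min_snv_threshold(alpha: float, n_samples: int, n_snvs: int,
                      mean_het: float) -> int:
    """Minimum SNVs per ROH so that < ``alpha`` of ROH arise by chance.

    Returns ceil( ln(alpha / (n_samples * n_snvs)) / ln(1 - mean_het) ):
    the run length whose chance occurrence probability, multiplied by the
    number of (sample, marker) starting points, stays below alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 < mean_het < 1:
        raise ValueError("mean_het must be in (0, 1) — log undefined otherwise")
    if n_samples <= 0 or n_snvs <= 0:
        raise ValueError("counts must be positive")
    return math.ceil(math.log(alpha / (n_samples * n_snvs))
                     / math.log(1.0 - mean_het))


def window_scan(calls: np.ndarray, positions: np.ndarray,
                p: ROHParams) -> np.ndarray:
    """Per-SNV eligibility mask for one sample on one chromosome.

    Chromosomes with fewer SNVs than ``window_snp`` are scanned with a single
    truncated window covering all of them.
    """
    calls = np.asarray(calls, dtype=np.int8)
    positions = np.asarray(positions)
    if calls.shape != positions.shape:
        raise ValueError("calls and positions must align")
    n = calls.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    if positions.size > 1 and not np.all(np.diff(positions) > 0):
        raise ValueError("positions must be strictly increasing")

    w = min(p.window_snp, n)
    het = np.concatenate([[0], np.cumsum(calls == 1)])
    mis = np.concatenate([[0], np.cumsum(calls == MISSING)])
    n_windows = n - w + 1
    starts = np.arange(n_windows)
    hom_window = ((het[starts + w] - het[starts] <= p.window_het)
                  & (mis[starts + w] - mis[starts] <= p.window_missing))

    hom_cum = np.concatenate([[0], np.cumsum(hom_window)])
    j = np.arange(n)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_windows - 1)
    hit_frac = (hom_cum[hi + 1] - hom_cum[lo]) / (hi - lo + 1)
    return (hit_frac >= p.hit_threshold) & (calls != 1)


def mean_marker_heterozygosity(m: GenotypeMatrix) -> float:
    """Mean per-site expected heterozygosity 2p(1-p) from allele frequencies.

    This is the marker-panel heterozygosity the chance-ROH calibration needs:
    unlike the observed het-call fraction it is not depressed by real
    autozygosity in the cohort, so the calibration does not inflate with
    inbreeding.
    """
    called = m.calls != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(m.calls == 1, 1, 0) + np.where(m.calls == 2, 2, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt.sum(axis=0) / (2 * n_called)
    exp_het = 2 * p * (1 - p)
    return float(np.nanmean(np.where(n_called > 0, exp_het, np.nan)))


def _resolve_min_snv(p: ROHParams, m: GenotypeMatrix, alpha: float = 0.05) -> int:
    mean_het = mean_marker_heterozygosity(m)
    if not 0 < mean_het < 1:
        raise ValueError("cannot calibrate min_snv: degenerate mean heterozygosity")
    value = min_snv_threshold(alpha, m.n_samples, m.n_sites, mean_het)
    logger.info("calibrated min_snv=%d (alpha=%g, n_samples=%d, n_snvs=%d, "
                "mean_het=%.4f)", value, alpha, m.n_samples, m.n_sites, mean_het)
    return value


def call_segments(mask: np.ndarray, calls: np.ndarray, positions: np.ndarray,
                  p: ROHParams, sample: str = "", chrom: str = "") -> list[ROHSegment]:
    """Turn an eligibility mask into filtered ROH segments.

    Requires an explicit ``p.min_snv`` (use :func:`detect_roh` for the
    auto-calibrated pipeline).
    """
    if p.min_snv is None:
        raise ValueError("call_segments needs an explicit min_snv")
    mask = np.asarray(mask, dtype=bool)
    calls = np.asarray(calls, dtype=np.int8)
    positions = np.asarray(positions, dtype=np.int64)
    max_gap = int(p.max_gap_kb * 1000)
    segments: list[ROHSegment] = []

    n = mask.size
    i = 0
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1]:
            j += 1
        # split the run [i, j] at gaps larger than max_gap
        piece_start = i
        for k in range(i, j + 1):
            last = (k == j)
            if not last and positions[k + 1] - positions[k] > max_gap:
                _emit(piece_start, k, calls, positions, p, sample, chrom, segments)
                piece_start = k + 1
            elif last:
                _emit(piece_start, k, calls, positions, p, sample, chrom, segments)
        i = j + 1
    return segments


def _emit(i0: int, i1: int, calls: np.ndarray, positions: np.ndarray,
          p: ROHParams, sample: str, chrom: str,
          out: list[ROHSegment]) -> None:
    # segments never start or end on a missing call
    while i0 <= i1 and calls[i0] == MISSING:
        i0 += 1
    while i1 >= i0 and calls[i1] == MISSING:
        i1 -= 1
    if i0 > i1:
        return
    span = calls[i0:i1 + 1]
    n_snvs = int((span != MISSING).sum())
    length = int(positions[i1] - positions[i0] + 1)
    if n_snvs < p.min_snv:
        return
    if length < p.min_kb * 1000:
        return
    if length / n_snvs > p.max_kb_per_snv * 1000:
        return
    out.append(ROHSegment(sample=sample, chrom=chrom,
                          start=int(positions[i0]), end=int(positions[i1]),
                          n_snvs=n_snvs, n_het=int((span == 1).sum())))


def detect_roh(m: GenotypeMatrix, p: ROHParams = ROHParams(),
               alpha: float = 0.05) -> list[ROHSegment]:
    """Scan every sample and chromosome of a filtered matrix.

    When ``p.min_snv`` is None the threshold is calibrated from the matrix
    itself (alpha, cohort size, marker count, mean heterozygosity) and logged.
    Deterministic for fixed input.
    """
    if p.min_snv is None:
        p = replace(p, min_snv=_resolve_min_snv(p, m, alpha))
    segments: list[ROHSegment] = []
    for chrom in m.chromosomes():
        sl = m.chrom_slice(chrom)
        positions = m.sites["pos"].to_numpy()[sl]
        for si, sample in enumerate(m.samples):
            calls = m.calls[si, sl]
            mask = window_scan(calls, positions, p)
            segments.extend(call_segments(mask, calls, positions, p,
                                          sample=sample, chrom=chrom))
    segments.sort(key=lambda s: (s.sample, s.chrom, s.start))
    return segments
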