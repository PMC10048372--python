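"""Synthetic diploid genotype cohorts with planted autozygosity.

The generator emulates the kind of within-breed whole-genome cohort the rest
of the package analyses: a fixed set of autosomes carrying uniformly placed
biallelic SNVs; per-site allele frequencies drawn from a symmetric Beta
distribution whose shape is solved from the desired non-ROH heterozygosity
(E[2p(1-p)] = h gives alpha = h / (1 - 2h)); optional subpopulations obtained
by perturbing shared ancestral frequencies on the logit scale; and, per
sample, non-overlapping autozygous segments drawn from a six-class length
mixture and placed until a target genomic inbreeding F is reached exactly.

Genotypes inside a planted segment are homozygous for one allele drawn by
its frequency, flipped to a (spurious) heterozygous call with probability
``error_rate``; outside, they are Hardy-Weinberg draws from the sample's
population frequency.  Missingness is an independent Bernoulli mask.
Everything is deterministic for a fixed seed.

Optional *island regions* plant a shared segment — homozygous for the same
allele in every carrier — in a chosen fraction of samples, emulating a
selection signature / ROH island.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .roh import ROHSegment

# Six length classes (bp bounds, mixture weight, exponential scale) chosen so
# that ~83% of segments fall below 4 Mb and ~4% above 10 Mb, with the
# shortest plantable segment at 0.3 Mb.
DEFAULT_LENGTH_MIXTURE: tuple[tuple[int, int, float, float], ...] = (
    (300_000, 1_000_000, 0.350, 700_000),
    (1_000_000, 2_000_000, 0.270, 1_000_000),
    (2_000_000, 4_000_000, 0.213, 2_000_000),
    (4_000_000, 8_000_000, 0.090, 4_000_000),
    (8_000_000, 10_000_000, 0.035, 2_000_000),
    (10_000_000, 30_000_000, 0.042, 4_000_000),
)

DEFAULT_CHROMOSOMES: Mapping[str, int] = {
    "1": 100_000_000,
    "2": 80_000_000,
    "3": 60_000_000,
}


@dataclass(frozen=True)
class IslandSpec:
    """A region planted autozygous (same haplotype) in a fraction of samples."""

    chrom: str
    start: int
    end: int
    carrier_fraction: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_samples: int = 33
    chromosomes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROMOSOMES))
    snv_density: float = 100.0  # SNVs per Mb
    het_outside: float = 0.268  # expected heterozygosity outside ROH
    # scalar, per-sample sequence, or (lo, hi) uniform range
    target_froh: float | tuple[float, float] | Sequence[float] = (0.32, 0.52)
    length_mixture: tuple[tuple[int, int, float, float], ...] = \
        DEFAULT_LENGTH_MIXTURE
    error_rate: float = 1e-3    # P(het call inside a true ROH)
    missing_rate: float = 0.05
    n_pops: int = 2
    divergence: float = 0.3     # logit-scale sd of per-pop frequency shifts
    pop_sizes: tuple[int, ...] | None = None
    islands: tuple[IslandSpec, ...] = ()

    def __post_init__(self) -> None:
        for name, rate in (("het_outside", self.het_outside),
                           ("error_rate", self.error_rate),
                           ("missing_rate", self.missing_rate)):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.het_outside < 0.5:
            raise ValueError("het_outside must be in (0, 0.5) for the "
                             "symmetric-Beta frequency model")
        if any(l <= 0 for l in self.chromosomes.values()):
            raise ValueError("chromosome lengths must be positive")
        w = sum(c[2] for c in self.length_mixture)
        if not np.isclose(w, 1.0):
            raise ValueError("length mixture weights must sum to 1")

    @property
    def genome_bp(self) -> int:
        return sum(self.chromosomes.values())


@dataclass
class TruthSet:
    """Ground truth of one simulation: planted segments, per-sample true
    autozygous fraction, population labels and per-population site
    frequencies."""

    segments: pd.DataFrame          # sample, chrom, start, end, length_bp
    froh: pd.Series                 # per-sample true autozygous fraction
    populations: pd.Series          # per-sample label
    site_freqs: np.ndarray          # n_pops x n_sites
    genome_bp: int

    def sample_segments(self, sample: str) -> pd.DataFrame:
        return self.segments[self.segments["sample"] == sample]


@dataclass
class SimResult:
    matrix: GenotypeMatrix
    truth: TruthSet


def _beta_alpha(het: float) -> float:
    # E[2 p (1-p)] = alpha / (2 alpha + 1) for Beta(alpha, alpha)
    return het / (1.0 - 2.0 * het)


def _draw_length(rng: np.random.Generator,
                 mixture: Sequence[tuple[int, int, float, float]]) -> int:
    weights = np.array([c[2] for c in mixture])
    lo, hi, _, scale = mixture[rng.choice(len(mixture), p=weights)]
    span = hi - lo
    u = rng.random()
    # inverse-CDF of an exponential truncated to [lo, hi)
    x = lo - scale * np.log1p(-u * (1.0 - np.exp(-span / scale)))
    return int(min(max(x, lo), hi - 1))


class _Placer:
    """Non-overlapping interval placement on one genome, rejection sampled."""

    def __init__(self, chromosomes: Mapping[str, int],
                 rng: np.random.Generator) -> None:
        self.chromosomes = dict(chromosomes)
        self.rng = rng
        self.names = list(chromosomes)
        lengths = np.array([chromosomes[c] for c in self.names], dtype=float)
        self.probs = lengths / lengths.sum()
        self.occupied: dict[str, list[tuple[int, int]]] = \
            {c: [] for c in self.names}

    def place_fixed(self, chrom: str, start: int, end: int) -> bool:
        ivs = self.occupied[chrom]
        i = bisect.bisect_left(ivs, (start, end))
        if i > 0 and ivs[i - 1][1] >= start:
            return False
        if i < len(ivs) and ivs[i][0] <= end:
            return False
        ivs.insert(i, (start, end))
        return True

    def _free_gaps(self, chrom: str) -> list[tuple[int, int]]:
        gaps = []
        prev = 0
        for s, e in self.occupied[chrom]:
            if s - 1 > prev:
                gaps.append((prev + 1, s - 1))
            prev = max(prev, e)
        if prev < self.chromosomes[chrom]:
            gaps.append((prev + 1, self.chromosomes[chrom]))
        return gaps

    def place(self, length: int) -> tuple[str, int, int] | None:
        """Place uniformly among all feasible start positions; None when no
        free gap can hold the segment."""
        candidates = []  # (chrom, gap_start, n_starts)
        weights = []
        for chrom in self.names:
            for gs, ge in self._free_gaps(chrom):
                n_starts = ge - gs + 1 - length + 1
                if n_starts > 0:
                    candidates.append((chrom, gs, n_starts))
                    weights.append(n_starts)
        if not candidates:
            return None
        w = np.asarray(weights, dtype=float)
        chrom, gs, n_starts = candidates[self.rng.choice(len(candidates),
                                                         p=w / w.sum())]
        start = gs + int(self.rng.integers(0, n_starts))
        end = start + length - 1
        assert self.place_fixed(chrom, start, end)
        return chrom, start, end

    def largest_gap(self) -> tuple[str, int, int] | None:
        best = None
        for chrom in self.names:
            for gs, ge in self._free_gaps(chrom):
                if best is None or ge - gs > best[2] - best[1]:
                    best = (chrom, gs, ge)
        return best


def _site_positions(cfg: SimConfig, rng: np.random.Generator
                    ) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    frames = []
    pos_by_chrom = {}
    for chrom, length in cfg.chromosomes.items():
        n = int(round(cfg.snv_density * length / 1e6))
        pos = np.array([], dtype=np.int64)
        while pos.size < n:
            extra = rng.integers(1, length + 1, size=int(n * 1.2) + 16)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=n, replace=False))
        pos_by_chrom[chrom] = pos
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "ref": "A", "alt": "G",
            "filter": "PASS", "vtype": "SNV"}))
    return pd.concat(frames, ignore_index=True), pos_by_chrom


def _resolve_targets(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    t = cfg.target_froh
    if isinstance(t, (int, float)):
        return np.full(cfg.n_samples, float(t))
    t = tuple(t)
    if len(t) == 2 and all(isinstance(v, (int, float)) for v in t) \
            and len(t) != cfg.n_samples:
        lo, hi = t
        return rng.uniform(lo, hi, size=cfg.n_samples)
    if len(t) != cfg.n_samples:
        raise ValueError("per-sample target_froh length mismatch")
    return np.asarray(t, dtype=float)


def _pop_labels(cfg: SimConfig) -> list[str]:
    sizes = cfg.pop_sizes
    if sizes is None:
        base = cfg.n_samples // cfg.n_pops
        rem = cfg.n_samples % cfg.n_pops
        sizes = tuple(base + (1 if i < rem else 0) for i in range(cfg.n_pops))
    if sum(sizes) != cfg.n_samples or len(sizes) != cfg.n_pops:
        raise ValueError("pop_sizes must sum to n_samples over n_pops groups")
    labels = []
    for i, size in enumerate(sizes):
        labels.extend([f"pop{i + 1}"] * size)
    return labels


def simulate(cfg: SimConfig) -> SimResult:
    """Generate one cohort; see the module docstring for the model."""
    rng = np.random.default_rng(cfg.seed)
    genome = cfg.genome_bp

    sites, pos_by_chrom = _site_positions(cfg, rng)
    n_sites = len(sites)

    # ancestral then per-population site frequencies
    alpha = _beta_alpha(cfg.het_outside)
    p_anc = np.clip(rng.beta(alpha, alpha, size=n_sites), 0.005, 0.995)
    logit = np.log(p_anc / (1 - p_anc))
    pop_freqs = np.empty((cfg.n_pops, n_sites))
    for k in range(cfg.n_pops):
        shift = rng.normal(0.0, cfg.divergence, size=n_sites) \
            if cfg.divergence > 0 else 0.0
        pop_freqs[k] = 1.0 / (1.0 + np.exp(-(logit + shift)))

    pop_labels = _pop_labels(cfg)
    pop_index = {f"pop{i + 1}": i for i in range(cfg.n_pops)}
    samples = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    targets = _resolve_targets(cfg, rng)

    # shared island haplotypes: one allele per island site, common to carriers
    island_carriers: list[np.ndarray] = []
    island_alleles: list[np.ndarray] = []
    island_site_idx: list[np.ndarray] = []
    chrom_offsets = {}
    off = 0
    for chrom, pos in pos_by_chrom.items():
        chrom_offsets[chrom] = off
        off += pos.size
    for isl in cfg.islands:
        k = int(np.ceil(isl.carrier_fraction * cfg.n_samples))
        carriers = np.sort(rng.choice(cfg.n_samples, size=k, replace=False))
        pos = pos_by_chrom[isl.chrom]
        lo = int(np.searchsorted(pos, isl.start, side="left"))
        hi = int(np.searchsorted(pos, isl.end, side="right"))
        idx = np.arange(lo, hi) + chrom_offsets[isl.chrom]
        alleles = (rng.random(idx.size) < p_anc[idx]).astype(np.int8)
        island_carriers.append(carriers)
        island_alleles.append(alleles)
        island_site_idx.append(idx)

    # plant segments per sample
    seg_rows = []
    calls = np.empty((cfg.n_samples, n_sites), dtype=np.int8)
    min_len = cfg.length_mixture[0][0]
    for si, sample in enumerate(samples):
        placer = _Placer(cfg.chromosomes, rng)
        planted: list[tuple[str, int, int]] = []
        total = 0
        for which, carriers in enumerate(island_carriers):
            if si not in carriers:
                continue
            isl = cfg.islands[which]
            pad_l = int(rng.uniform(2e5, 8e5))
            pad_r = int(rng.uniform(2e5, 8e5))
            start = max(1, isl.start - pad_l)
            end = min(cfg.chromosomes[isl.chrom], isl.end + pad_r)
            if not placer.place_fixed(isl.chrom, start, end):
                raise RuntimeError("island placement collision")
            planted.append((isl.chrom, start, end))
            total += end - start + 1
        needed = targets[si] * genome
        while total < needed:
            length = _draw_length(rng, cfg.length_mixture)
            remaining = needed - total
            if remaining < length:
                if remaining >= min_len:
                    length = int(remaining)
                elif planted:
                    # extend the previous segment rather than placing a sliver
                    chrom, start, end = planted[-1]
                    grow = int(remaining)
                    if end + grow <= cfg.chromosomes[chrom] and \
                            placer.place_fixed(chrom, end + 1, end + grow):
                        placer.occupied[chrom].remove((start, end))
                        placer.occupied[chrom].remove((end + 1, end + grow))
                        placer.place_fixed(chrom, start, end + grow)
                        planted[-1] = (chrom, start, end + grow)
                        total += grow
                    break
                else:
                    break
            spot = placer.place(length)
            if spot is None:
                # no gap fits the drawn length: fill the largest gap instead
                gap = placer.largest_gap()
                if gap is None or gap[2] - gap[1] + 1 < min_len:
                    raise RuntimeError(
                        f"target autozygosity {targets[si]:.3f} unreachable "
                        f"for {sample}: shortfall {needed - total:.0f} bp")
                chrom, gs, ge = gap
                length = min(length, ge - gs + 1)
                placer.place_fixed(chrom, gs, gs + length - 1)
                spot = (chrom, gs, gs + length - 1)
            chrom, start, end = spot
            planted.append((chrom, start, end))
            total += length
        for chrom, start, end in sorted(planted):
            seg_rows.append((sample, chrom, start, end, end - start + 1))

        # genotypes: HWE background, overwritten inside planted segments
        p_s = pop_freqs[pop_index[pop_labels[si]]]
        dosage = rng.binomial(2, p_s).astype(np.int8)
        roh_mask = np.zeros(n_sites, dtype=bool)
        for chrom, start, end in planted:
            pos = pos_by_chrom[chrom]
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, end, side="right"))
            roh_mask[chrom_offsets[chrom] + lo: chrom_offsets[chrom] + hi] = True
        n_roh = int(roh_mask.sum())
        if n_roh:
            allele = (rng.random(n_roh) < p_s[roh_mask]).astype(np.int8)
            dosage[roh_mask] = 2 * allele
        for which, carriers in enumerate(island_carriers):
            if si in carriers:
                dosage[island_site_idx[which]] = 2 * island_alleles[which]
        if n_roh and cfg.error_rate > 0:
            flip = rng.random(n_roh) < cfg.error_rate
            idx = np.flatnonzero(roh_mask)[flip]
            dosage[idx] = 1
        if cfg.missing_rate > 0:
            dosage[rng.random(n_sites) < cfg.missing_rate] = MISSING
        calls[si] = dosage

    seg_df = pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "start", "end", "length_bp"])
    froh_true = seg_df.groupby("sample")["length_bp"].sum() \
        .reindex(samples, fill_value=0) / genome
    truth = TruthSet(
        segments=seg_df,
        froh=froh_true.rename("true_froh"),
        populations=pd.Series(pop_labels, index=samples, name="population"),
        site_freqs=pop_freqs,
        genome_bp=genome,
    )
    matrix = GenotypeMatrix(samples=samples, sites=sites, calls=calls)
    return SimResult(matrix=matrix, truth=truth)


def _interval_overlap(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Total bp overlap between two sets of disjoint sorted intervals."""
    total = 0
    i = j = 0
    a = sorted(a)
    b = sorted(b)
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            total += hi - lo + 1
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def truth_compare(called: Sequence[ROHSegment], truth: TruthSet,
                  min_planted_bp: int = 0) -> pd.DataFrame:
    """Base-pair recall and precision of called ROH against planted truth.

    Recall = overlap / planted length, restricted to planted segments of at
    least ``min_planted_bp``; precision = overlap with *all* planted bp /
    called length.  Per-sample rows; NaN where the denominator is empty.
    """
    called_by = {}
    for s in called:
        called_by.setdefault(s.sample, {}).setdefault(s.chrom, []) \
            .append((s.start, s.end))
    rows = []
    for sample in truth.froh.index:
        planted = truth.sample_segments(sample)
        planted_sel = planted[planted["length_bp"] >= min_planted_bp]
        csegs = called_by.get(sample, {})
        overlap_sel = 0
        overlap_all = 0
        for chrom, grp in planted.groupby("chrom"):
            c = csegs.get(chrom, [])
            ivs = list(zip(grp["start"], grp["end"]))
            overlap_all += _interval_overlap(ivs, c)
        for chrom, grp in planted_sel.groupby("chrom"):
            c = csegs.get(chrom, [])
            ivs = list(zip(grp["start"], grp["end"]))
            overlap_sel += _interval_overlap(ivs, c)
        planted_bp = int(planted_sel["length_bp"].sum())
        called_bp = sum(e - s + 1 for ivs in csegs.values() for s, e in ivs)
        rows.append({
            "sample": sample,
            "planted_bp": planted_bp,
            "called_bp": called_bp,
            "recall": overlap_sel / planted_bp if planted_bp else np.nan,
            "precision": overlap_all / called_bp if called_bp else np.nan,
        })
    return pd.DataFrame(rows).set_index("sample")
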