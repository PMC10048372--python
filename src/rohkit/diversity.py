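"""Per-sample and per-group diversity summaries.

Observed heterozygosity, the genomic inbreeding coefficient F_ROH (total ROH
length over the autosomal genome length covered by SNV positions), its
decomposition over ROH length classes, and a one-way ANOVA of group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix
from .roh import ROHSegment


@dataclass(frozen=True)
class LengthClassScheme:
    """Ascending bp cut points partitioning ROH lengths into classes.

    Default 1, 2, 4, 8, 10 Mb -> six classes: <1, 1-2, 2-4, 4-8, 8-10, >10 Mb.
    Binning is [lower, upper) so every segment falls in exactly one class.
    """

    boundaries: tuple[int, ...] = (1_000_000, 2_000_000, 4_000_000,
                                   8_000_000, 10_000_000)

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) < 1 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly ascending, >=1 cut")

    @property
    def labels(self) -> list[str]:
        mb = [f"{x / 1e6:g}" for x in self.boundaries]
        out = [f"<{mb[0]}Mb"]
        out += [f"{mb[i]}-{mb[i + 1]}Mb" for i in range(len(mb) - 1)]
        out.append(f">{mb[-1]}Mb")
        return out

    def classify(self, length_bp: int) -> int:
        return int(np.searchsorted(self.boundaries, length_bp, side="right"))


@dataclass(frozen=True)
class GenomeDenominator:
    """Autosomal bp covered by SNV positions — the F_ROH denominator."""

    value_bp: int

    def __post_init__(self) -> None:
        if self.value_bp <= 0:
            raise ValueError("denominator must be positive")


def observed_heterozygosity(m: GenotypeMatrix) -> tuple[pd.Series, float]:
    """Per-sample het calls / called genotypes, plus the unweighted cohort
    mean.  A sample with no called genotype gets NaN and is excluded from
    the mean."""
    called = (m.calls != MISSING).sum(axis=1)
    het = (m.calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(called > 0, het / called, np.nan)
    per_sample = pd.Series(frac, index=m.samples, name="obs_het")
    return per_sample, float(np.nanmean(frac))


def compute_denominator(m: GenotypeMatrix,
                        override: int | None = None) -> GenomeDenominator:
    """Sum over chromosomes of (max SNV pos - min SNV pos + 1), or a fixed
    constant when ``override`` is given (for published denominators whose
    derivation differs)."""
    if override is not None:
        return GenomeDenominator(int(override))
    total = 0
    for _, grp in m.sites.groupby("chrom", sort=False):
        pos = grp["pos"]
        if len(pos):
            total += int(pos.max() - pos.min() + 1)
    return GenomeDenominator(total)


def _check_non_overlapping(segments: Sequence[ROHSegment]) -> None:
    by_chrom: dict[str, list[ROHSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]")


def froh(segments: Sequence[ROHSegment], d: GenomeDenominator) -> float:
    """Total ROH length of one sample divided by the genome denominator."""
    if not segments:
        return 0.0
    samples = {s.sample for s in segments}
    if len(samples) > 1:
        raise ValueError(f"froh expects one sample's segments, got {samples}")
    _check_non_overlapping(segments)
    return sum(s.length_bp for s in segments) / d.value_bp


def froh_by_class(segments: Sequence[ROHSegment],
                  scheme: LengthClassScheme,
                  d: GenomeDenominator) -> pd.Series:
    """F_ROH split by ROH length class; the class sums re-add to F_ROH
    exactly (each segment is binned into exactly one class)."""
    if segments:
        _check_non_overlapping(segments)
    totals = np.zeros(len(scheme.boundaries) + 1, dtype=np.int64)
    for s in segments:
        totals[scheme.classify(s.length_bp)] += s.length_bp
    return pd.Series(totals / d.value_bp, index=scheme.labels, name="froh")


def sample_diversity_table(m: GenotypeMatrix,
                           segments: Sequence[ROHSegment],
                           d: GenomeDenominator,
                           groups: Mapping[str, str] | None = None,
                           scheme: LengthClassScheme = LengthClassScheme(),
                           ) -> pd.DataFrame:
    """Per-sample summary: group, n_roh, total/mean ROH length, F_ROH,
    per-class F_ROH and observed heterozygosity."""
    het, _ = observed_heterozygosity(m)
    by_sample: dict[str, list[ROHSegment]] = {s: [] for s in m.samples}
    for seg in segments:
        by_sample.setdefault(seg.sample, []).append(seg)
    rows = []
    for sample in m.samples:
        segs = by_sample[sample]
        total = sum(s.length_bp for s in segs)
        row = {
            "sample": sample,
            "group": (groups or {}).get(sample, ""),
            "n_roh": len(segs),
            "total_roh_bp": total,
            "mean_roh_bp": total / len(segs) if segs else np.nan,
            "froh": froh(segs, d),
            "obs_het": het[sample],
        }
        row.update({f"froh_{lab}": v
                    for lab, v in froh_by_class(segs, scheme, d).items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


def group_anova(values: Sequence[float],
                groups: Sequence[str]) -> tuple[float, float]:
    """Classical one-way ANOVA across group labels: F statistic and upper-tail
    p-value.  Requires >=2 groups with >=2 samples each."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if values.shape != labels.shape:
        raise ValueError("values and groups must align")
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    arrays = [values[labels == g] for g in uniq]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two samples")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)
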