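"""ROH islands: per-SNV incidence, >=90% island calling, gene annotation
and within-island haplotype audit.

Incidence at a SNV is the fraction of samples whose ROH cover that position.
Islands are maximal runs of *consecutive* SNVs (index space — bp gaps do not
break an island, but the largest internal gap is reported for audit) whose
incidence reaches the threshold; there is no minimum size, so a single SNV
can form an island.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genotypes import MISSING, GenotypeMatrix
from .roh import ROHSegment


@dataclass
class IslandRegion:
    chrom: str
    start: int  # 1-based bp of first member SNV
    end: int    # 1-based bp of last member SNV
    n_snvs: int
    min_incidence: float
    max_gap_bp: int = 0
    genes: list[str] = field(default_factory=list)
    het_breaks: list["HetBreak"] = field(default_factory=list)


@dataclass(frozen=True)
class HetBreak:
    """A sub-interval of an island where >=1 sample shows a stretch of >=k
    consecutive heterozygous calls."""

    chrom: str
    start: int
    end: int
    n_samples: int


def snv_incidence(segments: Sequence[ROHSegment],
                  m: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNV fraction of samples whose ROH cover it.

    Returns a DataFrame (chrom, pos, incidence) aligned with ``m.sites``.
    Segments of one sample must be non-overlapping, so a simple count per
    sample-covering segment is exact.
    """
    counts = np.zeros(m.n_sites, dtype=np.int32)
    positions = m.sites["pos"].to_numpy()
    slices = {c: m.chrom_slice(c) for c in m.chromosomes()}
    for seg in segments:
        sl = slices.get(seg.chrom)
        if sl is None:
            continue
        pos = positions[sl]
        lo = int(np.searchsorted(pos, seg.start, side="left"))
        hi = int(np.searchsorted(pos, seg.end, side="right"))
        counts[sl.start + lo: sl.start + hi] += 1
    return pd.DataFrame({
        "chrom": m.sites["chrom"],
        "pos": m.sites["pos"],
        "incidence": counts / m.n_samples,
    })


def call_islands(track: pd.DataFrame, threshold: float = 0.90) -> list[IslandRegion]:
    """Maximal runs of consecutive SNVs with incidence >= threshold.

    With 33 samples the 90% rule triggers at exactly 30 covered samples
    (30/33 = 0.909 >= 0.90; 29/33 = 0.879 < 0.90).
    """
    regions: list[IslandRegion] = []
    for chrom, grp in track.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        inc = grp["incidence"].to_numpy()
        above = inc >= threshold
        i = 0
        n = len(pos)
        while i < n:
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            gaps = np.diff(pos[i:j + 1])
            regions.append(IslandRegion(
                chrom=str(chrom), start=int(pos[i]), end=int(pos[j]),
                n_snvs=j - i + 1,
                min_incidence=float(inc[i:j + 1].min()),
                max_gap_bp=int(gaps.max()) if gaps.size else 0))
            i = j + 1
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _gff_feature_name(attributes: str) -> str:
    fields = dict(kv.split("=", 1) for kv in attributes.split(";") if "=" in kv)
    for key in ("Name", "gene", "gene_name", "ID"):
        if key in fields:
            return fields[key]
    return attributes


def read_gene_intervals(path: str) -> pd.DataFrame:
    """Load gene intervals from GFF3 (``gene`` features; 1-based inclusive)
    or BED (0-based half-open), normalised to 1-based inclusive columns
    (chrom, start, end, name)."""
    rows = []
    if path.endswith((".bed", ".bed.txt")):
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                rows.append((f[0], int(f[1]) + 1, int(f[2]), name))
    else:
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                rows.append((f[0], int(f[3]), int(f[4]), _gff_feature_name(f[8])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def annotate_islands(regions: Sequence[IslandRegion],
                     annotation: pd.DataFrame) -> list[IslandRegion]:
    """Attach gene names overlapping each island by >=1 bp (in place, also
    returned).  Regions on chromosomes absent from the annotation get an
    empty list and a warning."""
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in annotation.groupby("chrom", sort=False):
        tree = IntervalTree()
        for _, row in grp.iterrows():
            tree[row["start"]: row["end"] + 1] = row["name"]  # half-open tree
        trees[str(chrom)] = tree
    for region in regions:
        tree = trees.get(region.chrom)
        if tree is None:
            warnings.warn(f"no annotation for chromosome {region.chrom}")
            region.genes = []
            continue
        hits = tree[region.start: region.end + 1]
        region.genes = sorted({iv.data for iv in hits})
    return list(regions)


def haplotype_audit(region: IslandRegion, m: GenotypeMatrix,
                    min_het_run: int = 2) -> tuple[str, list[HetBreak]]:
    """Check whether an island reflects one shared haplotype.

    Verdict ``identical`` iff at every member SNV all samples carry the same
    homozygous genotype or are missing.  ``het_breaks`` lists maximal
    sub-intervals where any sample shows >= ``min_het_run`` consecutive
    heterozygous calls, with the number of affected samples.
    """
    sl = m.chrom_slice(region.chrom)
    pos = m.sites["pos"].to_numpy()[sl]
    lo = int(np.searchsorted(pos, region.start, side="left"))
    hi = int(np.searchsorted(pos, region.end, side="right"))
    calls = m.calls[:, sl.start + lo: sl.start + hi]
    pos = pos[lo:hi]

    identical = True
    for j in range(calls.shape[1]):
        col = calls[:, j]
        called = col[col != MISSING]
        if called.size == 0:
            continue
        if (called == 1).any() or np.unique(called).size > 1:
            identical = False
            break

    # per-sample runs of consecutive het calls, merged across samples
    runs: list[tuple[int, int, int]] = []  # (start_idx, end_idx, sample_idx)
    for si in range(calls.shape[0]):
        het = calls[si] == 1
        i = 0
        while i < het.size:
            if not het[i]:
                i += 1
                continue
            j = i
            while j + 1 < het.size and het[j + 1]:
                j += 1
            if j - i + 1 >= min_het_run:
                runs.append((i, j, si))
            i = j + 1

    breaks: list[HetBreak] = []
    if runs:
        runs.sort()
        cur_lo, cur_hi = runs[0][0], runs[0][1]
        members = {runs[0][2]}
        for a, b, si in runs[1:]:
            if a <= cur_hi:  # overlapping index intervals merge
                cur_hi = max(cur_hi, b)
                members.add(si)
            else:
                breaks.append(HetBreak(region.chrom, int(pos[cur_lo]),
                                       int(pos[cur_hi]), len(members)))
                cur_lo, cur_hi, members = a, b, {si}
        breaks.append(HetBreak(region.chrom, int(pos[cur_lo]),
                               int(pos[cur_hi]), len(members)))
    verdict = "identical" if identical else "not-identical"
    return verdict, breaks


def islands_to_frame(regions: Sequence[IslandRegion]) -> pd.DataFrame:
    rows = [(r.chrom, r.start, r.end, r.n_snvs, r.min_incidence, r.max_gap_bp,
             ",".join(r.genes)) for r in regions]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snvs",
                                       "min_incidence", "max_gap_bp", "genes"])
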