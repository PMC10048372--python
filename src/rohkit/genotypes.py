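"""Genotype containers, VCF input and site-quality filtering.

The central container is :class:`GenotypeMatrix`: an ordered samples x sites
matrix of diploid dosage codes (0 hom-ref, 1 het, 2 hom-alt, -1 missing).
Coordinates are 1-based inclusive throughout (VCF convention); BED output
converts to 0-based half-open.

Half-called genotypes (e.g. ``0/.``) are treated as missing — conservative
and unambiguous.  Chromosome labels are opaque strings; the autosome set is
supplied by the caller, never inferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING: int = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "filter", "vtype"]


def classify_vtype(ref: str, alts: Sequence[str]) -> str:
    """SNV iff ref and every alt are single bases; indel if all are plain
    sequence alleles of unequal length; anything else (symbolic alleles,
    no alt) is 'other'."""
    if not alts:
        return "other"
    if any(a.startswith("<") or a == "*" or not a for a in alts):
        return "other"
    if len(ref) == 1 and all(len(a) == 1 for a in alts):
        return "SNV"
    return "indel"


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: tuple[str, ...]
    filter: str = "PASS"

    @property
    def vtype(self) -> str:
        return classify_vtype(self.ref, self.alt)


@dataclass
class GenotypeMatrix:
    """Samples x ordered variant sites with dosage codes 0/1/2/MISSING.

    ``sites`` is a DataFrame with columns chrom, pos, ref, alt (comma-joined),
    filter, vtype; ``calls`` is an int8 array of shape (n_samples, n_sites).
    """

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.sites)})"
            )
        self.sites = self.sites.reset_index(drop=True)
        self._validate_sites()

    def _validate_sites(self) -> None:
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(
                    f"site positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        return list(dict.fromkeys(self.sites["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous site-index slice for one chromosome."""
        idx = np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            return slice(0, 0)
        if not np.all(np.diff(idx) == 1):
            raise ValueError(f"sites of chromosome {chrom} are not contiguous")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[keep].reset_index(drop=True),
            calls=self.calls[:, keep],
        )

    def call_rate(self) -> np.ndarray:
        """Per-site fraction of non-missing genotypes."""
        return (self.calls != MISSING).mean(axis=0)


@dataclass(frozen=True)
class FilterPolicy:
    """Site-quality policy: PASS status, call rate strictly greater than
    ``min_call_rate`` (so >90% keeps a 30/33 site and drops 29/33), biallelic
    SNVs only, and an explicit autosome set."""

    require_pass: bool = True
    min_call_rate: float = 0.90
    biallelic_snv_only: bool = True
    allowed_chroms: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in [0, 1]")


def _dosage_from_alleles(a0: int, a1: int) -> int:
    if a0 < 0 or a1 < 0:
        return MISSING
    if a0 != a1:
        return 1
    return 0 if a0 == 0 else 2


def read_vcf(path: str, sample_subset: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read a multi-sample VCF (plain or bgzipped) into a GenotypeMatrix.

    Phased and unphased genotypes are treated identically; any genotype with a
    missing allele (``./.`` or half-calls) becomes MISSING.  Multi-allelic
    records are retained (het between two alt alleles codes as 1) and left to
    :func:`apply_filters` to remove.
    """
    vcf = VCF(path)
    if "GT" not in {f["ID"] for f in vcf.header_iter() if f["HeaderType"] == "FORMAT"}:
        raise ValueError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    if sample_subset is not None:
        missing = set(sample_subset) - set(samples)
        if missing:
            raise ValueError(f"samples not in VCF: {sorted(missing)}")
        sample_idx = [samples.index(s) for s in sample_subset]
        samples = list(sample_subset)
    else:
        sample_idx = list(range(len(samples)))

    rows = []
    cols = []
    for v in vcf:
        alts = tuple(v.ALT) if v.ALT else ()
        filt = "PASS" if v.FILTER is None else v.FILTER
        rows.append((v.CHROM, v.POS, v.REF, ",".join(alts), filt,
                     classify_vtype(v.REF, alts)))
        arr = v.genotype.array()
        if arr.shape[1] < 3:  # haploid records: duplicate the single allele
            alle = arr[:, 0]
            col = [_dosage_from_alleles(int(alle[i]), int(alle[i])) for i in sample_idx]
        else:
            col = [_dosage_from_alleles(int(arr[i, 0]), int(arr[i, 1]))
                   for i in sample_idx]
        cols.append(col)
    vcf.close()

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    calls = (np.array(cols, dtype=np.int8).T if cols
             else np.zeros((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


def write_vcf(m: GenotypeMatrix, path: str) -> None:
    """Write a GenotypeMatrix as a minimal plain-text VCF 4.2 file."""
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FILTER=<ID=LowQual,Description="Low quality">\n')
        for chrom, grp in m.sites.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(m.samples) + "\n")
        chroms = m.sites["chrom"].to_numpy()
        pos = m.sites["pos"].to_numpy()
        refs = m.sites["ref"].to_numpy()
        alts = m.sites["alt"].to_numpy()
        filts = m.sites["filter"].to_numpy()
        for j in range(m.n_sites):
            gts = "\t".join(code_to_gt[int(c)] for c in m.calls[:, j])
            fh.write(f"{chroms[j]}\t{pos[j]}\t.\t{refs[j]}\t{alts[j] or '.'}\t.\t"
                     f"{filts[j]}\t.\tGT\t{gts}\n")


def apply_filters(m: GenotypeMatrix, p: FilterPolicy) -> GenotypeMatrix:
    """Retain sites satisfying the policy; sample and site order preserved.

    Idempotent: filtering a filtered matrix changes nothing.
    """
    if m.n_sites == 0:
        return m
    keep = np.ones(m.n_sites, dtype=bool)
    if p.require_pass:
        keep &= (m.sites["filter"] == "PASS").to_numpy()
    if p.biallelic_snv_only:
        n_alt = m.sites["alt"].map(lambda a: len(a.split(",")) if a else 0).to_numpy()
        keep &= (m.sites["vtype"] == "SNV").to_numpy() & (n_alt == 1)
    if p.allowed_chroms is not None:
        keep &= m.sites["chrom"].isin(p.allowed_chroms).to_numpy()
    keep &= m.call_rate() > p.min_call_rate
    if not keep.any():
        warnings.warn("no sites survive filtering; returning empty matrix")
    return m.subset_sites(keep)


def write_segments_bed(segments: Iterable, path: str) -> None:
    """Write ROH segments as BED: chrom, 0-based start, end, sample, n_snvs.

    Input is sorted by (sample, chrom, start) if it is not already.
    """
    segs = sorted(segments, key=lambda s: (s.sample, s.chrom, s.start))
    with open(path, "w") as fh:
        for s in segs:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.sample}\t{s.n_snvs}\n")


def read_segments_bed(path: str):
    """Inverse of :func:`write_segments_bed` (coordinates back to 1-based)."""
    from .roh import ROHSegment  # local import to avoid a cycle

    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start0, end, sample, n_snvs = line.rstrip("\n").split("\t")[:5]
            out.append(ROHSegment(sample=sample, chrom=chrom,
                                  start=int(start0) + 1, end=int(end),
                                  n_snvs=int(n_snvs), n_het=0))
    return out


def segments_to_frame(segments: Iterable) -> pd.DataFrame:
    """Tabulate ROH segments (sample, chrom, start, end, n_snvs, n_het, length_bp)."""
    rows = [(s.sample, s.chrom, s.start, s.end, s.n_snvs, s.n_het, s.length_bp)
            for s in segments]
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_snvs", "n_het",
                       "length_bp"])
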