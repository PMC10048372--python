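"""Breed-relevant variant genotyping, risk-haplotype doses and index, group
frequency comparison, and mtDNA haplotype assignment.

Definitions ship as YAML under ``rohkit/data``: the trait-variant table
(coordinates on the working assembly), the four histiocytic-sarcoma risk loci
with their haplotype-defining SNV positions, and an mtDNA haplotype table.
The haplotype *dose* at a risk locus is a consensus rule — the rounded median
of the dosages at the defining SNVs — with the per-SNV discordance fraction
always reported so the call can be audited; the published studies do not
state the aggregation rule, so it is explicit configuration here, not a
claim.  Likewise the A/B/C index mapping from total risk-allele count is a
configurable monotone rule with a non-authoritative default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class TraitVariantDef:
    label: str
    trait: str
    omia_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class RiskLocusDef:
    label: str
    chrom: str
    defining_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.defining_positions:
            raise ValueError("risk locus needs >=1 defining position")


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype-class counts at one variant; present=False marks a variant
    absent from the matrix (reported explicitly, never as zeros)."""

    n_refref: int
    n_refalt: int
    n_altalt: int
    n_missing: int = 0
    present: bool = True

    @property
    def n_called(self) -> int:
        return self.n_refref + self.n_refalt + self.n_altalt


def _data_path(name: str):
    return resources.files("rohkit").joinpath("data", name)


def load_trait_variants(path=None) -> list[TraitVariantDef]:
    src = path if path is not None else _data_path("trait_variants.yaml")
    with open(src) as fh:
        entries = yaml.safe_load(fh)
    return [TraitVariantDef(**e) for e in entries]


def load_risk_loci(path=None) -> list[RiskLocusDef]:
    src = path if path is not None else _data_path("risk_loci.yaml")
    with open(src) as fh:
        entries = yaml.safe_load(fh)
    return [RiskLocusDef(label=e["label"], chrom=str(e["chrom"]),
                         defining_positions=tuple(e["defining_positions"]))
            for e in entries]


def load_mtdna_table(path=None) -> dict[str, set[tuple[int, str]]]:
    """Haplotype label -> set of (position, allele) defining variants."""
    src = path if path is not None else _data_path("mtdna_haplotypes_synthetic.yaml")
    with open(src) as fh:
        entries = yaml.safe_load(fh)
    table = {}
    for label, variants in entries.items():
        if label in table:
            raise ValueError(f"duplicate haplotype label {label}")
        table[label] = {(int(v["pos"]), str(v["allele"])) for v in variants}
    return table


def find_site(m: GenotypeMatrix, v: TraitVariantDef) -> int | None:
    """Exact-coordinate + allele match (no local realignment)."""
    hit = (m.sites["chrom"].to_numpy() == v.chrom) \
        & (m.sites["pos"].to_numpy() == v.pos) \
        & (m.sites["ref"].to_numpy() == v.ref) \
        & (m.sites["alt"].to_numpy() == v.alt)
    idx = np.flatnonzero(hit)
    return int(idx[0]) if idx.size else None


def genotype_counts(m: GenotypeMatrix, v: TraitVariantDef) -> GenotypeCounts:
    """Count Ref/Ref, Ref/Alt, Alt/Alt and missing over all samples; counts
    plus missing always sum to the sample count."""
    j = find_site(m, v)
    if j is None:
        return GenotypeCounts(0, 0, 0, 0, present=False)
    col = m.calls[:, j]
    return GenotypeCounts(
        n_refref=int((col == 0).sum()),
        n_refalt=int((col == 1).sum()),
        n_altalt=int((col == 2).sum()),
        n_missing=int((col == MISSING).sum()),
    )


def allele_frequency(counts: GenotypeCounts) -> float:
    """Alternative-allele frequency (het + 2*hom-alt) / (2*called)."""
    if not counts.present or counts.n_called == 0:
        raise ValueError("allele frequency undefined: no called genotypes")
    return (counts.n_refalt + 2 * counts.n_altalt) / (2 * counts.n_called)


def haplotype_dose(m: GenotypeMatrix, locus: RiskLocusDef,
                   sample: str) -> tuple[int | None, float]:
    """Consensus risk-haplotype dose in {0,1,2} for one sample.

    Dose is the rounded (half-up) median of the dosages at the defining SNVs
    present and called; if fewer than half the defining positions are
    genotyped the dose is missing (None).  Returns (dose, discordance) where
    discordance is the fraction of called defining SNVs disagreeing with the
    consensus.
    """
    si = m.sample_index(sample)
    chrom_mask = m.sites["chrom"].to_numpy() == locus.chrom
    pos = m.sites["pos"].to_numpy()
    dosages = []
    for target in locus.defining_positions:
        idx = np.flatnonzero(chrom_mask & (pos == target))
        if idx.size:
            call = int(m.calls[si, int(idx[0])])
            if call != MISSING:
                dosages.append(call)
    if len(dosages) < math.ceil(len(locus.defining_positions) / 2):
        return None, float("nan")
    med = float(np.median(dosages))
    dose = int(math.floor(med + 0.5))
    discordance = float(np.mean(np.asarray(dosages) != dose))
    return dose, discordance


def locus_genotype_counts(m: GenotypeMatrix,
                          locus: RiskLocusDef) -> GenotypeCounts:
    """Aggregate per-sample haplotype doses into genotype-class counts."""
    doses = [haplotype_dose(m, locus, s)[0] for s in m.samples]
    return GenotypeCounts(
        n_refref=sum(d == 0 for d in doses),
        n_refalt=sum(d == 1 for d in doses),
        n_altalt=sum(d == 2 for d in doses),
        n_missing=sum(d is None for d in doses),
    )


DEFAULT_RISK_RULE: dict[str, tuple[int, int]] = {
    # non-authoritative monotone default: total risk-allele count -> category
    "A": (0, 2),
    "B": (3, 5),
    "C": (6, 8),
}


def _validate_risk_rule(rule: Mapping[str, tuple[int, int]]) -> None:
    spans = sorted(rule.items(), key=lambda kv: kv[1][0])
    covered = []
    for label, (lo, hi) in spans:
        if lo > hi:
            raise ValueError(f"rule band {label} has lo > hi")
        covered.extend(range(lo, hi + 1))
    if covered != list(range(0, 9)):
        raise ValueError("risk rule must partition total doses 0..8")
    order = [label for label, _ in spans]
    if order != sorted(order):  # A < B < C in label order = monotone risk
        raise ValueError("risk rule must be monotone in total dose")


def risk_index(doses: Sequence[int | None],
               rule: Mapping[str, tuple[int, int]] | None = None) -> str | None:
    """Map the four locus doses to the A/B/C risk category (C = greatest
    risk).  Any missing dose yields a missing index."""
    rule = dict(rule) if rule is not None else dict(DEFAULT_RISK_RULE)
    _validate_risk_rule(rule)
    if len(doses) != 4:
        raise ValueError("expected doses at exactly four risk loci")
    if any(d is None for d in doses):
        return None
    total = int(sum(doses))
    for label, (lo, hi) in rule.items():
        if lo <= total <= hi:
            return label
    raise AssertionError("validated rule must cover every total")


def compare_group_frequencies(
        counts_g1: tuple[int, int],
        counts_g2: tuple[int, int]) -> tuple[float, float, float, float]:
    """Compare allele/haplotype frequencies between two groups.

    Inputs are (risk, non-risk) allele counts per group.  Returns
    (freq_g1, freq_g2, odds_ratio, two-sided Fisher exact p).
    """
    a, b = counts_g1
    c, d = counts_g2
    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        warnings.warn("empty margin in 2x2 table; p set to 1")
        return (a / (a + b) if a + b else float("nan"),
                c / (c + d) if c + d else float("nan"),
                float("nan"), 1.0)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return a / (a + b), c / (c + d), float(odds), float(p)


@dataclass(frozen=True)
class MtdnaAssignment:
    haplotypes: tuple[str, ...]   # all fully matched labels (ties reported)
    unexplained: tuple[tuple[int, str], ...]
    best_partial: str | None = None
    best_partial_fraction: float = 0.0

    @property
    def label(self) -> str:
        return "/".join(self.haplotypes) if self.haplotypes else "unassigned"


def mtdna_haplotype(sample_variants: set[tuple[int, str]],
                    table: Mapping[str, set[tuple[int, str]]]) -> MtdnaAssignment:
    """Assign the haplotype(s) whose defining variant set is fully contained
    in the sample's variant profile; variants outside every definition are
    listed as unexplained.  With no full match, report the best partial
    match."""
    if not table:
        raise ValueError("empty haplotype table")
    full = [label for label, defn in table.items()
            if defn and defn <= sample_variants]
    defined = set().union(*table.values())
    unexplained = tuple(sorted(sample_variants - defined))
    if full:
        return MtdnaAssignment(haplotypes=tuple(sorted(full)),
                               unexplained=unexplained)
    best, best_frac = None, 0.0
    for label, defn in table.items():
        frac = len(defn & sample_variants) / len(defn) if defn else 0.0
        if frac > best_frac:
            best, best_frac = label, frac
    return MtdnaAssignment(haplotypes=(), unexplained=unexplained,
                           best_partial=best, best_partial_fraction=best_frac)


def trait_variant_report(m: GenotypeMatrix,
                         defs: Sequence[TraitVariantDef] | None = None
                         ) -> pd.DataFrame:
    """Genotype-class counts and alternative-allele frequency for every
    trait-variant definition (frequency rounded to 3 decimals for report)."""
    defs = defs if defs is not None else load_trait_variants()
    rows = []
    for v in defs:
        c = genotype_counts(m, v)
        freq = (round(allele_frequency(c), 3)
                if c.present and c.n_called else np.nan)
        rows.append((v.label, v.gene, v.trait, c.present, c.n_refref,
                     c.n_refalt, c.n_altalt, c.n_missing, freq))
    return pd.DataFrame(rows, columns=[
        "label", "gene", "trait", "genotyped", "n_refref", "n_refalt",
        "n_altalt", "n_missing", "alt_frequency"])
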