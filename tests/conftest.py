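"""Shared fixtures: simulated cohorts and a 33-dog fixture matrix whose
genotype-class counts match the published breed-variant table."""

import numpy as np
import pandas as pd
import pytest

from rohkit import (
    GenotypeMatrix,
    SimConfig,
    detect_roh,
    load_risk_loci,
    load_trait_variants,
    simulate,
)
from rohkit.genotypes import classify_vtype

# printed genotype-class counts (Ref/Ref, Ref/Alt, Alt/Alt) for the 33-dog
# cohort; inputs to the fixture VCF, from which every frequency is recomputed
TABLE2_COUNTS = {
    "SOD1_c118GA": (10, 21, 2),
    "SOD1_c52AT": (32, 1, 0),
    "SP110_42620442": (4, 15, 14),
    "SP110_42623004": (5, 14, 14),
    "SP110_42628769": (23, 9, 1),
    "SP110_42631341": (23, 9, 1),
    "SP110_42633078": (14, 15, 4),
    "GFAP_18459694": (33, 0, 0),
    "IGF1_41511739": (31, 2, 0),
    "MSRB3_8395407del": (1, 0, 32),
    "FGF5_35475211": (33, 0, 0),
    "FGF5_35475230dup": (33, 0, 0),
    "FGF5_35475218del": (33, 0, 0),
    "FGF5_35486609": (33, 0, 0),
    "FGF5_35494497": (0, 0, 33),
    "ASIP_black_back": (0, 0, 33),
}
TABLE2_FREQS = {
    "SOD1_c118GA": 0.379,
    "SOD1_c52AT": 0.015,
    "SP110_42620442": 0.652,
    "SP110_42623004": 0.636,
    "SP110_42628769": 0.167,
    "SP110_42631341": 0.167,
    "SP110_42633078": 0.348,
    "GFAP_18459694": 0.000,
    "IGF1_41511739": 0.030,
    "MSRB3_8395407del": 0.970,
    "FGF5_35475211": 0.000,
    "FGF5_35475230dup": 0.000,
    "FGF5_35475218del": 0.000,
    "FGF5_35486609": 0.000,
    "FGF5_35494497": 1.000,
    "ASIP_black_back": 1.000,
}
RISK_COUNTS = {
    "chr5_33Mb": (5, 12, 16),
    "chr11_41Mb": (2, 14, 17),
    "chr11_44Mb": (4, 17, 12),
    "chr14_11Mb": (3, 19, 11),
}
RISK_FREQS = {
    "chr5_33Mb": 0.667,
    "chr11_41Mb": 0.727,
    "chr11_44Mb": 0.621,
    "chr14_11Mb": 0.621,
}


def build_table2_matrix() -> GenotypeMatrix:
    """33-sample matrix with the published per-variant genotype-class counts;
    every defining SNV of a risk locus carries the sample's haplotype dose."""
    samples = [f"D{i + 1:02d}" for i in range(33)]
    rows = []
    cols = []
    for v in load_trait_variants():
        rr, ra, aa = TABLE2_COUNTS[v.label]
        assert rr + ra + aa == 33
        rows.append((v.chrom, v.pos, v.ref, v.alt, "PASS",
                     classify_vtype(v.ref, (v.alt,))))
        cols.append([0] * rr + [1] * ra + [2] * aa)
    for locus in load_risk_loci():
        rr, ra, aa = RISK_COUNTS[locus.label]
        dose_col = [0] * rr + [1] * ra + [2] * aa
        for pos in locus.defining_positions:
            rows.append((locus.chrom, pos, "A", "G", "PASS", "SNV"))
            cols.append(dose_col)
    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "filter", "vtype"])
    calls = np.array(cols, dtype=np.int8).T
    order = np.lexsort((sites["pos"].to_numpy(),))
    # stable sort positions within each chromosome, keeping chrom blocks
    frames = []
    idx_parts = []
    for chrom in dict.fromkeys(sites["chrom"]):
        part = sites.index[sites["chrom"] == chrom].to_numpy()
        part = part[np.argsort(sites.loc[part, "pos"].to_numpy())]
        idx_parts.append(part)
    order = np.concatenate(idx_parts)
    return GenotypeMatrix(samples=samples,
                          sites=sites.iloc[order],
                          calls=calls[:, order])


@pytest.fixture(scope="session")
def table2_matrix() -> GenotypeMatrix:
    return build_table2_matrix()


@pytest.fixture(scope="session")
def sim_default():
    """Default study-conditions cohort: 33 samples, two subpopulations,
    per-sample F drawn on (0.32, 0.52)."""
    return simulate(SimConfig(seed=101))


@pytest.fixture(scope="session")
def roh_default(sim_default):
    return detect_roh(sim_default.matrix)


@pytest.fixture(scope="session")
def sim_tiny():
    """Desk-scale cohort for I/O round trips: 6 samples, two short autosomes."""
    cfg = SimConfig(seed=5, n_samples=6,
                    chromosomes={"1": 8_000_000, "2": 5_000_000},
                    target_froh=0.2, n_pops=1, divergence=0.0)
    return simulate(cfg)
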