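import numpy as np
import pandas as pd
import pytest

from tillerqtl import QtlEffect, SimConfig, simulate_bsa_experiment


@pytest.fixture(scope="session")
def two_qtl_experiment():
    """A bulked-segregant RIL(9) experiment with the study's design:
    49 lines, 8/12 bulks, complementary-epistasis QTLs on chr1 and chr6
    with the additive/dominance effects reported for the two loci."""
    cfg = SimConfig(
        chrom_lengths=[("chr1", 20_000_000), ("chr6", 20_000_000)],
        n_individuals=49,
        marker_spacing_bp=2_000,
        pop_type="RIL9",
        qtls=[QtlEffect("chr1", 6_000_000, 1.63, 0.60),
              QtlEffect("chr6", 14_000_000, 1.04, 1.25)],
        epistasis="complementary",
        noise_sd=0.3,
        phenotype_scale=3,
        depth_mean=50,
        seed=20,
    )
    table, pop, pheno, bulks = simulate_bsa_experiment(cfg, 8, 12)
    return cfg, table, pop, pheno, bulks


@pytest.fixture(scope="session")
def fitted_scan(two_qtl_experiment):
    from tillerqtl import QtlSeqScan

    cfg, table, *_ = two_qtl_experiment
    model = QtlSeqScan(snp_table=table, pop_model="RIL9", n_high=8, n_low=12,
                       chrom_lengths=cfg.chrom_lengths)
    return model.fit(alpha=0.05, n_reps=5000, window_reps=500, seed=7)


@pytest.fixture(scope="session")
def high_power_scan():
    """A high-resolution design (200 RILs bulked 30/30, depth 200, one
    additive QTL) where the refinement ladder has real localizing power;
    used to validate the fine-mapping machinery itself."""
    from tillerqtl import QtlSeqScan

    cfg = SimConfig(
        chrom_lengths=[("chr1", 10_000_000)],
        n_individuals=200,
        marker_spacing_bp=2_000,
        pop_type="RIL9",
        qtls=[QtlEffect("chr1", 6_000_000, 2.0, 0.0)],
        epistasis="additive",
        noise_sd=0.3,
        phenotype_scale=3,
        depth_mean=200,
        seed=2,
    )
    table, *_ = simulate_bsa_experiment(cfg, 30, 30)
    model = QtlSeqScan(snp_table=table, pop_model="RIL9", n_high=30,
                       n_low=30, chrom_lengths=cfg.chrom_lengths)
    res = model.fit(alpha=0.05, n_reps=4000, window_reps=300, seed=102)
    return cfg, res


def simulate_f2_markers(n=204, n_markers=17, length_cm=26.6, seed=0,
                        qtl_cm=None, a=0.0, d=0.0, noise_sd=1.0):
    """F2 marker genotypes on one linkage group with an optional QTL.

    Gamete alleles follow a Markov chain along evenly spaced markers
    (Haldane); returns (codes DataFrame, marker_info, phenotypes, truth_cm).
    """
    rng = np.random.default_rng(seed)
    cm = np.linspace(0.0, length_cm, n_markers)
    if qtl_cm is not None:
        cm = np.sort(np.unique(np.append(cm, qtl_cm)))
    r_adj = 0.5 * (1 - np.exp(-np.diff(cm) / 50.0))

    def gametes(size):
        g = np.empty((size, cm.size), dtype=np.int8)
        g[:, 0] = rng.integers(0, 2, size)
        for k, r in enumerate(r_adj):
            flip = rng.random(size) < r
            g[:, k + 1] = np.where(flip, 1 - g[:, k], g[:, k])
        return g

    dosage = gametes(n) + gametes(n)
    y = rng.normal(0.0, noise_sd, n)
    if qtl_cm is not None and (a or d):
        j = int(np.argmin(np.abs(cm - qtl_cm)))
        x = dosage[:, j].astype(float) - 1.0
        z = (dosage[:, j] == 1).astype(float)
        y = y + a * x + d * z
    codes = pd.DataFrame(np.array(["A", "H", "B"])[dosage],
                         columns=[f"m{k + 1}" for k in range(cm.size)])
    info = pd.DataFrame({"MARKER": codes.columns, "CHROM": "1",
                         "POS": (cm * 250_000).astype(np.int64) + 1})
    return codes, info, y, cm
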