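"""Recombination-fraction EM vs grid-search ML, Kosambi arithmetic, map
construction, HK/ICIM scans vs direct least squares, and permutation
thresholds."""

import numpy as np
import pandas as pd
import pytest

from tillerqtl import (IntervalMapper, LinkageConfig, build_map, estimate_rf,
                       haldane_inv, hk_scan, icim_scan, kosambi, kosambi_inv,
                       permutation_threshold)
from tillerqtl.linkage import encode_genotypes, f2_class_probs

from conftest import simulate_f2_markers


class TestKosambi:
    def test_zero_r_is_zero_distance(self):
        assert kosambi(0.0) == 0.0

    def test_quarter_r_closed_form(self):
        assert kosambi(0.25) == pytest.approx(25 * np.log(3.0), abs=1e-9)
        assert kosambi(0.25) == pytest.approx(27.465, abs=1e-3)

    @pytest.mark.parametrize("r", np.arange(0.01, 0.46, 0.04))
    def test_inverse_identity(self, r):
        assert kosambi_inv(kosambi(r)) == pytest.approx(r, abs=1e-12)

    def test_r_above_half_capped(self):
        assert kosambi(0.6) == kosambi(0.5)
        assert np.isfinite(kosambi(0.5))


def simulate_two_marker_f2(r, n, seed):
    rng = np.random.default_rng(seed)
    g1a = rng.integers(0, 2, n)
    g1b = rng.integers(0, 2, n)
    flip_a = rng.random(n) < r
    flip_b = rng.random(n) < r
    g2a = np.where(flip_a, 1 - g1a, g1a)
    g2b = np.where(flip_b, 1 - g1b, g1b)
    return (g1a + g1b).astype(np.int8), (g2a + g2b).astype(np.int8)


def grid_search_ml_rf(dos_i, dos_j):
    """Independent oracle: maximize the F2 class likelihood on a fine grid."""
    counts = np.zeros((3, 3))
    np.add.at(counts, (dos_i, dos_j), 1.0)
    grid = np.arange(0.0001, 0.5, 1e-4)
    best_r, best_ll = 0.25, -np.inf
    for r in grid:
        ll = float((counts * np.log(f2_class_probs(r))).sum())
        if ll > best_ll:
            best_ll, best_r = ll, r
    return best_r


class TestEstimateRf:
    def test_cosegregating_markers_give_zero(self):
        d = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 2], dtype=np.int8)
        assert estimate_rf(d, d) == pytest.approx(0.0, abs=1e-6)

    def test_unlinked_markers_near_half(self):
        d1, d2 = simulate_two_marker_f2(0.5, 2000, seed=1)
        assert estimate_rf(d1, d2) == pytest.approx(0.5, abs=0.03)

    def test_em_matches_grid_search_oracle(self):
        d1, d2 = simulate_two_marker_f2(0.1, 200, seed=2)
        em = estimate_rf(d1, d2)
        grid = grid_search_ml_rf(d1, d2)
        assert em == pytest.approx(grid, abs=1e-3)

    @pytest.mark.parametrize("true_r", [0.05, 0.2, 0.35])
    def test_em_matches_oracle_across_linkage_strengths(self, true_r):
        d1, d2 = simulate_two_marker_f2(true_r, 300, seed=int(true_r * 100))
        assert estimate_rf(d1, d2) == pytest.approx(
            grid_search_ml_rf(d1, d2), abs=1e-3)

    def test_missing_pairs_dropped_and_min_n_enforced(self):
        d1 = np.array([0, 1, 2, -1] * 2, dtype=np.int8)
        d2 = np.array([0, 1, 2, 0] * 2, dtype=np.int8)
        with pytest.raises(ValueError, match="need >= 10"):
            estimate_rf(d1, d2)


class TestBuildMap:
    def _info(self, n, chrom="1"):
        return pd.DataFrame({"MARKER": [f"m{k}" for k in range(n)],
                             "CHROM": chrom,
                             "POS": np.arange(1, n + 1) * 1000})

    def test_equidistant_markers_distances_add(self):
        rng = np.random.default_rng(3)
        n = 2000
        g1 = rng.integers(0, 2, n)
        h1 = rng.integers(0, 2, n)
        flip = lambda g: np.where(rng.random(n) < 0.1, 1 - g, g)
        g2, h2 = flip(g1), flip(h1)
        g3, h3 = flip(g2), flip(h2)
        dosage = np.column_stack([g1 + h1, g2 + h2, g3 + h3]).astype(np.int8)
        gmap = build_map(dosage, self._info(3))
        r12 = estimate_rf(dosage[:, 0], dosage[:, 1])
        r23 = estimate_rf(dosage[:, 1], dosage[:, 2])
        assert gmap.length("1") == pytest.approx(kosambi(r12) + kosambi(r23))

    def test_single_marker_zero_length(self):
        dosage = np.array([[0], [1], [2]] * 5, dtype=np.int8)
        gmap = build_map(dosage, self._info(1))
        assert gmap.length("1") == 0.0

    def test_first_marker_at_zero_positions_nondecreasing(self):
        codes, info, _, _ = simulate_f2_markers(n=200, seed=4)
        gmap = build_map(encode_genotypes(codes), info)
        cm = gmap.cm["1"]
        assert cm[0] == 0.0
        assert np.all(np.diff(cm) >= 0)


WORKED_CODES = ["A", "A", "H", "H", "B", "B"]
WORKED_Y = np.array([1.0, 1.0, 5.0, 5.0, 9.0, 9.0])


def worked_mapper(y=WORKED_Y):
    codes = pd.DataFrame({"m1": WORKED_CODES,
                          "m2": ["A", "A", "H", "B", "B", "B"]})
    info = pd.DataFrame({"MARKER": ["m1", "m2"], "CHROM": "1",
                         "POS": [1000, 200_000]})
    mapper = IntervalMapper(genotypes=codes, marker_info=info, phenotypes=y)
    # too few individuals to estimate rf: supply the map directly
    from tillerqtl import GeneticMap

    gmap = GeneticMap(groups=["1"], markers={"1": ["m1", "m2"]},
                      cm={"1": np.array([0.0, 10.0])},
                      rf_adjacent={"1": np.array([haldane_inv(10.0)])},
                      capped={"1": np.array([False])})
    return mapper, gmap


class TestHkScan:
    def test_worked_set_lod_matches_least_squares_oracle(self):
        mapper, gmap = worked_mapper()
        res = hk_scan(mapper.dosage, mapper.marker_info, gmap,
                      mapper.phenotypes)
        at_marker = res.table.iloc[0]  # scan position on m1
        # direct least-squares oracle at the marker (dosage known exactly)
        x = np.array([-1, -1, 0, 0, 1, 1], dtype=float)
        z = np.array([0, 0, 1, 1, 0, 0], dtype=float)
        X = np.column_stack([np.ones(6), x, z])
        beta, *_ = np.linalg.lstsq(X, WORKED_Y, rcond=None)
        rss1 = float(((WORKED_Y - X @ beta) ** 2).sum())
        rss0 = float(((WORKED_Y - WORKED_Y.mean()) ** 2).sum())
        lod = 3.0 * np.log10(rss0 / max(rss1, 1e-12 * rss0))
        assert at_marker["LOD"] == pytest.approx(lod, rel=1e-9)
        assert at_marker["ADD"] == pytest.approx(beta[1], abs=1e-9)
        assert at_marker["DOM"] == pytest.approx(beta[2], abs=1e-9)

    def test_perfect_fit_hits_documented_lod_ceiling(self):
        # phenotype exactly the additive dosage: RSS1=0 guard caps LOD at
        # (n/2) * log10(1/1e-12) = 6n
        y = np.array([-1.0, -1.0, 0.0, 0.0, 1.0, 1.0])
        mapper, gmap = worked_mapper(y)
        res = hk_scan(mapper.dosage, mapper.marker_info, gmap,
                      mapper.phenotypes)
        assert res.table["LOD"].max() == pytest.approx(6 * 6, abs=1e-6)

    def test_lod_invariant_under_affine_phenotype_transform(self):
        codes, info, y, _ = simulate_f2_markers(n=150, qtl_cm=13.0, a=1.0,
                                                d=0.3, seed=5)
        m1 = IntervalMapper(genotypes=codes, marker_info=info, phenotypes=y)
        m2 = IntervalMapper(genotypes=codes, marker_info=info,
                            phenotypes=3.5 * y - 2.0)
        r1 = hk_scan(m1.dosage, m1.marker_info, m1.build_map(), m1.phenotypes)
        r2 = hk_scan(m2.dosage, m2.marker_info, m2.build_map(), m2.phenotypes)
        assert np.allclose(r1.table["LOD"], r2.table["LOD"], atol=1e-8)

    def test_scan_at_marker_equals_per_marker_regression(self):
        codes, info, y, cm = simulate_f2_markers(n=200, qtl_cm=13.0, a=1.2,
                                                 d=0.4, seed=6)
        mapper = IntervalMapper(genotypes=codes, marker_info=info,
                                phenotypes=y)
        res = hk_scan(mapper.dosage, mapper.marker_info, mapper.build_map(),
                      y, LinkageConfig(step_cm=0.25))
        gmap = mapper.build_map()
        for k in (0, 5, 10):
            pos = gmap.cm["1"][k]
            row = res.table.iloc[(res.table["CM"] - pos).abs().argmin()]
            if abs(row["CM"] - pos) > 1e-6:
                continue
            x = mapper.dosage[:, k].astype(float) - 1
            z = (mapper.dosage[:, k] == 1).astype(float)
            X = np.column_stack([np.ones(y.size), x, z])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss1 = float(((y - X @ beta) ** 2).sum())
            rss0 = float(((y - y.mean()) ** 2).sum())
            lod = (y.size / 2) * np.log10(rss0 / rss1)
            assert row["LOD"] == pytest.approx(lod, rel=1e-6)

    def test_null_phenotype_rarely_beats_threshold(self):
        hits = 0
        for seed in range(10):
            codes, info, y, _ = simulate_f2_markers(n=200, seed=100 + seed)
            mapper = IntervalMapper(genotypes=codes, marker_info=info,
                                    phenotypes=y)
            gmap = mapper.build_map()
            cfg = LinkageConfig(n_permutations=200, seed=seed)
            res = hk_scan(mapper.dosage, mapper.marker_info, gmap, y, cfg)
            thr = permutation_threshold(mapper.dosage, mapper.marker_info,
                                        gmap, y, cfg)
            if res.table["LOD"].max() > thr:
                hits += 1
        assert hits <= 2  # ~5% expected exceedance


class TestIcim:
    def test_reduces_to_hk_when_no_cofactor_passes_pin(self):
        codes, info, y, _ = simulate_f2_markers(n=120, seed=7)  # null trait
        mapper = IntervalMapper(genotypes=codes, marker_info=info,
                                phenotypes=y)
        gmap = mapper.build_map()
        cfg = LinkageConfig(pin=1e-9)
        hk = hk_scan(mapper.dosage, mapper.marker_info, gmap, y, cfg)
        ic = icim_scan(mapper.dosage, mapper.marker_info, gmap, y, cfg)
        assert np.allclose(hk.table["LOD"], ic.table["LOD"])
        assert ic.method == "icim"

    def test_background_absorption_raises_peak_lod(self):
        # two unlinked QTLs on separate groups: adjusting for the other
        # QTL's cofactor should usually sharpen each peak
        wins = 0
        for seed in range(8):
            c1, i1, y1, _ = simulate_f2_markers(n=204, qtl_cm=13.0, a=1.2,
                                                d=0.0, noise_sd=1.0,
                                                seed=200 + seed)
            c2, i2, y2, _ = simulate_f2_markers(n=204, qtl_cm=12.0, a=1.2,
                                                d=0.0, noise_sd=0.0,
                                                seed=300 + seed)
            i2 = i2.assign(CHROM="6", MARKER=[f"n{k}" for k in
                                              range(len(i2))])
            c2.columns = i2["MARKER"]
            codes = pd.concat([c1, c2], axis=1)
            info = pd.concat([i1, i2], ignore_index=True)
            y = y1 + y2
            mapper = IntervalMapper(genotypes=codes, marker_info=info,
                                    phenotypes=y)
            gmap = mapper.build_map()
            hk = hk_scan(mapper.dosage, mapper.marker_info, gmap, y)
            ic = icim_scan(mapper.dosage, mapper.marker_info, gmap, y)
            better = 0
            for g in ("1", "6"):
                hk_peak = hk.table[hk.table["GROUP"] == g]["LOD"].max()
                ic_peak = ic.table[ic.table["GROUP"] == g]["LOD"].max()
                if ic_peak >= hk_peak:
                    better += 1
            wins += (better == 2)
        assert wins >= 5  # >= 80% of replicates in expectation


class TestPermutationThreshold:
    def test_constant_phenotype_gives_zero(self):
        codes, info, _, _ = simulate_f2_markers(n=50, seed=8)
        mapper = IntervalMapper(genotypes=codes, marker_info=info,
                                phenotypes=np.ones(50))
        thr = permutation_threshold(mapper.dosage, mapper.marker_info,
                                    mapper.build_map(), mapper.phenotypes,
                                    LinkageConfig(n_permutations=100))
        assert thr == 0.0

    def test_same_seed_reproduces_threshold(self):
        codes, info, y, _ = simulate_f2_markers(n=100, seed=9)
        mapper = IntervalMapper(genotypes=codes, marker_info=info,
                                phenotypes=y)
        gmap = mapper.build_map()
        cfg = LinkageConfig(n_permutations=200, seed=77)
        t1 = permutation_threshold(mapper.dosage, mapper.marker_info, gmap,
                                   y, cfg)
        t2 = permutation_threshold(mapper.dosage, mapper.marker_info, gmap,
                                   y, cfg)
        assert t1 == t2


class TestParameterRecovery:
    def test_additive_dominance_estimates_recover_truth(self):
        # F2 of 204 on a 26.6 cM group of 17 markers, one QTL with the
        # chr1 effect sizes; peak estimates should be unbiased
        a_true, d_true = 1.63, 0.60
        adds, doms = [], []
        for seed in range(20):
            codes, info, y, _ = simulate_f2_markers(
                n=204, n_markers=17, length_cm=26.6, qtl_cm=13.0,
                a=a_true, d=d_true, noise_sd=2.0, seed=400 + seed)
            mapper = IntervalMapper(genotypes=codes, marker_info=info,
                                    phenotypes=y)
            res = hk_scan(mapper.dosage, mapper.marker_info,
                          mapper.build_map(), y)
            peak = res.peak("1")
            adds.append(peak["ADD"])
            doms.append(peak["DOM"])
        for est, truth in ((adds, a_true), (doms, d_true)):
            est = np.asarray(est)
            se = est.std(ddof=1) / np.sqrt(len(est))
            assert abs(est.mean() - truth) < 2 * max(se, 0.05)


class TestEncodeGenotypes:
    def test_codes_roundtrip(self):
        codes = pd.DataFrame({"m1": ["A", "H", "B", "-"]})
        assert list(encode_genotypes(codes)[:, 0]) == [0, 1, 2, -1]

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError, match="invalid genotype code"):
            encode_genotypes(pd.DataFrame({"m1": ["A", "X"]}))


def test_mapper_end_to_end_summary(two_qtl_f2=None):
    codes, info, y, _ = simulate_f2_markers(n=204, n_markers=17,
                                            length_cm=26.6, qtl_cm=13.0,
                                            a=1.63, d=0.60, noise_sd=2.0,
                                            seed=500)
    mapper = IntervalMapper(genotypes=codes, marker_info=info, phenotypes=y)
    res = mapper.fit(method="icim",
                     config=LinkageConfig(n_permutations=200, seed=1))
    text = res.summary()
    assert "LOD threshold" in text
    assert res.threshold > 0
    rep = res.qtl_report()
    assert not rep.empty
    assert {"LOD", "PVE_pct", "Add", "Dom"} <= set(rep.columns)
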