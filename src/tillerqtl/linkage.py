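"""F2 validation mapping: linkage maps and interval-mapping scans.

Recombination fractions between codominant F2 markers are estimated by EM
on the 3x3 two-locus genotype-class table; adjacent fractions become map
distances through the Kosambi function and interval mapping proceeds on a
1 cM grid by Haley-Knott regression of the (numeric) high-tillering score
on the expected additive dosage and dominance indicator at each position.
An ICIM-style variant first selects background marker cofactors by stepwise
regression (entry probability PIN) and scans the cofactor-adjusted
phenotype. Genome-wide LOD thresholds come from phenotype permutations.

Genotype codes: A = recurrent (Milyang23) homozygote, H = heterozygote,
B = donor (Hapcheonaengmi3) homozygote; internally dosage 0/1/2 with -1
for missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CODE_TO_DOSAGE = {"A": 0, "H": 1, "B": 2, "-": -1, "U": -1, "": -1}

R_CAP = 0.4999  # recombination fractions are capped below 0.5 before mapping


@dataclass
class LinkageConfig:
    step_cm: float = 1.0
    pin: float = 0.001  # stepwise p-to-enter (p-to-remove is 2*pin)
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_cm <= 0:
            raise ValueError("step_cm must be positive")
        if not (0 < self.pin < 1):
            raise ValueError("PIN must be in (0, 1)")


# ---------------------------------------------------------------------------
# map functions


def kosambi(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance in cM: d = 25 ln((1+2r)/(1-2r))."""
    r = np.minimum(np.asarray(r, dtype=float), R_CAP)
    if np.any(r < 0):
        raise ValueError("recombination fraction must be >= 0")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inv(d: float | np.ndarray) -> float | np.ndarray:
    """Inverse Kosambi: r = tanh(d/50) / 2 for d in cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def haldane(r: float | np.ndarray) -> float | np.ndarray:
    """Haldane map distance in cM: d = -50 ln(1-2r)."""
    r = np.minimum(np.asarray(r, dtype=float), R_CAP)
    d = -50.0 * np.log(1 - 2 * r)
    return float(d) if d.ndim == 0 else d


def haldane_inv(d: float | np.ndarray) -> float | np.ndarray:
    d = np.asarray(d, dtype=float)
    r = 0.5 * (1.0 - np.exp(-d / 50.0))
    return float(r) if r.ndim == 0 else r


MAP_FUNCTIONS = {"kosambi": (kosambi, kosambi_inv),
                 "haldane": (haldane, haldane_inv)}


# ---------------------------------------------------------------------------
# recombination-fraction estimation (codominant F2, coupling phase)


def f2_class_probs(r: float) -> np.ndarray:
    """3x3 matrix of P(dosage_i, dosage_j) for two F2 loci at rf ``r``."""
    gam = np.array([[(1 - r) / 2, r / 2], [r / 2, (1 - r) / 2]])  # P(a_i, a_j)
    probs = np.zeros((3, 3))
    for a1 in (0, 1):
        for b1 in (0, 1):
            for a2 in (0, 1):
                for b2 in (0, 1):
                    probs[a1 + a2, b1 + b2] += gam[a1, b1] * gam[a2, b2]
    return probs


# recombinant-gamete count by genotype class; the double heterozygote (1,1)
# is a coupling/repulsion mixture handled in the E-step
_REC_COUNT = np.array([[0.0, 1.0, 2.0],
                       [1.0, np.nan, 1.0],
                       [2.0, 1.0, 0.0]])


def estimate_rf(dos_i: np.ndarray, dos_j: np.ndarray,
                tol: float = 1e-10, max_iter: int = 2000) -> float:
    """Maximum-likelihood recombination fraction between two F2 markers.

    EM over the standard two-locus genotype-class likelihood: the E-step
    fills in the expected number of recombinant gametes for the phase-
    ambiguous double heterozygote, 2r^2 / ((1-r)^2 + r^2); the M-step is
    the recombinant-gamete fraction. Pairs with either genotype missing are
    dropped; at least 10 joint observations are required.
    """
    keep = (dos_i >= 0) & (dos_j >= 0)
    gi, gj = dos_i[keep], dos_j[keep]
    n = gi.size
    if n < 10:
        raise ValueError(f"only {n} jointly genotyped individuals (need >= 10)")
    counts = np.zeros((3, 3))
    np.add.at(counts, (gi, gj), 1.0)
    n_dh = counts[1, 1]
    fixed_rec = np.nansum(counts * _REC_COUNT)
    r = 0.25
    for _ in range(max_iter):
        e_dh = 2 * r * r / ((1 - r) ** 2 + r * r) if n_dh else 0.0
        r_new = (fixed_rec + n_dh * e_dh) / (2.0 * n)
        r_new = min(max(r_new, 0.0), 0.5)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    return float(r)


# ---------------------------------------------------------------------------
# genetic map


@dataclass
class GeneticMap:
    """Ordered markers with cumulative cM positions per linkage group."""

    groups: list[str]
    markers: dict[str, list[str]]
    cm: dict[str, np.ndarray]
    rf_adjacent: dict[str, np.ndarray]
    capped: dict[str, np.ndarray]
    map_function: str = "kosambi"

    def length(self, group: str) -> float:
        c = self.cm[group]
        return float(c[-1]) if len(c) else 0.0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "GROUP": self.groups,
            "N_MARKERS": [len(self.markers[g]) for g in self.groups],
            "LENGTH_CM": [round(self.length(g), 2) for g in self.groups],
        })


def build_map(dosage: np.ndarray, marker_info: pd.DataFrame,
              map_function: str = "kosambi") -> GeneticMap:
    """Adjacent-pair rf -> cM map, markers in fixed physical order.

    ``marker_info`` needs MARKER, CHROM, POS columns aligned with the
    columns of ``dosage`` (individuals x markers, dosage codes).
    """
    if map_function not in MAP_FUNCTIONS:
        raise ValueError(f"unknown map function {map_function!r}")
    to_cm = MAP_FUNCTIONS[map_function][0]
    groups, markers, cms, rfs, caps = [], {}, {}, {}, {}
    for chrom, info in marker_info.groupby("CHROM", sort=False):
        order = info.sort_values("POS").index.to_numpy()
        names = marker_info.loc[order, "MARKER"].tolist()
        cols = [marker_info.index.get_loc(i) for i in order]
        rf = np.zeros(max(len(cols) - 1, 0))
        capped = np.zeros_like(rf, dtype=bool)
        for k in range(len(cols) - 1):
            r = estimate_rf(dosage[:, cols[k]], dosage[:, cols[k + 1]])
            if r >= 0.5 - 1e-9:
                logger.warning("adjacent markers %s-%s look unlinked (r=%.3f)",
                               names[k], names[k + 1], r)
                capped[k] = True
            rf[k] = min(r, R_CAP)
        cm = np.concatenate([[0.0], np.cumsum(to_cm(rf))]) if len(cols) > 1 \
            else np.array([0.0])
        groups.append(chrom)
        markers[chrom] = names
        cms[chrom] = cm
        rfs[chrom] = rf
        caps[chrom] = capped
    return GeneticMap(groups=groups, markers=markers, cm=cms,
                      rf_adjacent=rfs, capped=caps, map_function=map_function)


# ---------------------------------------------------------------------------
# conditional QTL genotype probabilities (F2, Haldane within interval)


def _flank_table(r1: float, r2: float) -> np.ndarray:
    """P(g_q | g_L, g_R) as a (3,3,3) array indexed [gL, gq, gR].

    Built from per-gamete haplotype probabilities (each F2 individual is two
    independent gametes): P(aL, aq, aR) = 1/2 * t(aL,aq;r1) * t(aq,aR;r2).
    """
    t1 = np.array([[1 - r1, r1], [r1, 1 - r1]])
    t2 = np.array([[1 - r2, r2], [r2, 1 - r2]])
    hap = 0.5 * t1[:, :, None] * t2[None, :, :]  # (aL, aq, aR)
    joint = np.zeros((3, 3, 3))
    for h1 in np.ndindex(2, 2, 2):
        for h2 in np.ndindex(2, 2, 2):
            g = (h1[0] + h2[0], h1[1] + h2[1], h1[2] + h2[2])
            joint[g] += hap[h1] * hap[h2]
    marg = joint.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = joint / marg
    cond = np.where(marg > 0, cond, 1.0 / 3.0)
    return np.transpose(cond, (0, 2, 1))  # -> [gL, gR, gq]


def _single_table(r: float) -> np.ndarray:
    """P(g_q | g_M) for one informative flanking marker: (3,3) [gM, gq]."""
    t = np.array([[1 - r, r], [r, 1 - r]])
    joint = np.zeros((3, 3))
    for a1 in (0, 1):
        for b1 in (0, 1):
            for a2 in (0, 1):
                for b2 in (0, 1):
                    joint[a1 + a2, b1 + b2] += 0.25 * t[a1, b1] * t[a2, b2]
    return joint / joint.sum(axis=1, keepdims=True)


_F2_PRIOR = np.array([0.25, 0.5, 0.25])


def qtl_genotype_probs(dosage: np.ndarray, marker_cm: np.ndarray,
                       scan_cm: float) -> np.ndarray:
    """P(QTL genotype) per individual at a scan position, conditioning on
    the nearest non-missing flanking markers (Haldane within interval).

    ``dosage``: (n, m) for one linkage group, columns in map order.
    Returns (n, 3) probabilities for dosage 0/1/2.
    """
    n, m = dosage.shape
    out = np.tile(_F2_PRIOR, (n, 1))
    left_of = np.flatnonzero(marker_cm <= scan_cm + 1e-9)
    right_of = np.flatnonzero(marker_cm >= scan_cm - 1e-9)
    cache: dict[tuple, np.ndarray] = {}
    for i in range(n):
        li = next((j for j in left_of[::-1] if dosage[i, j] >= 0), None)
        ri = next((j for j in right_of if dosage[i, j] >= 0), None)
        if li is not None and ri is not None and li == ri:
            # scan position sits on a genotyped marker
            g = np.zeros(3)
            g[dosage[i, li]] = 1.0
            out[i] = g
            continue
        key = (li, ri)
        tab = cache.get(key)
        if tab is None:
            if li is not None and ri is not None:
                r1 = haldane_inv(scan_cm - marker_cm[li])
                r2 = haldane_inv(marker_cm[ri] - scan_cm)
                tab = _flank_table(r1, r2)
            elif li is not None:
                tab = _single_table(haldane_inv(scan_cm - marker_cm[li]))
            elif ri is not None:
                tab = _single_table(haldane_inv(marker_cm[ri] - scan_cm))
            else:
                tab = None
            cache[key] = tab if tab is not None else np.array([])
        if li is None and ri is None:
            continue  # keep the prior
        tab = cache[key]
        if li is not None and ri is not None:
            out[i] = tab[dosage[i, li], dosage[i, ri]]
        elif li is not None:
            out[i] = tab[dosage[i, li]]
        else:
            out[i] = tab[dosage[i, ri]]
    return out


# ---------------------------------------------------------------------------
# Haley-Knott scan


@dataclass
class ScanResult:
    """Per-position interval-mapping statistics plus peak extraction."""

    table: pd.DataFrame  # GROUP, CM, LOD, PVE, ADD, DOM, LEFT, RIGHT
    method: str
    threshold: float | None = None
    config: LinkageConfig | None = None

    def peak(self, group: str) -> pd.Series:
        sub = self.table[self.table["GROUP"] == group]
        return sub.loc[sub["LOD"].idxmax()]

    def peaks(self, min_lod: float | None = None) -> pd.DataFrame:
        thr = min_lod if min_lod is not None else (self.threshold or 0.0)
        rows = []
        for g in self.table["GROUP"].unique():
            p = self.peak(g)
            if p["LOD"] >= thr:
                rows.append(p)
        cols = self.table.columns
        return pd.DataFrame(rows, columns=cols).reset_index(drop=True)

    def summary(self) -> str:
        lines = [f"Interval mapping scan ({self.method.upper()})"]
        if self.threshold is not None:
            lines.append(f"LOD threshold (permutation): {self.threshold:.4f}")
        pk = self.peaks()
        if pk.empty:
            lines.append("No QTL above threshold.")
        else:
            lines.append(pk.to_string(index=False,
                                      float_format=lambda v: f"{v:.2f}"))
        return "\n".join(lines)


def _design_at(dosage: np.ndarray, cm: np.ndarray, pos: float) -> np.ndarray:
    """[x_hat, z_hat] columns at a scan position for one group."""
    probs = qtl_genotype_probs(dosage, cm, pos)
    x = probs[:, 2] - probs[:, 0]
    z = probs[:, 1]
    return np.column_stack([x, z])


def _scan_grid(cm: np.ndarray, step: float) -> np.ndarray:
    grid = np.arange(0.0, cm[-1] + 1e-9, step)
    if grid.size == 0 or grid[-1] < cm[-1] - 1e-9:
        grid = np.append(grid, cm[-1])
    return grid


def _flanking(cm: np.ndarray, names: list[str], pos: float) -> tuple[str, str]:
    li = int(np.searchsorted(cm, pos + 1e-9) - 1)
    li = max(li, 0)
    ri = min(li + 1, len(names) - 1)
    return names[li], names[ri]


def _lod_pve(y: np.ndarray, xz: np.ndarray) -> tuple[float, float, float, float]:
    """LOD, PVE%, additive and dominance estimates from y ~ 1 + x + z."""
    n = y.size
    ybar = y - y.mean()
    rss0 = float(ybar @ ybar)
    X = np.column_stack([np.ones(n), xz])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    if rss0 <= 0:
        return 0.0, 0.0, float(beta[1]), float(beta[2])
    eps = max(rss1, 1e-12 * rss0)  # perfect-fit guard: LOD ceiling
    lod = (n / 2.0) * np.log10(rss0 / eps)
    pve = 100.0 * (1.0 - rss1 / rss0)
    return float(lod), float(pve), float(beta[1]), float(beta[2])


def hk_scan(dosage: np.ndarray, marker_info: pd.DataFrame, gmap: GeneticMap,
            phenotypes: np.ndarray,
            config: LinkageConfig | None = None) -> ScanResult:
    """Haley-Knott regression scan on a cM grid.

    At each position the phenotype is regressed on the expected additive
    dosage (in [-1, 1]) and heterozygote probability from the flanking
    markers; LOD = (n/2) log10(RSS0/RSS1) against the intercept-only model.
    """
    config = config or LinkageConfig()
    y = np.asarray(phenotypes, dtype=float)
    rows = []
    for g in gmap.groups:
        cols = _group_columns(marker_info, g)
        cm = gmap.cm[g]
        names = gmap.markers[g]
        sub = dosage[:, cols]
        for pos in _scan_grid(cm, config.step_cm):
            lod, pve, add, dom = _lod_pve(y, _design_at(sub, cm, pos))
            left, right = _flanking(cm, names, pos)
            rows.append((g, pos, lod, pve, add, dom, left, right))
    table = pd.DataFrame(rows, columns=["GROUP", "CM", "LOD", "PVE", "ADD",
                                        "DOM", "LEFT", "RIGHT"])
    return ScanResult(table=table, method="hk", config=config)


def _group_columns(marker_info: pd.DataFrame, group: str) -> list[int]:
    info = marker_info[marker_info["CHROM"] == group].sort_values("POS")
    return [marker_info.index.get_loc(i) for i in info.index]


# ---------------------------------------------------------------------------
# ICIM: stepwise cofactor selection + adjusted scan


def _impute_marker_design(dosage: np.ndarray, marker_info: pd.DataFrame,
                          gmap: GeneticMap) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Additive (x) and dominance (z) marker variables with missing values
    replaced by their flanking-conditional expectations."""
    n, m = dosage.shape
    xcols = np.empty((n, m))
    zcols = np.empty((n, m))
    meta = []
    for g in gmap.groups:
        cols = _group_columns(marker_info, g)
        cm = gmap.cm[g]
        sub = dosage[:, cols]
        for k, j in enumerate(cols):
            probs = qtl_genotype_probs(sub, cm, cm[k])
            xcols[:, j] = probs[:, 2] - probs[:, 0]
            zcols[:, j] = probs[:, 1]
            meta.append((g, gmap.markers[g][k]))
    return xcols, zcols, meta


def _stepwise_select(y: np.ndarray, candidates: np.ndarray,
                     p_enter: float, p_remove: float) -> list[int]:
    """Forward-backward stepwise OLS with partial-F tests."""
    from scipy.stats import f as fdist

    n = y.size
    selected: list[int] = []
    while True:
        changed = False
        # forward step
        best_p, best_j = 1.0, None
        rss_cur = _ols_rss(y, candidates[:, selected]) if selected else \
            float(((y - y.mean()) ** 2).sum())
        for j in range(candidates.shape[1]):
            if j in selected:
                continue
            rss_new = _ols_rss(y, candidates[:, selected + [j]])
            df2 = n - len(selected) - 2
            if df2 <= 0 or rss_new <= 0:
                continue
            F = (rss_cur - rss_new) / (rss_new / df2)
            p = float(fdist.sf(F, 1, df2))
            if p < best_p:
                best_p, best_j = p, j
        if best_j is not None and best_p < p_enter:
            selected.append(best_j)
            changed = True
        # backward step
        if len(selected) > 1:
            rss_full = _ols_rss(y, candidates[:, selected])
            worst_p, worst_j = -1.0, None
            df2 = n - len(selected) - 1
            for j in selected:
                rest = [k for k in selected if k != j]
                rss_red = _ols_rss(y, candidates[:, rest])
                F = (rss_red - rss_full) / (rss_full / df2) if rss_full > 0 else np.inf
                p = float(fdist.sf(F, 1, df2))
                if p > worst_p:
                    worst_p, worst_j = p, j
            if worst_j is not None and worst_p > p_remove:
                selected.remove(worst_j)
                changed = True
        if not changed:
            break
    return selected


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    A = np.column_stack([np.ones(y.size), X]) if X.size else \
        np.ones((y.size, 1))
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ beta
    return float(r @ r)


def icim_scan(dosage: np.ndarray, marker_info: pd.DataFrame, gmap: GeneticMap,
              phenotypes: np.ndarray,
              config: LinkageConfig | None = None) -> ScanResult:
    """Inclusive composite interval mapping (additive model).

    Stage 1 selects background marker variables by stepwise regression at
    entry probability PIN (removal at 2*PIN). Stage 2 rescans each position
    with the phenotype adjusted by the selected cofactors, excluding any
    cofactor on the marker pair flanking the current interval.
    """
    config = config or LinkageConfig()
    y = np.asarray(phenotypes, dtype=float)
    xcols, zcols, meta = _impute_marker_design(dosage, marker_info, gmap)
    cand = np.concatenate([xcols, zcols], axis=1)  # additive then dominance
    m = xcols.shape[1]
    selected = _stepwise_select(y, cand, config.pin, 2 * config.pin)
    if not selected:
        res = hk_scan(dosage, marker_info, gmap, phenotypes, config)
        return ScanResult(table=res.table, method="icim", config=config)
    sel_markers = [meta[j % m] for j in selected]
    rows = []
    for g in gmap.groups:
        cols = _group_columns(marker_info, g)
        cm = gmap.cm[g]
        names = gmap.markers[g]
        sub = dosage[:, cols]
        for pos in _scan_grid(cm, config.step_cm):
            left, right = _flanking(cm, names, pos)
            keep = [j for j, (mg, mn) in zip(selected, sel_markers)
                    if not (mg == g and mn in (left, right))]
            if keep:
                X = np.column_stack([np.ones(y.size), cand[:, keep]])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                y_adj = y - cand[:, keep] @ beta[1:]
            else:
                y_adj = y
            lod, pve, add, dom = _lod_pve(y_adj, _design_at(sub, cm, pos))
            rows.append((g, pos, lod, pve, add, dom, left, right))
    table = pd.DataFrame(rows, columns=["GROUP", "CM", "LOD", "PVE", "ADD",
                                        "DOM", "LEFT", "RIGHT"])
    return ScanResult(table=table, method="icim", config=config)


# ---------------------------------------------------------------------------
# permutation threshold


def permutation_threshold(dosage: np.ndarray, marker_info: pd.DataFrame,
                          gmap: GeneticMap, phenotypes: np.ndarray,
                          config: LinkageConfig | None = None) -> float:
    """Genome-wide (1-alpha) LOD threshold from phenotype permutations.

    The marker design is fixed, so each position's regression is reduced to
    a QR projection applied to all permuted phenotype vectors at once; the
    threshold is the empirical (1-alpha) quantile of per-permutation maximum
    LOD. Permutations use the Haley-Knott statistic (under the permutation
    null, cofactor selection at PIN almost never fires, so the HK and ICIM
    nulls coincide).
    """
    config = config or LinkageConfig()
    y = np.asarray(phenotypes, dtype=float)
    n = y.size
    if np.allclose(y, y[0]):
        return 0.0
    rng = np.random.default_rng(config.seed)
    B = config.n_permutations
    Y = np.empty((n, B))
    for b in range(B):
        Y[:, b] = y[rng.permutation(n)]
    rss0 = float(((y - y.mean()) ** 2).sum())  # permutation-invariant
    max_lod = np.zeros(B)
    for g in gmap.groups:
        cols = _group_columns(marker_info, g)
        cm = gmap.cm[g]
        sub = dosage[:, cols]
        for pos in _scan_grid(cm, config.step_cm):
            X = np.column_stack([np.ones(n), _design_at(sub, cm, pos)])
            Q, _ = np.linalg.qr(X)
            rss1 = np.sum(Y * Y, axis=0) - np.sum((Q.T @ Y) ** 2, axis=0)
            rss1 = np.maximum(rss1, 1e-12 * rss0)
            lod = (n / 2.0) * np.log10(rss0 / rss1)
            np.maximum(max_lod, lod, out=max_lod)
    return float(np.quantile(max_lod, 1.0 - config.alpha))


def encode_genotypes(codes: pd.DataFrame) -> np.ndarray:
    """A/H/B/- codes -> dosage matrix (int8, -1 missing)."""
    arr = codes.fillna("-").astype(str).to_numpy()
    out = np.full(arr.shape, -1, dtype=np.int8)
    for code, d in CODE_TO_DOSAGE.items():
        out[arr == code] = d
    bad = ~np.isin(arr, list(CODE_TO_DOSAGE))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"invalid genotype code {arr[i, j]!r} "
                         f"(individual {i}, marker {codes.columns[j]})")
    return out
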