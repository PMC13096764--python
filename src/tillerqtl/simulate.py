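"""Synthetic bulked-segregant data with the structure QTL-seq assumes.

Simulates biparental rice populations (F2, recombinant inbred lines,
backcross-derived lines), assigns ordinal high-tillering (HT) scores under a
configurable genetic model — by default complementary two-locus epistasis,
where the donor (Hapcheonaengmi3) allele must be present at *both* HT loci
for the trait to appear in the recurrent (Milyang23) background — forms
phenotypic bulks, and emits per-bulk allele-depth SNP tables.

Genotypes are coded as donor-allele dosage: 0 = recurrent homozygote (AA),
1 = heterozygote, 2 = donor homozygote (BB).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default physical-to-genetic rate, cM per Mb
DEFAULT_CM_PER_MB = 4.0


@dataclass(frozen=True)
class QtlEffect:
    """One QTL: position plus additive/dominance effects on the latent scale.

    ``a`` is the effect per donor allele (half the homozygote contrast),
    ``d`` the heterozygote deviation, both in latent-score units.
    """

    chrom: str
    pos_bp: int
    a: float
    d: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.d)):
            raise ValueError("QTL effects must be finite")
        if self.pos_bp < 1:
            raise ValueError("QTL position must be >= 1")


@dataclass
class SimConfig:
    """Design of a simulated bulked-segregant experiment.

    Parameters
    ----------
    chrom_lengths
        ``[(chrom, length_bp), ...]``.
    marker_spacing_bp
        Mean spacing of SNP sites (sites are a Poisson process along each
        chromosome).
    pop_type
        ``"F2"``, ``"RIL9"`` (recombinant inbred, selfed to generation 9),
        or ``"BC1F1"`` — any generation via ``RIL<g>`` / ``BC1F<g>``.
    qtls
        QTLs with latent-scale effects.
    epistasis
        ``"complementary"`` (trait needs a donor allele at every QTL) or
        ``"additive"`` (no gating).
    noise_sd
        Standard deviation of the latent environmental noise.
    phenotype_scale
        Top of the ordinal score range; 3 mimics the RIL scoring,
        9 the F2 scoring.
    depth_mean
        Mean sequencing depth per SNP per bulk (Poisson, truncated at >= 1).
    """

    chrom_lengths: list[tuple[str, int]]
    n_individuals: int
    marker_spacing_bp: float = 10_000.0
    pop_type: str = "RIL9"
    qtls: list[QtlEffect] = field(default_factory=list)
    epistasis: str = "complementary"
    noise_sd: float = 1.0
    phenotype_scale: int = 3
    depth_mean: float = 30.0
    cm_per_mb: float = DEFAULT_CM_PER_MB
    seed: int = 0
    #: explicit per-chromosome site positions (e.g. a fixed marker panel);
    #: when set, marker_spacing_bp is ignored for those chromosomes
    fixed_sites: dict[str, list[int]] | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if any(length <= 0 for _, length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.phenotype_scale < 2:
            raise ValueError("phenotype scale needs at least two classes")
        chroms = {c for c, _ in self.chrom_lengths}
        for q in self.qtls:
            if q.chrom not in chroms:
                raise ValueError(f"QTL on undeclared chromosome {q.chrom!r}")
            length = dict(self.chrom_lengths)[q.chrom]
            if q.pos_bp > length:
                raise ValueError(
                    f"QTL at {q.chrom}:{q.pos_bp} beyond chromosome end {length}"
                )
        parse_pop_type(self.pop_type)  # validate early


def parse_pop_type(pop_type: str) -> tuple[str, int]:
    """Split a population code into (kind, generation).

    ``F2`` -> ("F2", 2); ``RIL9`` / ``RIL(9)`` -> ("RIL", 9);
    ``BC1F3`` -> ("BC1F", 3).
    """
    s = pop_type.replace("(", "").replace(")", "").strip().upper()
    if s == "F2":
        return "F2", 2
    m = re.fullmatch(r"RIL(\d+)", s)
    if m:
        g = int(m.group(1))
        if g < 2:
            raise ValueError("RIL generation must be >= 2")
        return "RIL", g
    m = re.fullmatch(r"BC1F(\d+)", s)
    if m:
        return "BC1F", int(m.group(1))
    raise ValueError(f"unknown pop_type {pop_type!r}")


@dataclass
class PopulationGenotypes:
    """Individuals x loci donor-dosage matrix with locus coordinates."""

    dosage: np.ndarray  # (n, m) int8, values 0/1/2
    chrom: np.ndarray  # (m,) str
    pos: np.ndarray  # (m,) int64, 1-based bp

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def locus_index(self, chrom: str, pos_bp: int) -> int:
        """Index of the locus nearest to (chrom, pos_bp)."""
        on = np.flatnonzero(self.chrom == chrom)
        if on.size == 0:
            raise ValueError(f"no loci on chromosome {chrom!r}")
        return int(on[np.argmin(np.abs(self.pos[on] - pos_bp))])


@dataclass(frozen=True)
class BulkAssignment:
    """Index sets of the two phenotypic bulks."""

    high: np.ndarray
    low: np.ndarray

    def __post_init__(self) -> None:
        if np.intersect1d(self.high, self.low).size:
            raise ValueError("bulks must be disjoint")

    @property
    def n_high(self) -> int:
        return len(self.high)

    @property
    def n_low(self) -> int:
        return len(self.low)


# ---------------------------------------------------------------------------
# gamete / population simulation


def _site_positions(length: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """SNP sites as a Poisson process with the given mean spacing (1-based)."""
    n_expect = max(int(2 * length / spacing) + 20, 20)
    gaps = rng.exponential(spacing, size=n_expect)
    pos = np.cumsum(gaps)
    while pos[-1] < length:  # pragma: no cover - spacing guard
        more = rng.exponential(spacing, size=n_expect)
        pos = np.concatenate([pos, pos[-1] + np.cumsum(more)])
    pos = pos[pos <= length]
    pos = np.unique(np.maximum(pos.astype(np.int64), 1))
    if pos.size == 0:
        pos = np.array([1], dtype=np.int64)
    return pos


def _gamete(hap0: np.ndarray, hap1: np.ndarray, gpos: np.ndarray,
            glen: float, rng: np.random.Generator) -> np.ndarray:
    """One meiotic product. Crossovers are a Poisson process on the genetic
    scale (Haldane: no interference); ``gpos`` are locus positions in Morgans
    and ``glen`` the chromosome's genetic length in Morgans."""
    k = rng.poisson(glen)
    start = rng.integers(0, 2)
    if k == 0:
        return hap0 if start == 0 else hap1
    xo = np.sort(rng.uniform(0.0, glen, size=k))
    phase = (start + np.searchsorted(xo, gpos)) % 2
    return np.where(phase == 0, hap0, hap1)


def _meiosis_pair(ind: tuple[np.ndarray, np.ndarray], gpos: np.ndarray,
                  glen: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    return (_gamete(ind[0], ind[1], gpos, glen, rng),
            _gamete(ind[0], ind[1], gpos, glen, rng))


def simulate_population(config: SimConfig,
                        rng: np.random.Generator | None = None) -> PopulationGenotypes:
    """Simulate a segregating population by gamete-level meiosis.

    The F1 is heterozygous everywhere (recurrent x donor). F2 individuals
    take one gamete from each of two independent F1 meioses; RIL(g)
    individuals are selfed single-seed-descent lines carried to generation g
    (g-1 meiosis rounds from the F1); BC1F(g) lines are one backcross to the
    recurrent parent followed by selfing.
    """
    kind, gen = parse_pop_type(config.pop_type)
    if rng is None:
        rng = np.random.default_rng(config.seed)

    chroms: list[np.ndarray] = []
    poss: list[np.ndarray] = []
    per_chrom: list[tuple[np.ndarray, float]] = []
    for chrom, length in config.chrom_lengths:
        if config.fixed_sites is not None and chrom in config.fixed_sites:
            pos = np.asarray(sorted(config.fixed_sites[chrom]), dtype=np.int64)
            if pos.size == 0 or pos[0] < 1 or pos[-1] > length:
                raise ValueError(f"fixed sites for {chrom!r} outside [1, {length}]")
        else:
            pos = _site_positions(length, config.marker_spacing_bp, rng)
        # make sure declared QTLs sit exactly on a simulated site
        qpos = np.array([q.pos_bp for q in config.qtls if q.chrom == chrom],
                        dtype=np.int64)
        if qpos.size:
            pos = np.unique(np.concatenate([pos, qpos]))
        gpos = pos * (config.cm_per_mb / 100.0) / 1e6  # Morgans
        glen = length * (config.cm_per_mb / 100.0) / 1e6
        chroms.append(np.repeat(chrom, pos.size))
        poss.append(pos)
        per_chrom.append((gpos, glen))

    n = config.n_individuals
    out_blocks: list[np.ndarray] = []
    for (gpos, glen), pos in zip(per_chrom, poss):
        m = pos.size
        a = np.zeros(m, dtype=np.int8)  # recurrent haplotype
        b = np.ones(m, dtype=np.int8)  # donor haplotype
        block = np.empty((n, m), dtype=np.int8)
        for i in range(n):
            if kind == "F2":
                g1 = _gamete(a, b, gpos, glen, rng)
                g2 = _gamete(a, b, gpos, glen, rng)
                block[i] = g1 + g2
            elif kind == "RIL":
                ind = (_gamete(a, b, gpos, glen, rng),
                       _gamete(a, b, gpos, glen, rng))  # an F2 individual
                for _ in range(gen - 2):  # self on to generation g
                    ind = _meiosis_pair(ind, gpos, glen, rng)
                block[i] = ind[0] + ind[1]
            else:  # BC1F(g)
                bc1 = (_gamete(a, b, gpos, glen, rng), a)
                ind = bc1
                for _ in range(gen - 1):
                    ind = _meiosis_pair(ind, gpos, glen, rng)
                block[i] = ind[0] + ind[1]
        out_blocks.append(block)

    return PopulationGenotypes(
        dosage=np.concatenate(out_blocks, axis=1),
        chrom=np.concatenate(chroms),
        pos=np.concatenate(poss),
    )


# ---------------------------------------------------------------------------
# phenotypes


def latent_scores(pop: PopulationGenotypes, config: SimConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Latent (unbinned) HT score: gated genetic value plus Gaussian noise."""
    if config.epistasis == "complementary" and len(config.qtls) < 2:
        raise ValueError("complementary epistasis needs at least two QTLs")
    idx = [pop.locus_index(q.chrom, q.pos_bp) for q in config.qtls]
    for q, j in zip(config.qtls, idx):
        if pop.chrom[j] != q.chrom or pop.pos[j] != q.pos_bp:
            logger.warning("QTL %s:%d mapped to nearest simulated locus %s:%d",
                           q.chrom, q.pos_bp, pop.chrom[j], pop.pos[j])
    x = pop.dosage[:, idx].astype(float)  # donor dosage per QTL
    z = (x == 1).astype(float)
    a = np.array([q.a for q in config.qtls])
    d = np.array([q.d for q in config.qtls])
    genetic = x @ a + z @ d
    if config.epistasis == "complementary":
        gate = (x >= 1).all(axis=1)
        genetic = np.where(gate, genetic, 0.0)
    elif config.epistasis != "additive":
        raise ValueError(f"unknown epistasis rule {config.epistasis!r}")
    noise = rng.normal(0.0, config.noise_sd, size=pop.n_individuals) \
        if config.noise_sd > 0 else 0.0
    return genetic + noise


def _max_genetic_value(config: SimConfig) -> float:
    return float(sum(max(2 * q.a, q.a + q.d, 0.0) for q in config.qtls))


def assign_phenotypes(pop: PopulationGenotypes, config: SimConfig,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Ordinal HT scores from 1 (no HT, recurrent-parent type) to the scale top.

    The latent score is thresholded at the 95% quantile of the null latent
    distribution (pure noise), so the no-HT class dominates when genetic
    effects are absent or small; latent values above that threshold are cut
    into the remaining classes by equal-width bins up to the maximal genetic
    value.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    latent = latent_scores(pop, config, rng)
    from scipy.stats import norm

    t0 = norm.ppf(0.95, loc=0.0, scale=config.noise_sd) if config.noise_sd > 0 else 0.0
    k = config.phenotype_scale
    gmax = _max_genetic_value(config)
    width = max((gmax - t0) / (k - 1), 1e-9) if gmax > t0 else 1.0
    score = np.ones(pop.n_individuals, dtype=np.int64)
    above = latent > t0
    score[above] = 1 + np.minimum(
        np.ceil((latent[above] - t0) / width).astype(np.int64), k - 1
    )
    return score


# ---------------------------------------------------------------------------
# bulks


def form_bulks(phenotypes: np.ndarray, n_high: int, n_low: int,
               rule: str = "rank") -> BulkAssignment:
    """Pick the two phenotypic bulks.

    ``rule="rank"``: high bulk = top ``n_high`` scores, low bulk = bottom
    ``n_low`` (ties broken by individual index, ascending).
    ``rule="class"``: high bulk = individuals at the maximum score, low at
    the minimum, truncated to the requested sizes.
    """
    phenotypes = np.asarray(phenotypes)
    n = phenotypes.size
    if n_high + n_low > n:
        raise ValueError(f"bulk sizes {n_high}+{n_low} exceed population size {n}")
    idx = np.arange(n)
    if rule == "rank":
        if np.all(phenotypes == phenotypes[0]):
            logger.warning("all phenotype scores identical; bulks are index-ordered")
        # stable sort on (-score, index) for the high bulk
        order_desc = np.lexsort((idx, -phenotypes))
        order_asc = np.lexsort((idx, phenotypes))
        high = np.sort(order_desc[:n_high])
        low_pool = [i for i in order_asc if i not in set(high)]
        low = np.sort(np.array(low_pool[:n_low], dtype=np.int64))
    elif rule == "class":
        hi, lo = phenotypes.max(), phenotypes.min()
        if hi == lo:
            raise ValueError("all scores identical; class rule cannot form bulks")
        high = idx[phenotypes == hi][:n_high]
        low = idx[phenotypes == lo][:n_low]
        if len(high) < n_high or len(low) < n_low:
            raise ValueError("not enough individuals in the extreme classes")
    else:
        raise ValueError(f"unknown bulk selection rule {rule!r}")
    return BulkAssignment(high=high, low=low)


# ---------------------------------------------------------------------------
# read sampling


def _truncated_poisson(mean: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Poisson depths truncated at >= 1 (zero-depth sites are unobservable)."""
    d = rng.poisson(mean, size=size)
    zero = d == 0
    while zero.any():
        d[zero] = rng.poisson(mean, size=int(zero.sum()))
        zero = d == 0
    return d


def sample_snp_table(pop: PopulationGenotypes, bulks: BulkAssignment,
                     config: SimConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-bulk allele depths at every simulated SNP site.

    The bulk's true donor-allele frequency is the mean donor dosage over its
    members divided by 2; total depth is Poisson(depth_mean) truncated at
    >= 1 and the donor read count Binomial(depth, frequency). ALT is the
    donor allele throughout.
    """
    if bulks.n_high == 0 or bulks.n_low == 0:
        raise ValueError("both bulks must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    m = pop.n_loci
    rows = {}
    for name, members in (("HIGH", bulks.high), ("LOW", bulks.low)):
        f = pop.dosage[members].sum(axis=0) / (2.0 * len(members))
        depth = _truncated_poisson(config.depth_mean, m, rng)
        alt = rng.binomial(depth, f)
        rows[f"{name}_ALT"] = alt
        rows[f"{name}_REF"] = depth - alt
    df = pd.DataFrame({
        "CHROM": pop.chrom,
        "POS": pop.pos,
        "REF": "A",
        "ALT": "T",
        "HIGH_REF": rows["HIGH_REF"],
        "HIGH_ALT": rows["HIGH_ALT"],
        "LOW_REF": rows["LOW_REF"],
        "LOW_ALT": rows["LOW_ALT"],
    })
    return df.sort_values(["CHROM", "POS"], kind="stable").reset_index(drop=True)


def simulate_f2_study(seed: int = 0, n: int = 204, noise_sd: float = 2.0,
                      a1: float = 1.63, d1: float = 0.60,
                      a2: float = 1.04, d2: float = 1.25,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, SimConfig]:
    """The validation-cross design: an F2 genotyped at a fixed marker panel.

    204 F2 plants, 41 markers (17 evenly spaced on chromosome 1 spanning
    26.6 cM, 24 on chromosome 6 spanning 24.0 cM at 4 cM/Mb), one HT QTL
    per group placed on the middle marker, complementary epistasis, and the
    1-9 ordinal HT score.

    Returns (genotype codes A/H/B, marker_info, phenotypes, config).
    """
    len1, len6 = 6_650_000, 6_000_000  # 26.6 and 24.0 cM at 4 cM/Mb
    m1 = np.linspace(1, len1, 17).astype(np.int64)
    m6 = np.linspace(1, len6, 24).astype(np.int64)
    cfg = SimConfig(
        chrom_lengths=[("1", len1), ("6", len6)],
        n_individuals=n,
        pop_type="F2",
        qtls=[QtlEffect("1", int(m1[8]), a1, d1),
              QtlEffect("6", int(m6[11]), a2, d2)],
        epistasis="complementary",
        noise_sd=noise_sd,
        phenotype_scale=9,
        seed=seed,
        fixed_sites={"1": m1.tolist(), "6": m6.tolist()},
    )
    rng = np.random.default_rng(seed)
    pop = simulate_population(cfg, rng)
    pheno = assign_phenotypes(pop, cfg, rng)
    codes = pd.DataFrame(np.array(["A", "H", "B"])[pop.dosage])
    names = [f"{c}_M{k + 1:02d}"
             for c, mm in (("1", m1), ("6", m6)) for k in range(len(mm))]
    codes.columns = names
    info = pd.DataFrame({"MARKER": names,
                         "CHROM": pop.chrom,
                         "POS": pop.pos})
    return codes, info, pheno.astype(float), cfg


def simulate_bsa_experiment(config: SimConfig, n_high: int, n_low: int,
                            ) -> tuple[pd.DataFrame, PopulationGenotypes, np.ndarray, BulkAssignment]:
    """End-to-end convenience: population -> phenotypes -> bulks -> SNP table.

    A single generator seeded from ``config.seed`` drives every stage, so a
    fixed config reproduces the dataset exactly.
    """
    rng = np.random.default_rng(config.seed)
    pop = simulate_population(config, rng)
    pheno = assign_phenotypes(pop, config, rng)
    bulks = form_bulks(pheno, n_high=n_high, n_low=n_low)
    table = sample_snp_table(pop, bulks, config, rng)
    return table, pop, pheno, bulks
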