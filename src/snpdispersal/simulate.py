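"""Truth-known spatial-pedigree simulator.

Generates populations with the statistical structure the downstream
analysis assumes: a non-overlapping-generation pedigree, sex-specific
natal dispersal of home-range centers, Mendelian SNP genotypes on a
mixed autosomal/X/Y/mtDNA panel, and replicated "fecal samples" whose
observed genotypes carry allelic dropout and per-allele miscalls.

Defaults emulate a noninvasively sampled Scandinavian brown-bear
population: ~96-SNP panel with mean autosomal MAF 0.37, a study
rectangle of ~45,000 km^2, female/male dispersal-kernel means of
12.9/33.8 km, 1-19 samples per individual, a per-allele genotyping
error rate of 3.8e-4, and slightly more than half of the population
sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markers import (
    AUTOSOMAL,
    HET,
    HOM_A,
    HOM_B,
    INVALID,
    MISSING,
    MTDNA,
    X_LINKED,
    Y_LINKED,
    MarkerPanel,
    build_panel,
)

#: Empirical distribution of fecal-sample counts per individual
#: (1..19), from the study's frequency table; counts inside the binned
#: rows (6-10, 11-15, 16-19) are spread uniformly.
DEFAULT_SAMPLES_PER_IND = np.zeros(19)
DEFAULT_SAMPLES_PER_IND[:5] = [275, 45, 25, 24, 10]
DEFAULT_SAMPLES_PER_IND[5:10] = 25 / 5
DEFAULT_SAMPLES_PER_IND[10:15] = 7 / 5
DEFAULT_SAMPLES_PER_IND[15:19] = 3 / 4
DEFAULT_SAMPLES_PER_IND /= DEFAULT_SAMPLES_PER_IND.sum()

STUDY_SIDE_KM = 214.0  # sqrt(45,000 km^2) study rectangle


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Rates are probabilities in [0, 1]; lengths are kilometers.
    ``n_generations`` counts generations including the founders (the
    study pedigrees span two to three generations).
    """

    n_founders_f: int = 120
    n_founders_m: int = 120
    n_generations: int = 3
    mean_offspring_per_mother: float = 2.2
    L_autosomal: int = 87
    maf_mean: float = 0.37
    epsilon: float = 3.8e-4
    dropout_rate: float = 0.01
    missing_rate: float = 0.0035
    invalid_rate: float = 0.003
    disp_mean_f_km: float = 12.9
    disp_mean_m_km: float = 33.8
    dispersal_kernel: str = "exponential"  # or "halfnormal"
    samples_per_ind_dist: np.ndarray = field(
        default_factory=lambda: DEFAULT_SAMPLES_PER_IND.copy()
    )
    sample_scatter_km: float = 3.0
    #: dependent cubs travel with their mother, so their fecal sites sit
    #: on the mother's sample track rather than scattering independently
    cub_scatter_km: float = 0.2
    prop_sampled: float = 433 / 810
    cub_litter_prob: float = 0.15
    study_side_km: float = STUDY_SIDE_KM
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epsilon", "dropout_rate", "missing_rate", "invalid_rate",
                     "prop_sampled", "cub_litter_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_generations < 2:
            raise ValueError("n_generations must be >= 2")
        if min(self.n_founders_f, self.n_founders_m, self.L_autosomal) < 1:
            raise ValueError("counts must be >= 1")
        if min(self.disp_mean_f_km, self.disp_mean_m_km, self.sample_scatter_km) < 0:
            raise ValueError("lengths must be >= 0")
        if self.dispersal_kernel not in ("exponential", "halfnormal"):
            raise ValueError(f"unknown kernel {self.dispersal_kernel!r}")
        p = np.asarray(self.samples_per_ind_dist, dtype=float)
        if p.ndim != 1 or len(p) != 19 or (p < 0).any() or not math.isclose(p.sum(), 1.0):
            raise ValueError("samples_per_ind_dist must be 19 probabilities summing to 1")
        self.samples_per_ind_dist = p

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class TruthPopulation:
    """Ground truth: pedigree, sexes, centers, haplotypes, genotypes."""

    individuals: pd.DataFrame  # id, sex, mother_id, father_id, generation,
    #                            x_km, y_km, sampled, cub_litter, mt_haplotype
    true_genotypes: np.ndarray | None = None  # (n, n_loci) int8
    panel: MarkerPanel | None = None

    @property
    def n(self) -> int:
        return len(self.individuals)

    def index_of(self) -> dict[str, int]:
        return {iid: i for i, iid in enumerate(self.individuals["id"])}


def simulate_allele_frequencies(
    L: int, maf_mean: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw per-locus minor-allele frequencies with the given mean.

    MAFs are ``0.5 * Beta(2m*k, (1-2m)*k)`` with concentration ``k=30``,
    clipped to [0.01, 0.5], so the sample mean concentrates tightly
    around ``maf_mean`` for panels of realistic size.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 0.0 < maf_mean <= 0.5:
        raise ValueError(f"maf_mean must be in (0, 0.5], got {maf_mean}")
    rng = np.random.default_rng(seed)
    if maf_mean == 0.5:
        return np.full(L, 0.5)
    k = 30.0
    m2 = 2.0 * maf_mean
    maf = 0.5 * rng.beta(m2 * k, (1.0 - m2) * k, size=L)
    return np.clip(maf, 0.01, 0.5)


def default_panel(config: SimulationConfig, rng: np.random.Generator | None = None) -> MarkerPanel:
    """Panel with simulated autosomal MAFs and the standard X/Y/mtDNA layout."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    maf = simulate_allele_frequencies(config.L_autosomal, config.maf_mean, rng)
    x_maf = simulate_allele_frequencies(3, config.maf_mean, rng)
    return build_panel(1.0 - maf, 1.0 - x_maf)


def simulate_pedigree_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TruthPopulation:
    """Build a non-overlapping-generation pedigree.

    Each mother of generation g draws a Poisson number of offspring and,
    per litter, a single father uniformly from the same generation's
    males (polygamy allowed). Offspring sex is a fair coin. Litters of
    the final generation are, with probability ``cub_litter_prob``,
    flagged as pre-dispersal cubs.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows: list[dict] = []
    for i in range(config.n_founders_f):
        rows.append(dict(id=f"F0_{i:04d}", sex="F", mother_id=None, father_id=None,
                         generation=0, cub_litter=False))
    for i in range(config.n_founders_m):
        rows.append(dict(id=f"M0_{i:04d}", sex="M", mother_id=None, father_id=None,
                         generation=0, cub_litter=False))
    prev = rows
    last_gen = config.n_generations - 1
    for g in range(1, config.n_generations):
        mothers = [r for r in prev if r["sex"] == "F"]
        fathers = [r for r in prev if r["sex"] == "M"]
        cur: list[dict] = []
        if fathers:
            counts = rng.poisson(config.mean_offspring_per_mother, size=len(mothers))
            for mother, k in zip(mothers, counts):
                if k == 0:
                    continue
                father = fathers[rng.integers(len(fathers))]
                is_cub = g == last_gen and rng.random() < config.cub_litter_prob
                for _ in range(k):
                    sex = "F" if rng.random() < 0.5 else "M"
                    cur.append(dict(
                        id=f"{sex}{g}_{len(rows) + len(cur):04d}", sex=sex,
                        mother_id=mother["id"], father_id=father["id"],
                        generation=g, cub_litter=is_cub,
                    ))
        rows.extend(cur)
        prev = cur
    df = pd.DataFrame(rows)
    n = len(df)
    sampled = np.zeros(n, dtype=bool)
    k = int(round(config.prop_sampled * n))
    sampled[rng.choice(n, size=k, replace=False)] = True
    df["sampled"] = sampled
    return TruthPopulation(individuals=df)


def _displacements(n: int, mean_km: float, kernel: str, rng: np.random.Generator) -> np.ndarray:
    """Isotropic displacement vectors (km) with the given magnitude mean."""
    if mean_km == 0 or n == 0:
        return np.zeros((n, 2))
    if kernel == "exponential":
        mag = rng.exponential(mean_km, size=n)
    else:  # half-normal with the requested mean
        mag = np.abs(rng.normal(0.0, mean_km * math.sqrt(math.pi / 2.0), size=n))
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return np.column_stack([mag * np.cos(theta), mag * np.sin(theta)])


def assign_home_ranges(
    truth: TruthPopulation, config: SimulationConfig, rng: np.random.Generator | None = None
) -> TruthPopulation:
    """Place founder centers uniformly on the study rectangle and move
    each non-cub offspring away from its mother by a sex-specific
    dispersal kernel; displacements leaving the rectangle are truncated
    to the boundary. Cub litters stay at the mother's center.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    df = truth.individuals.copy()
    side = config.study_side_km
    x = np.zeros(len(df))
    y = np.zeros(len(df))
    idx = {iid: i for i, iid in enumerate(df["id"])}
    for g in sorted(df["generation"].unique()):
        sub = df[df["generation"] == g]
        if g == 0:
            for i in sub.index:
                x[i], y[i] = rng.uniform(0, side, size=2)
            continue
        for sex, mean in (("F", config.disp_mean_f_km), ("M", config.disp_mean_m_km)):
            rows = sub[sub["sex"] == sex]
            disp = _displacements(len(rows), mean, config.dispersal_kernel, rng)
            for (i, r), d in zip(rows.iterrows(), disp):
                mi = idx[r["mother_id"]]
                if r["cub_litter"]:
                    x[i], y[i] = x[mi], y[mi]
                else:
                    x[i] = min(max(x[mi] + d[0], 0.0), side)
                    y[i] = min(max(y[mi] + d[1], 0.0), side)
    df["x_km"] = x
    df["y_km"] = y
    return TruthPopulation(df, truth.true_genotypes, truth.panel)


def _founder_diploid(freq_a: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(2, 1.0 - freq_a, size=(n, len(freq_a))).astype(np.int8)


def _transmit(parent_codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One allele (B-copy count 0/1) per locus from a diploid parent."""
    p_b = parent_codes / 2.0
    return (rng.random(parent_codes.shape) < p_b).astype(np.int8)


def simulate_true_genotypes(
    truth: TruthPopulation, panel: MarkerPanel, rng: np.random.Generator
) -> TruthPopulation:
    """Draw error-free genotypes: founders from Hardy-Weinberg, offspring
    by Mendelian transmission; X hemizygous in males (reported as
    homozygotes), Y present only in males, mtDNA copied matrilineally.
    """
    df = truth.individuals
    n, L = len(df), panel.n_loci
    G = np.full((n, L), MISSING, dtype=np.int8)
    idx = truth.index_of()
    a_idx, x_idx, y_idx, mt_idx = (panel.autosomal_idx, panel.x_idx,
                                   panel.y_idx, panel.mt_idx)
    hap_labels = list(panel.haplotype_key)
    hap_probs = np.array([0.96, 0.03, 0.01])[: len(hap_labels)]
    hap_probs = hap_probs / hap_probs.sum()
    haplos = np.empty(n, dtype=object)
    order = df.sort_values("generation").index
    for i in order:
        row = df.loc[i]
        male = row["sex"] == "M"
        if row["mother_id"] is None or pd.isna(row["mother_id"]):
            G[i, a_idx] = _founder_diploid(panel.freq_a[a_idx], 1, rng)[0]
            xa = _founder_diploid(panel.freq_a[x_idx], 1, rng)[0]
            if male:
                xa = 2 * (rng.random(len(x_idx)) < 1 - panel.freq_a[x_idx]).astype(np.int8)
            G[i, x_idx] = xa
            haplos[i] = hap_labels[rng.choice(len(hap_labels), p=hap_probs)]
        else:
            mi, fi = idx[row["mother_id"]], idx[row["father_id"]]
            G[i, a_idx] = _transmit(G[mi, a_idx], rng) + _transmit(G[fi, a_idx], rng)
            bm = _transmit(G[mi, x_idx], rng)
            if male:
                G[i, x_idx] = 2 * bm  # maternal X only, reported homozygous
            else:
                G[i, x_idx] = bm + (G[fi, x_idx] // 2)  # father passes his single X
            haplos[i] = haplos[mi]
        G[i, y_idx] = HOM_A if male else MISSING
        G[i, mt_idx] = np.asarray(panel.haplotype_key[haplos[i]], dtype=np.int8)
    out = df.copy()
    out["mt_haplotype"] = haplos
    return TruthPopulation(out, G, panel)


# per-allele miscall transition rows, built once per epsilon
def _miscall_matrix(epsilon: float) -> np.ndarray:
    e, f = epsilon, 1.0 - epsilon
    return np.array([
        [f * f, 2 * e * f, e * e],
        [e * f, f * f + e * e, e * f],
        [e * e, 2 * e * f, f * f],
    ])


def observe_genotypes(
    true_calls: np.ndarray,
    panel: MarkerPanel,
    epsilon: float,
    dropout_rate: float,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
    invalid_rate: float = 0.0,
) -> np.ndarray:
    """Corrupt one replicate of true calls: heterozygote allelic dropout
    (one allele lost with probability ``dropout_rate``, so a true het is
    read as either homozygote), then symmetric per-allele miscalls with
    probability ``epsilon``, then missingness/invalidation. Haploid
    (Y, mtDNA) calls are left error-free, as in scoring conventions that
    exclude them from error estimation.
    """
    obs = true_calls.copy()
    diploid = np.concatenate([panel.autosomal_idx, panel.x_idx])
    sub = obs[:, diploid]
    valid = sub >= 0
    # dropout: true hets only
    het = (sub == HET) & valid
    drop = het & (rng.random(sub.shape) < dropout_rate)
    sub[drop] = np.where(rng.random(sub.shape) < 0.5, HOM_A, HOM_B)[drop]
    if epsilon > 0:
        M = _miscall_matrix(epsilon)
        u = rng.random(sub.shape)
        cum = np.cumsum(M, axis=1)
        for g in (HOM_A, HET, HOM_B):
            m = (sub == g) & valid
            sub[m] = np.searchsorted(cum[g], u[m]).astype(np.int8)
    if missing_rate > 0:
        sub[valid & (rng.random(sub.shape) < missing_rate)] = MISSING
    if invalid_rate > 0:
        sub[(sub >= 0) & (rng.random(sub.shape) < invalid_rate)] = INVALID
    obs[:, diploid] = sub
    return obs


def simulate_fecal_samples(
    truth: TruthPopulation, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Sample table (sample_id, individual_id, x_km, y_km) for sampled
    individuals: counts from ``samples_per_ind_dist`` (support 1..19),
    isotropic Gaussian scatter of scale ``sample_scatter_km`` around the
    home-range center. A family with dependent cubs travels as a unit
    over a restricted range, so cub-litter offspring and their mothers
    draw samples with the tight ``cub_scatter_km`` scale around the
    shared center instead of the full home-range scatter.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    df = truth.individuals
    cub_mothers = set(df.loc[df["cub_litter"], "mother_id"])
    rows = []
    for _, r in df[df["sampled"]].iterrows():
        k = 1 + rng.choice(19, p=config.samples_per_ind_dist)
        family_unit = r["cub_litter"] or r["id"] in cub_mothers
        scale = config.cub_scatter_km if family_unit else config.sample_scatter_km
        sc = rng.normal(0.0, scale, size=(k, 2))
        for j in range(k):
            rows.append(dict(
                sample_id=f"{r['id']}_s{j}", individual_id=r["id"],
                x_km=r["x_km"] + sc[j, 0], y_km=r["y_km"] + sc[j, 1],
            ))
    return pd.DataFrame(rows)


def simulate_genotype_table(
    truth: TruthPopulation,
    panel: MarkerPanel,
    epsilon: float,
    dropout_rate: float,
    rng: np.random.Generator | int,
    samples: pd.DataFrame | None = None,
    missing_rate: float = 0.0,
    invalid_rate: float = 0.0,
) -> "GenotypeTable":
    """Observed genotype table, one row per fecal sample (replicates of
    an individual share its true genotype but carry independent errors).
    With no sample table, each sampled individual yields one row.
    """
    from .qc import GenotypeTable  # local import to avoid a cycle

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if truth.true_genotypes is None:
        truth = simulate_true_genotypes(truth, panel, rng)
    idx = truth.index_of()
    if samples is None:
        ids = [i for i in truth.individuals.loc[truth.individuals["sampled"], "id"]]
        sample_ids = [f"{i}_s0" for i in ids]
    else:
        ids = list(samples["individual_id"])
        sample_ids = list(samples["sample_id"])
    rows = np.array([idx[i] for i in ids], dtype=int)
    true_calls = truth.true_genotypes[rows]
    obs = observe_genotypes(true_calls, panel, epsilon, dropout_rate, rng,
                            missing_rate, invalid_rate)
    return GenotypeTable(sample_ids=sample_ids, group_ids=list(ids),
                         calls=obs, locus_ids=list(panel.locus_ids))


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    panel: MarkerPanel
    truth: TruthPopulation
    samples: pd.DataFrame
    genotypes: "object"  # GenotypeTable


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: pedigree, home ranges, fecal samples and
    observed replicate genotypes. Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    panel = default_panel(config, rng)
    truth = simulate_pedigree_population(config, rng)
    truth = assign_home_ranges(truth, config, rng)
    truth = simulate_true_genotypes(truth, panel, rng)
    samples = simulate_fecal_samples(truth, config, rng)
    gt = simulate_genotype_table(
        truth, panel, config.epsilon, config.dropout_rate, rng, samples,
        config.missing_rate, config.invalid_rate,
    )
    return SimulatedDataset(config, panel, truth, samples, gt)
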