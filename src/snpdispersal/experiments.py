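"""Replicate-level calibration experiments.

Self-contained, seeded experiment functions shared by the analysis
scripts, the test suite and the acceptance script: estimator
calibration on pairs of known relationship, pedigree-reconstruction
self-consistency, triad orientation accuracy, sex-biased dispersal
recovery, and Mantel null calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import qc, relatedness, spatial
from .dispersal import natal_distances, rank_sum_test, records_frame
from .markers import MISSING
from .parentage import (
    LikelihoodTables,
    ParentageConfig,
    Pedigree,
    _codes,
    reconstruct_pedigree,
)
from .simulate import (
    DEFAULT_SAMPLES_PER_IND,
    SimulationConfig,
    _displacements,
    simulate_dataset,
)

# ---------------------------------------------------------------------------
# relatedness-estimator calibration


def _hwe_genotypes(n: int, q: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(2, q[None, :], size=(n, len(q))).astype(np.int8)


def _offspring(gm: np.ndarray, gf: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    bm = (rng.random(gm.shape) < gm / 2.0).astype(np.int8)
    bf = (rng.random(gf.shape) < gf / 2.0).astype(np.int8)
    return bm + bf


def relationship_pair_r(
    kind: str,
    n_pairs: int,
    L: int = 87,
    maf: float = 0.37,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Lynch-Ritland r for simulated pairs of a known relationship.

    ``kind``: 'po' (parent-offspring), 'fs' (full sibs), 'hs' (half
    sibs, shared mother), 'gg' (grandparent-grandchild) or 'unrelated'.
    Genotypes are error-free draws at ``L`` loci of identical minor
    allele frequency ``maf``; the estimator is given the true
    frequencies.
    """
    rng = np.random.default_rng(seed)
    q = np.full(L, maf)
    a = _hwe_genotypes(n_pairs, q, rng)
    if kind == "po":
        mate = _hwe_genotypes(n_pairs, q, rng)
        b = _offspring(a, mate, rng)
    elif kind == "fs":
        p2 = _hwe_genotypes(n_pairs, q, rng)
        a, b = _offspring(a, p2, rng), _offspring(a, p2, rng)
    elif kind == "hs":
        f1 = _hwe_genotypes(n_pairs, q, rng)
        f2 = _hwe_genotypes(n_pairs, q, rng)
        a, b = _offspring(a, f1, rng), _offspring(a, f2, rng)
    elif kind == "gg":
        mate1 = _hwe_genotypes(n_pairs, q, rng)
        mate2 = _hwe_genotypes(n_pairs, q, rng)
        parent = _offspring(a, mate1, rng)
        b = _offspring(parent, mate2, rng)
    elif kind == "unrelated":
        b = _hwe_genotypes(n_pairs, q, rng)
    else:
        raise ValueError(f"unknown relationship {kind!r}")
    r, _ = relatedness.pairwise_r(a, b, 1.0 - q)
    return r


# ---------------------------------------------------------------------------
# pedigree reconstruction self-consistency


@dataclass
class ReconstructionResult:
    true_edges: set
    inferred_edges: set
    n_individuals: int
    n_assignments: int

    @property
    def exact_match(self) -> bool:
        return self.true_edges == self.inferred_edges

    @property
    def recall(self) -> float:
        """Fraction of true (sampled-pair) parent edges recovered."""
        if not self.true_edges:
            return float("nan")
        return len(self.true_edges & self.inferred_edges) / len(self.true_edges)


def pedigree_reconstruction_run(
    seed: int,
    n_founders: int = 8,
    n_generations: int = 3,
    prop_sampled: float = 1.0,
    epsilon: float = 0.0,
    parentage_config: ParentageConfig | None = None,
) -> ReconstructionResult:
    """Full sim -> QC -> parentage run, by default under ideal
    observation: no genotyping error, no dropout, no missing calls,
    every individual sampled - where the reconstructed pedigree should
    equal the truth. Lower ``prop_sampled`` to study recall
    degradation under the study's partial-sampling conditions."""
    cfg = SimulationConfig(
        n_founders_f=n_founders, n_founders_m=n_founders,
        n_generations=n_generations, epsilon=epsilon, dropout_rate=0.0,
        missing_rate=0.0, invalid_rate=0.0, prop_sampled=prop_sampled,
        seed=seed,
    )
    ds = simulate_dataset(cfg)
    cons = qc.consolidate_replicates(ds.genotypes, ds.panel)
    ind = qc.build_individuals(cons, ds.panel)
    a_idx = ds.panel.autosomal_idx
    calls = cons.individuals.calls[:, a_idx]
    # the panel's generating frequencies: at this deliberately small
    # population size, frequencies re-estimated from a few related
    # families are too noisy to stand in for the population values
    freq_a = ds.panel.freq_a[a_idx]
    sex_arr = ind["sex"].to_numpy()
    if parentage_config is not None:
        pcfg = parentage_config
    elif prop_sampled == 1.0:
        # whole population sampled: the candidate-pool maxima are the
        # sampled counts themselves (no unsampled-parent mass)
        pcfg = ParentageConfig(
            N_f_max=int((sex_arr == "F").sum()),
            N_m_max=int((sex_arr == "M").sum()),
        )
    else:
        pcfg = ParentageConfig()
    ped = reconstruct_pedigree(calls, list(ind["id"]), sex_arr, freq_a, pcfg)
    truth = ds.truth.individuals
    sampled_ids = set(ind["id"])
    true_edges = set()
    for _, r in truth.iterrows():
        if r["id"] not in sampled_ids:
            continue
        if r["mother_id"] is not None and r["mother_id"] in sampled_ids:
            true_edges.add((r["mother_id"], r["id"], "mother"))
        if r["father_id"] is not None and r["father_id"] in sampled_ids:
            true_edges.add((r["father_id"], r["id"], "father"))
    return ReconstructionResult(
        true_edges=true_edges, inferred_edges=ped.edge_set(),
        n_individuals=len(ind), n_assignments=len(ped.accepted),
    )


def triad_orientation_accuracy(
    n_triads: int = 500,
    L: int = 87,
    maf: float = 0.37,
    epsilon: float = 1.538e-4,
    seed: int = 0,
) -> float:
    """Fraction of simulated mother-father-offspring triples in which
    the member best explained as the offspring (maximum triad
    likelihood over sex-compatible orientations) is the true offspring.
    """
    rng = np.random.default_rng(seed)
    q = np.full(L, maf)
    freq_a = 1.0 - q
    tables = LikelihoodTables(freq_a, epsilon)
    lt = tables.log_triad()
    l_idx = np.arange(L)

    def ll(go, gm, gf):
        return float(lt[l_idx, _codes(gm), _codes(gf), _codes(go)].sum())

    correct = 0
    for _ in range(n_triads):
        gm = _hwe_genotypes(1, q, rng)[0]
        gf = _hwe_genotypes(1, q, rng)[0]
        go = _offspring(gm[None], gf[None], rng)[0]
        off_female = rng.random() < 0.5
        candidates = {"o": ll(go, gm, gf)}
        if off_female:
            candidates["m"] = ll(gm, go, gf)  # mother recast as the child
        else:
            candidates["f"] = ll(gf, gm, go)  # father recast as the child
        if max(candidates, key=candidates.get) == "o":
            correct += 1
    return correct / n_triads


# ---------------------------------------------------------------------------
# sex-biased dispersal recovery


def dispersal_recovery_replicate(
    seed: int | np.random.Generator,
    n_f: int = 38,
    n_m: int = 25,
    mean_f_km: float = 12.9,
    mean_m_km: float = 33.8,
    kernel: str = "exponential",
    scatter_km: float = 3.0,
    region_km: float = 214.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one study's worth of mother-offspring pairs through the
    spatial pipeline and return the recovered (female, male) natal
    distances.

    Mothers sit at uniform positions; offspring are displaced by the
    sex-specific kernel on an unbounded plane (no boundary truncation,
    isolating estimator behavior from edge effects); both generations
    are observed through scattered fecal samples and median centers,
    and distances come from the oriented mother links.
    """
    rng = np.random.default_rng(seed)
    n = n_f + n_m
    sexes = np.array(["F"] * n_f + ["M"] * n_m, dtype=object)
    mothers = rng.uniform(0, region_km, size=(n, 2))
    disp = np.vstack([
        _displacements(n_f, mean_f_km, kernel, rng),
        _displacements(n_m, mean_m_km, kernel, rng),
    ])
    offspring = mothers + disp
    ped = Pedigree()
    centers: dict[str, np.ndarray] = {}
    sexes_by_id: dict[str, str] = {}
    for i in range(n):
        mid, oid = f"mom{i}", f"off{i}"
        ped.add([(mid, oid, "mother")])
        sexes_by_id[mid] = "F"
        sexes_by_id[oid] = str(sexes[i])
        for iid, true_xy in ((mid, mothers[i]), (oid, offspring[i])):
            k = 1 + rng.choice(19, p=DEFAULT_SAMPLES_PER_IND)
            pts = true_xy[None, :] + rng.normal(0.0, scatter_km, size=(k, 2))
            centers[iid] = spatial.median_center(pts)
    recs = natal_distances(ped, centers, sexes_by_id)
    df = records_frame(recs)
    kept = df[~df["is_cub"]]
    return (kept.loc[kept["offspring_sex"] == "F", "distance_km"].to_numpy(),
            kept.loc[kept["offspring_sex"] == "M", "distance_km"].to_numpy())


def sex_bias_recovery(
    n_reps: int = 40, seed: int = 0, alpha: float = 0.05, **kw
) -> dict:
    """Run ``n_reps`` dispersal-recovery replicates; report the mean
    recovered female/male dispersal means and the fraction of
    replicates in which the two-sided rank-sum test rejects."""
    rng = np.random.default_rng(seed)
    means_f, means_m, rejections = [], [], 0
    for _ in range(n_reps):
        d_f, d_m = dispersal_recovery_replicate(rng, **kw)
        means_f.append(d_f.mean())
        means_m.append(d_m.mean())
        _, p = rank_sum_test(d_f, d_m)
        rejections += p < alpha
    return dict(
        mean_f=float(np.median(means_f)), mean_m=float(np.median(means_m)),
        reject_rate=rejections / n_reps, n_reps=n_reps,
    )


# ---------------------------------------------------------------------------
# Mantel null calibration


def mantel_null_pvalues(
    n_runs: int = 200, n: int = 30, n_perm: int = 99, seed: int = 0
) -> np.ndarray:
    """p-values of the Mantel test on independent random matrices;
    uniform on (0, 1] when the test is calibrated."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_runs)
    for k in range(n_runs):
        D = _random_sym(n, rng)
        R = _random_sym(n, rng)
        _, out[k] = spatial.mantel_test(
            D, R, n_perm=n_perm, seed=rng, alternative="greater"
        )
    return out


def _random_sym(n: int, rng: np.random.Generator) -> np.ndarray:
    m = rng.random((n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m
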