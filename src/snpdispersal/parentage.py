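"""Likelihood-based parentage assignment and pedigree assembly.

A transparent, deterministic simplification of MCMC parentage samplers:
for every focal individual all candidate-parent hypotheses are scored
with an explicit genotyping-error-aware Mendelian likelihood, combined
with a prior that gives unsampled parents mass proportional to the
assumed number of unsampled candidates per sex, and the maximum-
posterior hypothesis is retained when it clears a posterior threshold.
High-confidence assignments are then assembled greedily into disjoint,
sex-consistent, acyclic pedigrees.

Only autosomal loci enter the likelihoods; the mtDNA haplotype serves
as a post-hoc maternity consistency check (violations are flagged, not
auto-rejected).

Likelihoods are conditional on the candidates' observed genotypes,
P(g_offspring | g_candidates, H): the candidates' own genotype
marginals are common to all hypotheses for a focal individual and
cancel in the posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .markers import HET, HOM_A, HOM_B

_NEG_INF = -np.inf

# ---------------------------------------------------------------------------
# single-locus building blocks


def error_model(epsilon: float) -> np.ndarray:
    """Genotype confusion matrix E[true, observed] from independent
    symmetric per-allele miscalls with probability ``epsilon``."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0,1]")
    e, f = epsilon, 1.0 - epsilon
    return np.array([
        [f * f, 2 * e * f, e * e],
        [e * f, f * f + e * e, e * f],
        [e * e, 2 * e * f, f * f],
    ])


def _gamete(g: int) -> np.ndarray:
    """P(transmitted allele is B | parent genotype)."""
    return np.array([1.0 - g / 2.0, g / 2.0])  # [P(A), P(B)]


def transmission_prob(g_off: int, g_mother: int, g_father: int) -> float:
    """Mendelian P(offspring genotype | parent genotypes) at one
    biallelic autosomal locus."""
    pm, pf = _gamete(g_mother), _gamete(g_father)
    probs = np.outer(pm, pf)  # allele pairs (maternal, paternal)
    by_geno = np.array([probs[0, 0], probs[0, 1] + probs[1, 0], probs[1, 1]])
    return float(by_geno[g_off])


def _transmission_tensor() -> np.ndarray:
    T = np.empty((3, 3, 3))
    for gm in range(3):
        for gf in range(3):
            for go in range(3):
                T[gm, gf, go] = transmission_prob(go, gm, gf)
    return T


_T = _transmission_tensor()


def _hwe(freq_a: np.ndarray) -> np.ndarray:
    """HWE genotype priors per locus, shape (L, 3) in B-count coding."""
    p = np.asarray(freq_a, dtype=float)
    q = 1.0 - p
    return np.stack([p * p, 2 * p * q, q * q], axis=1)


class LikelihoodTables:
    """Per-locus log-likelihood lookup tables for observed-call codes.

    Observed codes are mapped to indices 0..3 where 3 pools missing and
    invalid calls (a missing call contributes a factor that cancels
    between hypotheses: 1 for the focal individual, the HWE posterior
    for a candidate).
    """

    def __init__(self, freq_a: np.ndarray, epsilon: float):
        self.freq_a = np.asarray(freq_a, dtype=float)
        self.epsilon = float(epsilon)
        L = len(self.freq_a)
        E = error_model(epsilon)
        H = _hwe(self.freq_a)  # (L, 3)
        # posterior of the candidate's true genotype given its observed
        # call: P(t | obs) prop to HWE_t * E[t, obs]; obs index 3 -> HWE
        post = H[:, :, None] * E[None, :, :]  # (L, true, obs)
        post = post / post.sum(axis=1, keepdims=True)
        self.post = np.concatenate([post, H[:, :, None]], axis=2)  # (L,3,4)
        # offspring emission: P(obs | t); obs index 3 -> 1
        self.emit = np.concatenate([E.T[None], np.ones((1, 1, 3))], axis=1)
        self.emit = np.broadcast_to(self.emit, (L, 4, 3))  # (L, obs, true)
        self.hwe = H
        # single-parent transmission with the co-parent integrated over
        # the population allele frequencies
        q = 1.0 - self.freq_a
        Td = np.empty((L, 3, 3))  # (L, t_parent, t_off)
        for tp in range(3):
            gam = _gamete(tp)
            for to in range(3):
                Td[:, tp, to] = (
                    gam[0] * ((1 - q) if to == 0 else (q if to == 1 else 0.0))
                    + gam[1] * (0.0 if to == 0 else ((1 - q) if to == 1 else q))
                )
        self.Td = Td
        self._logs: dict[str, np.ndarray] = {}

    def log_dyad(self) -> np.ndarray:
        """log P(g_o | g_p) table, shape (L, 4 parent obs, 4 off obs)."""
        if "dyad" not in self._logs:
            # L,tp,to sums: post (L,3,4) x Td (L,3,3) x emit (L,4,3)
            lik = np.einsum("ltp,lto,loe->lpe", self.post, self.Td,
                            np.swapaxes(self.emit, 1, 2))
            # lik dims: (L, parent obs p, off obs e)? einsum above:
            # post[l,t,p] Td[l,t,o] emit_sw[l,o,e] -> [l,p,e]
            with np.errstate(divide="ignore"):
                self._logs["dyad"] = np.log(lik)
        return self._logs["dyad"]

    def log_triad(self) -> np.ndarray:
        """log P(g_o | g_m, g_f), shape (L, 4, 4, 4) obs codes (m, f, o)."""
        if "triad" not in self._logs:
            emit_sw = np.swapaxes(self.emit, 1, 2)  # (L, true, obs)
            lik = np.einsum("lmp,lnq,lmno,loe->lpqe", self.post, self.post,
                            np.broadcast_to(_T, (len(self.freq_a), 3, 3, 3)),
                            emit_sw)
            with np.errstate(divide="ignore"):
                self._logs["triad"] = np.log(lik)
        return self._logs["triad"]

    def log_unrelated(self) -> np.ndarray:
        """log P(g_o) under HWE, shape (L, 4)."""
        if "unrel" not in self._logs:
            lik = np.einsum("lt,lte->le", self.hwe, np.swapaxes(self.emit, 1, 2))
            lik = np.concatenate([lik, np.ones((len(self.freq_a), 1))], axis=1)
            with np.errstate(divide="ignore"):
                self._logs["unrel"] = np.log(lik)
        return self._logs["unrel"]


def _codes(g: np.ndarray) -> np.ndarray:
    """Map stored call codes to table indices (missing/invalid -> 3)."""
    g = np.asarray(g)
    return np.where(g >= 0, g, 3)


def triad_loglik(
    g_o: np.ndarray, g_m: np.ndarray, g_f: np.ndarray,
    freq_a: np.ndarray, epsilon: float,
    tables: LikelihoodTables | None = None,
) -> float:
    """Log-likelihood that (m, f) are the parents of o, multiplied over
    loci; missing calls are marginalized. -inf signals a Mendelian
    exclusion at zero error rate."""
    t = tables if tables is not None else LikelihoodTables(freq_a, epsilon)
    lt = t.log_triad()
    l_idx = np.arange(lt.shape[0])
    return float(lt[l_idx, _codes(g_m), _codes(g_f), _codes(g_o)].sum())


def dyad_loglik(
    g_o: np.ndarray, g_p: np.ndarray,
    freq_a: np.ndarray, epsilon: float,
    tables: LikelihoodTables | None = None,
) -> float:
    """Log-likelihood that p is a parent of o with the co-parent
    unsampled (its transmitted allele drawn from population
    frequencies)."""
    t = tables if tables is not None else LikelihoodTables(freq_a, epsilon)
    ld = t.log_dyad()
    l_idx = np.arange(ld.shape[0])
    return float(ld[l_idx, _codes(g_p), _codes(g_o)].sum())


def unrelated_loglik(
    g_o: np.ndarray, freq_a: np.ndarray, epsilon: float,
    tables: LikelihoodTables | None = None,
) -> float:
    t = tables if tables is not None else LikelihoodTables(freq_a, epsilon)
    lu = t.log_unrelated()
    return float(lu[np.arange(lu.shape[0]), _codes(g_o)].sum())


# ---------------------------------------------------------------------------
# population-level assignment


@dataclass
class ParentageConfig:
    """Candidate-pool sizes, typing error and posterior filter.

    ``N_f_max``/``N_m_max`` are the assumed numbers of candidate mothers
    and fathers in the population (sampled plus unsampled); the excess
    over the sampled counts sets the prior mass on unsampled parents.
    """

    N_f_max: int = 663
    N_m_max: int = 516
    epsilon: float = 1.538e-4
    posterior_threshold: float = 0.95

    def __post_init__(self) -> None:
        if not 0.5 < self.posterior_threshold <= 1.0:
            raise ValueError("posterior_threshold must be in (0.5, 1]")
        if not 0.0 <= self.epsilon <= 0.05:
            raise ValueError("epsilon must be in [0, 0.05]")


@dataclass
class ParentageAssignment:
    offspring_id: str
    mother_id: str | None  # None = unsampled
    father_id: str | None
    loglik: float
    posterior: float
    #: log Bayes-factor of this hypothesis against the both-parents-
    #: unsampled hypothesis (priors included); used to arbitrate
    #: between mutually exclusive assignments during assembly.
    gain: float = 0.0
    arity: str = field(init=False)

    def __post_init__(self) -> None:
        both = self.mother_id is not None and self.father_id is not None
        self.arity = "triad" if both else "dyad"


def _logsumexp(v: np.ndarray) -> float:
    m = np.max(v)
    if not np.isfinite(m):
        return _NEG_INF
    return float(m + np.log(np.sum(np.exp(v - m))))


def hypothesis_posteriors(
    focal: int,
    calls: np.ndarray,
    sexes: np.ndarray,
    config: ParentageConfig,
    tables: LikelihoodTables,
    dyad_tot: np.ndarray,
    unrel_tot: np.ndarray,
    exclude: set[int] | frozenset[int] = frozenset(),
) -> list[tuple[str | None, str | None, float, float]]:
    """Posterior over parentage hypotheses for one focal individual.

    Returns (mother_idx|None, father_idx|None, score, posterior) rows,
    where score is the hypothesis log-likelihood plus log-prior;
    posteriors over the full hypothesis set sum to one. Candidate pairs
    for the triad hypotheses are pre-screened by a positive dyad
    likelihood ratio against the unrelated hypothesis. ``exclude``
    removes candidates (e.g. the focal's pedigree descendants when
    assignment is conditioned on a partially assembled pedigree).
    """
    n = calls.shape[0]
    ok = np.ones(n, dtype=bool)
    ok[focal] = False
    for e in exclude:
        ok[e] = False
    females = np.flatnonzero((sexes == "F") & ok)
    males = np.flatnonzero((sexes == "M") & ok)
    tot_f = int((sexes == "F").sum())
    tot_m = int((sexes == "M").sum())
    if config.N_f_max < tot_f or config.N_m_max < tot_m:
        raise ValueError("N_f_max/N_m_max below the number of sampled candidates")
    u_f = config.N_f_max - tot_f
    u_m = config.N_m_max - tot_m
    lr = dyad_tot[focal] - unrel_tot[focal]
    cand_f = females[lr[females] > 0]
    cand_m = males[lr[males] > 0]
    lt = tables.log_triad()
    l_idx = np.arange(lt.shape[0])
    go = _codes(calls[focal])
    hyps: list[tuple[int | None, int | None, float]] = []
    for m in cand_f:
        gm = _codes(calls[m])
        for f in cand_m:
            ll = float(lt[l_idx, gm, _codes(calls[f]), go].sum())
            if np.isfinite(ll):
                hyps.append((m, f, ll))
    for m in females:
        hyps.append((m, None, dyad_tot[focal, m] + math.log(u_m) if u_m > 0 else _NEG_INF))
    for f in males:
        hyps.append((None, f, dyad_tot[focal, f] + math.log(u_f) if u_f > 0 else _NEG_INF))
    none_ll = (
        unrel_tot[focal] + math.log(u_f) + math.log(u_m)
        if u_f > 0 and u_m > 0 else _NEG_INF
    )
    hyps.append((None, None, none_ll))
    scores = np.array([h[2] for h in hyps])
    z = _logsumexp(scores)
    out = []
    for (m, f, s) in hyps:
        post = math.exp(s - z) if np.isfinite(s) and np.isfinite(z) else 0.0
        out.append((m, f, s, post))
    return out


def dyad_loglik_matrix(calls: np.ndarray, tables: LikelihoodTables) -> np.ndarray:
    """M[o, p] = log P(g_o | p parent, co-parent unsampled), all ordered
    pairs, vectorized per locus."""
    ld = tables.log_dyad()  # (L, 4, 4)
    n, L = calls.shape
    codes = _codes(calls)
    M = np.zeros((n, n))
    for l in range(L):
        M += ld[l][np.ix_(codes[:, l], codes[:, l])].T  # [o,p] = ld[p_code,o_code]
    return M


def unrelated_loglik_vector(calls: np.ndarray, tables: LikelihoodTables) -> np.ndarray:
    lu = tables.log_unrelated()
    codes = _codes(calls)
    return lu[np.arange(lu.shape[0])[None, :], codes].sum(axis=1)


def assign_parentage(
    calls: np.ndarray,
    ids: list[str],
    sexes: np.ndarray,
    freq_a: np.ndarray,
    config: ParentageConfig | None = None,
) -> list[ParentageAssignment]:
    """Maximum-posterior parentage per focal individual.

    ``calls`` are consolidated autosomal genotypes (n, L); ``sexes`` the
    called sexes ('F'/'M'/'U'; undetermined individuals are scored as
    offspring but excluded from candidate-parent pools). An assignment
    is emitted only when the best hypothesis names at least one sampled
    parent and its posterior clears ``config.posterior_threshold``.
    """
    config = config or ParentageConfig()
    tables = LikelihoodTables(freq_a, config.epsilon)
    dyad_tot = dyad_loglik_matrix(calls, tables)
    unrel_tot = unrelated_loglik_vector(calls, tables)
    sexes = np.asarray(sexes, dtype=object)
    out: list[ParentageAssignment] = []
    for o in range(calls.shape[0]):
        a = _best_assignment(o, calls, ids, sexes, config, tables,
                             dyad_tot, unrel_tot)
        if a is not None:
            out.append(a)
    return out


def _best_assignment(
    o: int,
    calls: np.ndarray,
    ids: list[str],
    sexes: np.ndarray,
    config: ParentageConfig,
    tables: LikelihoodTables,
    dyad_tot: np.ndarray,
    unrel_tot: np.ndarray,
    exclude: set[int] | frozenset[int] = frozenset(),
) -> ParentageAssignment | None:
    rows = hypothesis_posteriors(o, calls, sexes, config, tables,
                                 dyad_tot, unrel_tot, exclude)
    m, f, score, post = max(rows, key=lambda r: r[3])
    if (m is None and f is None) or post < config.posterior_threshold:
        return None
    return _to_assignment(o, m, f, score, post, ids, sexes, config, unrel_tot)


def _to_assignment(
    o: int, m: int | None, f: int | None, score: float, post: float,
    ids: list[str], sexes: np.ndarray, config: ParentageConfig,
    unrel_tot: np.ndarray,
) -> ParentageAssignment:
    # prior-free log Bayes factor against the unrelated hypothesis
    log_prior = 0.0
    if m is None:
        log_prior += math.log(max(config.N_f_max - int((sexes == "F").sum()), 1))
    if f is None:
        log_prior += math.log(max(config.N_m_max - int((sexes == "M").sum()), 1))
    return ParentageAssignment(
        offspring_id=ids[o],
        mother_id=ids[m] if m is not None else None,
        father_id=ids[f] if f is not None else None,
        loglik=score, posterior=post,
        gain=(score - log_prior) - unrel_tot[o],
    )


def _candidate_assignments(
    o: int,
    calls: np.ndarray,
    ids: list[str],
    sexes: np.ndarray,
    config: ParentageConfig,
    tables: LikelihoodTables,
    dyad_tot: np.ndarray,
    unrel_tot: np.ndarray,
    max_hyps: int = 8,
    score_window: float = 12.0,
) -> list[ParentageAssignment]:
    """Hypothesis pool for one focal: the top-scoring parentage
    hypotheses naming at least one sampled parent, within
    ``score_window`` log-units of the best and capped at ``max_hyps``.

    Near-tied alternatives (e.g. a true father versus a son or full
    sibling recast as father) are kept so that pedigree assembly can
    arbitrate between them by joint consistency rather than by the
    focal's marginal posterior alone.
    """
    rows = hypothesis_posteriors(o, calls, sexes, config, tables,
                                 dyad_tot, unrel_tot)
    rows = [r for r in rows if not (r[0] is None and r[1] is None)
            and np.isfinite(r[2])]
    if not rows:
        return []
    rows.sort(key=lambda r: -r[2])
    best = rows[0][2]
    out = []
    for m, f, score, post in rows[:max_hyps]:
        if score < best - score_window:
            break
        out.append(_to_assignment(o, m, f, score, post, ids, sexes, config,
                                  unrel_tot))
    return out


# ---------------------------------------------------------------------------
# pedigree assembly


class Pedigree:
    """Directed parent->offspring graph with per-edge sex roles."""

    def __init__(self) -> None:
        self.graph = nx.DiGraph()
        self.unoriented_dyads: list[tuple[str, str]] = []

    def add_individual(self, iid: str) -> None:
        self.graph.add_node(iid)

    def parent(self, iid: str, role: str) -> str | None:
        if not self.graph.has_node(iid):
            return None
        for p in self.graph.predecessors(iid):
            if self.graph.edges[p, iid]["role"] == role:
                return p
        return None

    def mother_of(self, iid: str) -> str | None:
        return self.parent(iid, "mother")

    def father_of(self, iid: str) -> str | None:
        return self.parent(iid, "father")

    def _edge_ok(self, parent: str, child: str, role: str) -> bool:
        if parent == child:
            return False
        if self.graph.has_node(child) and self.parent(child, role) not in (None, parent):
            return False
        if (self.graph.has_node(parent) and self.graph.has_node(child)
                and nx.has_path(self.graph, child, parent)):
            return False
        return True

    def can_add(self, edges: list[tuple[str, str, str]]) -> bool:
        """Atomically check a set of (parent, child, role) edges."""
        trial = self.graph.copy()
        for parent, child, role in edges:
            saved, self.graph = self.graph, trial
            ok = self._edge_ok(parent, child, role)
            self.graph = saved
            if not ok:
                return False
            trial.add_edge(parent, child, role=role)
        return True

    def add(self, edges: list[tuple[str, str, str]]) -> None:
        for parent, child, role in edges:
            self.graph.add_edge(parent, child, role=role)

    def remove(self, edges: list[tuple[str, str, str]]) -> None:
        for parent, child, _ in edges:
            if self.graph.has_edge(parent, child):
                self.graph.remove_edge(parent, child)

    def edge_set(self) -> set[tuple[str, str, str]]:
        return {(u, v, d["role"]) for u, v, d in self.graph.edges(data=True)}

    def components(self, include_unoriented: bool = True) -> list[set[str]]:
        und = self.graph.to_undirected()
        if include_unoriented:
            und = nx.Graph(und)
            und.add_edges_from(self.unoriented_dyads)
        return [c for c in nx.connected_components(und) if len(c) > 1]

    def component_summary(self) -> pd.DataFrame:
        rows = []
        for k, comp in enumerate(self.components()):
            sub = self.graph.subgraph(comp)
            span = nx.dag_longest_path_length(sub) + 1 if sub.number_of_edges() else 1
            rows.append(dict(component=k, size=len(comp), generation_span=span))
        return pd.DataFrame(rows)


def _assignment_edges(
    a: ParentageAssignment, sexes_by_id: dict[str, str]
) -> list[tuple[str, str, str]]:
    edges = []
    if a.mother_id is not None:
        if sexes_by_id.get(a.mother_id) != "F":
            return []
        edges.append((a.mother_id, a.offspring_id, "mother"))
    if a.father_id is not None:
        if sexes_by_id.get(a.father_id) != "M":
            return []
        edges.append((a.father_id, a.offspring_id, "father"))
    return edges


def assemble_pedigree(
    assignments: list[ParentageAssignment],
    sexes_by_id: dict[str, str],
) -> Pedigree:
    """Greedy maximum-posterior pedigree assembly.

    Assignments are inserted atomically (the full parent set of an
    offspring), triads before dyads - a triad fixes its own direction
    through allele sharing, a pairwise dyad does not - and within each
    arity in decreasing posterior (then likelihood) order. An assignment
    is rejected if it would create a cycle, give anyone a second parent
    of the same sex, or violate sex roles. A repair sweep then removes
    any accepted assignment whose blocked competitors carry a larger
    summed likelihood gain (log Bayes factor against the unsampled-
    parents hypothesis), preferring the pedigree configuration that
    best explains the whole sample.
    """
    ped = Pedigree()
    order = sorted(
        assignments,
        key=lambda a: (a.arity != "triad", -a.gain, -a.posterior, -a.loglik),
    )
    accepted: list[ParentageAssignment] = []
    rejected: list[ParentageAssignment] = []
    assigned: set[str] = set()
    for a in order:
        edges = _assignment_edges(a, sexes_by_id)
        if edges and a.offspring_id not in assigned and ped.can_add(edges):
            ped.add(edges)
            accepted.append(a)
            assigned.add(a.offspring_id)
        else:
            rejected.append(a)
    for _ in range(4):  # repair sweeps; terminates early at fixpoint
        changed = False
        for a in list(accepted):
            edges = _assignment_edges(a, sexes_by_id)
            ped.remove(edges)
            assigned.discard(a.offspring_id)
            admitted: list[ParentageAssignment] = []
            for b in sorted(rejected, key=lambda b: -b.gain):
                if b.offspring_id in assigned or any(
                    b.offspring_id == c.offspring_id for c in admitted
                ):
                    continue
                b_edges = _assignment_edges(b, sexes_by_id)
                if b_edges and ped.can_add(b_edges):
                    ped.add(b_edges)
                    admitted.append(b)
            if admitted and sum(b.gain for b in admitted) > a.gain:
                accepted.remove(a)
                for b in admitted:
                    rejected.remove(b)
                    assigned.add(b.offspring_id)
                accepted.extend(admitted)
                rejected.append(a)
                changed = True
            else:
                for b in admitted:
                    ped.remove(_assignment_edges(b, sexes_by_id))
                if ped.can_add(edges):
                    ped.add(edges)
                    assigned.add(a.offspring_id)
                else:  # displaced during repair; treat as rejected
                    accepted.remove(a)
                    rejected.append(a)
                    changed = True
        if not changed:
            break
    ped.accepted = accepted  # type: ignore[attr-defined]
    ped.rejected = rejected  # type: ignore[attr-defined]
    return ped


def orient_dyads(
    ped: Pedigree,
    assignments: list[ParentageAssignment],
    sexes_by_id: dict[str, str],
) -> Pedigree:
    """Resolve the direction of isolated single-parent (dyad) links.

    Triad members are oriented by construction. For a pure dyad {a, b}
    the pairwise parent-offspring likelihood is symmetric, so the link
    is kept oriented only when exactly one orientation is structurally
    possible (the other would create a cycle or a second same-sex
    parent); when both orientations are admissible the edge inserted at
    assembly time is demoted to an unoriented parent-offspring link,
    which downstream dispersal estimation ignores.
    """
    pairs: dict[frozenset, ParentageAssignment] = {}
    for a in getattr(ped, "accepted", assignments):
        if a.arity == "dyad":
            p = a.mother_id or a.father_id
            pairs.setdefault(frozenset((p, a.offspring_id)), a)
    for pair in pairs:
        a, b = sorted(pair)
        current = None
        for parent, child in ((a, b), (b, a)):
            if ped.graph.has_edge(parent, child):
                current = (parent, child, ped.graph.edges[parent, child]["role"])
        if current is None:
            continue
        ped.remove([current])
        options = []
        for parent, child in ((a, b), (b, a)):
            role = {"F": "mother", "M": "father"}.get(sexes_by_id.get(parent))
            if role is not None and ped.can_add([(parent, child, role)]):
                options.append((parent, child, role))
        if len(options) == 1:
            ped.add(options)
        elif len(options) >= 2:
            ped.unoriented_dyads.append((a, b))
        else:  # neither fits once removed; restore the assembled edge
            ped.add([current])
    return ped


def reconstruct_pedigree(
    calls: np.ndarray,
    ids: list[str],
    sexes: np.ndarray,
    freq_a: np.ndarray,
    config: ParentageConfig | None = None,
    max_passes: int = 4,
) -> Pedigree:
    """End-to-end pedigree reconstruction: per-focal maximum-posterior
    assignment, greedy assembly with repair, then conditional
    reassignment passes.

    Without age data, a sampled offspring is genotypically as good a
    "parent" of its own parent as the reverse, which dilutes per-focal
    posteriors. The reassignment passes recompute the posterior of every
    still-unassigned individual conditional on the current pedigree -
    excluding its pedigree descendants from the candidate pools - and
    insert any hypothesis that now clears the threshold, iterating to a
    fixpoint. This approximates joint maximum-a-posteriori pedigree
    inference while remaining deterministic.
    """
    config = config or ParentageConfig()
    sexes = np.asarray(sexes, dtype=object)
    tables = LikelihoodTables(freq_a, config.epsilon)
    dyad_tot = dyad_loglik_matrix(calls, tables)
    unrel_tot = unrelated_loglik_vector(calls, tables)
    pool: list[ParentageAssignment] = []
    for o in range(calls.shape[0]):
        pool.extend(_candidate_assignments(o, calls, ids, sexes, config,
                                           tables, dyad_tot, unrel_tot))
    sexes_by_id = dict(zip(ids, sexes))
    ped = assemble_pedigree(pool, sexes_by_id)
    pos = {iid: i for i, iid in enumerate(ids)}
    for _ in range(max_passes):
        # demote structurally ambiguous dyad edges first so a reversed
        # parent-offspring dyad cannot masquerade as pedigree structure
        ped = orient_dyads(ped, ped.accepted, sexes_by_id)
        changed = False
        assigned = {a.offspring_id for a in ped.accepted
                    if ped.graph.in_degree(a.offspring_id) > 0}
        for o, iid in enumerate(ids):
            if iid in assigned or not ped.graph.has_node(iid):
                continue
            desc = {pos[d] for d in nx.descendants(ped.graph, iid) if d in pos}
            a = _best_assignment(o, calls, ids, sexes, config, tables,
                                 dyad_tot, unrel_tot, exclude=desc)
            if a is None or a.arity != "triad":
                continue  # a lone dyad adds no orientable structure here
            edges = _assignment_edges(a, sexes_by_id)
            if edges and ped.can_add(edges):
                ped.add(edges)
                ped.accepted.append(a)
                changed = True
        if not changed:
            break
    # confidence filter: keep an accepted hypothesis only if its
    # posterior, conditional on the assembled structure (pedigree
    # descendants excluded from the candidate pools), clears the
    # threshold
    for a in list(ped.accepted):
        o = pos[a.offspring_id]
        desc = ({pos[d] for d in nx.descendants(ped.graph, a.offspring_id)
                 if d in pos} if ped.graph.has_node(a.offspring_id) else set())
        rows = hypothesis_posteriors(o, calls, sexes, config, tables,
                                     dyad_tot, unrel_tot, exclude=desc)
        target = (
            pos[a.mother_id] if a.mother_id is not None else None,
            pos[a.father_id] if a.father_id is not None else None,
        )
        post = next((p for m, f, _, p in rows if (m, f) == target), 0.0)
        if post >= config.posterior_threshold:
            a.posterior = post
        else:
            ped.remove(_assignment_edges(a, sexes_by_id))
            ped.accepted.remove(a)
    ped = orient_dyads(ped, ped.accepted, sexes_by_id)
    ped.unoriented_dyads = [
        (a, b) for a, b in dict.fromkeys(ped.unoriented_dyads)
        if not (ped.graph.has_edge(a, b) or ped.graph.has_edge(b, a))
    ]
    return ped


def mt_consistency_flags(
    ped: Pedigree, haplotypes: dict[str, str]
) -> list[tuple[str, str]]:
    """Mother-offspring pairs whose mtDNA haplotypes disagree (flagged,
    never auto-rejected)."""
    bad = []
    for child in ped.graph.nodes:
        m = ped.mother_of(child)
        if m is None:
            continue
        hm, hc = haplotypes.get(m), haplotypes.get(child)
        if hm not in (None, "unassigned") and hc not in (None, "unassigned") and hm != hc:
            bad.append((m, child))
    return bad
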