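"""Pairwise Lynch-Ritland relatedness.

The Lynch & Ritland (1999) regression estimator measures, per locus,
how much individual y's alleles are over-represented among individual
x's alleles relative to Hardy-Weinberg expectation. With x the
reference, alleles (a, b) for x and (c, d) for y, and S.. the
allele-identity indicator:

    r_x(l) = [p_a (S_bc + S_bd) + p_b (S_ac + S_ad) - 4 p_a p_b]
             / [(1 + S_ab)(p_a + p_b) - 4 p_a p_b]

Loci are combined with the Lynch-Ritland weights, locus weight =
denominator / (2 p_a p_b), and the reported coefficient is the mean of
the two reciprocal (x-reference and y-reference) multilocus estimates.
Unbiased for all true r, the estimator has sampling range beyond [0, 1];
parent-offspring and full-sib pairs center on 0.5, half-sibs and
grandparent-grandchild on 0.25, unrelated pairs on 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import HET, HOM_A, HOM_B

_ALLELES = {HOM_A: (0, 0), HET: (0, 1), HOM_B: (1, 1)}


def _pair_tables(freq_a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus lookup tables for the weighted estimator with reference x.

    Returns ``num[gx, gy, l]`` (= per-locus numerator / (2 p_a p_b), i.e.
    weight x estimate) and ``den[gx, l]`` (= the Lynch-Ritland locus
    weight). Monomorphic loci yield NaN and must be masked upstream.
    """
    p = np.asarray(freq_a, dtype=float)
    freqs = np.stack([p, 1.0 - p])  # allele index 0 = A, 1 = B
    num = np.full((3, 3, len(p)), np.nan)
    den = np.full((3, len(p)), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        for gx, (a, b) in _ALLELES.items():
            pa, pb = freqs[a], freqs[b]
            s_ab = 1.0 if a == b else 0.0
            d = (1.0 + s_ab) * (pa + pb) - 4.0 * pa * pb
            w = 2.0 * pa * pb  # zero at monomorphic loci -> NaN, masked upstream
            den[gx] = d / w
            for gy, (c, d_al) in _ALLELES.items():
                s = lambda u, v: 1.0 if u == v else 0.0
                n = (pa * (s(b, c) + s(b, d_al)) + pb * (s(a, c) + s(a, d_al))
                     - 4.0 * pa * pb)
                num[gx, gy] = n / w
    return num, den


def _directional_r(
    gx: np.ndarray, gy: np.ndarray, num: np.ndarray, den: np.ndarray,
    valid: np.ndarray, l_idx: np.ndarray,
) -> np.ndarray:
    """Weighted multilocus estimate with x as reference, rows = pairs."""
    n_sum = np.where(valid, num[gx.clip(0), gy.clip(0), l_idx], 0.0).sum(axis=1)
    d_sum = np.where(valid, den[gx.clip(0), l_idx], 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return n_sum / d_sum


def pairwise_r(
    g1: np.ndarray, g2: np.ndarray, freq_a: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetrized Lynch-Ritland r for aligned arrays of genotype pairs.

    ``g1``, ``g2``: (n_pairs, L) coded genotypes; loci with a missing or
    invalid call in either member, or monomorphic frequencies, are
    excluded from both the sums and the weights of that pair.

    Returns ``(r, n_loci_used)``; pairs with no usable locus are NaN.
    """
    g1 = np.atleast_2d(np.asarray(g1, dtype=np.int8))
    g2 = np.atleast_2d(np.asarray(g2, dtype=np.int8))
    p = np.asarray(freq_a, dtype=float)
    num, den = _pair_tables(p)
    poly = (p > 0.0) & (p < 1.0)
    l_idx = np.arange(g1.shape[1])[None, :]
    valid = (g1 >= 0) & (g2 >= 0) & poly[None, :]
    r_x = _directional_r(g1, g2, num, den, valid, l_idx)
    r_y = _directional_r(g2, g1, num, den, valid, l_idx)
    # a direction with zero total weight (e.g. a lone heterozygous
    # reference at p = 0.5) is uninformative; use the other one
    both = np.stack([r_x, r_y])
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.where(
            np.isnan(both).all(axis=0), np.nan, np.nanmean(both, axis=0)
        )
    return r, valid.sum(axis=1)


def lynch_ritland_pair(
    gx: np.ndarray, gy: np.ndarray, freq_a: np.ndarray
) -> float:
    """Symmetrized estimate for a single pair of multilocus genotypes.

    Raises if the pair shares no usable locus.
    """
    r, n = pairwise_r(gx[None, :], gy[None, :], freq_a)
    if n[0] == 0:
        raise ValueError("no shared valid polymorphic loci for this pair")
    return float(r[0])


@dataclass
class RelatednessMatrix:
    ids: list[str]
    r: np.ndarray  # (n, n) symmetric, NaN diagonal / undefined pairs
    n_loci: np.ndarray  # loci used per pair

    def to_long(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(len(self.ids), k=1)
        return pd.DataFrame(dict(
            id1=[self.ids[i] for i in iu], id2=[self.ids[j] for j in ju],
            r=self.r[iu, ju], n_loci=self.n_loci[iu, ju],
        ))


def relatedness_matrix(
    calls: np.ndarray,
    ids: list[str],
    freq_a: np.ndarray,
    chunk: int = 20000,
) -> RelatednessMatrix:
    """All-pairs symmetric relatedness from autosomal calls.

    ``calls``: (n, L) coded autosomal genotypes. Allele frequencies are
    supplied by the caller (by default estimated once from all
    individuals, with no exclusion of the focal pair).
    """
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two individuals")
    R = np.full((n, n), np.nan)
    NL = np.zeros((n, n), dtype=int)
    iu, ju = np.triu_indices(n, k=1)
    for s in range(0, len(iu), chunk):
        i, j = iu[s : s + chunk], ju[s : s + chunk]
        r, nl = pairwise_r(calls[i], calls[j], freq_a)
        R[i, j] = R[j, i] = r
        NL[i, j] = NL[j, i] = nl
    return RelatednessMatrix(ids=list(ids), r=R, n_loci=NL)


def estimated_freq_a(calls: np.ndarray) -> np.ndarray:
    """Sample A-allele frequencies from coded genotypes (missing ignored)."""
    a = np.asarray(calls, dtype=float)
    a[a < 0] = np.nan
    return 1.0 - np.nanmean(a, axis=0) / 2.0


# ---------------------------------------------------------------------------
# pedigree relationship categories

PO, FS, HS, GG, MT = "PO", "FS", "HS", "GG", "MT"
CATEGORY_ORDER = [PO, FS, HS, GG, MT]


def categorize_pairs(
    parents: dict[str, tuple[str | None, str | None]],
    ids: list[str] | None = None,
) -> dict[tuple[str, str], str]:
    """Classify pairs by the closest pedigree relationship.

    ``parents`` maps each individual to its (mother, father), either of
    which may be None. Categories, in priority order: parent-offspring
    (direct edge), full siblings (both parents shared, both known), half
    siblings (exactly one shared parent), grandparent-grandchild (a
    directed two-step path, no direct edge), and mates (share at least
    one common offspring, no closer relation). Unrelated pairs are
    omitted from the result.
    """
    ids = list(parents) if ids is None else list(ids)
    par = {i: parents.get(i, (None, None)) for i in ids}
    children: dict[str, set[str]] = {}
    for o, (m, f) in par.items():
        for p in (m, f):
            if p is not None:
                children.setdefault(p, set()).add(o)
    out: dict[tuple[str, str], str] = {}
    for k, a in enumerate(ids):
        for b in ids[k + 1 :]:
            key = tuple(sorted((a, b)))  # canonical pair key
            ma, fa = par[a]
            mb, fb = par[b]
            if b in (ma, fa) or a in (mb, fb):
                out[key] = PO
                continue
            shared = sum(
                1 for pa, pb in ((ma, mb), (fa, fb)) if pa is not None and pa == pb
            )
            if shared == 2:
                out[key] = FS
                continue
            if shared == 1:
                out[key] = HS
                continue
            gp_a = {p for p in (ma, fa) if p is not None}
            gp_b = {p for p in (mb, fb) if p is not None}
            gpar_a = {q for p in gp_a for q in par.get(p, (None, None)) if q is not None}
            gpar_b = {q for p in gp_b for q in par.get(p, (None, None)) if q is not None}
            if a in gpar_b or b in gpar_a:
                out[key] = GG
                continue
            if children.get(a, set()) & children.get(b, set()):
                out[key] = MT
    return out


def category_summary(
    categories: dict[tuple[str, str], str], matrix: RelatednessMatrix
) -> pd.DataFrame:
    """Mean/SD/n of r per relationship category (Fig.-3-style table)."""
    pos = {iid: i for i, iid in enumerate(matrix.ids)}
    rows = []
    for cat in CATEGORY_ORDER:
        vals = [
            matrix.r[pos[a], pos[b]]
            for (a, b), c in categories.items()
            if c == cat and a in pos and b in pos
        ]
        vals = np.array([v for v in vals if np.isfinite(v)])
        if len(vals):
            rows.append(dict(category=cat, n=len(vals), mean_r=vals.mean(),
                             sd_r=vals.std(ddof=1) if len(vals) > 1 else np.nan))
    return pd.DataFrame(rows)
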