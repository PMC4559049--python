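"""Natal dispersal distances and sex-bias testing.

Natal dispersal is measured as the Euclidean distance between an
offspring's home-range center and its mother's. Offspring that are
still cubs accompanying their mother would contribute spurious zero
distances, so they are excluded by a three-part rule: a cub must have a
full sibling, the siblings must be at the same location (within a small
tolerance), and that location must be within a short distance of the
mother. The female/male distance distributions are compared with a
two-sided Wilcoxon rank-sum (Mann-Whitney) test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .parentage import Pedigree
from .spatial import euclidean_km


def _full_siblings(ped: Pedigree, iid: str) -> list[str]:
    m, f = ped.mother_of(iid), ped.father_of(iid)
    if m is None or f is None:
        return []
    return [
        o for o in ped.graph.successors(m)
        if o != iid and ped.graph.edges[m, o]["role"] == "mother"
        and ped.father_of(o) == f
    ]


def identify_cubs(
    ped: Pedigree,
    centers: dict[str, np.ndarray],
    delta_sib_km: float = 1.0,
    delta_mother_km: float = 1.0,
) -> set[str]:
    """Offspring flagged as pre-dispersal cubs.

    An offspring is a cub iff it has at least one full sibling such
    that the two sibling centers lie within ``delta_sib_km`` of each
    other and each lies within ``delta_mother_km`` of the mother's
    center. Offspring without a mother center are skipped with a
    warning.
    """
    cubs: set[str] = set()
    for iid in ped.graph.nodes:
        m = ped.mother_of(iid)
        if m is None:
            continue
        if m not in centers or iid not in centers:
            warnings.warn(f"missing center for mother-offspring pair ({m}, {iid})")
            continue
        if euclidean_km(centers[iid], centers[m]) > delta_mother_km:
            continue
        for sib in _full_siblings(ped, iid):
            if sib not in centers:
                continue
            if (euclidean_km(centers[iid], centers[sib]) <= delta_sib_km
                    and euclidean_km(centers[sib], centers[m]) <= delta_mother_km):
                cubs.add(iid)
                break
    return cubs


@dataclass
class DispersalRecord:
    offspring_id: str
    mother_id: str
    offspring_sex: str
    distance_km: float
    is_cub: bool


def natal_distances(
    ped: Pedigree,
    centers: dict[str, np.ndarray],
    sexes_by_id: dict[str, str],
    delta_sib_km: float = 1.0,
    delta_mother_km: float = 1.0,
) -> list[DispersalRecord]:
    """One record per offspring with an oriented mother link and both
    centers known; cubs are flagged (and excluded from summaries).
    Unoriented parent-offspring dyads contribute nothing."""
    cubs = identify_cubs(ped, centers, delta_sib_km, delta_mother_km)
    out = []
    for iid in sorted(ped.graph.nodes):
        m = ped.mother_of(iid)
        if m is None or m not in centers or iid not in centers:
            continue
        out.append(DispersalRecord(
            offspring_id=iid, mother_id=m,
            offspring_sex=sexes_by_id.get(iid, "U"),
            distance_km=euclidean_km(centers[iid], centers[m]),
            is_cub=iid in cubs,
        ))
    return out


def records_frame(records: list[DispersalRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def summarize_by_sex(records: list[DispersalRecord]) -> pd.DataFrame:
    """N / median / mean / SE / max of non-cub dispersal distances for
    all offspring, females and males. SE = sample SD (n-1) / sqrt(n),
    reported as NaN for singleton groups; empty groups are omitted with
    a warning."""
    kept = [r for r in records if not r.is_cub]
    rows = []
    for name, sel in (("all", kept),
                      ("F", [r for r in kept if r.offspring_sex == "F"]),
                      ("M", [r for r in kept if r.offspring_sex == "M"])):
        if not sel:
            warnings.warn(f"group {name!r} empty; omitted from summary")
            continue
        d = np.array([r.distance_km for r in sel])
        se = d.std(ddof=1) / np.sqrt(len(d)) if len(d) > 1 else np.nan
        rows.append(dict(group=name, n=len(d), median_km=float(np.median(d)),
                         mean_km=float(d.mean()), se_km=float(se),
                         max_km=float(d.max())))
    return pd.DataFrame(rows)


def rank_sum_test(
    distances_f: np.ndarray, distances_m: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (W, p) with W the first-sample U statistic (the convention
    R's wilcox.test prints). Exact p for small untied samples; normal
    approximation with tie and continuity corrections otherwise.
    """
    x = np.asarray(distances_f, dtype=float)
    y = np.asarray(distances_m, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(x), len(y)) <= 50
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)
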