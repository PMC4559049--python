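"""Home-range centers, pairwise distances, and isolation-by-distance
(Mantel/Pearson) tests.

Home-range centers are coordinate-wise medians of an individual's fecal
sample sites - robust to temporary excursions outside the range - and
distances are planar Euclidean (projected coordinates). Isolation by
distance is tested as the Mantel permutation correlation between the
distance and relatedness matrices; for opposite-sex pairs the matrix is
rectangular (asymmetric), so only a plain Pearson correlation applies.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform


def median_center(points: np.ndarray) -> np.ndarray:
    """Coordinate-wise median of sample locations; a single point is
    returned unchanged."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("median_center of an empty point set")
    return np.median(pts, axis=0)


def euclidean_km(a_xy: np.ndarray, b_xy: np.ndarray, units: str = "km") -> float:
    """Planar Euclidean distance in kilometers (inputs in km or m)."""
    d = math.dist(tuple(np.asarray(a_xy, float)), tuple(np.asarray(b_xy, float)))
    if units == "m":
        d /= 1000.0
    elif units != "km":
        raise ValueError("units must be 'km' or 'm'")
    return d


def centers_from_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Median center per individual from a sample table with columns
    individual_id, x_km, y_km."""
    rows = []
    for iid, grp in samples.groupby("individual_id", sort=False):
        c = median_center(grp[["x_km", "y_km"]].to_numpy())
        rows.append(dict(individual_id=iid, x_km=c[0], y_km=c[1], n_points=len(grp)))
    return pd.DataFrame(rows)


def distance_matrix_km(centers: np.ndarray) -> np.ndarray:
    """Symmetric pairwise Euclidean distances between center rows (km)."""
    return squareform(pdist(np.asarray(centers, dtype=float)))


def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_test(
    D: np.ndarray,
    R: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    alternative: str = "auto",
    method: str = "permutation",
) -> tuple[float, float]:
    """Mantel test between two symmetric matrices.

    The statistic is the Pearson correlation of the upper off-diagonal
    entries; the null is built by jointly permuting the rows and columns
    of ``R``. ``alternative`` is ``greater``, ``less``, ``two-sided`` or
    ``auto`` (one-sided in the direction of the observed sign).
    ``method='exact'`` enumerates every permutation (small n only) and
    returns the exact permutation p-value; otherwise
    p = (1 + #{permuted stat at least as extreme}) / (n_perm + 1).
    """
    D = np.asarray(D, dtype=float)
    R = np.asarray(R, dtype=float)
    n = D.shape[0]
    if D.shape != R.shape or D.shape != (n, n) or n < 3:
        raise ValueError("D and R must be square matrices of equal order >= 3")
    if not (np.allclose(D, D.T) and np.allclose(R, R.T)):
        raise ValueError("D and R must be symmetric")
    x = _offdiag(D)
    if np.ptp(x) == 0 or np.ptp(_offdiag(R)) == 0:
        raise ValueError("correlation undefined for a constant matrix")

    def corr_with(perm: np.ndarray) -> float:
        y = _offdiag(R[np.ix_(perm, perm)])
        return float(np.corrcoef(x, y)[0, 1])

    obs = corr_with(np.arange(n))
    if alternative == "auto":
        alternative = "greater" if obs >= 0 else "less"
    eps = 1e-12

    def extreme(s: float) -> bool:
        if alternative == "greater":
            return s >= obs - eps
        if alternative == "less":
            return s <= obs + eps
        if alternative == "two-sided":
            return abs(s) >= abs(obs) - eps
        raise ValueError(f"unknown alternative {alternative!r}")

    if method == "exact":
        if n > 8:
            raise ValueError("exact enumeration is limited to n <= 8")
        perms = list(itertools.permutations(range(n)))
        hits = sum(extreme(corr_with(np.array(p))) for p in perms)
        return obs, hits / len(perms)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    hits = sum(
        extreme(corr_with(rng.permutation(n))) for _ in range(n_perm)
    )
    return obs, (1 + hits) / (n_perm + 1)


@dataclass
class IBDResult:
    stratum: str
    n_individuals: int
    n_pairs: int
    pearson_r: float
    pearson_p: float
    mantel_r: float | None = None
    mantel_p: float | None = None


def _drop_nan_individuals(D: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Indices to keep so that R has no NaN off-diagonal entries
    (listwise deletion of the worst offenders)."""
    keep = np.arange(D.shape[0])
    Rw = R.copy()
    np.fill_diagonal(Rw, 0.0)
    while np.isnan(Rw).any():
        worst = np.argmax(np.isnan(Rw).sum(axis=0))
        sel = np.ones(Rw.shape[0], dtype=bool)
        sel[worst] = False
        Rw = Rw[np.ix_(sel, sel)]
        keep = keep[sel]
    return keep


def ibd_by_sex(
    D: np.ndarray,
    R: np.ndarray,
    sexes: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> list[IBDResult]:
    """Isolation-by-distance tests over a set of individuals (typically
    the putative parents): Mantel + Pearson for all pairs, female-female
    and male-male pairs, and Pearson only for opposite-sex pairs.
    Strata with fewer than three individuals are skipped with a warning.
    """
    sexes = np.asarray(sexes, dtype=object)
    out: list[IBDResult] = []
    strata = {
        "all": np.arange(len(sexes)),
        "female_female": np.flatnonzero(sexes == "F"),
        "male_male": np.flatnonzero(sexes == "M"),
    }
    for name, idx in strata.items():
        if len(idx) < 3:
            warnings.warn(f"stratum {name!r} has <3 individuals; skipped")
            continue
        Ds, Rs = D[np.ix_(idx, idx)].copy(), R[np.ix_(idx, idx)].copy()
        np.fill_diagonal(Ds, 0.0)  # diagonals never enter the statistic
        np.fill_diagonal(Rs, 0.0)
        keep = _drop_nan_individuals(Ds, Rs)
        Ds, Rs = Ds[np.ix_(keep, keep)], Rs[np.ix_(keep, keep)]
        if len(keep) < 3:
            warnings.warn(f"stratum {name!r} has <3 usable individuals; skipped")
            continue
        mr, mp = mantel_test(Ds, Rs, n_perm=n_perm, seed=seed)
        pr, pp = stats.pearsonr(_offdiag(Ds), _offdiag(Rs))
        out.append(IBDResult(name, len(keep), len(keep) * (len(keep) - 1) // 2,
                             float(pr), float(pp), mr, mp))
    f = np.flatnonzero(sexes == "F")
    m = np.flatnonzero(sexes == "M")
    if len(f) >= 2 and len(m) >= 2:
        d = D[np.ix_(f, m)].ravel()
        r = R[np.ix_(f, m)].ravel()
        ok = np.isfinite(d) & np.isfinite(r)
        pr, pp = stats.pearsonr(d[ok], r[ok])
        out.append(IBDResult("opposite_sex", len(f) + len(m), int(ok.sum()),
                             float(pr), float(pp)))
    return out
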