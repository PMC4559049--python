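"""Replicate consolidation, error-rate estimation, sex calling and panel
summary statistics for noninvasive SNP genotypes.

Noninvasive (fecal) genotyping yields several samples per individual;
replicate agreement is the only handle on the per-genotype error
process. Discordances at loci where at least one replicate is
heterozygous estimate the combined miscall rate, and the heterozygote ->
homozygote subset estimates allelic dropout under the one-allele-lost
model (the Broquet-Petit convention).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import (
    HET,
    HOM_A,
    HOM_B,
    INVALID,
    MISSING,
    Y_LINKED,
    MarkerPanel,
)


@dataclass
class GenotypeTable:
    """Per-sample biallelic calls with replicate groupings.

    ``calls`` is ``(n_samples, n_loci)`` int8 using the encoding in
    :mod:`snpdispersal.markers`. ``group_ids`` ties replicates of one
    individual together.
    """

    sample_ids: list[str]
    group_ids: list[str]
    calls: np.ndarray
    locus_ids: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError("calls shape does not match sample/locus ids")
        if len(self.group_ids) != len(self.sample_ids):
            raise ValueError("one group id per sample required")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def groups(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for i, g in enumerate(self.group_ids):
            out.setdefault(g, []).append(i)
        return {g: np.asarray(ix) for g, ix in out.items()}


@dataclass
class ConsolidationResult:
    individuals: GenotypeTable  # one row per retained replicate group
    n_samples: dict[str, int]
    contaminated: list[str]  # dropped groups (suspected mixtures)


def consolidate_replicates(
    table: GenotypeTable,
    panel: MarkerPanel,
    contamination_threshold: float = 0.2,
) -> ConsolidationResult:
    """Majority-vote consensus per individual.

    Per locus, the consensus is the strict majority among valid replicate
    calls; ties become missing. A group whose replicates disagree at more
    than ``contamination_threshold`` of pairwise-comparable autosomal
    genotypes is flagged as a probable mixture and dropped entirely.
    """
    groups = table.groups()
    if any(len(ix) == 0 for ix in groups.values()) or not groups:
        raise ValueError("empty replicate group")
    a_idx = panel.autosomal_idx
    keep_ids, rows, contaminated = [], [], []
    n_samples: dict[str, int] = {}
    for gid, ix in groups.items():
        sub = table.calls[ix]
        if len(ix) >= 2:
            mism, comp = 0, 0
            for i, j in itertools.combinations(range(len(ix)), 2):
                a, b = sub[i, a_idx], sub[j, a_idx]
                ok = (a >= 0) & (b >= 0)
                comp += int(ok.sum())
                mism += int((a[ok] != b[ok]).sum())
            if comp > 0 and mism / comp > contamination_threshold:
                contaminated.append(gid)
                continue
        cons = np.full(sub.shape[1], MISSING, dtype=np.int8)
        for l in range(sub.shape[1]):
            col = sub[:, l]
            valid = col[col >= 0]
            if len(valid) == 0:
                cons[l] = INVALID if (col == INVALID).any() else MISSING
                continue
            counts = np.bincount(valid, minlength=3)
            top = counts.max()
            winners = np.flatnonzero(counts == top)
            cons[l] = winners[0] if len(winners) == 1 else MISSING
        keep_ids.append(gid)
        rows.append(cons)
        n_samples[gid] = len(ix)
    individuals = GenotypeTable(
        sample_ids=keep_ids, group_ids=keep_ids,
        calls=np.array(rows, dtype=np.int8).reshape(len(rows), len(table.locus_ids)),
        locus_ids=table.locus_ids,
    )
    return ConsolidationResult(individuals, n_samples, contaminated)


@dataclass
class ErrorRates:
    mismatch_error_rate: float
    allelic_dropout_rate: float
    n_het_comparisons: int
    n_discordant: int


def estimate_error_rates(table: GenotypeTable, panel: MarkerPanel) -> ErrorRates:
    """Error rates from replicate concordance at diploid (non-Y, non-mt)
    loci.

    A comparison is a replicate pair at a locus where both calls are
    valid and at least one is heterozygous. The mismatch error rate is
    the fraction of those comparisons that disagree (for biallelic SNPs
    every such disagreement is a het/hom conflict); allelic dropout is
    the same count over twice the number of comparisons, since either of
    a heterozygote's two alleles could have dropped.
    """
    dip = np.concatenate([panel.autosomal_idx, panel.x_idx])
    n_het, n_disc = 0, 0
    any_group = False
    for gid, ix in table.groups().items():
        if len(ix) < 2:
            continue
        any_group = True
        sub = table.calls[ix][:, dip]
        for i, j in itertools.combinations(range(len(ix)), 2):
            a, b = sub[i], sub[j]
            ok = (a >= 0) & (b >= 0) & ((a == HET) | (b == HET))
            n_het += int(ok.sum())
            n_disc += int((a[ok] != b[ok]).sum())
    if not any_group or n_het == 0:
        raise ValueError("error rates undefined: no replicated heterozygote comparisons")
    return ErrorRates(
        mismatch_error_rate=n_disc / n_het,
        allelic_dropout_rate=n_disc / (2 * n_het),
        n_het_comparisons=n_het,
        n_discordant=n_disc,
    )


def determine_sex(y_calls: np.ndarray, x_calls: np.ndarray) -> str:
    """Y-presence sex call cross-checked against X zygosity.

    A sample with a call at every Y locus is male, provided no X locus
    is heterozygous; a sample missing at every Y locus is female (a
    heterozygous X confirms it). Anything else - partial Y signal, or a
    Y-positive sample with a heterozygous X - is 'U' (undetermined).
    """
    y = np.asarray(y_calls)
    x = np.asarray(x_calls)
    het_x = (x == HET).any()
    if (y >= 0).all():
        return "U" if het_x else "M"
    if (y == MISSING).all():
        return "F"
    return "U"


def call_sexes(individuals: GenotypeTable, panel: MarkerPanel) -> np.ndarray:
    yi, xi = panel.y_idx, panel.x_idx
    return np.array(
        [determine_sex(row[yi], row[xi]) for row in individuals.calls], dtype=object
    )


def assign_mt_haplotype(
    mt_calls: np.ndarray, haplotype_key: dict[str, tuple[int, ...]]
) -> str:
    """Exact-pattern match of the diagnostic mtDNA loci; any missing or
    off-key pattern is 'unassigned'."""
    pattern = tuple(int(c) for c in np.asarray(mt_calls))
    for label, key in haplotype_key.items():
        if pattern == tuple(key):
            return label
    return "unassigned"


def probability_of_identity(maf: np.ndarray) -> float:
    """Multilocus probability of identity under HWE and linkage
    equilibrium: product over loci of p^4 + 4 p^2 q^2 + q^4."""
    q = np.asarray(maf, dtype=float)
    p = 1.0 - q
    return float(np.prod(p**4 + 4 * p**2 * q**2 + q**4))


@dataclass
class PanelSummary:
    call_rate: float
    maf: np.ndarray  # per autosomal locus, estimated from the data
    pid: float


def panel_summaries(individuals: GenotypeTable, panel: MarkerPanel) -> PanelSummary:
    """Call rate over non-Y loci, autosomal MAFs estimated from the
    consolidated genotypes, and the panel's probability of identity."""
    if individuals.n_samples < 1:
        raise ValueError("need at least one individual")
    non_y = np.flatnonzero(panel.classes != Y_LINKED)
    sub = individuals.calls[:, non_y]
    call_rate = float((sub >= 0).sum() / sub.size)
    a = individuals.calls[:, panel.autosomal_idx].astype(float)
    a[a < 0] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq_b = np.nanmean(a, axis=0) / 2.0
    maf = np.minimum(freq_b, 1.0 - freq_b)
    ok = ~np.isnan(maf)
    return PanelSummary(call_rate=call_rate, maf=maf,
                        pid=probability_of_identity(maf[ok]))


def build_individuals(
    consolidation: ConsolidationResult, panel: MarkerPanel
) -> pd.DataFrame:
    """Individual table: id, called sex, mtDNA haplotype, sample count."""
    tab = consolidation.individuals
    sexes = call_sexes(tab, panel)
    haps = [
        assign_mt_haplotype(row[panel.mt_idx], panel.haplotype_key)
        for row in tab.calls
    ]
    return pd.DataFrame(dict(
        id=tab.group_ids, sex=sexes, mt_haplotype=haps,
        n_samples=[consolidation.n_samples[g] for g in tab.group_ids],
    ))
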