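"""Marker panel definitions and genotype encoding.

Biallelic genotypes are stored as small integers counting copies of the
B allele: 0 = A/A, 1 = A/B, 2 = B/B. Two sentinel codes distinguish a
failed call from an invalidated one:

* ``MISSING`` (-1): no call (e.g. amplification failure, or a Y locus in
  a female, where absence is itself informative).
* ``INVALID`` (-2): the call was made but judged unreliable (ambiguous
  genotyping cluster) and is excluded from every statistic.

A :class:`MarkerPanel` carries, per locus, its class (autosomal, X, Y or
mtDNA-diagnostic) and the population frequency of the A allele. By
convention the simulator makes B the minor allele, so the minor allele
frequency of locus *l* is ``1 - freq_a[l]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HOM_A = 0
HET = 1
HOM_B = 2
MISSING = -1
INVALID = -2

#: genotype call <-> CSV string coding
CALL_STRINGS = {HOM_A: "A/A", HET: "A/B", HOM_B: "B/B", MISSING: "./.", INVALID: "x/x"}
STRING_CALLS = {v: k for k, v in CALL_STRINGS.items()}

AUTOSOMAL = "autosomal"
X_LINKED = "X"
Y_LINKED = "Y"
MTDNA = "mtDNA"

#: Diagnostic four-locus mtDNA patterns for the three Scandinavian
#: matrilines. Haploid states are reported as homozygous calls.
DEFAULT_HAPLOTYPE_KEY: dict[str, tuple[int, int, int, int]] = {
    "south": (HOM_A, HOM_A, HOM_A, HOM_A),
    "middle": (HOM_B, HOM_B, HOM_A, HOM_A),
    "north": (HOM_B, HOM_B, HOM_B, HOM_B),
}


@dataclass
class MarkerPanel:
    """A typed SNP panel with population allele frequencies.

    Parameters
    ----------
    locus_ids:
        One identifier per locus.
    classes:
        Locus class, one of ``autosomal``/``X``/``Y``/``mtDNA`` per locus.
    freq_a:
        Population frequency of the A allele per locus. Y loci are
        presence/absence markers; their entry is ignored (set to NaN).
    """

    locus_ids: list[str]
    classes: np.ndarray
    freq_a: np.ndarray
    haplotype_key: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_HAPLOTYPE_KEY)
    )

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=object)
        self.freq_a = np.asarray(self.freq_a, dtype=float)
        if not (len(self.locus_ids) == len(self.classes) == len(self.freq_a)):
            raise ValueError("locus_ids, classes and freq_a must have equal length")
        bad = [
            (lid, f)
            for lid, c, f in zip(self.locus_ids, self.classes, self.freq_a)
            if c != Y_LINKED and not (0.0 < f < 1.0)
        ]
        if bad:
            raise ValueError(f"non-Y loci need a frequency in (0,1): {bad[:5]}")

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def _idx(self, cls: str) -> np.ndarray:
        return np.flatnonzero(self.classes == cls)

    @property
    def autosomal_idx(self) -> np.ndarray:
        return self._idx(AUTOSOMAL)

    @property
    def x_idx(self) -> np.ndarray:
        return self._idx(X_LINKED)

    @property
    def y_idx(self) -> np.ndarray:
        return self._idx(Y_LINKED)

    @property
    def mt_idx(self) -> np.ndarray:
        return self._idx(MTDNA)

    @property
    def autosomal_maf(self) -> np.ndarray:
        """Minor allele frequency of each autosomal locus (B allele)."""
        return 1.0 - self.freq_a[self.autosomal_idx]


def build_panel(
    autosomal_freq_a: np.ndarray,
    x_freq_a: np.ndarray | None = None,
    n_y: int = 2,
    n_mt: int = 4,
    haplotype_key: dict[str, tuple[int, ...]] | None = None,
) -> MarkerPanel:
    """Assemble a panel in the layout used throughout: autosomal loci
    first, then X, Y and mtDNA-diagnostic loci.

    Defaults mirror the 96-SNP brown-bear panel: 87 autosomal + 3 X +
    2 Y + 4 mtDNA markers.
    """
    autosomal_freq_a = np.asarray(autosomal_freq_a, dtype=float)
    if x_freq_a is None:
        x_freq_a = np.full(3, 0.63)
    x_freq_a = np.asarray(x_freq_a, dtype=float)
    key = dict(haplotype_key) if haplotype_key is not None else dict(DEFAULT_HAPLOTYPE_KEY)
    n_a, n_x = len(autosomal_freq_a), len(x_freq_a)
    locus_ids = (
        [f"snp{i:03d}" for i in range(1, n_a + 1)]
        + [f"xsnp{i}" for i in range(1, n_x + 1)]
        + [f"ysnp{i}" for i in range(1, n_y + 1)]
        + [f"mtsnp{i}" for i in range(1, n_mt + 1)]
    )
    classes = np.array(
        [AUTOSOMAL] * n_a + [X_LINKED] * n_x + [Y_LINKED] * n_y + [MTDNA] * n_mt,
        dtype=object,
    )
    # mtDNA loci get a nominal frequency (haplotype dominated by "south");
    # they never enter frequency-based statistics.
    freq_a = np.concatenate(
        [autosomal_freq_a, x_freq_a, np.full(n_y, np.nan), np.full(n_mt, 0.95)]
    )
    return MarkerPanel(locus_ids, classes, freq_a, key)
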