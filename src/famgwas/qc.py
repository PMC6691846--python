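"""Variant-level quality control and windowed LD pruning.

The QC cascade follows the fixed order used throughout the package:
minor-allele-frequency filter first, then call rate on the remainder,
then (optionally) completeness. The order matters — each report count is
conditional on the previous filter — and :class:`QCReport` records the
telescoping bookkeeping.

LD pruning mirrors the classic ``--indep-pairwise <window> <step> <r2>``
procedure: a sliding window of variants, within which one member of every
pair exceeding the r² cutoff is greedily removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .data import GenotypeMatrix

__all__ = [
    "QCReport",
    "minor_allele_frequency",
    "filter_variants",
    "ld_r2",
    "ld_prune",
]


@dataclass
class QCReport:
    """Telescoping counts of the variant QC cascade."""

    n_input: int
    n_removed_maf: int
    n_after_maf: int
    n_removed_callrate: int
    n_after_callrate: int
    n_with_missing: int
    n_complete: int
    maf_min: float
    callrate_min: float
    require_complete: bool

    def __post_init__(self) -> None:
        if self.n_input - self.n_removed_maf != self.n_after_maf:
            raise ValueError("QC counts do not telescope at the MAF step")
        if self.n_after_maf - self.n_removed_callrate != self.n_after_callrate:
            raise ValueError("QC counts do not telescope at the call-rate step")
        if self.n_with_missing + self.n_complete != self.n_after_callrate:
            raise ValueError("missing/complete split does not partition")

    def to_dict(self) -> dict:
        return asdict(self)


def minor_allele_frequency(dosage_column) -> float:
    """Folded alt-allele frequency over non-missing diploid calls.

    Returns min(f, 1 - f) where f is the alt-allele frequency, so the
    value always refers to the minor allele and lies in [0, 0.5].
    """
    col = np.asarray(dosage_column, dtype=float)
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise ValueError("all genotypes missing; MAF undefined")
    f = obs.sum() / (2 * obs.size)
    return float(min(f, 1.0 - f))


def _column_mafs(dosages: np.ndarray) -> np.ndarray:
    """Vectorized folded MAF per column (NaN-aware); all-missing -> NaN."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def filter_variants(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    callrate_min: float = 0.90,
    require_complete: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the MAF → call-rate → completeness cascade, in that order.

    Variants with folded MAF < ``maf_min`` are removed first; of the
    remainder, variants with call rate < ``callrate_min``; finally, when
    ``require_complete`` is set, any variant with at least one missing
    genotype. The report counts each stage on the surviving set only.
    """
    for name, thr in (("maf_min", maf_min), ("callrate_min", callrate_min)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {thr}")
    n_input = gm.n_variants
    if n_input == 0:
        report = QCReport(0, 0, 0, 0, 0, 0, 0, maf_min, callrate_min,
                          require_complete)
        return gm, report

    mafs = _column_mafs(gm.dosages)
    # an all-missing column has undefined MAF; treat as failing the MAF filter
    pass_maf = ~np.isnan(mafs) & (mafs >= maf_min)
    n_removed_maf = int((~pass_maf).sum())

    callrate = 1.0 - np.isnan(gm.dosages).mean(axis=0)
    pass_cr = pass_maf & (callrate >= callrate_min)
    n_removed_cr = int(pass_maf.sum() - pass_cr.sum())

    has_missing = np.isnan(gm.dosages).any(axis=0)
    n_with_missing = int((pass_cr & has_missing).sum())
    n_complete = int((pass_cr & ~has_missing).sum())

    keep = pass_cr & ~has_missing if require_complete else pass_cr
    out = GenotypeMatrix(
        gm.sample_ids, gm.variants.loc[keep], gm.dosages[:, keep]
    )
    report = QCReport(
        n_input=n_input,
        n_removed_maf=n_removed_maf,
        n_after_maf=int(pass_maf.sum()),
        n_removed_callrate=n_removed_cr,
        n_after_callrate=int(pass_cr.sum()),
        n_with_missing=n_with_missing,
        n_complete=n_complete,
        maf_min=maf_min,
        callrate_min=callrate_min,
        require_complete=require_complete,
    )
    return out, report


def ld_r2(col_a, col_b) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete samples.

    Composite (genotypic) LD — no phasing is assumed. A constant column
    among the complete pairs is degenerate; r² is defined as 0 with a
    warning.
    """
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        raise ValueError("need >= 2 pairwise-complete samples for r^2")
    a, b = a[ok], b[ok]
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        warnings.warn("constant dosage column among complete pairs; r^2 := 0")
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def ld_prune(
    gm: GenotypeMatrix,
    window_variants: int = 50,
    step_variants: int = 5,
    r2_max: float = 0.05,
) -> list[str]:
    """Windowed pairwise-r² pruning; returns the retained variant ids.

    Within each window of ``window_variants`` consecutive variants
    (advanced by ``step_variants``, per chromosome), while any retained
    pair has r² > ``r2_max`` one member is removed: the one with the lower
    MAF, ties going to the later genome position.
    """
    if window_variants < step_variants:
        raise ValueError("window must be >= step")
    if step_variants < 1:
        raise ValueError("step must be >= 1")
    keep = np.ones(gm.n_variants, dtype=bool)
    mafs = _column_mafs(gm.dosages)
    chroms = gm.variants["chrom"].to_numpy()

    for chrom in pd_unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while True:
            win = idx[start : start + window_variants]
            if win.size >= 2:
                _prune_window(gm.dosages, win, keep, mafs, r2_max)
            if start + window_variants >= idx.size:
                break
            start += step_variants
    return [vid for vid, k in zip(gm.variant_ids, keep) if k]


def _prune_window(dosages, win, keep, mafs, r2_max) -> None:
    """Greedy removal inside one window until no retained pair violates r2_max."""
    active = [i for i in win if keep[i]]
    changed = True
    while changed:
        changed = False
        for ai in range(len(active)):
            i = active[ai]
            if not keep[i]:
                continue
            for j in active[ai + 1 :]:
                if not keep[j]:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        r2 = ld_r2(dosages[:, i], dosages[:, j])
                    except ValueError:
                        continue
                if r2 > r2_max:
                    # drop lower MAF; tie -> later position (j is later)
                    drop = i if (mafs[i] < mafs[j]) else j
                    if mafs[i] == mafs[j]:
                        drop = j
                    keep[drop] = False
                    changed = True
                    if drop == i:
                        break
            # restart scan after any removal of i
        active = [i for i in active if keep[i]]


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Order-preserving unique (chromosomes in genome order)."""
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return np.array(list(seen))
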