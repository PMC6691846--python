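"""Single-SNP family-based association scan and its diagnostics.

Each variant is tested by a likelihood-ratio test between the family
random-intercept model with the variant as the sole genotype fixed effect
and the intercept-only null (both by maximum likelihood, df = 1). The
multiple-testing threshold divides alpha by the number of independent
SNPs, obtained from windowed LD pruning. Inflation of the p-value
distribution is summarized by the genomic-control factor lambda_GC and a
QQ table; nothing is corrected — inflation is reported, not removed.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix
from .lmm import FamilyLMM, lrt_pvalue

__all__ = [
    "significance_threshold",
    "scan",
    "qq_inflation",
    "manhattan_table",
]

#: Median of the chi-square(1) distribution, the null reference for lambda_GC.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


def significance_threshold(n_independent: int, alpha: float = 0.05):
    """Per-test threshold alpha / n_independent, raw and to one significant figure.

    The rounded value is what gets used for flagging (e.g. 0.05 / 497
    rounds to 1e-4).
    """
    if n_independent < 1:
        raise ValueError("n_independent must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    raw = alpha / n_independent
    rounded = float(f"{raw:.0e}")
    return raw, rounded


def scan(
    gm: GenotypeMatrix,
    phenotype,
    family_ids=None,
    threshold: float = 1e-4,
) -> pd.DataFrame:
    """Per-variant association scan under the family random-intercept model.

    With ``family_ids=None`` the scan degenerates to ordinary linear
    regression (no random effect) — useful to demonstrate the inflation
    that family structure induces when ignored.

    Returns a DataFrame with columns ``chrom, pos, id, p_value, beta,
    significant``; monomorphic variants are skipped with a warning.
    """
    y = np.asarray(phenotype, dtype=float).ravel()
    if y.size != gm.n_samples:
        raise ValueError("phenotype length does not match sample count")
    null = FamilyLMM(criterion="ml").fit(None, y, groups=family_ids)
    rows = []
    for j in range(gm.n_variants):
        col = gm.dosages[:, j]
        meta = gm.variants.iloc[j]
        if np.isnan(col).any():
            warnings.warn(
                f"variant {meta['id']} has missing genotypes; skipped "
                "(scan expects QC-passed complete variants)"
            )
            continue
        if np.all(col == col[0]):
            warnings.warn(f"monomorphic variant {meta['id']} skipped")
            continue
        full = FamilyLMM(criterion="ml").fit(col[:, None], y, groups=family_ids)
        p = lrt_pvalue(full, null)
        rows.append(
            {
                "chrom": meta["chrom"],
                "pos": int(meta["pos"]),
                "id": meta["id"],
                "p_value": p,
                "beta": float(full.beta_[1]),
                "significant": bool(p < threshold),
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "p_value", "beta", "significant"]
    )


def qq_inflation(p_values) -> tuple[float, pd.DataFrame]:
    """Genomic-control lambda and a plot-ready QQ table.

    lambda_GC is the median chi-square(1) statistic implied by the
    p-values divided by the null median 0.4549; the table pairs sorted
    observed -log10 p with uniform expected quantiles.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    m = p.size
    obs = -np.log10(np.sort(p))  # descending -log10 p, smallest p first
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    table = pd.DataFrame({"expected": expected, "observed": obs})
    return lam, table


def _is_scaffold(chrom: str) -> bool:
    return "scaffold" in str(chrom).lower()


def _chrom_sort_key(chrom: str):
    digits = "".join(ch for ch in str(chrom) if ch.isdigit())
    return (0, int(digits)) if digits else (1, str(chrom))


def manhattan_table(results: pd.DataFrame):
    """Cumulative genome coordinates for a Manhattan plot.

    Returns ``(main, scaffolds)``: placed chromosomes get a cumulative
    coordinate (each chromosome offset by the spans of those before it)
    and an alternating color index; variants on unplaced scaffolds are
    routed to the secondary table untouched.
    """
    cols = ["chrom", "pos", "id", "p_value", "neg_log10_p", "cum_pos",
            "color_index"]
    if len(results) == 0:
        return pd.DataFrame(columns=cols), pd.DataFrame(columns=cols[:5])
    df = results.copy()
    df["neg_log10_p"] = -np.log10(df["p_value"].clip(lower=1e-300))
    scaffold_mask = df["chrom"].map(_is_scaffold)
    scaff = df.loc[scaffold_mask, ["chrom", "pos", "id", "p_value",
                                   "neg_log10_p"]].reset_index(drop=True)
    main = df.loc[~scaffold_mask].copy()
    if len(main) == 0:
        return main.reindex(columns=cols), scaff
    chroms = sorted(main["chrom"].unique(), key=_chrom_sort_key)
    offset, offsets, color = 0, {}, {}
    for i, c in enumerate(chroms):
        offsets[c] = offset
        color[c] = i % 2
        offset += int(main.loc[main["chrom"] == c, "pos"].max())
    main["cum_pos"] = main["pos"] + main["chrom"].map(offsets)
    main["color_index"] = main["chrom"].map(color)
    main = main.sort_values(["cum_pos"]).reset_index(drop=True)
    return main.reindex(columns=cols), scaff
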