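"""Model choice by clustered leave-one-out cross-validation.

Every candidate model (a selector configuration: SES at some alpha and
conditioning-set size, or gOMP at some BIC stop threshold) is scored by
leave-one-out cross-validation that respects the family structure: the
held-out sample is predicted from the refit fixed effects *plus* the BLUP
of its family estimated on the training folds,

    err_ij = (y_ij - x_ij' beta[i,j] - blup_i[i,j])^2,

and both the mean (the textbook LOOCV estimate) and the median of the
per-sample squared errors are reported. The best model minimizes the
*median* squared error (ties broken toward fewer selected variants, then
grid order). By default the selector is re-run inside every training
fold, so the held-out sample never influences its own selection; a
fixed-signature mode (selection once on the full data) is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix
from .fs import GOMP, SES
from .lmm import FamilyLMM

__all__ = ["ModelConfig", "CVReport", "default_grid", "loocv_errors",
           "compare_models"]


@dataclass(frozen=True)
class ModelConfig:
    """One selector configuration in the comparison grid."""

    algorithm: str  # "ses" or "gomp"
    alpha: float | None = None
    max_k: int | None = None
    stop_delta: float | None = None

    @property
    def tag(self) -> str:
        if self.algorithm == "ses":
            return f"ses_a{self.alpha}_k{self.max_k}"
        return f"gomp_d{self.stop_delta}"


def default_grid() -> list[ModelConfig]:
    """The 10-model grid: 8 SES variants and 2 gOMP variants."""
    grid = [
        ModelConfig("ses", alpha=a, max_k=k)
        for a in (0.01, 0.05)
        for k in (2, 3, 4, 5)
    ]
    grid += [ModelConfig("gomp", stop_delta=d) for d in (2.0, 4.0)]
    return grid


@dataclass
class CVReport:
    """Per-model LOOCV summaries and the selected best model."""

    per_model: pd.DataFrame = field(default_factory=pd.DataFrame)
    errors: dict = field(default_factory=dict)  # tag -> per-sample sq. errors
    best_model: str = ""

    def median_error(self, tag: str) -> float:
        return float(np.median(self.errors[tag]))


def loocv_errors(
    selected_variants,
    gm: GenotypeMatrix,
    y,
    family_ids,
) -> np.ndarray:
    """Per-sample squared LOOCV errors for a fixed variant set.

    For every sample the mixed model is refit on the other n-1 samples
    with the selected variants as fixed effects; the held-out phenotype
    is predicted as fixed effects plus the training BLUP of its family
    (fixed effects alone when its family vanished from training, with a
    warning).
    """
    y = np.asarray(y, dtype=float).ravel()
    fam = np.asarray(family_ids)
    n = y.size
    if fam.size != n or gm.n_samples != n:
        raise ValueError("genotypes, phenotype and family labels must align")
    sel = list(selected_variants)
    X = (
        np.column_stack([gm.column(v) for v in sel])
        if sel
        else np.empty((n, 0))
    )
    if np.isnan(X).any():
        raise ValueError("selected variants contain missing genotypes")
    k_fam = len(np.unique(fam))
    if n < k_fam + len(sel) + 2:
        raise ValueError(
            f"n={n} too small for {k_fam} families and {len(sel)} variants"
        )
    errors = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fit = FamilyLMM(criterion="ml").fit(
            X[mask], y[mask], groups=fam[mask]
        )
        if str(fam[i]) not in fit.blups_:
            warnings.warn(
                f"family {fam[i]} absent from training fold {i}; "
                "prediction uses fixed effects only"
            )
        pred = fit.predict(X[i : i + 1], groups=fam[i : i + 1])[0]
        errors[i] = (y[i] - pred) ** 2
    return errors


def _select(config: ModelConfig, X, y, fam):
    if config.algorithm == "ses":
        model = SES(alpha=config.alpha, max_k=config.max_k).fit(
            X, y, groups=fam
        )
        return model.selected_
    if config.algorithm == "gomp":
        model = GOMP(stop_delta=config.stop_delta).fit(X, y)
        return model.selected_
    raise ValueError(f"unknown algorithm {config.algorithm!r}")


def compare_models(
    gm: GenotypeMatrix,
    y,
    family_ids,
    grid: list[ModelConfig] | None = None,
    fixed_signature: bool = False,
) -> CVReport:
    """Score every grid configuration by clustered LOOCV; pick the best.

    With ``fixed_signature`` the selector runs once on the full data and
    only the mixed model is refit per fold (cheaper, but the held-out
    sample influences selection); the default re-selects inside every
    fold. A selector failure on a fold falls back to the intercept-only
    model for that fold, with a warning.
    """
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ValueError("empty model grid")
    y = np.asarray(y, dtype=float).ravel()
    fam = np.asarray(family_ids)
    n = y.size
    D = gm.dosages
    if np.isnan(D).any():
        raise ValueError("model comparison expects complete genotypes")

    rows, errors = [], {}
    for config in grid:
        errs = np.empty(n)
        n_sel_folds = []
        if fixed_signature:
            fixed_sel = _select(config, D, y, fam)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            if fixed_signature:
                sel = fixed_sel
            else:
                try:
                    sel = _select(config, D[mask], y[mask], fam[mask])
                except Exception as exc:  # selector failure -> null model
                    warnings.warn(
                        f"{config.tag} failed on fold {i} ({exc}); "
                        "recording the null-model error"
                    )
                    sel = []
            # a selection larger than the training fold can refit is kept
            # only up to its leading (most informative) members
            cap = max(0, (n - 1) - len(np.unique(fam)) - 2)
            if len(sel) > cap:
                warnings.warn(
                    f"{config.tag} selected {len(sel)} variants on fold {i}; "
                    f"truncated to the first {cap} for the refit"
                )
                sel = list(sel)[:cap]
            n_sel_folds.append(len(sel))
            Xt = D[mask][:, sel] if sel else np.empty((n - 1, 0))
            fit = FamilyLMM(criterion="ml").fit(Xt, y[mask], groups=fam[mask])
            x_new = D[i : i + 1, sel] if sel else np.empty((1, 0))
            pred = fit.predict(x_new, groups=fam[i : i + 1])[0]
            errs[i] = (y[i] - pred) ** 2
        errors[config.tag] = errs
        rows.append(
            {
                "tag": config.tag,
                "algorithm": config.algorithm,
                "alpha": config.alpha,
                "max_k": config.max_k,
                "stop_delta": config.stop_delta,
                "median_sq_error": float(np.median(errs)),
                "mean_sq_error_loocv": float(np.mean(errs)),
                "mean_n_selected": float(np.mean(n_sel_folds)),
            }
        )
    per_model = pd.DataFrame(rows)
    order = np.lexsort(
        (
            np.arange(len(per_model)),
            per_model["mean_n_selected"].to_numpy(),
            per_model["median_sq_error"].to_numpy(),
        )
    )
    best = per_model.iloc[order[0]]["tag"]
    return CVReport(per_model=per_model, errors=errors, best_model=best)
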