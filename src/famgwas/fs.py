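"""Multi-SNP signature discovery: SES and generalized OMP.

Two complementary selectors:

* :class:`SES` (statistically equivalent signatures) — forward max–min
  constraint-based selection. Each candidate's association with the
  phenotype is summarized by the *maximum* p-value over conditional
  independence tests given subsets of the already-selected features; a
  candidate whose maximum exceeds ``alpha`` is discarded, and otherwise
  the candidate with the *minimum* such p-value is admitted next. The
  conditional test is a mixed-model likelihood-ratio test, so family
  structure is respected. Discarded candidates that are interchangeable
  with a selected feature (the symmetric swap test also fails to reject)
  are recorded in that feature's equivalence class, from which multiple
  statistically equivalent signatures can be enumerated.

* :class:`GOMP` (generalized orthogonal matching pursuit) — greedy linear
  selection: repeatedly admit the column most correlated with the current
  residuals, refit least squares on everything admitted, and stop when
  the BIC improvement between successive models drops below
  ``stop_delta`` BIC units.

Both are scikit-learn selector estimators (fit / get_support /
transform); :func:`ses` and :func:`gomp` are thin wrappers returning the
plain result records.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .data import GenotypeMatrix
from .lmm import FamilyLMM, lrt_pvalue

__all__ = ["Signature", "OMPTrace", "SES", "GOMP", "ci_test", "ses", "gomp",
           "expand_signatures"]


@dataclass
class Signature:
    """SES output: selected features plus interchangeable alternatives."""

    selected: list = field(default_factory=list)
    equivalence_classes: dict = field(default_factory=dict)
    alpha: float = 0.05
    max_k: int = 3

    @property
    def n_signatures(self) -> int:
        out = 1
        for s in self.selected:
            out *= len(self.equivalence_classes[s])
        return out


@dataclass
class OMPTrace:
    """gOMP output: ordered selections and the BIC path."""

    selected: list = field(default_factory=list)
    bic_path: list = field(default_factory=list)
    bic_start: float = float("nan")
    stop_delta: float = 2.0


# ----------------------------------------------------------------------
# conditional independence test
# ----------------------------------------------------------------------
def ci_test(y, candidate, cond_set=None, family_ids=None) -> float:
    """Mixed-model LRT p-value of ``candidate`` given ``cond_set``.

    Compares the family random-intercept model with fixed effects
    {cond_set, candidate} against {cond_set}. A candidate numerically
    collinear with the conditioning set (plus intercept) carries no
    additional information and returns p = 1.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty response")
    cand = np.asarray(candidate, dtype=float).ravel()
    if cand.size != y.size:
        raise ValueError("candidate length does not match y")
    if cond_set is None:
        Z = np.empty((y.size, 0))
    else:
        Z = np.asarray(cond_set, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    if _collinear(cand, Z):
        return 1.0
    null = FamilyLMM(criterion="ml").fit(Z, y, groups=family_ids)
    full = FamilyLMM(criterion="ml").fit(
        np.column_stack([Z, cand]), y, groups=family_ids
    )
    return lrt_pvalue(full, null)


def _collinear(cand: np.ndarray, Z: np.ndarray, tol: float = 1e-8) -> bool:
    design = np.column_stack([np.ones(cand.size), Z])
    coef, *_ = np.linalg.lstsq(design, cand, rcond=None)
    resid = cand - design @ coef
    return float(np.linalg.norm(resid)) <= tol * (np.linalg.norm(cand) + 1.0)


class _CachedTester:
    """ci_test with memoized null fits, shared across one SES run."""

    def __init__(self, X, y, family_ids):
        self.X = X
        self.y = y
        self.groups = family_ids
        self._nulls: dict = {}

    def _null(self, cond: tuple) -> FamilyLMM:
        key = tuple(sorted(cond))
        if key not in self._nulls:
            self._nulls[key] = FamilyLMM(criterion="ml").fit(
                self.X[:, list(key)], self.y, groups=self.groups
            )
        return self._nulls[key]

    def p_value(self, j: int, cond: tuple) -> float:
        Z = self.X[:, list(cond)]
        if _collinear(self.X[:, j], Z):
            return 1.0
        null = self._null(cond)
        full = FamilyLMM(criterion="ml").fit(
            np.column_stack([Z, self.X[:, j]]), self.y, groups=self.groups
        )
        return lrt_pvalue(full, null)


# ----------------------------------------------------------------------
# SES
# ----------------------------------------------------------------------
class SES(SelectorMixin, BaseEstimator):
    """Statistically equivalent signatures selector.

    Parameters
    ----------
    alpha : float in (0, 1)
        Significance threshold of the conditional independence tests.
    max_k : int >= 0
        Maximum conditioning-set size. ``max_k=0`` reduces the algorithm
        to marginal filtering.

    Attributes
    ----------
    selected_ : list of int — admitted feature indices, in order.
    equivalence_classes_ : dict int -> set of int, each containing its key.
    support_ : bool mask over features.
    """

    def __init__(self, alpha: float = 0.05, max_k: int = 3):
        self.alpha = alpha
        self.max_k = max_k

    def fit(self, X, y, groups=None):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.max_k < 0:
            raise ValueError("max_k must be >= 0")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.size != n:
            raise ValueError("X and y have different lengths")
        self.n_features_in_ = p
        tester = _CachedTester(X, y, groups)

        assoc = np.array([tester.p_value(j, ()) for j in range(p)])
        alive = assoc <= self.alpha
        selected: list[int] = []
        equiv: dict[int, set[int]] = {}

        while True:
            candidates = [j for j in range(p) if alive[j] and j not in selected]
            if not candidates:
                break
            best = min(candidates, key=lambda j: (assoc[j], j))
            selected.append(best)
            equiv[best] = {best}
            others = [j for j in candidates if j != best]
            prev = [s for s in selected if s != best]
            for j in others:
                for r in range(min(self.max_k, len(selected)) ):
                    stop = False
                    for comb in itertools.combinations(prev, r):
                        cond = (best, *comb)
                        if len(cond) > self.max_k:
                            continue
                        pj = tester.p_value(j, cond)
                        if pj > assoc[j]:
                            assoc[j] = pj
                        if assoc[j] > self.alpha:
                            alive[j] = False
                            # symmetric swap: is the admitted feature
                            # interchangeable with j given the rest?
                            swap_cond = tuple(c for c in cond if c != best) + (j,)
                            if tester.p_value(best, swap_cond) > self.alpha:
                                equiv[best].add(j)
                            stop = True
                            break
                    if stop:
                        break
                if self.max_k == 0:
                    break

        self.selected_ = selected
        self.equivalence_classes_ = equiv
        self.assoc_ = assoc
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[selected] = True
        return self

    def _get_support_mask(self):
        return self.support_


def ses(y, X, alpha: float = 0.05, max_k: int = 3, family_ids=None) -> Signature:
    """Run SES; accepts a :class:`GenotypeMatrix` or a plain dosage array.

    Returns a :class:`Signature` whose ids are variant ids when a
    genotype matrix is given, else column indices.
    """
    if isinstance(X, GenotypeMatrix):
        names = X.variant_ids
        mat = X.dosages
        if np.isnan(mat).any():
            raise ValueError("SES expects QC-passed complete genotypes")
    else:
        mat = np.asarray(X, dtype=float)
        names = list(range(mat.shape[1]))
    model = SES(alpha=alpha, max_k=max_k).fit(mat, y, groups=family_ids)
    sel = [names[j] for j in model.selected_]
    classes = {
        names[k]: {names[j] for j in v}
        for k, v in model.equivalence_classes_.items()
    }
    return Signature(sel, classes, alpha=alpha, max_k=max_k)


def expand_signatures(sig: Signature, limit: int = 100) -> list[set]:
    """Enumerate equivalent signatures by Cartesian substitution.

    Each selected feature may be replaced by any member of its
    equivalence class; enumeration is deterministic (selected member
    first, remaining members in sorted order) and truncated at ``limit``.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    pools = []
    for s in sig.selected:
        members = sig.equivalence_classes.get(s, {s})
        rest = sorted(m for m in members if m != s)
        pools.append([s, *rest])
    out = []
    for combo in itertools.product(*pools):
        out.append(set(combo))
        if len(out) >= limit:
            break
    return out or [set()]


# ----------------------------------------------------------------------
# gOMP
# ----------------------------------------------------------------------
class GOMP(SelectorMixin, BaseEstimator):
    """Generalized orthogonal matching pursuit with BIC-difference stopping.

    Columns are standardized internally and the response centered; the
    model is plain linear (no random effect). Set ``stop_delta`` in BIC
    units (2 or 4 are the conventional choices).
    """

    def __init__(self, stop_delta: float = 2.0):
        self.stop_delta = stop_delta

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.size != n:
            raise ValueError("X and y have different lengths")
        self.n_features_in_ = p
        yc = y - y.mean()
        tss = float(yc @ yc)
        self.support_ = np.zeros(p, dtype=bool)
        self.selected_ = []
        self.bic_path_ = []
        if tss == 0.0:
            self.bic_start_ = float("nan")
            return self
        sd = X.std(axis=0)
        Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        Xs[:, sd == 0] = 0.0

        def bic(rss: float, k: int) -> float:
            return n * np.log(max(rss, 1e-30) / n) + (k + 2) * np.log(n)

        bic_prev = bic(tss, 0)
        self.bic_start_ = bic_prev
        resid = yc.copy()
        selected: list[int] = []
        while len(selected) < min(n - 2, p):
            scores = np.abs(Xs.T @ resid)
            scores[selected] = -np.inf
            j = int(np.argmax(scores))
            if not np.isfinite(scores[j]) or scores[j] <= 0:
                break
            trial = selected + [j]
            coef, *_ = np.linalg.lstsq(Xs[:, trial], yc, rcond=None)
            new_resid = yc - Xs[:, trial] @ coef
            rss = float(new_resid @ new_resid)
            bic_new = bic(rss, len(trial))
            if bic_prev - bic_new <= self.stop_delta:
                break
            selected = trial
            resid = new_resid
            self.bic_path_.append(bic_new)
            bic_prev = bic_new
        self.selected_ = selected
        self.support_[selected] = True
        self._Xs = Xs
        self._resid = resid
        return self

    def _get_support_mask(self):
        return self.support_


def gomp(y, X, stop_delta: float = 2.0) -> OMPTrace:
    """Run gOMP; accepts a :class:`GenotypeMatrix` or a plain array."""
    if isinstance(X, GenotypeMatrix):
        names = X.variant_ids
        mat = X.dosages
    else:
        mat = np.asarray(X, dtype=float)
        names = list(range(mat.shape[1]))
    model = GOMP(stop_delta=stop_delta).fit(mat, y)
    return OMPTrace(
        selected=[names[j] for j in model.selected_],
        bic_path=list(model.bic_path_),
        bic_start=model.bic_start_,
        stop_delta=stop_delta,
    )
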