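"""Multiple matrix regression with randomization (MMRR).

Pairwise distance matrices are unfolded to lower-triangle vectors,
standardized (zero mean, unit variance) and regressed by ordinary least
squares; significance comes from permuting the response matrix's rows and
columns simultaneously — the exchangeable units are the populations, not
the pairs — and comparing |t| per coefficient (and F overall) against the
permutation distribution with the +1 correction, so the smallest
attainable p is 1 / (n_perm + 1).

`MMRR` is an sklearn-style estimator (fit, trailing-underscore
attributes, get_params/set_params); `mmrr` and `backward_select` are the
functional surface used by the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator

from .popgen import PairMatrix


def unfold(M: PairMatrix | np.ndarray) -> np.ndarray:
    """Lower-triangle vectorization, row-major with i > j.

    Order contract: (1,0), (2,0), (2,1), (3,0), ... — stable and shared by
    every matrix in one regression.
    """
    vals = M.values if isinstance(M, PairMatrix) else np.asarray(M, dtype=float)
    n = vals.shape[0]
    if vals.shape != (n, n) or n < 3:
        raise ValueError("need a square matrix with n >= 3")
    if not np.allclose(vals, vals.T, atol=1e-12):
        raise ValueError("matrix is not symmetric")
    return vals[np.tril_indices(n, k=-1)]


def refold(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of `unfold`: symmetric matrix with zero diagonal."""
    out = np.zeros((n, n))
    out[np.tril_indices(n, k=-1)] = vec
    return out + out.T


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("constant matrix cannot be standardized")
    return (v - v.mean()) / sd


@dataclass
class MMRRResult:
    """Coefficients, t statistics and permutation p-values of one MMRR fit."""

    predictors: list[str]
    coef: np.ndarray
    tstat: np.ndarray
    pvalues: np.ndarray
    intercept: float
    intercept_t: float
    intercept_p: float
    r_squared: float
    fstat: float
    f_pvalue: float
    n_permutations: int
    seed: int

    def coef_of(self, name: str) -> float:
        return float(self.coef[self.predictors.index(name)])

    def p_of(self, name: str) -> float:
        return float(self.pvalues[self.predictors.index(name)])


class MMRR(BaseEstimator):
    """Matrix regression of a response distance matrix on predictor matrices.

    Parameters
    ----------
    n_permutations : int
        Permutations of the response matrix for significance (default 999,
        giving an attainable p floor of 0.001).
    standardize : bool
        Standardize unfolded vectors before fitting, so coefficients are
        comparable across predictors.
    random_state : int
        Seed for the permutation stream.

    Attributes (after fit)
    ----------------------
    coef_, tstat_, pvalues_ : per-predictor arrays
    intercept_, intercept_t_, intercept_p_ : intercept statistics
    r_squared_, fstat_, f_pvalue_ : overall fit
    names_ : predictor names in coefficient order
    """

    def __init__(self, n_permutations: int = 999, standardize: bool = True,
                 random_state: int = 0):
        self.n_permutations = n_permutations
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X: Mapping[str, PairMatrix] | list, y: PairMatrix):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if isinstance(X, Mapping):
            names = list(X)
            mats = [X[k] for k in names]
        else:
            mats = list(X)
            names = [f"x{i}" for i in range(len(mats))]
        if not mats:
            raise ValueError("need at least one predictor matrix")
        for i, m in enumerate(mats):
            if isinstance(m, PairMatrix) and m.labels != y.labels:
                mats[i] = m.reorder(y.labels)
        n = y.n
        yv = unfold(y)
        Xcols = [unfold(m) for m in mats]
        if self.standardize:
            yv = _standardize(yv)
            Xcols = [_standardize(c) for c in Xcols]
        D = np.column_stack([np.ones(len(yv))] + Xcols)
        cond = np.linalg.cond(D)
        if cond > 1e10:
            worst = self._most_collinear(names, Xcols)
            raise ValueError(
                f"collinear predictors (condition number {cond:.3g}): {worst}"
            )
        XtX_inv = np.linalg.inv(D.T @ D)
        proj = XtX_inv @ D.T
        p = len(Xcols)

        def ols_stats(yvec):
            beta = proj @ yvec
            resid = yvec - D @ beta
            rss = resid @ resid
            dof = len(yvec) - p - 1
            sigma2 = rss / dof if dof > 0 else np.nan
            se = np.sqrt(sigma2 * np.diag(XtX_inv))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = beta / se
            tss = ((yvec - yvec.mean()) ** 2).sum()
            r2 = 1.0 - rss / tss if tss > 0 else np.nan
            f = (r2 / p) / ((1.0 - r2) / dof) if dof > 0 and r2 < 1 else np.inf
            return beta, t, r2, f

        beta, t, r2, f = ols_stats(yv)
        rng = np.random.default_rng(self.random_state)
        count_t = np.zeros(p + 1)
        count_f = 0
        yvals = y.values
        for _ in range(self.n_permutations):
            perm = rng.permutation(n)
            yp = unfold(yvals[np.ix_(perm, perm)])
            if self.standardize:
                yp = _standardize(yp)
            _, tp, _, fp = ols_stats(yp)
            count_t += np.abs(tp) >= np.abs(t)
            if fp >= f:
                count_f += 1
        pvals = (1.0 + count_t) / (self.n_permutations + 1.0)
        self.names_ = names
        self.coef_ = beta[1:]
        self.intercept_ = float(beta[0])
        self.tstat_ = t[1:]
        self.intercept_t_ = float(t[0])
        self.pvalues_ = pvals[1:]
        self.intercept_p_ = float(pvals[0])
        self.r_squared_ = float(r2)
        self.fstat_ = float(f)
        self.f_pvalue_ = (1.0 + count_f) / (self.n_permutations + 1.0)
        return self

    @staticmethod
    def _most_collinear(names, cols):
        worst, pair = -1.0, (names[0], names[0])
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                r = abs(np.corrcoef(cols[i], cols[j])[0, 1])
                if r > worst:
                    worst, pair = r, (names[i], names[j])
        return pair

    def result(self) -> MMRRResult:
        return MMRRResult(
            predictors=list(self.names_),
            coef=self.coef_.copy(),
            tstat=self.tstat_.copy(),
            pvalues=self.pvalues_.copy(),
            intercept=self.intercept_,
            intercept_t=self.intercept_t_,
            intercept_p=self.intercept_p_,
            r_squared=self.r_squared_,
            fstat=self.fstat_,
            f_pvalue=self.f_pvalue_,
            n_permutations=self.n_permutations,
            seed=self.random_state,
        )


def mmrr(
    Y: PairMatrix,
    X: Mapping[str, PairMatrix] | list,
    n_perm: int = 999,
    seed: int = 0,
    standardize: bool = True,
) -> MMRRResult:
    """Fit an MMRR and return its result record."""
    est = MMRR(n_permutations=n_perm, standardize=standardize, random_state=seed)
    est.fit(X, Y)
    return est.result()


@dataclass
class BackwardSelectionResult:
    """Final MMRR model plus the rejected terms with their re-test p-values."""

    final: MMRRResult | None
    retained: list[str]
    rejected: dict[str, float]
    intercept_only: bool


def backward_select(
    Y: PairMatrix,
    X: Mapping[str, PairMatrix],
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> BackwardSelectionResult:
    """Backward model selection with re-testing of excluded terms.

    Fit all predictors; while any is non-significant (p >= alpha) drop the
    one with the largest p and refit. Then re-test each excluded predictor
    by adding it singly to the retained set, re-admitting qualifiers
    (largest qualifying p first) and repeating both phases until stable.
    Rejected terms are reported with the p-value from their final re-test
    (or their p at elimination if the final model is empty).
    """
    if not X:
        raise ValueError("need at least one predictor")
    retained = list(X)
    rejected_p: dict[str, float] = {}
    seen: set[frozenset] = set()
    while True:
        # elimination phase
        while retained:
            res = mmrr(Y, {k: X[k] for k in retained}, n_perm=n_perm, seed=seed)
            worst = max(retained, key=res.p_of)
            if res.p_of(worst) < alpha:
                break
            rejected_p[worst] = res.p_of(worst)
            retained.remove(worst)
        state = frozenset(retained)
        if state in seen:
            break
        seen.add(state)
        # re-admission phase: test each excluded term singly on top of the
        # retained set
        excluded = [k for k in X if k not in retained]
        qualifiers = {}
        for name in excluded:
            res = mmrr(
                Y, {k: X[k] for k in retained + [name]}, n_perm=n_perm, seed=seed
            )
            p = res.p_of(name)
            rejected_p[name] = p
            if p < alpha:
                qualifiers[name] = p
        if not qualifiers:
            break
        readmit = max(qualifiers, key=qualifiers.get)
        retained.append(readmit)
        rejected_p.pop(readmit, None)
    if retained:
        final = mmrr(Y, {k: X[k] for k in retained}, n_perm=n_perm, seed=seed)
        return BackwardSelectionResult(final, retained, rejected_p, False)
    return BackwardSelectionResult(None, [], rejected_p, True)
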