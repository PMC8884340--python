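"""Statistical battery: mixed RM-ANOVA, planned contrasts with FDR
correction, varimax PCA with regression factor scores, and backward
stepwise regression.

The ANOVA reports both the univariate (subject-by-factor error term) and the
multivariate (difference-score Wilks) form for within-subject effects, since
the two differ in their error degrees of freedom; callers choose which to
quote.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

__all__ = [
    "bh_adjust",
    "mixed_anova",
    "paired_contrast",
    "independent_contrast",
    "planned_contrasts",
    "PcaResult",
    "pca_varimax",
    "RegressionResult",
    "backward_stepwise",
]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Mixed repeated-measures ANOVA


def _multivariate_within_tests(
    wide: np.ndarray, groups: np.ndarray
) -> list[dict]:
    """Wilks tests of the within effect and its group interaction on
    successive-difference scores (unweighted cell means)."""
    n, k = wide.shape
    levels = np.unique(groups)
    g = len(levels)
    # successive-difference transform
    C = np.zeros((k - 1, k))
    for i in range(k - 1):
        C[i, i], C[i, i + 1] = 1.0, -1.0
    D = wide @ C.T
    # cell-means design
    X = np.zeros((n, g))
    for j, lev in enumerate(levels):
        X[:, j] = (groups == lev).astype(float)
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ D
    E = D.T @ D - B.T @ (X.T @ D)
    df_e = n - g
    q = k - 1

    def wilks_test(L: np.ndarray, effect: str) -> dict:
        LB = L @ B
        M = L @ XtX_inv @ L.T
        H = LB.T @ np.linalg.inv(np.atleast_2d(M)) @ LB
        lam = np.linalg.det(E) / np.linalg.det(E + H)
        df2 = df_e - q + 1
        F = (1 - lam) / lam * df2 / q
        p = sps.f.sf(F, q, df2)
        return {
            "effect": effect,
            "approach": "multivariate",
            "F": F,
            "df1": q,
            "df2": df2,
            "p": p,
            "np2": 1 - lam,
        }

    grand = np.full((1, g), 1.0 / g)  # unweighted grand mean
    results = [wilks_test(grand, "within")]
    if g == 2:
        contrast = np.array([[1.0, -1.0]])
        results.append(wilks_test(contrast, "interaction"))
    else:
        # Helmert-style group contrasts; combined Wilks
        Lg = np.zeros((g - 1, g))
        for i in range(g - 1):
            Lg[i, i], Lg[i, i + 1] = 1.0, -1.0
        LB = Lg @ B
        M = Lg @ XtX_inv @ Lg.T
        H = LB.T @ np.linalg.inv(M) @ LB
        lam = np.linalg.det(E) / np.linalg.det(E + H)
        # Rao's F approximation
        pq = q * (g - 1)
        t = np.sqrt((q**2 * (g - 1) ** 2 - 4) / (q**2 + (g - 1) ** 2 - 5))
        w = df_e - (q - (g - 1) + 1) / 2.0
        df2 = w * t - pq / 2 + 1
        F = (1 - lam**(1 / t)) / lam**(1 / t) * df2 / pq
        results.append(
            {
                "effect": "interaction",
                "approach": "multivariate",
                "F": F,
                "df1": pq,
                "df2": df2,
                "p": sps.f.sf(F, pq, df2),
                "np2": 1 - lam,
            }
        )
    return results


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    subject: str = "participant_id",
) -> pd.DataFrame:
    """Two-way mixed ANOVA (one between-subject, one within-subject factor).

    Subjects with incomplete within-factor cells are dropped listwise.
    Returns a tidy frame with one row per effect × approach: the univariate
    rows carry partial eta squared from the standard mixed decomposition;
    within-factor effects additionally get multivariate (Wilks) rows.
    """
    for factor in (within, between):
        if data[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has fewer than 2 levels")

    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "listwise deletion of %d subject(s) with incomplete cells: %s",
            len(dropped),
            dropped,
        )
    keep = data[data[subject].isin(complete.index)]

    aov = pg.mixed_anova(
        data=keep, dv=dv, within=within, between=between, subject=subject
    )
    label = {between: "between", within: "within", "Interaction": "interaction"}
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    rows = [
        {
            "effect": label[r["Source"]],
            "approach": "univariate",
            "F": r["F"],
            "df1": r["DF1"],
            "df2": r["DF2"],
            "p": r[p_col],
            "np2": r["np2"],
        }
        for _, r in aov.iterrows()
    ]

    group_of = keep.groupby(subject)[between].first().loc[complete.index]
    rows.extend(
        _multivariate_within_tests(complete.to_numpy(), group_of.to_numpy())
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Planned contrasts


def paired_contrast(x: Sequence[float], y: Sequence[float]) -> dict:
    """Paired-samples t test with Cohen's d on the difference scores."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired contrast requires two equal-length vectors, n >= 2")
    diff = x - y
    t, p = sps.ttest_rel(x, y)
    sd = diff.std(ddof=1)
    d = 0.0 if sd == 0 else diff.mean() / sd
    if sd == 0:
        t, p = 0.0, 1.0
    return {"t": float(t), "df": x.size - 1, "p": float(p), "d": float(d)}


def independent_contrast(x: Sequence[float], y: Sequence[float]) -> dict:
    """Welch independent-samples t test; Cohen's d uses the pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("independent contrast requires n >= 2 per cell")
    t, p = sps.ttest_ind(x, y, equal_var=False)
    res = sps.ttest_ind(x, y, equal_var=False)
    nx, ny = x.size, y.size
    pooled = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    d = 0.0 if pooled == 0 else (x.mean() - y.mean()) / pooled
    return {"t": float(t), "df": float(res.df), "p": float(p), "d": float(d)}


def planned_contrasts(
    contrasts: Sequence[tuple[str, Sequence[float], Sequence[float], bool]],
) -> pd.DataFrame:
    """Run a declared family of contrasts with BH correction over the family.

    Each element is ``(label, x, y, paired)``.  Contrasts with too few
    observations are skipped (and logged), not silently filled.
    """
    import logging

    rows = []
    for label, x, y, paired in contrasts:
        try:
            res = paired_contrast(x, y) if paired else independent_contrast(x, y)
        except ValueError as exc:
            logging.getLogger(__name__).warning("skipping contrast %r: %s", label, exc)
            continue
        rows.append({"label": label, "paired": paired, **res})
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["p_adj"] = bh_adjust(frame["p"].to_numpy())
    return frame


# ---------------------------------------------------------------------------
# PCA with varimax rotation and regression factor scores


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    n_retained: int
    loadings: pd.DataFrame  # unrotated, retained components
    rotated_loadings: pd.DataFrame
    rotation_matrix: np.ndarray
    variance_explained: np.ndarray  # proportion per rotated component
    scores: pd.DataFrame  # regression-method factor scores
    loading_threshold: float

    @property
    def salient(self) -> pd.DataFrame:
        """Boolean mask of rotated loadings at or above the threshold."""
        return self.rotated_loadings.abs() >= self.loading_threshold


def _varimax(loadings: np.ndarray, normalize: bool = True, tol: float = 1e-10,
             max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Kaiser-normalized varimax; returns rotated loadings and the
    orthonormal rotation matrix."""
    L = loadings.copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    h = np.sqrt((L**2).sum(axis=1)) if normalize else np.ones(p)
    h[h == 0] = 1.0
    L = L / h[:, None]
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        LR = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (LR**3 - LR @ np.diag((LR**2).sum(axis=0)) / p)
        )
        R = u @ vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    rotated = (L @ R) * h[:, None]
    return rotated, R


def pca_varimax(
    data: pd.DataFrame,
    eigen_threshold: float = 1.0,
    loading_threshold: float = 0.6,
) -> PcaResult:
    """Correlation-matrix PCA, components retained at eigenvalue strictly
    above ``eigen_threshold``, varimax-rotated, with regression-method
    factor scores.
    """
    import logging

    constant = [c for c in data.columns if data[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    if data.shape[1] < 2:
        raise ValueError("PCA requires at least 2 variables")
    if data.shape[0] <= data.shape[1]:
        logging.getLogger(__name__).warning(
            "n (%d) <= number of variables (%d); solution may be unstable",
            data.shape[0],
            data.shape[1],
        )

    X = data.to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    # strictly above threshold; the epsilon keeps eigenvalues that are
    # exactly at the boundary (identity correlation) from sneaking in on
    # floating-point noise
    n_retained = int(np.sum(eigvals > eigen_threshold + 1e-9))
    if n_retained == 0:
        raise ValueError(
            f"no component with eigenvalue > {eigen_threshold}; nothing retained"
        )
    loadings = eigvecs[:, :n_retained] * np.sqrt(eigvals[:n_retained])
    # deterministic sign: largest-magnitude loading positive
    for j in range(n_retained):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] *= -1

    rotated, rotation = _varimax(loadings)
    for j in range(rotated.shape[1]):
        pivot = np.argmax(np.abs(rotated[:, j]))
        if rotated[pivot, j] < 0:
            rotated[:, j] *= -1
    # order rotated components by explained variance
    ssl = (rotated**2).sum(axis=0)
    comp_order = np.argsort(ssl)[::-1]
    rotated = rotated[:, comp_order]
    ssl = ssl[comp_order]

    variance_explained = ssl / data.shape[1]
    weights = np.linalg.solve(R, rotated)  # regression (Thurstone) weights
    scores = Z @ weights

    comp_names = [f"RC{j + 1}" for j in range(n_retained)]
    return PcaResult(
        eigenvalues=eigvals,
        n_retained=n_retained,
        loadings=pd.DataFrame(
            loadings, index=data.columns, columns=[f"PC{j + 1}" for j in range(n_retained)]
        ),
        rotated_loadings=pd.DataFrame(rotated, index=data.columns, columns=comp_names),
        rotation_matrix=rotation,
        variance_explained=variance_explained,
        scores=pd.DataFrame(scores, index=data.index, columns=comp_names),
        loading_threshold=loading_threshold,
    )


# ---------------------------------------------------------------------------
# Backward stepwise regression


@dataclass
class RegressionResult:
    retained: list[str]
    coefficients: pd.DataFrame  # B, SE, t, p, p_adj (intercept included)
    r_squared: float
    f_statistic: float
    model_p: float
    dropped: list[str] = field(default_factory=list)


def backward_stepwise(
    y: Sequence[float],
    predictors: pd.DataFrame,
    removal_alpha: float = 0.10,
) -> RegressionResult:
    """OLS with iterative removal of the least significant predictor.

    At each step the predictor with the largest coefficient p-value above
    ``removal_alpha`` is dropped; iteration stops when every remaining
    predictor clears the threshold (or none remain).  Perfectly collinear
    predictors are dropped up front.  Coefficient p-values of the final
    model (intercept included) are BH-adjusted.
    """
    import logging

    log = logging.getLogger(__name__)
    y = np.asarray(y, dtype=float)
    X = predictors.copy().astype(float)
    if len(y) != len(X):
        raise ValueError("y and predictors have different lengths")
    if len(y) <= X.shape[1]:
        log.warning(
            "n (%d) barely exceeds predictor count (%d); estimates unstable",
            len(y),
            X.shape[1],
        )

    dropped: list[str] = []
    # shed perfectly collinear columns
    while X.shape[1] > 0:
        mat = np.column_stack([np.ones(len(X)), X.to_numpy()])
        if np.linalg.matrix_rank(mat) == mat.shape[1]:
            break
        victim = X.columns[-1]
        log.warning("dropping collinear predictor %r", victim)
        dropped.append(victim)
        X = X.drop(columns=[victim])

    while True:
        model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
        pvals = model.pvalues.drop("const", errors="ignore")
        if pvals.empty:
            break
        worst = pvals.idxmax()
        if pvals[worst] <= removal_alpha:
            break
        dropped.append(worst)
        X = X.drop(columns=[worst])

    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    coef = pd.DataFrame(
        {
            "B": model.params,
            "SE": model.bse,
            "t": model.tvalues,
            "p": model.pvalues,
        }
    )
    coef["p_adj"] = bh_adjust(coef["p"].to_numpy())
    return RegressionResult(
        retained=list(X.columns),
        coefficients=coef,
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue) if X.shape[1] else float("nan"),
        model_p=float(model.f_pvalue) if X.shape[1] else float("nan"),
        dropped=dropped,
    )
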