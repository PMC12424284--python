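"""Statistical stages: varimax PCA, paired rest/task comparisons with FDR,
partial least squares correlation (PLSC), and the working-memory
efficiency score.

PLSC decomposes the cross-block correlation matrix R = X'Y/(n-1) of two
z-scored blocks by SVD. Each latent variable's effect size is the
proportion of cross-block covariance it explains (squared singular value
over the sum of squared singular values). Significance comes from a
permutation test on the rows of Y; salience reliability from a bootstrap
over subjects with Procrustes alignment of each replicate's saliences to
the original solution, flagging saliences whose percentile 95% CI
excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FEATURE_COLUMNS, BehaviorTrial, FeatureTable


# ---------------------------------------------------------------------------
# PCA with varimax rotation

@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    n_retained: int
    loadings: pd.DataFrame          # feature x rotated component
    explained_variance_pct: np.ndarray
    communalities: pd.Series
    unstable_retention: bool = False


def _varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Kaiser-normalized varimax rotation; returns the rotation matrix."""
    p, k = loadings.shape
    if k < 2:
        return np.eye(k)
    h = np.sqrt((loadings ** 2).sum(axis=1))
    h[h == 0] = 1.0
    A = loadings / h[:, None]
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        L = A @ R
        u, s, vt = np.linalg.svd(
            A.T @ (L ** 3 - L @ np.diag((L ** 2).sum(axis=0)) / p)
        )
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    return R


def pca_varimax(table: FeatureTable, eigenvalue_min: float = 1.0) -> PCAResult:
    """PCA of the feature correlation matrix with varimax rotation.

    Components are retained by the eigenvalue > 1 rule, rotated with
    Kaiser-normalized varimax, and sign-fixed so each component's
    largest-|loading| entry is positive. Communalities are invariant
    under the (orthogonal) rotation.
    """
    X = table.features.to_numpy(dtype=float)
    n, p = X.shape
    if n < p:
        raise ValueError(f"fewer rows ({n}) than features ({p})")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(FEATURE_COLUMNS, sd) if s == 0]
        raise ValueError(f"constant feature columns: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    corr = Z.T @ Z / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    retained = int(np.sum(eigval > eigenvalue_min))
    if retained == 0:
        raise ValueError("no component with eigenvalue above threshold")
    if n < 3 * retained:
        raise ValueError(f"need >= 3x more rows than retained components ({retained})")
    # flag knife-edge retention (all eigenvalues hovering at 1)
    unstable = bool(np.all(np.abs(eigval - 1.0) < 0.15))
    L = eigvec[:, :retained] * np.sqrt(eigval[:retained])
    R = _varimax(L)
    Lr = L @ R
    # order rotated components by explained variance, sign-fix
    ssq = (Lr ** 2).sum(axis=0)
    comp_order = np.argsort(ssq)[::-1]
    Lr = Lr[:, comp_order]
    for j in range(retained):
        if Lr[np.argmax(np.abs(Lr[:, j])), j] < 0:
            Lr[:, j] = -Lr[:, j]
    expl = (Lr ** 2).sum(axis=0) / p * 100.0
    comm = pd.Series((Lr ** 2).sum(axis=1), index=list(FEATURE_COLUMNS))
    loadings = pd.DataFrame(
        Lr, index=list(FEATURE_COLUMNS),
        columns=[f"PC{j + 1}" for j in range(retained)],
    )
    return PCAResult(
        eigenvalues=eigval, n_retained=retained, loadings=loadings,
        explained_variance_pct=expl, communalities=comm,
        unstable_retention=unstable,
    )


# ---------------------------------------------------------------------------
# paired comparisons with BH FDR

@dataclass
class PairedTestResult:
    feature: str
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    cohens_d: float


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_compare(rest: FeatureTable, task: FeatureTable) -> list[PairedTestResult]:
    """Two-sided paired t-tests per feature, diff = rest - task.

    With this sign convention a task increase gives a negative t.
    Cohen's d for paired designs is mean(diff)/SD(diff) = t/sqrt(n).
    BH adjustment runs across the 16 features.
    """
    r = rest.df.sort_values("subject")
    t_ = task.df.sort_values("subject")
    if list(r["subject"]) != list(t_["subject"]):
        raise ValueError("rest and task tables must contain the same subjects")
    n = len(r)
    if n < 3:
        raise ValueError("need at least 3 paired subjects")
    results = []
    p_raw = []
    for col in FEATURE_COLUMNS:
        diff = r[col].to_numpy(dtype=float) - t_[col].to_numpy(dtype=float)
        sd = diff.std(ddof=1)
        if sd == 0:
            if np.allclose(diff, 0):
                tstat, p = 0.0, 1.0
            else:
                raise ValueError(f"zero-variance non-zero differences for {col}")
        else:
            tstat, p = stats.ttest_rel(
                r[col].to_numpy(dtype=float), t_[col].to_numpy(dtype=float)
            )
        d = diff.mean() / sd if sd > 0 else 0.0
        results.append(PairedTestResult(col, float(tstat), n - 1, float(p), np.nan, float(d)))
        p_raw.append(float(p))
    p_adj = bh_adjust(np.asarray(p_raw))
    for res, pa in zip(results, p_adj):
        res.p_adjusted = float(pa)
    return results


# ---------------------------------------------------------------------------
# PLSC

@dataclass
class PLSCResult:
    singular_values: np.ndarray
    x_saliences: np.ndarray          # p x k
    y_saliences: np.ndarray          # q x k
    x_scores: np.ndarray             # n x k
    y_scores: np.ndarray             # n x k
    covexp: np.ndarray               # k
    perm_p: np.ndarray | None = None
    x_ci: np.ndarray | None = None   # p x k x 2
    y_ci: np.ndarray | None = None
    x_reliable: np.ndarray | None = None
    y_reliable: np.ndarray | None = None
    n_redrawn: int = 0


def _zscore(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column in PLSC block")
    return (M - M.mean(axis=0)) / sd


def plsc_fit(X: np.ndarray, Y: np.ndarray) -> PLSCResult:
    """SVD of the cross-block correlation matrix of two z-scored blocks.

    Saliences (unit-norm singular vectors) play the role of loadings;
    covexp_i = s_i^2 / sum_j s_j^2 is each latent variable's share of the
    cross-block covariance. Sign convention: the largest-|salience| entry
    of each X-salience column is positive (the Y column flips with it).
    """
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if n < 3:
        raise ValueError("need n >= 3")
    Zx, Zy = _zscore(X), _zscore(Y)
    R = Zx.T @ Zy / (n - 1)
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    k = min(X.shape[1], Y.shape[1])
    U, s, V = U[:, :k], s[:k], V[:, :k]
    for j in range(k):
        if U[np.argmax(np.abs(U[:, j])), j] < 0:
            U[:, j] = -U[:, j]
            V[:, j] = -V[:, j]
    ssq = s ** 2
    return PLSCResult(
        singular_values=s, x_saliences=U, y_saliences=V,
        x_scores=Zx @ U, y_scores=Zy @ V,
        covexp=ssq / ssq.sum(),
    )


def _singular_values(Zx: np.ndarray, Zy: np.ndarray, k: int) -> np.ndarray:
    s = np.linalg.svd(Zx.T @ Zy / (Zx.shape[0] - 1), compute_uv=False)
    return s[:k]


def plsc_permutation(
    X: np.ndarray, Y: np.ndarray, result: PLSCResult,
    n_perm: int = 1000, seed: int | None = None,
) -> np.ndarray:
    """Permutation p-values per latent variable.

    Rows of Y are permuted uniformly; each permuted decomposition's
    singular values are compared LV-by-LV against the observed ones,
    p_i = (1 + #{s_perm_i >= s_obs_i}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution is coarse")
    rng = np.random.default_rng(seed)
    Zx, Zy = _zscore(np.asarray(X, float)), _zscore(np.asarray(Y, float))
    k = result.singular_values.size
    obs = result.singular_values
    count = np.zeros(k, dtype=int)
    n = Zy.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s = _singular_values(Zx, Zy[perm], k)
        count += s >= obs
    p = (1 + count) / (n_perm + 1)
    result.perm_p = p
    return p


def plsc_bootstrap(
    X: np.ndarray, Y: np.ndarray, result: PLSCResult,
    n_boot: int = 1000, seed: int | None = None, ci: float = 95.0,
) -> PLSCResult:
    """Bootstrap percentile CIs and reliability flags for every salience.

    Subjects are resampled with replacement (X and Y rows jointly); each
    replicate's saliences are aligned to the original solution by an
    orthogonal Procrustes rotation of U (the same rotation applied to V)
    to prevent sign/axis flipping. A salience is reliable when its CI
    excludes zero. Degenerate resamples (constant column) are redrawn.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need n >= 10 for a subject bootstrap")
    rng = np.random.default_rng(seed)
    k = result.singular_values.size
    bx = np.empty((n_boot, X.shape[1], k))
    by = np.empty((n_boot, Y.shape[1], k))
    n_redrawn = 0
    for b in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            Xb, Yb = X[idx], Y[idx]
            if (Xb.std(axis=0) > 0).all() and (Yb.std(axis=0) > 0).all():
                break
            n_redrawn += 1
        else:
            raise ValueError("could not draw a non-degenerate bootstrap resample")
        fit = plsc_fit(Xb, Yb)
        # Procrustes-align replicate saliences to the original
        M = fit.x_saliences.T @ result.x_saliences
        W, _, Zt = np.linalg.svd(M)
        Rot = W @ Zt
        bx[b] = fit.x_saliences @ Rot
        by[b] = fit.y_saliences @ Rot
    lo, hi = (100 - ci) / 2, 100 - (100 - ci) / 2
    x_ci = np.stack(np.percentile(bx, [lo, hi], axis=0), axis=-1)
    y_ci = np.stack(np.percentile(by, [lo, hi], axis=0), axis=-1)
    result.x_ci, result.y_ci = x_ci, y_ci
    result.x_reliable = (x_ci[..., 0] > 0) | (x_ci[..., 1] < 0)
    result.y_reliable = (y_ci[..., 0] > 0) | (y_ci[..., 1] < 0)
    result.n_redrawn = n_redrawn
    return result


# ---------------------------------------------------------------------------
# working-memory efficiency

@dataclass
class EfficiencyRecord:
    subject: str
    load: int
    accuracy: float
    mean_rt: float
    efficiency: float


def wm_efficiency(
    trials: list[BehaviorTrial], rt_on_correct_only: bool = True
) -> list[EfficiencyRecord]:
    """Accuracy / mean RT per subject x load (speeds pooled).

    Mean RT is taken over correct trials by default (inverse-efficiency
    convention). A subject-load cell with zero accuracy scores an
    efficiency of 0.
    """
    if not trials:
        raise ValueError("no trials")
    cells: dict[tuple[str, int], list[BehaviorTrial]] = {}
    for tr in trials:
        cells.setdefault((tr.subject_id, tr.load), []).append(tr)
    records = []
    for (subj, load) in sorted(cells):
        ts = cells[(subj, load)]
        acc = float(np.mean([t.correct for t in ts]))
        pool = [t.rt for t in ts if t.correct] if rt_on_correct_only else [t.rt for t in ts]
        if acc == 0.0:
            records.append(EfficiencyRecord(subj, load, 0.0, float("nan"), 0.0))
            continue
        mean_rt = float(np.mean(pool))
        if mean_rt == 0:
            raise ValueError(f"zero mean RT for subject {subj} load {load}")
        records.append(EfficiencyRecord(subj, load, acc, mean_rt, acc / mean_rt))
    return records


def efficiency_block(records: list[EfficiencyRecord]) -> pd.DataFrame:
    """Wide subject x load efficiency matrix (columns eff_1back..eff_3back)."""
    df = pd.DataFrame([(r.subject, r.load, r.efficiency) for r in records],
                      columns=["subject", "load", "efficiency"])
    wide = df.pivot(index="subject", columns="load", values="efficiency")
    wide.columns = [f"eff_{c}back" for c in wide.columns]
    return wide
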