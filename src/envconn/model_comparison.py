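"""Structural versus structuro-functional regression of cognition.

Asks whether electrophysiological connectivity explains variance in a
cognitive score beyond two structural MRI damage markers (global lesion
load, normalized thalamic volume).  A purely structural OLS model is
compared with one augmented by selected mean-network connectivity values;
the functional features are first orthogonalized with respect to the
structural markers — a reparametrization that isolates their independent
contribution but leaves R² unchanged.

Because the larger model is biased toward higher R², the comparison is
nonparametric: null samples of R² are generated by jointly shuffling the
subject order of the orthogonalized feature block (structural markers and
score stay fixed), which preserves the features' internal correlation and,
in expectation, their orthogonality to the structural block.  The mean of
that null distribution is the adjusted structural R² — what the augmented
model would explain by chance alone — and the permutation p-value is the
fraction of null samples at or above the observed full-model R² (add-one
estimator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import StatsError, residualize


@dataclass
class ModelComparison:
    r2_structural: float
    r2_adjusted_null_mean: float
    r2_full: float
    p_perm: float
    n_perm: int
    n_features: int

    def report(self) -> dict:
        return {
            "r2_structural": self.r2_structural,
            "r2_structural_adjusted": self.r2_adjusted_null_mean,
            "r2_structuro_functional": self.r2_full,
            "p_perm": self.p_perm,
            "n_perm": self.n_perm,
            "n_features": self.n_features,
        }


def _design(n: int, *blocks: np.ndarray | None) -> np.ndarray:
    cols = [np.ones((n, 1))]
    for b in blocks:
        if b is not None and b.size:
            cols.append(np.asarray(b, float).reshape(n, -1))
    return np.hstack(cols)


def fit_r2(score: np.ndarray, block: np.ndarray | None) -> float:
    """Coefficient of determination of the OLS fit score ~ 1 + block.

    Invariant under any invertible linear reparametrization of the block.
    """
    y = np.asarray(score, float)
    n = y.size
    X = _design(n, block)
    if n <= X.shape[1]:
        raise StatsError("need more subjects than regressors")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StatsError("rank-deficient design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    return 1.0 - float((resid**2).sum()) / ss_tot


def orthogonalize_features(F: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Residualize every feature column on [intercept, structural markers].

    The returned block has zero sample covariance with each structural
    marker and with the intercept (column means are zero).
    """
    F = np.asarray(F, float)
    S = np.asarray(S, float)
    if F.ndim == 1:
        F = F[:, None]
    if S.ndim == 1:
        S = S[:, None]
    if np.linalg.matrix_rank(_design(S.shape[0], S)) < S.shape[1] + 1:
        raise StatsError("rank-deficient structural block")
    return residualize(F, S)


def compare_models(
    score: np.ndarray,
    S: np.ndarray,
    F: np.ndarray | None,
    n_perm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    orthogonalize: bool = True,
) -> ModelComparison:
    """Permutation comparison of score ~ S against score ~ S + F.

    ``S`` (n, 2 typically) are the structural markers, ``F`` (n, k) the
    functional features, orthogonalized internally unless already so.
    With an empty feature block the comparison is degenerate: identical
    R² and p = 1.
    """
    if n_perm < 100:
        raise StatsError("n_perm must be at least 100")
    y = np.asarray(score, float)
    S = np.asarray(S, float)
    if S.ndim == 1:
        S = S[:, None]
    n = y.size

    r2_structural = fit_r2(y, S)
    if F is None or np.size(F) == 0:
        return ModelComparison(r2_structural, r2_structural, r2_structural,
                               1.0, n_perm, 0)

    F = np.asarray(F, float)
    if F.ndim == 1:
        F = F[:, None]
    k = F.shape[1]
    if n <= S.shape[1] + k + 1:
        raise StatsError("more regressors than subjects allow")
    Fp = orthogonalize_features(F, S) if orthogonalize else F

    X0 = _design(n, S)  # intercept + structural
    r2_full = fit_r2(y, np.hstack([S, Fp]))

    # Null distribution: joint row shuffles of the orthogonalized features.
    # R² for each permuted design via batched normal equations; the
    # feature Gram block F'F is shuffle-invariant.
    if rng is None:
        rng = np.random.default_rng(seed)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    A = X0.T @ X0                      # (p0, p0)
    X0ty = X0.T @ y
    FtF = Fp.T @ Fp
    p0 = X0.shape[1]
    null_r2 = np.empty(n_perm)
    done = 0
    chunk = 2048
    while done < n_perm:
        m = min(chunk, n_perm - done)
        idx = np.stack([rng.permutation(n) for _ in range(m)])
        Fperm = Fp[idx]                            # (m, n, k)
        B = np.einsum("ni,mnk->mik", X0, Fperm)    # X0' F_perm
        d = np.einsum("mnk,n->mk", Fperm, y)       # F_perm' y
        M = np.empty((m, p0 + k, p0 + k))
        M[:, :p0, :p0] = A
        M[:, :p0, p0:] = B
        M[:, p0:, :p0] = np.transpose(B, (0, 2, 1))
        M[:, p0:, p0:] = FtF
        rhs = np.concatenate(
            [np.broadcast_to(X0ty, (m, p0)), d], axis=1
        )
        beta = np.linalg.solve(M, rhs[..., None])[..., 0]
        ss_model = np.einsum("mp,mp->m", beta, rhs) - n * y.mean() ** 2
        null_r2[done:done + m] = ss_model / ss_tot
        done += m

    p_perm = (1.0 + float(np.sum(null_r2 >= r2_full))) / (n_perm + 1.0)
    return ModelComparison(
        r2_structural=r2_structural,
        r2_adjusted_null_mean=float(null_r2.mean()),
        r2_full=r2_full,
        p_perm=p_perm,
        n_perm=n_perm,
        n_features=k,
    )
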