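"""Confound-regressed permutation statistics for connectome contrasts.

Implements the inference layer of the pipeline: Welch-t group contrasts and
score-regression beta coefficients over every (node, band) x (node, band)
entry, with per-entry confound regression (two power regressors plus
demographic/technical covariates), two-tailed maximum-statistic permutation
correction, behavioral score contrasts, and the mean-network vs nodewise
effect-size ratio.

Statistical conventions
-----------------------
* Welch's unequal-variance t with Welch-Satterthwaite degrees of freedom —
  chosen for unbalanced group sizes.
* Confounds are regressed out once, before permuting: shared confounds in
  a pooled label-independent fit that keeps group means, patients-only
  regressors within the patient group (see :func:`run_group_contrast` for
  the rationale); permutations then shuffle the residualized matrices
  rather than re-fitting the confound model inside every permutation.
* Permutation p-values use the add-one estimator (1 + #{null >= obs}) /
  (n_perm + 1), which never returns zero.
* The corrected threshold is the (1 - alpha/family)th percentile of the
  null distribution of the maximum absolute statistic, with linear
  interpolation of the empirical quantile.
* Binary confounds (sex, system, benzodiazepine) enter as 0/1 indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectome import MeanNetworkRSFC, MultiLayerRSFC
from .parcellation import ConnectomeDef
from .synthetic import BEHAVIORAL_SCORES

__all__ = [
    "AnalysisPlan", "StatMatrix", "PermutationResult",
    "residualize", "welch_t_stat", "behavioral_contrast",
    "stack_multilayer", "stack_mean_network", "entry_power_regressors",
    "residualize_entries", "welch_contrast_matrix", "score_beta_matrix",
    "beta_contrast_matrix", "max_stat_test", "effect_size_ratio",
]


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Analysis plan / Bonferroni families

@dataclass(frozen=True)
class AnalysisPlan:
    """The registered set of tests, from which Bonferroni families follow.

    The full study design: one group contrast, correlations with 10 scores
    in patients (EDSS, disease duration, 7 neuropsychological, BDI) and 8
    in controls, each run at both nodewise and mean-network level, giving a
    38-test rsFC family; the behavioral family covers the 7
    neuropsychological scores plus depression (8 tests).
    """

    n_contrasts: int = 1
    n_patient_scores: int = 10
    n_control_scores: int = 8
    levels: int = 2  # nodewise and mean-network

    @property
    def rsfc_family(self) -> int:
        return (self.n_contrasts + self.n_patient_scores
                + self.n_control_scores) * self.levels

    @property
    def behavioral_family(self) -> int:
        return len(BEHAVIORAL_SCORES)


# ---------------------------------------------------------------------------
# OLS residualization

def residualize(values: np.ndarray, regressors: np.ndarray | None,
                add_intercept: bool = True,
                keep_mean: bool = False) -> np.ndarray:
    """OLS residuals of ``values`` (n,) or (n, m) on ``regressors`` (n, k).

    An intercept is always included unless disabled, so residuals are
    centered and orthogonal to every regressor.  With ``keep_mean`` the
    fitted contribution of the *centered* regressors is subtracted, so the
    sample mean of the values survives untouched while within-sample
    confound variance is removed.  That is what a between-group contrast
    of within-group-residualized values requires: full residualization
    would center every group exactly and erase the group difference, while
    subtracting an uncentered fit would replace each group's mean by an
    extrapolation of its confound model to zero.  Raises on rank-deficient
    designs (e.g. a constant all-zero column next to the intercept).
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    cols = [] if regressors is None else [np.asarray(regressors, float).reshape(n, -1)]
    if add_intercept:
        cols.insert(0, np.ones((n, 1)))
    if not cols:
        return v.copy()
    X = np.hstack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StatsError("rank-deficient confound design")
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    if keep_mean and add_intercept and X.shape[1] > 1:
        Xc = X[:, 1:] - X[:, 1:].mean(axis=0)
        return v - Xc @ beta[1:]
    return v - X @ beta


# ---------------------------------------------------------------------------
# Welch statistic

def welch_t_stat(a: np.ndarray, b: np.ndarray, axis: int = 0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Welch's t and Welch-Satterthwaite degrees of freedom along ``axis``."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.shape[axis], b.shape[axis]
    if na < 2 or nb < 2:
        raise StatsError("need at least 2 observations per group")
    ma, mb = a.mean(axis=axis), b.mean(axis=axis)
    va, vb = a.var(axis=axis, ddof=1), b.var(axis=axis, ddof=1)
    sa, sb = va / na, vb / nb
    denom = np.sqrt(sa + sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    return t, df


def behavioral_contrast(
    table: pd.DataFrame,
    scores: tuple[str, ...] = BEHAVIORAL_SCORES,
    confounds: tuple[str, ...] = ("age", "sex", "education"),
    patient_extra: tuple[str, ...] = ("benzodiazepine",),
    alpha: float = 0.05,
    group_col: str = "group",
    groups: tuple[str, str] = ("patient", "control"),
) -> pd.DataFrame:
    """Welch-t contrast of behavioral scores between the two groups.

    Confounds are regressed out within each group beforehand (patients get
    the extra benzodiazepine indicator).  The Bonferroni family defaults to
    the number of scores tested (8 for the standard battery).
    """
    family = len(scores)
    rows = []
    for score in scores:
        resids = []
        for g, extra in zip(groups, (patient_extra, ())):
            sub = table[table[group_col] == g]
            y = sub[score].to_numpy(float)
            if np.isnan(y).any():
                raise StatsError(f"missing {score} values in group {g!r}")
            X = sub[list(confounds + extra)].to_numpy(float)
            resids.append(residualize(y, X, keep_mean=True))
        a, b = resids
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            raise StatsError(f"zero variance in both groups for {score!r}")
        t, df = welch_t_stat(a, b)
        p = 2 * sps.t.sf(abs(float(t)), float(df))
        rows.append(dict(score=score, t=float(t), df=float(df), p=p,
                         p_bonferroni=min(1.0, p * family),
                         significant=p * family < alpha, family_size=family))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stacking multi-layer / mean-network matrices across subjects

@dataclass
class EntrySet:
    """Flat list of unique defined matrix entries shared by all subjects.

    Each entry is a pair of flat (node- or network-major) indices (p, q)
    with p < q for off-diagonal blocks; ``meta`` carries human-readable
    labels per entry.
    """

    entries: list[tuple[int, int]]
    meta: pd.DataFrame
    level: str  # "nodewise" | "mean_network"


def stack_multilayer(mls: list[MultiLayerRSFC]) -> tuple[np.ndarray, EntrySet]:
    """Stack subjects' multi-layer matrices into (n_subjects, n_entries)."""
    conn = mls[0].conn
    defined = np.logical_and.reduce([m.defined for m in mls])
    iu, ju = np.where(np.triu(defined, k=1))
    entries = list(zip(iu.tolist(), ju.tolist()))
    vals = np.stack([m.values[iu, ju] for m in mls])
    meta = _entry_meta_nodewise(entries, conn)
    return vals, EntrySet(entries, meta, "nodewise")


def _entry_meta_nodewise(entries, conn: ConnectomeDef) -> pd.DataFrame:
    rows = []
    for p, q in entries:
        i, a = conn.unflatten(p)
        j, b = conn.unflatten(q)
        rows.append(dict(node_i=conn.nodes[i].label, band_a=conn.bands[a].name,
                         node_j=conn.nodes[j].label, band_b=conn.bands[b].name,
                         i=i, a=a, j=j, b=b))
    return pd.DataFrame(rows)


def stack_mean_network(mns: list[MeanNetworkRSFC]) -> tuple[np.ndarray, EntrySet]:
    """Stack mean-network matrices; includes within-network (diagonal-block)
    entries, i.e. p <= q over (network, band) flat indices, excluding
    same-network same-band duplicates below the diagonal."""
    first = mns[0]
    nets, nb = first.networks, first.conn.n_bands
    K = len(nets) * nb
    defined = np.logical_and.reduce(
        [np.isfinite(m.values) for m in mns]
    )
    iu, ju = np.where(np.triu(defined))
    entries = list(zip(iu.tolist(), ju.tolist()))
    vals = np.stack([m.values[iu, ju] for m in mns])
    rows = []
    for p, q in entries:
        u, a = divmod(p, nb)
        v, b = divmod(q, nb)
        rows.append(dict(network_u=nets[u], band_a=first.conn.bands[a].name,
                         network_v=nets[v], band_b=first.conn.bands[b].name,
                         u=u, a=a, v=v, b=b))
    return vals, EntrySet(entries, pd.DataFrame(rows), "mean_network")


# ---------------------------------------------------------------------------
# Entry-specific confounds

def entry_power_regressors(
    power: np.ndarray,
    entry_set: EntrySet,
) -> np.ndarray:
    """Per-entry power regressors, shape (n_entries, n_subjects, 2).

    ``power`` is (n_subjects, n_nodes_or_networks, n_bands).  For entry
    ((i, a), (j, b)) the regressors are subject powers at (i, a) and (j, b):
    each endpoint's power in its own entry band.
    """
    m = entry_set.meta
    if entry_set.level == "nodewise":
        pi = power[:, m["i"].to_numpy(), m["a"].to_numpy()]
        pj = power[:, m["j"].to_numpy(), m["b"].to_numpy()]
    else:
        pi = power[:, m["u"].to_numpy(), m["a"].to_numpy()]
        pj = power[:, m["v"].to_numpy(), m["b"].to_numpy()]
    return np.stack([pi.T, pj.T], axis=-1)


def residualize_entries(
    values: np.ndarray,
    base_confounds: np.ndarray | None,
    power_regressors: np.ndarray | None = None,
    keep_mean: bool = False,
) -> np.ndarray:
    """Residualize each entry's values on its own confound design.

    ``values`` is (n_subjects, n_entries); ``base_confounds`` (n_subjects,
    k) is shared by all entries; ``power_regressors`` (n_entries,
    n_subjects, 2) varies per entry.  Returns residuals of the same shape;
    ``keep_mean`` is forwarded to :func:`residualize`.
    """
    v = np.asarray(values, float)
    if power_regressors is None:
        return residualize(v, base_confounds, keep_mean=keep_mean)
    n, m = v.shape
    out = np.empty_like(v)
    base = (np.zeros((n, 0)) if base_confounds is None
            else np.asarray(base_confounds, float).reshape(n, -1))
    for e in range(m):
        X = np.hstack([base, power_regressors[e]])
        out[:, e] = residualize(v[:, e], X, keep_mean=keep_mean)
    return out


# ---------------------------------------------------------------------------
# Statistic matrices

@dataclass
class StatMatrix:
    """Per-entry statistic values aligned with an :class:`EntrySet`."""

    values: np.ndarray
    kind: str  # welch_t | beta | delta_beta
    entry_set: EntrySet | None = None
    df: np.ndarray | None = None


def welch_contrast_matrix(resid_a: np.ndarray, resid_b: np.ndarray,
                          entry_set: EntrySet | None = None) -> StatMatrix:
    """Entrywise Welch t between two groups of residualized values."""
    if resid_a.shape[0] < 3 or resid_b.shape[0] < 3:
        raise StatsError("need at least 3 subjects per group")
    t, df = welch_t_stat(resid_a, resid_b)
    return StatMatrix(t, "welch_t", entry_set, df=df)


def score_beta_matrix(resid_values: np.ndarray, resid_score: np.ndarray,
                      entry_set: EntrySet | None = None) -> StatMatrix:
    """Entrywise regression coefficient of the score.

    ``resid_values`` and ``resid_score`` have had the confounds regressed
    out; by Frisch-Waugh the simple slope of residualized values on the
    residualized score equals the score's coefficient in the joint multiple
    regression with all confounds.
    """
    s = np.asarray(resid_score, float)
    ss = float(s @ s)
    if ss == 0:
        raise StatsError("score has zero variance after residualization")
    beta = (s @ np.asarray(resid_values, float)) / ss
    return StatMatrix(beta, "beta", entry_set)


def beta_contrast_matrix(resid_a: np.ndarray, score_a: np.ndarray,
                         resid_b: np.ndarray, score_b: np.ndarray,
                         entry_set: EntrySet | None = None) -> StatMatrix:
    """Group difference of score-regression coefficients (A minus B)."""
    ba = score_beta_matrix(resid_a, score_a).values
    bb = score_beta_matrix(resid_b, score_b).values
    return StatMatrix(ba - bb, "delta_beta", entry_set)


# ---------------------------------------------------------------------------
# Maximum-statistic permutation test

@dataclass
class PermutationResult:
    observed: StatMatrix
    null_max: np.ndarray
    threshold: float
    supra: np.ndarray
    p_max: float
    n_perm: int
    alpha: float
    family_size: int

    @property
    def corrected_alpha(self) -> float:
        return self.alpha / self.family_size

    def report(self) -> dict:
        return {
            "statistic": self.observed.kind,
            "observed_max_abs": float(np.nanmax(np.abs(self.observed.values))),
            "p_max": self.p_max,
            "threshold": self.threshold,
            "n_supra": int(self.supra.sum()),
            "n_perm": self.n_perm,
            "alpha": self.alpha,
            "family_size": self.family_size,
        }


def _null_max_group_shuffle(values_a, values_b, stat: str, score_a, score_b,
                            n_perm, rng, chunk=256) -> np.ndarray:
    """Null |max| distribution by shuffling group labels.

    Pooled residualized values are re-split into pseudo-groups of the
    original sizes for every permutation; scores (for delta_beta) travel
    with their subject.
    """
    pooled = np.vstack([values_a, values_b])
    na = values_a.shape[0]
    n = pooled.shape[0]
    if stat == "delta_beta":
        pooled_score = np.concatenate([score_a, score_b])
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        idx = np.stack([rng.permutation(n) for _ in range(k)])
        pa = pooled[idx[:, :na]]          # (k, na, m)
        pb = pooled[idx[:, na:]]
        if stat == "welch_t":
            t, _ = welch_t_stat(pa, pb, axis=1)
        else:
            sa = pooled_score[idx[:, :na]]
            sb = pooled_score[idx[:, na:]]
            sa = sa - sa.mean(axis=1, keepdims=True)
            sb = sb - sb.mean(axis=1, keepdims=True)
            ca = pa - pa.mean(axis=1, keepdims=True)
            cb = pb - pb.mean(axis=1, keepdims=True)
            ba = np.einsum("kn,knm->km", sa, ca) / (sa**2).sum(axis=1)[:, None]
            bb = np.einsum("kn,knm->km", sb, cb) / (sb**2).sum(axis=1)[:, None]
            t = ba - bb
        out[done:done + k] = np.nanmax(np.abs(t), axis=-1)
        done += k
    return out


def _null_max_score_shuffle(values, score, n_perm, rng, chunk=512) -> np.ndarray:
    """Null |max| distribution by shuffling subject order against scores."""
    s = np.asarray(score, float)
    v = np.asarray(values, float)
    n = v.shape[0]
    out = np.empty(n_perm)
    done = 0
    ss = float(((s - s.mean())**2).sum())
    vc = v - v.mean(axis=0, keepdims=True)
    while done < n_perm:
        k = min(chunk, n_perm - done)
        idx = np.stack([rng.permutation(n) for _ in range(k)])
        sp = s[idx]
        sp = sp - sp.mean(axis=1, keepdims=True)
        beta = np.einsum("kn,nm->km", sp, vc) / ss
        out[done:done + k] = np.nanmax(np.abs(beta), axis=-1)
        done += k
    return out


def max_stat_test(
    observed: StatMatrix,
    *,
    values_a: np.ndarray | None = None,
    values_b: np.ndarray | None = None,
    values: np.ndarray | None = None,
    score: np.ndarray | None = None,
    score_a: np.ndarray | None = None,
    score_b: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    family_size: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Two-tailed maximum-statistic permutation correction.

    The permutation scheme follows the statistic: ``welch_t`` and
    ``delta_beta`` shuffle group labels over the pooled residualized
    matrices; ``beta`` shuffles subject order against the score.  The
    corrected threshold is the (1 - alpha/family_size)th percentile of the
    null distribution of the maximum absolute statistic over all entries;
    ``p_max`` is the add-one permutation p-value of the observed maximum.
    """
    if n_perm < 100:
        raise StatsError("n_perm must be at least 100")
    if rng is None:
        rng = np.random.default_rng(seed)
    kind = observed.kind
    if kind in ("welch_t", "delta_beta"):
        if values_a is None or values_b is None:
            raise StatsError(f"{kind} requires values_a and values_b")
        if kind == "delta_beta" and (score_a is None or score_b is None):
            raise StatsError("delta_beta requires score_a and score_b")
        null_max = _null_max_group_shuffle(values_a, values_b, kind,
                                           score_a, score_b, n_perm, rng)
    elif kind == "beta":
        if values is None or score is None:
            raise StatsError("beta requires values and score")
        null_max = _null_max_score_shuffle(values, score, n_perm, rng)
    else:
        raise StatsError(f"unknown statistic kind {kind!r}")

    corrected = alpha / family_size
    threshold = float(np.quantile(null_max, 1.0 - corrected,
                                  method="linear"))
    obs = np.abs(observed.values)
    obs_max = float(np.nanmax(obs))
    p_max = (1.0 + float(np.sum(null_max >= obs_max))) / (n_perm + 1.0)
    supra = np.where(np.isnan(obs), False, obs > threshold)
    return PermutationResult(
        observed=observed, null_max=null_max, threshold=threshold,
        supra=supra, p_max=p_max, n_perm=n_perm, alpha=alpha,
        family_size=family_size,
    )


# ---------------------------------------------------------------------------
# End-to-end group contrast

DEFAULT_CONFOUNDS = ("age", "sex", "education", "system")
DEFAULT_PATIENT_EXTRA = ("benzodiazepine",)


def run_group_contrast(
    signals: list,
    table: pd.DataFrame,
    conn: ConnectomeDef,
    level: str = "nodewise",
    n_perm: int = 1000,
    alpha: float = 0.05,
    family_size: int = 1,
    seed: int | None = None,
    confounds: tuple[str, ...] = DEFAULT_CONFOUNDS,
    patient_extra: tuple[str, ...] = DEFAULT_PATIENT_EXTRA,
    orthogonalize: bool = True,
    groups: tuple[str, str] = ("patient", "control"),
    scheme: str = "pooled",
) -> tuple[PermutationResult, EntrySet]:
    """Full confound-regressed Welch-t group contrast from raw signals.

    Builds each subject's multi-layer matrix (optionally aggregated to
    mean-network level), residualizes every entry on its power regressors
    plus the demographic/technical confounds, and runs the two-tailed
    maximum-statistic permutation test.  Subject order in ``signals`` must
    match the rows of ``table``.

    ``scheme`` selects the confound regression: ``"pooled"`` (default)
    fits one nuisance model across both groups — the patients-only
    benzodiazepine indicator is simply zero for controls — and keeps the
    group means; ``"within_group"`` fits each group separately.  The
    pooled scheme is the default because separate per-group fits leave
    group-specific confound-mean offsets in the retained means that the
    label permutation cannot reproduce, which breaks exchangeability and
    inflates the family-wise error rate at small sample sizes.
    """
    from .connectome import build_multilayer, mean_network

    mls = [build_multilayer(s, conn, orthogonalize=orthogonalize)
           for s in signals]
    if level == "nodewise":
        values, entry_set = stack_multilayer(mls)
        power = np.stack([m.power.values for m in mls])
    elif level == "mean_network":
        mns = [mean_network(m, conn) for m in mls]
        values, entry_set = stack_mean_network(mns)
        power = np.stack([m.network_power for m in mns])
    else:
        raise StatsError(f"unknown level {level!r}")

    preg = entry_power_regressors(power, entry_set)
    grp = table["group"].to_numpy()
    resid = {}
    if scheme == "pooled":
        # Shared confounds in one label-independent nuisance fit; the
        # patients-only regressors (benzodiazepine) are removed within the
        # patient group, where they actually vary.  Pooling a patients-only
        # indicator instead would absorb part of the group contrast itself
        # (it is collinear with the group label).
        base = table[list(confounds)].to_numpy(float)
        resid_all = residualize_entries(values, base, preg, keep_mean=True)
        for g in groups:
            resid[g] = resid_all[grp == g]
        if patient_extra:
            sel = grp == groups[0]
            extra = table.loc[sel, list(patient_extra)].to_numpy(float)
            resid[groups[0]] = residualize_entries(
                resid[groups[0]], extra, None, keep_mean=True)
    elif scheme == "within_group":
        for g, extra in zip(groups, (patient_extra, ())):
            sel = grp == g
            base = table.loc[sel, list(confounds + extra)].to_numpy(float)
            resid[g] = residualize_entries(values[sel], base, preg[:, sel, :],
                                           keep_mean=True)
    else:
        raise StatsError(f"unknown residualization scheme {scheme!r}")

    observed = welch_contrast_matrix(resid[groups[0]], resid[groups[1]],
                                     entry_set)
    result = max_stat_test(
        observed, values_a=resid[groups[0]], values_b=resid[groups[1]],
        n_perm=n_perm, alpha=alpha, family_size=family_size, seed=seed,
    )
    return result, entry_set


def empirical_fwer(
    n_cohorts: int = 200,
    seed: int = 0,
    n_nodes: int = 10,
    n_bands: int = 2,
    n_per_group: int = 20,
    duration: float = 60.0,
    sampling_rate: float = 250.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Family-wise false-positive rate of the group contrast under the null.

    Generates ``n_cohorts`` exchangeable two-group cohorts (one shared
    envelope-correlation model, no group effect), runs the full
    confound-regressed Welch-t maximum-statistic contrast on each, and
    reports the fraction of cohorts with any supra-threshold entry,
    together with its normal-approximation 95% binomial CI.
    """
    from .synthetic import CohortSpec, default_target_corr, generate_cohort, \
        toy_connectome

    conn = toy_connectome(n_nodes, n_bands)
    target = default_target_corr(conn)
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=(n_cohorts, 2))
    rejections = 0
    p_max = []
    for c in range(n_cohorts):
        spec = CohortSpec(conn=conn, n_group_a=n_per_group,
                          n_group_b=n_per_group, duration=duration,
                          sampling_rate=sampling_rate, target_corr=target,
                          seed=int(sub_seeds[c, 0]))
        signals, table, _ = generate_cohort(spec)
        result, _ = run_group_contrast(signals, table, conn, n_perm=n_perm,
                                       alpha=alpha, family_size=1,
                                       seed=int(sub_seeds[c, 1]))
        rejections += int(result.supra.any())
        p_max.append(result.p_max)
    rate = rejections / n_cohorts
    half = 1.96 * np.sqrt(max(rate * (1 - rate), 1e-12) / n_cohorts)
    return {
        "fwer": rate,
        "ci95": (max(0.0, rate - half), min(1.0, rate + half)),
        "n_cohorts": n_cohorts,
        "rejections": rejections,
        "p_max": p_max,
        "alpha": alpha,
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# Effect-size ratio (mean-network vs single connections)

def effect_size_ratio(
    network_values: np.ndarray,
    nodewise_values: np.ndarray,
    network_entry_set: EntrySet,
    nodewise_entry_set: EntrySet,
    conn: ConnectomeDef,
) -> np.ndarray:
    """Effect size (mean/SD over subjects) of each mean-network value,
    divided by the average effect size of its contributing connections.

    A ratio near 1 means averaging adds nothing (connections redundant);
    for k independent same-mean connections it approaches sqrt(k).
    """
    if network_values.shape[0] < 2:
        raise StatsError("need at least 2 subjects")

    def es(x: np.ndarray) -> np.ndarray:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise StatsError("zero standard deviation in effect-size ratio")
        return x.mean(axis=0) / sd

    es_net = es(network_values)
    es_conn = es(nodewise_values)

    nets = conn.networks
    node_net = np.array([nets.index(nd.network) for nd in conn.nodes])
    nm = nodewise_entry_set.meta
    conn_net_u = node_net[nm["i"].to_numpy()]
    conn_net_v = node_net[nm["j"].to_numpy()]
    conn_a = nm["a"].to_numpy()
    conn_b = nm["b"].to_numpy()

    ratios = np.full(len(network_entry_set.entries), np.nan)
    for e, row in network_entry_set.meta.iterrows():
        u, v, a, b = row["u"], row["v"], row["a"], row["b"]
        sel = (
            ((conn_net_u == u) & (conn_net_v == v) & (conn_a == a) & (conn_b == b))
            | ((conn_net_u == v) & (conn_net_v == u) & (conn_a == b) & (conn_b == a))
        )
        if u == v and a != b:
            sel |= ((conn_net_u == u) & (conn_net_v == v)
                    & (conn_a == b) & (conn_b == a))
        if not sel.any():
            continue
        ratios[e] = es_net[e] / np.mean(es_conn[sel])
    return ratios
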