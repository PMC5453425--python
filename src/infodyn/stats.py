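"""Significance machinery: surrogate tests, permutation ANOVA, linear mixed
models and restricted-permutation correlations.

All permutation p-values use the +1 correction
``p = (1 + #{null >= observed}) / (1 + n_perm)`` so they are never exactly
zero, and every procedure takes an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from infodyn.errors import ParameterError

__all__ = [
    "SurrogateResult",
    "AnovaResult",
    "surrogate_test",
    "binomial_aggregate",
    "perm_anova_2way",
    "aggregate_by_recording",
    "lmm_compare",
    "icc",
    "spearman_restricted_perm",
    "perm_ttest_ind",
]


@dataclass
class SurrogateResult:
    observed: float
    null_values: np.ndarray
    p: float
    n_surrogates: int

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values))


def surrogate_test(
    source_epochs,
    target_epochs,
    estimator,
    n_surrogates: int = 500,
    seed: int = 0,
) -> SurrogateResult:
    """Test an estimate against epoch-shuffled surrogates.

    ``estimator(source_epochs, target_epochs) -> float``.  Surrogates
    permute whole epochs of the *target* only, preserving all within-epoch
    structure while destroying the source-target pairing (and hence any
    information transfer).
    """
    src = np.atleast_2d(np.asarray(source_epochs, dtype=float))
    tgt = np.atleast_2d(np.asarray(target_epochs, dtype=float))
    if src.shape[0] < 2:
        raise ParameterError("surrogate test needs at least 2 epochs to permute")
    observed = float(estimator(src, tgt))
    rng = np.random.default_rng(seed)
    null = np.empty(n_surrogates)
    for i in range(n_surrogates):
        perm = rng.permutation(tgt.shape[0])
        null[i] = estimator(src, tgt[perm])
    p = (1 + int(np.sum(null >= observed))) / (1 + n_surrogates)
    return SurrogateResult(observed=observed, null_values=null, p=p, n_surrogates=n_surrogates)


def binomial_aggregate(n_significant: int, n_recordings: int, p0: float = 0.05) -> float:
    """One-sided binomial aggregation over recordings.

    Upper-tail probability of seeing at least ``n_significant`` individually
    significant recordings out of ``n_recordings`` when each is significant
    with probability ``p0`` under the null.
    """
    if not 0 <= n_significant <= n_recordings:
        raise ParameterError("n_significant must lie in [0, n_recordings]")
    return float(sstats.binom.sf(n_significant - 1, n_recordings, p0))


# ---------------------------------------------------------------------------
# two-factor permutation ANOVA


@dataclass
class AnovaResult:
    F_main_A: float
    F_main_B: float
    F_interaction: float
    p_main_A: float
    p_main_B: float
    p_interaction: float
    n_perm: int
    seed: int
    factor_names: tuple = ("A", "B")

    def as_dict(self) -> dict:
        return {
            "factor_A": self.factor_names[0],
            "factor_B": self.factor_names[1],
            "F_main_A": self.F_main_A,
            "F_main_B": self.F_main_B,
            "F_interaction": self.F_interaction,
            "p_main_A": self.p_main_A,
            "p_main_B": self.p_main_B,
            "p_interaction": self.p_interaction,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    out = np.zeros((codes.size, n_levels - 1))
    for lev in range(1, n_levels):
        out[codes == lev, lev - 1] = 1.0
    return out


def _rss(y: np.ndarray, design: np.ndarray) -> float:
    _, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if res.size:
        return float(res[0])
    fit = design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(np.sum((y - fit) ** 2))


def _anova_f(y, a, b, na, nb, which: str) -> float:
    """Type II F-ratio for one effect of an (unbalanced) two-way layout."""
    ones = np.ones((y.size, 1))
    da, db = _dummies(a, na), _dummies(b, nb)
    inter = (da[:, :, None] * db[:, None, :]).reshape(y.size, -1)
    full = np.hstack([ones, da, db, inter])
    df_err = y.size - na * nb
    rss_full = _rss(y, full)
    ms_err = rss_full / df_err
    if which == "A":
        num = (_rss(y, np.hstack([ones, db])) - _rss(y, np.hstack([ones, da, db]))) / (na - 1)
    elif which == "B":
        num = (_rss(y, np.hstack([ones, da])) - _rss(y, np.hstack([ones, da, db]))) / (nb - 1)
    else:
        num = (_rss(y, np.hstack([ones, da, db])) - rss_full) / ((na - 1) * (nb - 1))
    return num / ms_err


def perm_anova_2way(
    values,
    factor_a,
    factor_b,
    n_perm: int = 10000,
    seed: int = 0,
    factor_names: tuple = ("A", "B"),
) -> AnovaResult:
    """Two-factor permutation ANOVA.

    Main effects use restricted permutations (levels of the tested factor
    shuffled only within levels of the other factor, so the other effect is
    preserved); the interaction permutes both factors jointly, which is an
    approximative test.  F-ratios use classical Type II sums of squares.
    """
    y = np.asarray(values, dtype=float)
    a_labels, a = np.unique(factor_a, return_inverse=True)
    b_labels, b = np.unique(factor_b, return_inverse=True)
    na, nb = a_labels.size, b_labels.size
    if na < 2 or nb < 2:
        raise ParameterError("each factor needs at least 2 levels")
    for la in range(na):
        for lb in range(nb):
            if np.sum((a == la) & (b == lb)) < 2:
                raise ParameterError(
                    f"cell ({a_labels[la]}, {b_labels[lb]}) has fewer than 2 observations"
                )
    rng = np.random.default_rng(seed)
    f_obs = {w: _anova_f(y, a, b, na, nb, w) for w in ("A", "B", "I")}

    exceed = {"A": 0, "B": 0, "I": 0}
    for _ in range(n_perm):
        # main effect A: permute A within levels of B
        a_perm = a.copy()
        for lb in range(nb):
            idx = np.nonzero(b == lb)[0]
            a_perm[idx] = a[idx[rng.permutation(idx.size)]]
        assert np.array_equal(np.sort(a_perm), np.sort(a))
        if _anova_f(y, a_perm, b, na, nb, "A") >= f_obs["A"]:
            exceed["A"] += 1
        # main effect B: permute B within levels of A
        b_perm = b.copy()
        for la in range(na):
            idx = np.nonzero(a == la)[0]
            b_perm[idx] = b[idx[rng.permutation(idx.size)]]
        assert np.array_equal(np.sort(b_perm), np.sort(b))
        if _anova_f(y, a, b_perm, na, nb, "B") >= f_obs["B"]:
            exceed["B"] += 1
        # interaction: permute both factors jointly (free permutation)
        pi = rng.permutation(y.size)
        if _anova_f(y[pi], a, b, na, nb, "I") >= f_obs["I"]:
            exceed["I"] += 1

    def _p(w):
        return (1 + exceed[w]) / (1 + n_perm)

    return AnovaResult(
        F_main_A=f_obs["A"],
        F_main_B=f_obs["B"],
        F_interaction=f_obs["I"],
        p_main_A=_p("A"),
        p_main_B=_p("B"),
        p_interaction=_p("I"),
        n_perm=n_perm,
        seed=seed,
        factor_names=factor_names,
    )


def aggregate_by_recording(table: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Median estimate per recording (and condition/direction cell).

    Per-epoch estimates are skewed, so the median is used as the
    per-recording summary entering the permutation ANOVA.
    """
    group_cols = [
        c for c in ("session_id", "condition", "direction_or_site", "measure")
        if c in table.columns
    ]
    if "session_id" not in group_cols:
        raise ParameterError("table needs a session_id column")
    out = table.groupby(group_cols, as_index=False, sort=True)[value_col].median()
    return out


# ---------------------------------------------------------------------------
# linear mixed models


def _lmm_design(table: pd.DataFrame, condition_ref: str | None):
    conditions = sorted(table["condition"].unique())
    if condition_ref is None:
        condition_ref = conditions[0]
    others = [c for c in conditions if c != condition_ref]
    X = {}
    for c in others:
        X[f"cond[{c}]"] = (table["condition"] == c).astype(float).to_numpy()
    directions = sorted(table["direction_or_site"].unique())
    if len(directions) != 2:
        raise ParameterError("LMM expects exactly 2 direction/site levels")
    # +1 / -1 coding for direction
    d = np.where(table["direction_or_site"] == directions[0], 1.0, -1.0)
    return X, d, others, directions


def _fit_lmm(y, exog: np.ndarray, groups, names):
    from statsmodels.regression.mixed_linear_model import MixedLM

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, exog, groups=groups)
        res = model.fit(reml=False, maxiter=500)
    k = exog.shape[1] + 2  # fixed effects + intercept variance + residual variance
    n = y.size
    return {
        "llf": float(res.llf),
        "k": k,
        "bic": float(-2 * res.llf + k * np.log(n)),
        "deviance": float(-2 * res.llf),
        "result": res,
        "names": names,
    }


def lmm_compare(
    table: pd.DataFrame,
    value_col: str = "value",
    condition_ref: str | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio model comparison for the nested epoch design.

    Fits, by maximum likelihood with a per-recording random intercept:
    a null model (fm_0), condition-only (fm_a), direction-only (fm_d),
    additive (fm_ab) and interaction (fm_axb) models.  Main effects are
    tested against fm_0, the interaction against fm_ab; the likelihood
    ratio is referred to a chi-squared distribution with df equal to the
    parameter difference.  BIC = -2 log L + k log N.
    """
    y = table[value_col].to_numpy(dtype=float)
    groups = table["session_id"].to_numpy()
    X_cond, d, cond_names, dir_names = _lmm_design(table, condition_ref)
    ones = np.ones_like(y)
    cond_cols = [X_cond[k] for k in X_cond]
    inter_cols = [c * d for c in cond_cols]

    fits = {
        "fm_0": _fit_lmm(y, np.column_stack([ones]), groups, ["intercept"]),
        "fm_a": _fit_lmm(
            y, np.column_stack([ones, *cond_cols]), groups, ["intercept", *X_cond]
        ),
        "fm_d": _fit_lmm(
            y, np.column_stack([ones, d]), groups, ["intercept", "direction"]
        ),
        "fm_ab": _fit_lmm(
            y,
            np.column_stack([ones, *cond_cols, d]),
            groups,
            ["intercept", *X_cond, "direction"],
        ),
        "fm_axb": _fit_lmm(
            y,
            np.column_stack([ones, *cond_cols, d, *inter_cols]),
            groups,
            ["intercept", *X_cond, "direction", *(f"{k}:direction" for k in X_cond)],
        ),
    }

    rows = []
    for name, baseline in (("fm_a", "fm_0"), ("fm_d", "fm_0"), ("fm_axb", "fm_ab")):
        full, red = fits[name], fits[baseline]
        chi2 = 2 * (full["llf"] - red["llf"])
        df = full["k"] - red["k"]
        p = float(sstats.chi2.sf(max(chi2, 0.0), df))
        rows.append(
            {
                "model": name,
                "baseline": baseline,
                "llf": full["llf"],
                "bic": full["bic"],
                "bic_baseline": red["bic"],
                "deviance": full["deviance"],
                "chi2": chi2,
                "df": df,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def icc(table: pd.DataFrame, value_col: str = "value") -> float:
    """Intraclass correlation: intercept variance / total variance.

    From the ML fit of the random-intercept-only model; quantifies how
    strongly epochs within one recording are dependent.
    """
    counts = table.groupby("session_id")[value_col].count()
    if len(counts) < 2 or counts.min() < 2:
        raise ParameterError("ICC needs >= 2 recordings with >= 2 epochs each")
    y = table[value_col].to_numpy(dtype=float)
    groups = table["session_id"].to_numpy()
    fit = _fit_lmm(y, np.ones((y.size, 1)), groups, ["intercept"])["result"]
    var_re = float(np.asarray(fit.cov_re)[0, 0])
    var_resid = float(fit.scale)
    return var_re / (var_re + var_resid)


# ---------------------------------------------------------------------------
# restricted-permutation correlation and permutation t-test


def spearman_restricted_perm(
    x, y, recording_ids, n_perm: int = 1000, seed: int = 0
) -> tuple:
    """Spearman correlation with a within-recording permutation null.

    Permuting ``y`` only within recordings destroys the x-y pairing while
    preserving between-recording level differences, so purely
    between-recording (confounded) association does not reach significance.
    Two-sided p with the +1 correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ids = np.asarray(recording_ids)
    if x.size != y.size or x.size != ids.size:
        raise ParameterError("x, y and recording_ids must be aligned")
    if np.unique(ids).size < 2:
        raise ParameterError("need at least 2 recordings")
    rho = float(sstats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    groups = [np.nonzero(ids == g)[0] for g in np.unique(ids)]
    exceed = 0
    y_perm = y.copy()
    for _ in range(n_perm):
        for idx in groups:
            y_perm[idx] = y[idx[rng.permutation(idx.size)]]
        if abs(float(sstats.spearmanr(x, y_perm).statistic)) >= abs(rho):
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return rho, p


def perm_ttest_ind(a, b, n_perm: int = 10000, seed: int = 0) -> tuple:
    """Permutation independent-samples t-test (two-sided on |t|)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t_obs = float(sstats.ttest_ind(a, b).statistic)
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.size)
        pa, pb = pooled[perm[: a.size]], pooled[perm[a.size:]]
        if abs(float(sstats.ttest_ind(pa, pb).statistic)) >= abs(t_obs):
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return t_obs, p
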