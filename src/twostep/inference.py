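"""Logistic regression of stay behavior and its inference machinery.

The model-based index is the coefficient of the previous-reward x
previous-transition interaction in a logistic regression of the stay
indicator; the previous-reward main effect is the model-free index.
The omnibus model crosses reward x transition with experimental
condition, delay, group, and visit, adds site, a fully interactive
mean-centered age covariate (crossed with the reward x transition x
condition x delay x group family), and additive IQ. Fitting is plain
maximum likelihood by iteratively reweighted least squares; dependence
of trials within subject is handled with a cluster-robust sandwich
covariance clustered by subject, which targets the same population-level
fixed effects as a by-subject random-effects fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "omnibus_spec",
    "build_design",
    "fit_logistic",
    "cluster_robust_se",
    "omnibus_model",
    "simple_effects",
    "significance_gate",
    "age_match_trim",
    "simulate_stay_features",
    "mb_index_spec",
]

MB_TERM = "prev_reward:prev_transition"

FACTOR_CODES: dict[str, dict] = {
    "condition": {"light": -0.5, "moderate": 0.5},
    "delay": {"short": -0.5, "long": 0.5},
    "group": {"control": -0.5, "PTSD": 0.5},
    "visit": {1: -0.5, 2: 0.5},
    "site": {"UW": -0.5, "UT": 0.5},
}
CONTINUOUS_CENTERED = ("age", "iq")


class DesignError(ValueError):
    """Schema or rank problems in the design matrix."""


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of a stay/switch logistic model.

    ``terms`` is a tuple of terms; each term is a tuple of variable names
    whose coded columns are multiplied elementwise. The intercept is
    implicit. ``cluster`` names the grouping variable for robust SEs.
    """

    terms: tuple[tuple[str, ...], ...]
    outcome: str = "stay"
    cluster: str = "subject_id"

    def __post_init__(self) -> None:
        have = set(self.terms)
        for term in self.terms:
            if len(term) > 1:
                for k in range(1, len(term)):
                    for sub in combinations(term, k):
                        if sub not in have:
                            raise DesignError(
                                f"term {term} requires constituent {sub} in the model"
                            )


def _factorial(variables: tuple[str, ...]) -> tuple[tuple[str, ...], ...]:
    out = []
    for k in range(1, len(variables) + 1):
        out.extend(combinations(variables, k))
    return tuple(out)


def omnibus_spec() -> ModelSpec:
    """The full stay/switch specification.

    Full factorial over (prev_reward, prev_transition, condition, delay,
    group, visit); site main effect; mean-centered age crossed with the
    reward x transition x condition x delay x group family; additive IQ.
    """
    behavioral = ("prev_reward", "prev_transition", "condition", "delay", "group", "visit")
    age_family = ("prev_reward", "prev_transition", "condition", "delay", "group")
    terms = list(_factorial(behavioral))
    terms.append(("site",))
    terms.append(("age",))
    terms.extend(("age",) + t for t in _factorial(age_family))
    terms.append(("iq",))
    return ModelSpec(terms=tuple(terms))


def mb_index_spec(*extra_factors: str) -> ModelSpec:
    """Reward x transition factorial, optionally crossed with extra factors.

    ``mb_index_spec()`` is the minimal model whose interaction coefficient
    is the model-based index; ``mb_index_spec("condition")`` adds the
    condition crossing used for within-group simple effects, etc.
    """
    return ModelSpec(
        terms=_factorial(("prev_reward", "prev_transition") + tuple(extra_factors))
    )


def term_name(term: tuple[str, ...]) -> str:
    return ":".join(term)


def _coded_column(features: pd.DataFrame, var: str) -> np.ndarray:
    if var not in features.columns:
        raise DesignError(f"feature column '{var}' missing from input frame")
    col = features[var]
    if var in FACTOR_CODES:
        mapped = col.map(FACTOR_CODES[var])
        if mapped.isna().any():
            bad = sorted(col[mapped.isna()].unique().tolist())
            raise DesignError(f"unrecognized level(s) {bad} for factor '{var}'")
        return mapped.to_numpy(dtype=float)
    x = col.to_numpy(dtype=float)
    if var in CONTINUOUS_CENTERED:
        x = x - x.mean()
    return x


def build_design(
    features: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Assemble (X, y, cluster_ids, column_names) from a feature frame.

    Binary factors are effect coded +/-0.5; age and IQ are centered at the
    sample mean of the frame being fit. Interaction columns are elementwise
    products of coded columns; the intercept column comes first.
    """
    if spec.outcome not in features.columns:
        raise DesignError(f"outcome column '{spec.outcome}' missing")
    if spec.cluster not in features.columns:
        raise DesignError(f"cluster column '{spec.cluster}' missing")
    n = len(features)
    base: dict[str, np.ndarray] = {}
    for term in spec.terms:
        for var in term:
            if var not in base:
                base[var] = _coded_column(features, var)
    cols = [np.ones(n)]
    names = ["intercept"]
    for term in spec.terms:
        x = base[term[0]].copy()
        for var in term[1:]:
            x = x * base[var]
        cols.append(x)
        names.append(term_name(term))
    X = np.column_stack(cols)
    y = features[spec.outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise DesignError("outcome must be binary 0/1")
    clusters = features[spec.cluster].to_numpy()
    return X, y, clusters, names


@dataclass
class FitResult:
    """Named coefficients with SEs, Wald statistics, and two-sided p-values."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n_obs: int
    converged: bool
    n_iter: int
    se_type: str = "model"
    n_clusters: int | None = None
    cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def statistic(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.statistic))

    def __getitem__(self, name: str) -> dict[str, float]:
        i = self.names.index(name)
        return {
            "estimate": float(self.coef[i]),
            "se": float(self.se[i]),
            "statistic": float(self.statistic[i]),
            "p": float(self.pvalues[i]),
        }

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.coef,
                "se": self.se,
                "statistic": self.statistic,
                "p": self.pvalues,
            }
        )


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(X.shape) * np.finfo(float).eps
    rank = int((d > tol).sum())
    if rank < X.shape[1]:
        bad = sorted(names[i] for i in piv[rank:])
        raise DesignError(f"design is rank deficient; collinear columns: {bad}")


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Maximum-likelihood logistic regression by IRLS.

    Convergence when the largest absolute coefficient change falls below
    ``tol`` (default 1e-8) or after ``max_iter`` iterations (flagged, not
    silent). Raises on rank-deficient designs (naming the collinear
    columns) and on apparent perfect separation (diverging coefficients).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    _check_rank(X, names)
    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        # working response; guard the degenerate w -> 0 tail
        w_safe = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w_safe
        WX = X * w_safe[:, None]
        beta_new = linalg.solve(X.T @ WX, X.T @ (w_safe * z), assume_a="pos")
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if np.max(np.abs(beta)) > 1e4:
            raise SeparationError(
                "coefficients diverging; data are (quasi-)perfectly separated"
            )
        if step < tol:
            converged = True
            break
    mu_fit = special.expit(X @ beta)
    if np.all(np.abs(y - mu_fit) < 1e-6):
        # every observation predicted with certainty: the MLE does not exist
        raise SeparationError("perfect separation: all outcomes fitted exactly")
    eta = X @ beta
    mu = special.expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    info = X.T @ (X * w[:, None])
    cov = linalg.inv(info)
    return FitResult(
        names=list(names),
        coef=beta,
        se=np.sqrt(np.diag(cov)),
        loglik=_loglik(X, y, beta),
        n_obs=len(y),
        converged=converged,
        n_iter=it,
        se_type="model",
        cov=cov,
    )


def cluster_robust_se(
    fit: FitResult, X: np.ndarray, y: np.ndarray, clusters: np.ndarray
) -> FitResult:
    """Replace SEs with the cluster-robust sandwich (scores summed by cluster).

    Estimates are untouched. With every observation its own cluster this is
    the heteroskedasticity-robust (HC0) sandwich. No small-sample scaling is
    applied, so duplicating each cluster's rows leaves z-statistics unchanged.
    """
    if not fit.converged:
        raise RuntimeError("refusing to sandwich a non-converged fit")
    X = np.asarray(X, dtype=float)
    labels, idx = np.unique(clusters, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("cluster-robust SEs need at least 2 clusters")
    mu = special.expit(X @ fit.coef)
    score = X * (y - mu)[:, None]
    u = np.zeros((len(labels), X.shape[1]))
    np.add.at(u, idx, score)
    meat = u.T @ u
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    bread = linalg.inv(X.T @ (X * w[:, None]))
    cov = bread @ meat @ bread
    return FitResult(
        names=fit.names,
        coef=fit.coef,
        se=np.sqrt(np.diag(cov)),
        loglik=fit.loglik,
        n_obs=fit.n_obs,
        converged=fit.converged,
        n_iter=fit.n_iter,
        se_type="cluster-robust",
        n_clusters=len(labels),
        cov=cov,
    )


def _check_cells(features: pd.DataFrame) -> None:
    cells = features.groupby(["group", "condition", "delay", "visit"], observed=True)[
        "subject_id"
    ].nunique()
    full = [
        (g, c, d, v)
        for g in FACTOR_CODES["group"]
        for c in FACTOR_CODES["condition"]
        for d in FACTOR_CODES["delay"]
        for v in FACTOR_CODES["visit"]
    ]
    empty = [cell for cell in full if cells.get(cell, 0) < 2]
    if empty:
        raise DesignError(f"design cells with < 2 subjects: {empty}")


def omnibus_model(features: pd.DataFrame, spec: ModelSpec | None = None) -> FitResult:
    """Fit the full omnibus stay model with by-subject cluster-robust SEs."""
    spec = spec if spec is not None else omnibus_spec()
    _check_cells(features)
    X, y, clusters, names = build_design(features, spec)
    fit = fit_logistic(X, y, names)
    return cluster_robust_se(fit, X, y, clusters)


def simple_effects(
    features: pd.DataFrame,
    within: dict[str, object],
    contrast: tuple[str, ...],
) -> FitResult:
    """Refit the stay model on a design subset and test one contrast.

    ``within`` filters the frame to the cell(s) of interest (e.g.
    ``{"group": "PTSD", "delay": "short"}``); ``contrast`` names the
    crossing to test, e.g. ``("prev_reward", "prev_transition",
    "condition")`` for a model-based-index difference between conditions.
    The refit model is the full factorial over the contrast's variables.
    Returns the fit (cluster-robust by subject); read the contrast
    coefficient via ``fit[":".join(contrast)]``.
    """
    sub = features
    for col, val in within.items():
        sub = sub[sub[col] == val]
    if sub.empty:
        raise DesignError(f"no rows after filtering on {within}")
    for var in contrast:
        if var in within:
            raise DesignError(f"contrast variable '{var}' is fixed by the filter")
        if var in FACTOR_CODES and sub[var].nunique() < 2:
            raise DesignError(f"contrast variable '{var}' does not vary in the subset")
    for var in contrast:
        if var in FACTOR_CODES:
            counts = sub.groupby(var, observed=True)["subject_id"].nunique()
            if (counts < 2).any():
                raise DesignError(
                    f"need >= 2 subjects per level of '{var}', got {counts.to_dict()}"
                )
    spec = ModelSpec(terms=_factorial(tuple(contrast)))
    X, y, clusters, names = build_design(sub, spec)
    fit = fit_logistic(X, y, names)
    return cluster_robust_se(fit, X, y, clusters)


def significance_gate(fit: FitResult, alpha: float = 0.001) -> pd.DataFrame:
    """Coefficients passing the interpretation gate p < alpha, by |statistic|.

    The study's convention: with ~30,000 trials and a large term count,
    only omnibus effects below alpha = .001 are interpreted.
    """
    out = fit.summary()
    out = out[out["p"] < alpha]
    return out.reindex(out["statistic"].abs().sort_values(ascending=False).index)


def age_match_trim(
    ages: pd.Series | dict,
    groups: pd.Series | dict,
    *,
    alpha: float = 0.05,
) -> tuple[list, int]:
    """Trim equal numbers of subjects per group until ages no longer differ.

    Repeatedly removes the youngest subject from the younger-mean group and
    the oldest from the older-mean group (one of each per step; group roles
    fixed at the start) until a Welch two-sample t-test of age gives
    p >= alpha. Ties in age are broken by subject-id order. Returns
    (retained subject ids, subjects removed per group).
    """
    ages = pd.Series(ages, dtype=float)
    groups = pd.Series(groups)
    if not ages.index.equals(groups.index):
        groups = groups.reindex(ages.index)
    labels = sorted(groups.dropna().unique().tolist())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    a_ids = ages[groups == labels[0]]
    b_ids = ages[groups == labels[1]]
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ValueError("each group needs at least 3 subjects")
    # group roles: remove from the tail pulling the means apart
    if a_ids.mean() <= b_ids.mean():
        younger, older = a_ids, b_ids
    else:
        younger, older = b_ids, a_ids
    # deterministic removal orders: youngest-first / oldest-first, id-order ties
    young_order = (
        younger.sort_index(kind="stable").sort_values(kind="stable").index.tolist()
    )
    old_order = (
        older.sort_index(kind="stable")
        .sort_values(ascending=False, kind="stable")
        .index.tolist()
    )
    removed = 0
    while True:
        y_kept = younger.drop(young_order[:removed])
        o_kept = older.drop(old_order[:removed])
        if len(y_kept) < 2 or len(o_kept) < 2:
            raise ValueError("groups exhausted before age matching succeeded")
        p = stats.ttest_ind(y_kept, o_kept, equal_var=False).pvalue
        if np.isnan(p) or p >= alpha:
            retained = sorted(list(y_kept.index) + list(o_kept.index))
            return retained, removed
        removed += 1


def simulate_stay_features(
    coef: dict[str, float],
    n_subjects: int,
    n_trials: int = 249,
    *,
    p_common: float = 0.70,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate lagged stay features directly from a logistic model.

    Independent oracle generator for parameter recovery: previous-trial
    transition codes are drawn with the task's 70/30 frequencies, reward
    codes fair, and the stay indicator Bernoulli in the inverse-logit of
    the supplied coefficients (keys "intercept", "prev_reward",
    "prev_transition", "prev_reward:prev_transition"). No agent is involved.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        r = np.where(rng.random(n_trials) < 0.5, 0.5, -0.5)
        t = np.where(rng.random(n_trials) < p_common, 0.5, -0.5)
        eta = (
            coef.get("intercept", 0.0)
            + coef.get("prev_reward", 0.0) * r
            + coef.get("prev_transition", 0.0) * t
            + coef.get(MB_TERM, 0.0) * r * t
        )
        stay = (rng.random(n_trials) < special.expit(eta)).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": f"S{s:03d}",
                    "stay": stay,
                    "prev_reward": r,
                    "prev_transition": t,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
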