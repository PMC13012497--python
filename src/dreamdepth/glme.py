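"""Linear mixed-effects engine for awakening-level models.

All models in this package share one structure: a Gaussian-identity linear
mixed model with a single random intercept for participant,

    y = X beta + Z b + e,   b_i ~ N(0, tau^2),   e ~ N(0, sigma^2 I),

where X holds the predictor(s) of interest plus the standard nuisance fixed
effects (experiment, night, time of night relative to midnight).  The solver
profiles the likelihood over the variance ratio lambda = tau^2 / sigma^2:
because Z is a group indicator, V = I + lambda Z Z' is block diagonal and
its inverse, determinant and the GLS cross-products have closed forms in the
per-group sums.  Fitting therefore reduces to a 1-D optimization, which is
what makes the 5,000-permutation channel-wise cluster procedure tractable.

Coefficients are reported from REML fits; log-likelihoods used for AIC/BIC
and likelihood-ratio comparisons always come from an ML fit of the same
model (the two fits share the profiled representation, so the ML refit is
essentially free).

Wald statistics follow the squared-standardized-coefficient convention
W = (beta/SE)^2 with p-values from a chi-square distribution with 1 df, and
95% confidence intervals are Wald-normal, beta +/- 1.96 SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "ModelSpec",
    "FitResult",
    "build_design",
    "fit_lmm",
    "wald_statistic",
    "channelwise_fit",
    "ChannelwiseWaldEngine",
    "compare_models",
    "tied_rank",
]

Z_95 = 1.959963984540054  # Phi^{-1}(0.975)

#: column placeholder substituted channel-by-channel in channel-wise models
BRAIN = "brain_activity"

#: columns treated as categorical (treatment/dummy coding) unless overridden
DEFAULT_CATEGORICAL = frozenset(
    {"experiment", "night", "report3", "report4", "report5", "report", "measure"}
)

_LOGLAM_LO, _LOGLAM_HI = -18.0, 18.0


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """One mixed-model formula: outcome ~ predictors + nuisance + (1|group)."""

    outcome: str
    predictors: tuple[str, ...]
    nuisance: tuple[str, ...] = ("experiment", "night", "time")
    group: str = "participant_id"
    categorical: frozenset[str] = DEFAULT_CATEGORICAL
    references: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        terms = set(self.predictors) | set(self.nuisance)
        if self.outcome in terms:
            raise ValueError(f"outcome {self.outcome!r} also appears as a predictor")

    @property
    def terms(self) -> tuple[str, ...]:
        # predictors of interest first, then nuisance, without duplicates
        seen, out = set(), []
        for t in self.predictors + self.nuisance:
            if t not in seen:
                seen.add(t)
                out.append(t)
        return tuple(out)


def _expand_terms(terms: Sequence[str]) -> list[str]:
    out: list[str] = []
    for term in terms:
        if "*" in term:
            a, b = term.split("*")
            for t in (a.strip(), b.strip(), f"{a.strip()}:{b.strip()}"):
                if t not in out:
                    out.append(t)
        elif term not in out:
            out.append(term)
    return out


def _main_effect_columns(df, name, categorical, references):
    """Columns for one main-effect term -> (names, list of value arrays)."""
    col = df[name]
    if name in categorical or col.dtype == object or isinstance(
        col.dtype, pd.CategoricalDtype
    ):
        levels = sorted(pd.unique(col.dropna()), key=str)
        if len(levels) < 2:
            raise ValueError(f"categorical term {name!r} has <2 levels")
        ref = references.get(name, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not found in {name!r}")
        names, cols = [], []
        for lev in levels:
            if lev == ref:
                continue
            names.append(f"{name}[{lev}]")
            cols.append((col == lev).to_numpy(float))
        return names, cols
    return [name], [col.to_numpy(float)]


def build_design(
    df: pd.DataFrame,
    terms: Sequence[str],
    categorical=DEFAULT_CATEGORICAL,
    references: Mapping[str, object] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Build a fixed-effects design matrix with treatment coding.

    Supports main effects, ``a:b`` products and ``a*b`` expansion.  The
    intercept is always the first column.
    """
    references = references or {}
    names: list[str] = ["intercept"]
    cols: list[np.ndarray] = [np.ones(len(df))]
    for term in _expand_terms(terms):
        if ":" in term:
            a, b = (t.strip() for t in term.split(":"))
            na, ca = _main_effect_columns(df, a, categorical, references)
            nb, cb = _main_effect_columns(df, b, categorical, references)
            for n1, c1 in zip(na, ca):
                for n2, c2 in zip(nb, cb):
                    names.append(f"{n1}:{n2}")
                    cols.append(c1 * c2)
        else:
            n, c = _main_effect_columns(df, term, categorical, references)
            names.extend(n)
            cols.extend(c)
    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        bad = [names[j] for j in range(X.shape[1]) if not np.isfinite(X[:, j]).all()]
        raise ValueError(f"non-finite values in design columns {bad}")
    return X, names


def design_for(df: pd.DataFrame, spec: ModelSpec):
    """Design matrix, column names, group codes and y for a ModelSpec."""
    X, names = build_design(df, spec.terms, spec.categorical, spec.references)
    groups, levels = pd.factorize(df[spec.group], sort=True)
    y = df[spec.outcome].to_numpy(float)
    return y, X, names, groups.astype(np.intp), list(levels)


# ---------------------------------------------------------------------------
# profiled random-intercept kernel
# ---------------------------------------------------------------------------


class _Kernel:
    """Sufficient statistics for profiled random-intercept GLS."""

    def __init__(self, y, X, codes, n_groups=None):
        self.n, self.p = X.shape
        G = int(codes.max()) + 1 if n_groups is None else n_groups
        self.G = G
        self.X, self.y, self.codes = X, y, codes
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        S = np.zeros((G, self.p))
        np.add.at(S, codes, X)
        self.S = S
        self.t = np.bincount(codes, weights=y, minlength=G)
        self.ng = np.bincount(codes, minlength=G).astype(float)

    def gls(self, lam):
        w = lam / (1.0 + lam * self.ng)  # (G,)
        A = self.XtX - (self.S * w[:, None]).T @ self.S
        b = self.Xty - self.S.T @ (w * self.t)
        q = self.yty - float((w * self.t) @ self.t)
        beta = np.linalg.solve(A, b)
        rss = max(q - float(b @ beta), 1e-300)
        logdetV = float(np.log1p(lam * self.ng).sum())
        return A, beta, rss, logdetV

    def neg2ll(self, loglam, reml):
        lam = np.exp(loglam)
        A, _, rss, logdetV = self.gls(lam)
        n, p = self.n, self.p
        if reml:
            s2 = rss / (n - p)
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            return (n - p) * (np.log(2 * np.pi * s2) + 1.0) + logdetV + logdetA
        s2 = rss / n
        return n * (np.log(2 * np.pi * s2) + 1.0) + logdetV

    def optimize(self, reml):
        res = minimize_scalar(
            self.neg2ll,
            bounds=(_LOGLAM_LO, _LOGLAM_HI),
            args=(reml,),
            method="bounded",
            options={"xatol": 1e-8},
        )
        loglam, crit = float(res.x), float(res.fun)
        # a variance ratio of exactly zero (no participant variance) lives on
        # the boundary; accept it if it beats the interior optimum
        at_zero = self.neg2ll(_LOGLAM_LO, reml)
        if at_zero <= crit:
            loglam, crit = _LOGLAM_LO, at_zero
        converged = bool(res.success) and np.isfinite(crit)
        return loglam, crit, converged


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """One mixed-model fit: coefficient table plus model-level metrics.

    ``params`` is indexed by coefficient name with columns estimate, se,
    wald, pvalue, ci_low, ci_high.  ``loglik`` is the log-likelihood of the
    reporting fit (REML by default); ``loglik_ml`` always holds the ML
    log-likelihood that AIC/BIC and likelihood-ratio comparisons are based
    on.  ``k`` counts estimated parameters (fixed effects + 2 variances).
    """

    params: pd.DataFrame
    loglik: float
    loglik_ml: float
    aic: float
    bic: float
    n: int
    n_groups: int
    k: int
    sigma2: float
    tau2: float
    converged: bool
    method: str
    spec: ModelSpec | None = None
    group_levels: list | None = None
    blups: np.ndarray | None = None

    def coef(self, name: str) -> pd.Series:
        return self.params.loc[name]


def wald_statistic(beta: float, se: float) -> tuple[float, float]:
    """Wald statistic W = (beta/SE)^2 and its chi-square(1) p-value."""
    if se <= 0:
        raise ValueError(f"standard error must be positive, got {se}")
    W = (beta / se) ** 2
    return W, float(stats.chi2.sf(W, 1))


def _result_from_kernel(kern: _Kernel, names, spec, levels, reml) -> FitResult:
    loglam, crit, converged = kern.optimize(reml)
    lam = np.exp(loglam)
    if loglam <= _LOGLAM_LO + 1e-9:
        lam = 0.0
    A, beta, rss, _ = kern.gls(lam)
    n, p = kern.n, kern.p
    sigma2 = rss / (n - p) if reml else rss / n
    tau2 = lam * sigma2
    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    if np.any(se <= 0):
        converged = False
        se = np.where(se <= 0, np.nan, se)
    W = (beta / se) ** 2
    pvals = stats.chi2.sf(W, 1)
    params = pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "wald": W,
            "pvalue": pvals,
            "ci_low": beta - Z_95 * se,
            "ci_high": beta + Z_95 * se,
        },
        index=pd.Index(names, name="coefficient"),
    )
    # ML log-likelihood for AIC/BIC and LRTs
    if reml:
        loglam_ml, crit_ml, conv_ml = kern.optimize(reml=False)
        converged = converged and conv_ml
        loglik_ml = -0.5 * crit_ml
        loglik = -0.5 * crit
    else:
        loglik_ml = loglik = -0.5 * crit
    k = p + 2
    aic = -2 * loglik_ml + 2 * k
    bic = -2 * loglik_ml + k * np.log(n)
    # BLUPs of the participant intercepts at the reporting fit
    w = (lam * kern.ng) / (1.0 + lam * kern.ng) if lam > 0 else np.zeros(kern.G)
    resid_sum = kern.t - kern.S @ beta
    blups = w * resid_sum / np.maximum(kern.ng, 1)
    return FitResult(
        params=params,
        loglik=float(loglik),
        loglik_ml=float(loglik_ml),
        aic=float(aic),
        bic=float(bic),
        n=n,
        n_groups=kern.G,
        k=k,
        sigma2=float(sigma2),
        tau2=float(tau2),
        converged=converged,
        method="REML" if reml else "ML",
        spec=spec,
        group_levels=levels,
        blups=blups,
    )


def fit_lmm(records: pd.DataFrame, spec: ModelSpec, reml: bool = True) -> FitResult:
    """Fit a Gaussian random-intercept mixed model.

    Raises on degenerate inputs (constant outcome, fewer than two groups,
    rank-deficient design); non-convergence of the 1-D variance optimization
    is flagged on the result rather than raised.
    """
    df = records.dropna(subset=[spec.outcome, *_columns_used(spec)])
    y, X, names, codes, levels = design_for(df, spec)
    if len(levels) < 2:
        raise ValueError(f"need >=2 groups in {spec.group!r}, got {len(levels)}")
    if np.ptp(y) == 0:
        raise ValueError(f"outcome {spec.outcome!r} is constant")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("too few observations for the requested design")
    kern = _Kernel(y, X, codes, n_groups=len(levels))
    res = _result_from_kernel(kern, names, spec, levels, reml)
    if not res.converged:
        warnings.warn("mixed-model variance optimization did not converge cleanly")
    return res


def _columns_used(spec: ModelSpec) -> list[str]:
    cols = {spec.group}
    for term in _expand_terms(spec.terms):
        for part in term.split(":"):
            cols.add(part.strip())
    return sorted(cols)


# ---------------------------------------------------------------------------
# channel-wise fitting
# ---------------------------------------------------------------------------


def _align_features(features: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    ids = records["record_id"]
    if ids.duplicated().any():
        raise ValueError("duplicate record_id in records")
    missing = ids[~ids.isin(features.index)].tolist()
    extra = [i for i in features.index if i not in set(ids)]
    if missing or extra:
        raise ValueError(
            f"feature rows do not match records; missing={missing[:5]} "
            f"extra={extra[:5]}"
        )
    return features.loc[ids]


def channelwise_fit(
    features: pd.DataFrame,
    records: pd.DataFrame,
    spec: ModelSpec,
    reml: bool = True,
) -> dict[str, FitResult | None]:
    """Fit ``spec`` once per electrode, substituting the channel column.

    ``features`` is a record x electrode table (index = record_id) whose
    column is injected into the model under the name ``brain_activity``
    (as outcome or predictor, wherever the spec references it).  Electrodes
    whose fit fails or does not converge map to ``None`` / a flagged result
    and are excluded from cluster formation downstream.
    """
    feats = _align_features(features, records)
    out: dict[str, FitResult | None] = {}
    for ch in feats.columns:
        df = records.assign(**{BRAIN: feats[ch].to_numpy()})
        try:
            out[ch] = fit_lmm(df, spec, reml=reml)
        except (ValueError, np.linalg.LinAlgError):
            out[ch] = None
    return out


class ChannelwiseWaldEngine:
    """Vectorized channel-wise Wald statistics for permutation testing.

    Precomputes per-electrode design cross-products once, then evaluates the
    model for an arbitrary permutation of the outcome with a vectorized
    golden-section search over the profiled variance ratio -- the exact same
    model as :func:`fit_lmm`, batched across electrodes.

    The statistic of interest defaults to the last design column generated
    by the spec's predictors (the interaction column for ``a*b`` terms).
    """

    _GOLDEN_ITERS = 64

    def __init__(self, records, features, spec: ModelSpec, term: str | None = None,
                 reml: bool = True):
        feats = _align_features(features, records)
        self.spec, self.reml = spec, reml
        self.channels = list(feats.columns)
        self.records = records.reset_index(drop=True)
        codes, levels = pd.factorize(self.records[spec.group], sort=True)
        self.codes = codes.astype(np.intp)
        self.G = len(levels)
        self.ng = np.bincount(self.codes, minlength=self.G).astype(float)
        self.outcome_is_brain = spec.outcome == BRAIN
        C = len(self.channels)

        # build per-channel designs (they differ in the brain column only,
        # and not at all when brain activity is the outcome)
        ref = self.records.assign(**{BRAIN: feats.iloc[:, 0].to_numpy()})
        X0, names = build_design(ref, spec.terms, spec.categorical, spec.references)
        self.names = names
        n, p = X0.shape
        self.n, self.p = n, p
        pred_cols = self._predictor_columns(ref, spec)
        if term is None:
            term = pred_cols[-1] if pred_cols else names[-1]
        if term not in names:
            raise ValueError(f"term {term!r} not among design columns {names}")
        self.term = term
        self.jterm = names.index(term)

        F = feats.to_numpy(float)  # (n, C)
        if self.outcome_is_brain:
            self.X = np.broadcast_to(X0, (C, n, p))
            self.Y = F
            self._y = None
        else:
            Xs = np.empty((C, n, p))
            for c in range(C):
                df = self.records.assign(**{BRAIN: F[:, c]})
                Xc, _ = build_design(df, spec.terms, spec.categorical,
                                     spec.references)
                Xs[c] = Xc
            self.X = Xs
            self.Y = None
            self._y = self.records[spec.outcome].to_numpy(float)

        self.XtX = np.einsum("cnp,cnq->cpq", self.X, self.X)
        S = np.zeros((C, self.G, p))
        for c in range(C):
            np.add.at(S[c], self.codes, self.X[c])
        self.S = S
        self.ok = np.array(
            [np.linalg.matrix_rank(self.X[c]) == p for c in range(C)]
        )

    @staticmethod
    def _predictor_columns(df, spec) -> list[str]:
        Xp, names_p = build_design(df, spec.predictors, spec.categorical,
                                   spec.references)
        return [n for n in names_p if n != "intercept"]

    # -- batched profiled criterion -------------------------------------

    def _crit(self, loglam, XtX, Xty, yty, t):
        lam = np.exp(loglam)  # (C,)
        w = lam[:, None] / (1.0 + lam[:, None] * self.ng)  # (C,G)
        wt = w * t
        A = XtX - np.einsum("cgp,cgq->cpq", self.S * w[..., None], self.S)
        b = Xty - np.einsum("cgp,cg->cp", self.S, wt)
        q = yty - (wt * t).sum(1)
        beta = np.linalg.solve(A, b[..., None])[..., 0]
        rss = np.maximum(q - (b * beta).sum(1), 1e-300)
        logdetV = np.log1p(lam[:, None] * self.ng).sum(1)
        n, p = self.n, self.p
        if self.reml:
            sign, logdetA = np.linalg.slogdet(A)
            crit = (n - p) * np.log(rss / (n - p)) + logdetV + logdetA
            crit = np.where(sign > 0, crit, np.inf)
        else:
            crit = n * np.log(rss / n) + logdetV
        return crit, (A, beta, rss)

    def wald_table(self, perm: np.ndarray | None = None) -> pd.DataFrame:
        """Per-electrode beta/SE/W/p/sign for the term of interest.

        ``perm`` is an index array applied to the outcome (rows of the
        feature matrix when brain activity is the outcome).
        """
        if self.outcome_is_brain:
            Ymat = self.Y if perm is None else self.Y[perm]
            Xty = np.einsum("cnp,nc->cp", self.X, Ymat)
            yty = np.einsum("nc,nc->c", Ymat, Ymat)
            t = np.zeros((len(self.channels), self.G))
            for c in range(len(self.channels)):
                t[c] = np.bincount(self.codes, weights=Ymat[:, c],
                                   minlength=self.G)
        else:
            y = self._y if perm is None else self._y[perm]
            Xty = np.einsum("cnp,n->cp", self.X, y)
            yty = np.full(len(self.channels), float(y @ y))
            t = np.broadcast_to(
                np.bincount(self.codes, weights=y, minlength=self.G),
                (len(self.channels), self.G),
            )

        XtX = self.XtX
        # vectorized golden-section search on log-lambda
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        C = len(self.channels)
        a = np.full(C, _LOGLAM_LO)
        b = np.full(C, _LOGLAM_HI)
        c1 = b - invphi * (b - a)
        c2 = a + invphi * (b - a)
        f1, _ = self._crit(c1, XtX, Xty, yty, t)
        f2, _ = self._crit(c2, XtX, Xty, yty, t)
        for _ in range(self._GOLDEN_ITERS):
            left = f1 < f2  # minimum lies in [a, c2]
            b_n = np.where(left, c2, b)
            a_n = np.where(left, a, c1)
            c1_n = np.where(left, b_n - invphi * (b_n - a_n), c2)
            c2_n = np.where(left, c1, a_n + invphi * (b_n - a_n))
            fx, _ = self._crit(np.where(left, c1_n, c2_n), XtX, Xty, yty, t)
            f1, f2 = np.where(left, fx, f2), np.where(left, f1, fx)
            a, b, c1, c2 = a_n, b_n, c1_n, c2_n
        loglam = 0.5 * (a + b)
        # boundary check: variance ratio ~ 0
        f_int, _ = self._crit(loglam, XtX, Xty, yty, t)
        f_lo, _ = self._crit(np.full(C, _LOGLAM_LO), XtX, Xty, yty, t)
        loglam = np.where(f_lo <= f_int, _LOGLAM_LO, loglam)
        _, (A, beta, rss) = self._crit(loglam, XtX, Xty, yty, t)
        dof = self.n - self.p if self.reml else self.n
        sigma2 = rss / dof
        cov = np.linalg.inv(A) * sigma2[:, None, None]
        j = self.jterm
        est = beta[:, j]
        se = np.sqrt(np.clip(cov[:, j, j], 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            W = (est / se) ** 2
        pval = stats.chi2.sf(W, 1)
        ok = self.ok & np.isfinite(W) & (se > 0)
        return pd.DataFrame(
            {
                "beta": est,
                "se": se,
                "wald": W,
                "pvalue": pval,
                "sign": np.where(est >= 0, 1, -1),
                "ok": ok,
            },
            index=pd.Index(self.channels, name="channel"),
        )


# ---------------------------------------------------------------------------
# model comparison and small utilities
# ---------------------------------------------------------------------------


def compare_models(full: FitResult, reduced: FitResult) -> dict[str, float]:
    """Likelihood-ratio test of nested ML fits plus AIC/BIC differences.

    Positive ``delta_aic``/``delta_bic`` favor the full model (lower
    AIC/BIC for the full model), matching the reporting convention of the
    contrast tables this package writes.
    """
    if full.n != reduced.n:
        raise ValueError(f"models fit to different n ({full.n} vs {reduced.n})")
    df = full.k - reduced.k
    if df < 0:
        raise ValueError("'full' model has fewer parameters than 'reduced'")
    lrt = 2.0 * (full.loglik_ml - reduced.loglik_ml)
    if lrt < -1e-6 * max(1.0, abs(full.loglik_ml)):
        raise ValueError("reduced model has higher likelihood; models not nested?")
    lrt = max(lrt, 0.0)
    if df == 0:
        p = 1.0 if lrt <= 1e-8 else 0.0
    else:
        p = float(stats.chi2.sf(lrt, df))
    return {
        "lrt_stat": float(lrt),
        "df": int(df),
        "lrt_p": p,
        "delta_aic": float(reduced.aic - full.aic),
        "delta_bic": float(reduced.bic - full.bic),
    }


def tied_rank(values) -> np.ndarray:
    """Average ranks with ties sharing their mean rank (1-based)."""
    arr = np.asarray(values, float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    return stats.rankdata(arr, method="average")
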