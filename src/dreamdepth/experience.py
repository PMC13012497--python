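"""Dream-report taxonomy, report-type contrasts, and phenomenology PCA.

Reports follow a two-level questionnaire: the first answer sorts each
awakening into conscious experience (CE), conscious experience without
recall of content (CEWR, a "white dream"), or no conscious experience
(NCE).  A follow-up refines CEWR into rich (rCEWR: the impression of a
forgotten rich experience) vs simple (sCEWR), and NCE into a contentless
sense of presence (CESP) vs full unconsciousness (UNC).  A missing
follow-up leaves the subtype missing while the three-level class stands.

Report-type effects on the ratings are estimated with one mixed model per
unordered pair of levels (no ordinal assumption across consciousness
levels), with Benjamini-Hochberg FDR across the pair family.  Dream
phenomenology is summarized by a PCA of six z-scored features (duration
log-transformed); the first two components are conventionally read as
perceptual immersion (PC1) and reflective thought (PC2).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .glme import FitResult, ModelSpec, fit_lmm
from .synthetic import PHENO_FEATURES

__all__ = [
    "classify_report",
    "report4_of",
    "pairwise_contrasts",
    "proportion_tests",
    "PCAResult",
    "phenomenology_pca",
    "pc_association",
]

_FOLLOWUPS = {
    "CE": {None},
    "CEWR": {None, "rich", "simple"},
    "NCE": {None, "presence", "unconscious"},
}
_SUBTYPE = {
    ("CEWR", "rich"): "rCEWR",
    ("CEWR", "simple"): "sCEWR",
    ("NCE", "presence"): "CESP",
    ("NCE", "unconscious"): "UNC",
    ("CE", None): "CE",
}


def classify_report(first_answer: str, followup: str | None = None):
    """Map the questionnaire answers to (report3, report5).

    CE needs no follow-up; CEWR resolves to rCEWR/sCEWR, NCE to CESP/UNC.
    A missing follow-up for CEWR/NCE leaves report5 as None (the subtype is
    unavailable but the three-level class is retained).  Contradictory
    combinations raise.
    """
    if first_answer not in _FOLLOWUPS:
        raise ValueError(f"unknown report class {first_answer!r}")
    if followup not in _FOLLOWUPS[first_answer]:
        raise ValueError(
            f"follow-up {followup!r} contradicts first-level answer "
            f"{first_answer!r}"
        )
    report5 = _SUBTYPE.get((first_answer, followup))
    return first_answer, report5


def report4_of(report5: str) -> str:
    """Collapse the five-level classification to {CE, CEWR, CESP, UNC}."""
    if report5 in ("rCEWR", "sCEWR"):
        return "CEWR"
    if report5 in ("CE", "CESP", "UNC"):
        return report5
    raise ValueError(f"unknown report5 level {report5!r}")


def pairwise_contrasts(
    records: pd.DataFrame,
    outcome: str,
    levels: tuple[str, ...] = ("CE", "CEWR", "CESP", "UNC"),
    level_col: str = "report4",
    nuisance: tuple[str, ...] = ("experiment", "night", "time"),
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """One mixed model per unordered level pair, BH-adjusted across pairs.

    beta is the effect of ``level_b`` relative to ``level_a`` (treatment
    coding with level_a as reference).  Pairs with an empty level are
    skipped with a warning.
    """
    df = records.copy()
    if level_col == "report4" and "report4" not in df:
        df["report4"] = df["report5"].map(
            lambda r: report4_of(r) if isinstance(r, str) else np.nan
        )
    rows = []
    for a, b in itertools.combinations(levels, 2):
        sub = df[df[level_col].isin([a, b])].dropna(subset=[level_col, outcome])
        if (sub[level_col] == a).sum() == 0 or (sub[level_col] == b).sum() == 0:
            warnings.warn(f"pair ({a}, {b}) skipped: empty level")
            continue
        spec = ModelSpec(
            outcome=outcome,
            predictors=(level_col,),
            nuisance=nuisance,
            references={level_col: a},
        )
        fit = fit_lmm(sub, spec)
        coef = fit.coef(f"{level_col}[{b}]")
        rows.append(
            {"level_a": a, "level_b": b, "beta": coef.estimate, "se": coef.se,
             "ci_low": coef.ci_low, "ci_high": coef.ci_high,
             "p": coef.pvalue, "n": fit.n}
        )
    tab = pd.DataFrame(rows)
    if len(tab):
        tab["q"] = multipletests(tab["p"].to_numpy(), method=adjust)[1]
    else:
        tab["q"] = []
    return tab


def proportion_tests(records: pd.DataFrame, min_participants: int = 5) -> dict:
    """Participant-wise report-type proportions and their tests.

    Friedman test across the three-level report proportions (one proportion
    triplet per participant), Wilcoxon signed-rank for the UNC share of NCE
    vs the CESP share, and for the sCEWR vs rCEWR share of CEWR.
    """
    df = records.dropna(subset=["report3"])
    counts = df.groupby("participant_id")["report3"].value_counts().unstack(
        fill_value=0
    )
    for lev in ("CE", "CEWR", "NCE"):
        if lev not in counts:
            counts[lev] = 0
    total = counts.sum(axis=1)
    empty = total[total == 0].index.tolist()
    if empty:
        warnings.warn(f"participants with zero reports excluded: {empty}")
        counts = counts[total > 0]
        total = total[total > 0]
    if len(counts) < min_participants:
        raise ValueError(
            f"need >= {min_participants} participants, got {len(counts)}"
        )
    props = counts[["CE", "CEWR", "NCE"]].div(total, axis=0)
    if props[["CE", "CEWR", "NCE"]].nunique().max() == 1:
        friedman_stat, friedman_p = 0.0, 1.0
    else:
        friedman_stat, friedman_p = stats.friedmanchisquare(
            props["CE"], props["CEWR"], props["NCE"]
        )

    def _share_test(sub_a: str, sub_b: str) -> tuple[float, float, float]:
        """Signed-rank test of share(sub_a) vs share(sub_b) within their
        parent class, paired by participant."""
        sub = records[records["report5"].isin([sub_a, sub_b])]
        cts = sub.groupby("participant_id")["report5"].value_counts().unstack(
            fill_value=0
        )
        for s in (sub_a, sub_b):
            if s not in cts:
                cts[s] = 0
        tot = cts[sub_a] + cts[sub_b]
        cts = cts[tot > 0]
        share = (cts[sub_a] / (cts[sub_a] + cts[sub_b])).to_numpy(float)
        diff = share - 0.5
        if len(diff) == 0 or np.allclose(diff, 0):
            return float(np.mean(share) if len(share) else np.nan), np.nan, 1.0
        res = stats.wilcoxon(diff, zero_method="wilcox")
        return float(share.mean()), float(share.std(ddof=1)), float(res.pvalue)

    unc_share, unc_share_sd, unc_p = _share_test("UNC", "CESP")
    scewr_share, scewr_share_sd, scewr_p = _share_test("sCEWR", "rCEWR")
    return {
        "proportions": props,
        "friedman_stat": float(friedman_stat),
        "friedman_p": float(friedman_p),
        "unc_share_mean": unc_share,
        "unc_share_sd": unc_share_sd,
        "signrank_p_unc_vs_cesp": unc_p,
        "scewr_share_mean": scewr_share,
        "scewr_share_sd": scewr_share_sd,
        "signrank_p_scewr_vs_rcewr": scewr_p,
    }


@dataclass
class PCAResult:
    """PCA of the six phenomenology features.

    ``loadings`` rows are orthonormal principal axes over the z-scored
    features; ``scores`` holds per-record component scores standardized to
    unit variance and sign-oriented so the largest-|loading| feature of
    each component loads positively (component signs are otherwise
    arbitrary).  ``means``/``sds`` are the z-scoring constants on the
    transformed (log-duration) scale.
    """

    loadings: pd.DataFrame  # components x features, orthonormal rows
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame  # record_id x retained components (pc1, pc2)
    means: pd.Series
    sds: pd.Series
    n_retained: int = 2


def phenomenology_pca(records: pd.DataFrame, n_retained: int = 2,
                      min_duration: float = 1.0) -> PCAResult:
    """PCA of duration (log seconds), vividness, perceptual-vs-thought,
    bizarreness, emotional intensity and dream awareness.

    Only records with all six ratings enter (in practice, CE reports).
    Features are z-scored globally before the eigendecomposition; a
    zero-variance feature is an error naming the offender.
    """
    cols = list(PHENO_FEATURES)
    df = records.dropna(subset=cols)
    if len(df) < 6:
        raise ValueError(f"need >= 6 complete rating vectors, got {len(df)}")
    X = df[cols].astype(float).copy()
    X["duration_seconds"] = np.log(np.clip(X["duration_seconds"], min_duration,
                                           None))
    means, sds = X.mean(), X.std(ddof=1)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance phenomenology feature(s): {zero}")
    Z = (X - means) / sds
    pca = PCA(n_components=len(cols), svd_solver="full")
    raw_scores = pca.fit_transform(Z.to_numpy())
    load = pca.components_  # (k, 6), orthonormal rows
    # orient: largest-|loading| feature of each component loads positively
    flip = np.array([
        -1.0 if row[np.argmax(np.abs(row))] < 0 else 1.0 for row in load
    ])
    load = load * flip[:, None]
    raw_scores = raw_scores * flip[None, :]
    sd_scores = raw_scores.std(axis=0, ddof=1)
    sd_scores[sd_scores == 0] = 1.0
    scores = raw_scores[:, :n_retained] / sd_scores[:n_retained]
    score_df = pd.DataFrame(
        scores,
        index=pd.Index(df["record_id"], name="record_id"),
        columns=[f"pc{i + 1}" for i in range(n_retained)],
    )
    return PCAResult(
        loadings=pd.DataFrame(load, columns=cols,
                              index=[f"pc{i + 1}" for i in range(len(cols))]),
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=score_df,
        means=means,
        sds=sds,
        n_retained=n_retained,
    )


def pc_association(records: pd.DataFrame, scores: pd.DataFrame, outcome: str,
                   component: str = "pc1",
                   nuisance: tuple[str, ...] = ("experiment", "night", "time"),
                   ) -> FitResult:
    """Mixed model of a rating on one phenomenology component score."""
    df = records.merge(scores[[component]], left_on="record_id",
                       right_index=True, how="inner")
    spec = ModelSpec(outcome=outcome, predictors=(component,), nuisance=nuisance)
    return fit_lmm(df, spec)
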