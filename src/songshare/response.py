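"""Playback-response compositing and treatment/distance effect tests.

The four behavioural response measures (duration of movements within 10 m of
the loudspeaker, time spent within 10 m, total movement duration, latency to
move) are reduced to composite scores by a principal components analysis of
their correlation matrix; components with eigenvalue > 1 are retained
(Kaiser's criterion).  Treatment effects on the scores are tested with a
mixed linear model (fixed: group, treatment, order, treatment x order;
random: subject intercept) plus pairwise paired permutation tests, and the
dependence of scores on singer distance with a random-intercept-per-treatment
mixed model fitted by REML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .permstats import PermutationResult, paired_permutation_test
from .songsynth import MEASURE_COLS, TREATMENTS


@dataclass(frozen=True)
class PCAModel:
    """Correlation-matrix PCA of the 4 response measures.

    ``loadings`` has one column per component (sign-fixed so the
    largest-magnitude loading in each column is positive); eigenvalues sum to
    4 and variance_pct = eigenvalue / 4 * 100.
    """

    loadings: np.ndarray  # (4, 4)
    eigenvalues: np.ndarray  # (4,)
    variance_pct: np.ndarray  # (4,)
    retained: tuple[int, ...]  # indices with eigenvalue > 1 (Kaiser)
    measures: tuple[str, ...] = MEASURE_COLS


def pca_scores(table: pd.DataFrame) -> tuple[PCAModel, pd.DataFrame]:
    """Fit the correlation-matrix PCA and score every row.

    Measures are standardized (zero mean, unit variance) across all rows
    pooled; scores are the standardized data projected on the eigenvectors.
    Returns the model and a copy of the table with PC1..PC4 columns added.
    """
    missing = [c for c in MEASURE_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"missing measure columns: {missing}")
    X = table[list(MEASURE_COLS)].to_numpy(dtype=float)
    if len(X) < 5:
        raise ValueError("need at least 5 rows for a stable PCA")
    if not np.all(np.isfinite(X)):
        raise ValueError("response measures must be finite")
    sd = X.std(axis=0, ddof=1)
    for col, s in zip(MEASURE_COLS, sd):
        if s == 0:
            raise ValueError(f"measure {col!r} is constant; PCA undefined")
    Z = (X - X.mean(axis=0)) / sd
    corr = Z.T @ Z / (len(Z) - 1)

    eigval, eigvec = np.linalg.eigh(corr)
    idx = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[idx], 0.0, None)
    eigvec = eigvec[:, idx]
    # Sign convention: the largest-|loading| measure loads positively.
    for k in range(eigvec.shape[1]):
        j = int(np.argmax(np.abs(eigvec[:, k])))
        if eigvec[j, k] < 0:
            eigvec[:, k] *= -1

    model = PCAModel(
        loadings=eigvec,
        eigenvalues=eigval,
        variance_pct=eigval / eigval.size * 100.0,
        # strict Kaiser rule; the epsilon keeps an eigenvalue that is
        # exactly 1 up to round-off from being retained
        retained=tuple(int(k) for k in range(eigval.size)
                       if eigval[k] > 1.0 + 1e-9),
    )
    scores = Z @ eigvec
    out = table.copy()
    for k in range(scores.shape[1]):
        out[f"PC{k + 1}"] = scores[:, k]
    return model, out


def loadings_table(model: PCAModel, n_components: int = 2) -> pd.DataFrame:
    """Report-style table: eigenvalue, % variance and loadings per component."""
    cols = [f"PC{k + 1}" for k in range(n_components)]
    rows = {"eigenvalue": model.eigenvalues[:n_components],
            "percent_variance": model.variance_pct[:n_components]}
    body = pd.DataFrame(rows, index=cols).T
    load = pd.DataFrame(model.loadings[:, :n_components],
                        index=list(model.measures), columns=cols)
    return pd.concat([body, load])


# ---------------------------------------------------------------------------
# Treatment comparisons
# ---------------------------------------------------------------------------

def _check_balanced(table: pd.DataFrame) -> None:
    missing = []
    for subj, sub in table.groupby("subject_id"):
        have = set(sub["treatment"])
        for trt in TREATMENTS:
            if trt not in have:
                missing.append((subj, trt))
        if len(sub) != len(TREATMENTS):
            extra = sub["treatment"].value_counts()
            if (extra > 1).any():
                missing.append((subj, "duplicate rows"))
    if missing:
        raise ValueError(f"unbalanced design; missing/duplicated cells: {missing}")


def compare_treatments(
    scored: pd.DataFrame,
    score_col: str = "PC1",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Omnibus mixed-model test plus pairwise paired permutation tests.

    Omnibus: score ~ group + treatment + order + treatment:order with a
    random intercept per subject, reporting a Wald F and p per fixed factor.
    Pairwise: two-tailed paired sign-flip permutation tests on the within-
    subject score differences for S-aN, S-dN and aN-dN.
    """
    import statsmodels.formula.api as smf

    _check_balanced(scored)
    y = scored[score_col].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"{score_col} scores are all identical; tests undefined")

    df = scored.rename(columns={score_col: "score"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # Sum-to-zero contrasts so each factor's Wald test is marginal
        # (Type-III-style) despite the treatment x order interaction.
        md = smf.mixedlm(
            "score ~ C(group_id, Sum) + C(treatment, Sum) + C(order, Sum)"
            " + C(treatment, Sum):C(order, Sum)",
            data=df,
            groups=df["subject_id"],
        )
        res = md.fit(reml=True)
        wald = res.wald_test_terms(scalar=True)
    rename = {
        "C(group_id, Sum)": "group",
        "C(treatment, Sum)": "treatment",
        "C(order, Sum)": "order",
        "C(treatment, Sum):C(order, Sum)": "treatment:order",
    }
    omnibus = {}
    for term, row in wald.table.iterrows():
        if term == "Intercept":
            continue
        term = rename.get(str(term), str(term))
        omnibus[str(term)] = {
            "statistic": float(row["statistic"]),
            "df": float(row["df_constraint"]),
            "p": float(row["pvalue"]),
        }

    wide = scored.pivot(index="subject_id", columns="treatment",
                        values=score_col)
    pairwise: dict[str, PermutationResult] = {}
    for a, b in (("S", "aN"), ("S", "dN"), ("aN", "dN")):
        pairs = wide[[a, b]].to_numpy()
        pairwise[f"{a}_vs_{b}"] = paired_permutation_test(
            pairs, n_perm=n_perm, seed=seed
        )
    return {"omnibus": omnibus, "pairwise": pairwise}


# ---------------------------------------------------------------------------
# Distance effect
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceEffect:
    slope: float  # score units per metre
    se: float
    fstat: float
    p: float
    residual_normality_p: float
    n: int


def distance_effect(scored: pd.DataFrame, score_col: str = "PC1") -> DistanceEffect:
    """Score against singer distance for the neighbour (aN/dN) rows.

    Mixed model score ~ distance with a random intercept per song treatment,
    fitted by REML; reports the slope with its Wald F/p and a Shapiro-Wilk
    normality p for the residuals.
    """
    import statsmodels.api as sm

    sub = scored[scored["treatment"].isin(["aN", "dN"])].copy()
    d = sub["distance_to_singer"].to_numpy(dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("every neighbour row needs a finite distance_to_singer")
    if len(np.unique(d)) < 2:
        raise ValueError("need at least 2 distinct distances")

    y = sub[score_col].to_numpy(dtype=float)
    exog = sm.add_constant(d)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = sm.MixedLM(y, exog, groups=sub["treatment"].to_numpy())
        try:
            res = md.fit(reml=True)
            slope = float(res.fe_params[1])
            se = float(res.bse_fe[1])
            resid = y - res.fittedvalues
        except (np.linalg.LinAlgError, ValueError):
            slope, se, resid = np.nan, np.nan, None
        if resid is None or not np.isfinite(se):
            # Random-effect variance on the boundary (or degenerate data):
            # collapse to the fixed-effects fit.
            ols = sm.OLS(y, exog).fit()
            slope, se = float(ols.params[1]), float(ols.bse[1])
            resid = ols.resid
    if se > 0 and np.isfinite(se):
        z = slope / se
        fstat = z * z
        p = float(2 * spstats.norm.sf(abs(z)))
    else:
        fstat, p = np.inf, 0.0
    if np.ptp(resid) == 0:
        norm_p = 1.0
    else:
        norm_p = float(spstats.shapiro(resid).pvalue)
    return DistanceEffect(slope, se, fstat, p, norm_p, len(y))
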