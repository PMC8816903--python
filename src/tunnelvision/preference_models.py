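"""Statistical layer linking object photometry to behavioral preference.

Two model families plus the nonparametric comparison workflow:

* all-subsets OLS with AIC selection over the three object descriptors
  (Weber contrast, peak wavelength, brightness), response = mean preference
  index per experiment;
* PCA regression on the 13-bin spectral AUC feature vector, removing the
  strong collinearity of reflectance spectra before an OLS fit, with the
  implied per-band effect reported (in particular for the medium 500-575 nm
  band);
* Kruskal-Wallis omnibus + pairwise Mann-Whitney U with Bonferroni
  correction and a compact letter display, and the one-sample t-test for
  "is the mean PI different from zero". The base tests are delegated to
  scipy; the bespoke content is the workflow.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FEATURES",
    "ModelFit",
    "ModelSelectionResult",
    "fit_all_subsets_aic",
    "PCARegressionResult",
    "pca_spectral_regression",
    "GroupComparison",
    "compare_groups",
    "one_sample_test",
    "feature_table",
]

FEATURES = ("contrast", "peak_wavelength", "brightness")


def feature_table(
    mean_pi: Sequence[float],
    contrast: Sequence[float],
    peak_wavelength: Sequence[float],
    brightness: Sequence[float],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-experiment object feature table (response =
    experiment mean preference index)."""
    df = pd.DataFrame(
        {
            "mean_pi": np.asarray(mean_pi, dtype=float),
            "contrast": np.asarray(contrast, dtype=float),
            "peak_wavelength": np.asarray(peak_wavelength, dtype=float),
            "brightness": np.asarray(brightness, dtype=float),
        }
    )
    if labels is not None:
        df["label"] = list(labels)
    if df["mean_pi"].isna().any():
        raise ValueError("missing response values")
    if not np.all(np.isfinite(df[list(FEATURES)].to_numpy())):
        raise ValueError("non-finite feature values")
    return df


@dataclass
class ModelFit:
    predictors: tuple[str, ...]
    k: int  # number of predictors
    loglik: float
    aic: float
    rss: float
    coef: dict[str, float]


@dataclass
class ModelSelectionResult:
    fits: list[ModelFit]
    best: ModelFit
    delta_aic: pd.DataFrame  # per-model AIC table sorted by AIC

    @property
    def selected_predictors(self) -> tuple[str, ...]:
        return self.best.predictors


def _gaussian_ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, float]:
    """OLS fit; returns (coefficients, RSS, max Gaussian log-likelihood)."""
    n = y.size
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return beta, rss, loglik


def fit_all_subsets_aic(
    table: pd.DataFrame,
    response: str = "mean_pi",
    features: Sequence[str] = FEATURES,
) -> ModelSelectionResult:
    """Fit every predictor subset (including intercept-only) by OLS and rank
    by Gaussian AIC.

    AIC = -2 loglik + 2 (k + 2), counting the intercept, the k slopes and
    the error variance as estimated parameters. Among models within 2 AIC of
    the minimum, the tie is resolved toward fewer predictors (then lower
    AIC), so a predictor must earn its place.
    """
    features = tuple(features)
    n = len(table)
    if n <= len(features) + 2:
        raise ValueError(
            f"need more than {len(features) + 2} rows to fit all subsets, got {n}"
        )
    y = table[response].to_numpy(dtype=float)
    fits: list[ModelFit] = []
    for r in range(len(features) + 1):
        for subset in itertools.combinations(features, r):
            X = np.column_stack(
                [np.ones(n)] + [table[f].to_numpy(dtype=float) for f in subset]
            )
            beta, rss, loglik = _gaussian_ols(y, X)
            k = len(subset)
            aic = -2.0 * loglik + 2.0 * (k + 2)
            coef = {"intercept": float(beta[0])}
            coef.update({f: float(b) for f, b in zip(subset, beta[1:])})
            fits.append(ModelFit(subset, k, loglik, aic, rss, coef))
    best_aic = min(f.aic for f in fits)
    # ties within 2 AIC go to the most parsimonious model
    contenders = [f for f in fits if f.aic - best_aic < 2.0]
    best = min(contenders, key=lambda f: (f.k, f.aic))
    rows = sorted(fits, key=lambda f: f.aic)
    delta = pd.DataFrame(
        {
            "predictors": ["+".join(f.predictors) or "(intercept)" for f in rows],
            "k": [f.k for f in rows],
            "loglik": [f.loglik for f in rows],
            "aic": [f.aic for f in rows],
            "delta_aic": [f.aic - best_aic for f in rows],
        }
    )
    return ModelSelectionResult(fits=fits, best=best, delta_aic=delta)


@dataclass
class PCARegressionResult:
    loadings: np.ndarray  # (n_components, n_bins)
    scores: np.ndarray  # (n_obs, n_components)
    explained_variance_ratio: np.ndarray
    coef: np.ndarray  # regression coefficients on component scores
    intercept: float
    r_squared: float
    band_effect: np.ndarray  # implied d(response)/d(bin) per spectral bin
    bin_edges: np.ndarray

    def band_effect_between(self, lo_nm: float, hi_nm: float) -> float:
        """Summed implied effect of the bins whose span lies in [lo, hi]."""
        lo_edges = self.bin_edges[:-1]
        hi_edges = self.bin_edges[1:]
        mask = (lo_edges >= lo_nm) & (hi_edges <= hi_nm)
        if not mask.any():
            raise ValueError("no spectral bins inside the requested band")
        return float(self.band_effect[mask].sum())


def pca_spectral_regression(
    auc_matrix: np.ndarray,
    response: Sequence[float],
    n_components: int = 2,
    bin_edges: np.ndarray | None = None,
    scale: bool = False,
) -> PCARegressionResult:
    """PCA on the (column-centered) spectral AUC matrix, then OLS of the
    response on the leading component scores.

    ``band_effect`` back-projects the fitted coefficients through the
    loadings, giving the implied effect of each wavelength bin on the
    response; its sign over 500-575 nm is the quantity of biological
    interest (more medium-wavelength content -> lower preference).
    """
    from sklearn.decomposition import PCA

    X = np.asarray(auc_matrix, dtype=float)
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if y.size != n:
        raise ValueError("response length does not match AUC matrix rows")
    if n < n_components + 2:
        raise ValueError("need at least n_components + 2 observations")
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)  # centers columns internally
    if np.linalg.matrix_rank(scores) < n_components:
        raise np.linalg.LinAlgError("requested more components than the data's rank")
    design = np.column_stack([np.ones(n), scores])
    beta, rss, _ = _gaussian_ols(y, design)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    band_effect = pca.components_.T @ beta[1:]
    if scale:
        band_effect = band_effect / sd
    if bin_edges is None:
        bin_edges = 350.0 + 25.0 * np.arange(p + 1)
    return PCARegressionResult(
        loadings=pca.components_,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        coef=beta[1:],
        intercept=float(beta[0]),
        r_squared=r2,
        band_effect=band_effect,
        bin_edges=np.asarray(bin_edges, dtype=float),
    )


@dataclass
class GroupComparison:
    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame  # group_a, group_b, u_statistic, p, p_threshold, significant
    letters: dict[str, str]  # compact letter display
    alpha: float
    n_comparisons: int


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.01,
    correction: str = "bonferroni",
) -> GroupComparison:
    """Kruskal-Wallis omnibus plus pairwise Mann-Whitney U tests with
    Bonferroni-corrected significance threshold, summarized as a compact
    letter display (groups sharing a letter are not significantly
    different)."""
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    names = list(groups)
    stat, p = stats.kruskal(*groups.values())
    pairs = list(itertools.combinations(names, 2))
    if correction == "bonferroni":
        threshold = alpha / len(pairs)
    elif correction == "none":
        threshold = alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    rows = []
    significant_pairs = set()
    for a, b in pairs:
        u, p_ab = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        sig = bool(p_ab < threshold)
        if sig:
            significant_pairs.add((a, b))
        rows.append(
            {"group_a": a, "group_b": b, "u_statistic": float(u),
             "p": float(p_ab), "p_threshold": threshold, "significant": sig}
        )
    letters = _compact_letter_display(names, significant_pairs)
    return GroupComparison(
        omnibus_statistic=float(stat),
        omnibus_p=float(p),
        pairwise=pd.DataFrame(rows),
        letters=letters,
        alpha=alpha,
        n_comparisons=len(pairs),
    )


def _compact_letter_display(
    names: Sequence[str], significant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb letter assignment: groups share a letter iff no
    significant difference separates them within that letter's clique."""
    differ = {frozenset(p) for p in significant_pairs}
    letter_sets: list[set[str]] = []
    for name in names:
        placed = False
        for s in letter_sets:
            if all(frozenset((name, other)) not in differ for other in s):
                s.add(name)
                placed = True
        if not placed:
            letter_sets.append({name})
    # absorb redundant subsets
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, list[str]] = {n: [] for n in names}
    for letter, s in zip(alphabet, letter_sets):
        for n in names:
            if n in s:
                out[n].append(letter)
    return {n: "".join(v) for n, v in out.items()}


def one_sample_test(
    values: Sequence[float], null: float = 0.0, sides: str = "two"
) -> tuple[float, float]:
    """One-sample t-test of the mean against ``null`` (default: is the mean
    preference index different from zero). Returns (t statistic, p)."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 3:
        raise ValueError("need at least 3 values")
    if np.var(vals, ddof=1) == 0:
        raise ValueError("zero variance sample")
    alternative = {"two": "two-sided", "less": "less", "greater": "greater"}[sides]
    res = stats.ttest_1samp(vals, popmean=null, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
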