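"""The adductome statistical layer.

Works on an adduct matrix (curated species x samples, normalized
intensities) joined with sample metadata:

- crude per-tissue adduct loads (summed normalized intensities after
  excluding the dominant epigenetic mark 5-MdC) with integer
  percentage apportionment;
- per-species sex comparisons by two-sided Mann-Whitney U with Storey
  q-value FDR estimation, and significance counts at FDR 10/5/1%;
- per-species one-way ANOVA age trends with Bonferroni-adjusted
  pairwise comparisons and oldest/youngest fold changes;
- Pearson correlation of adduct level against age;
- PCA of log-transformed autoscaled profiles followed by Gaussian
  mixture clustering over several covariance parameterizations, with
  the model selected by BIC (reported in the "larger is better"
  convention of the mclust workflow).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as ss
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

#: species excluded from adduct-load sums by default: the epigenetic
#: mark 5-MdC sits orders of magnitude above every adduct and would
#: swamp the load
DEFAULT_LOAD_EXCLUDE = ("5-MdC",)


def largest_remainder_percents(values: Sequence[float]) -> list[int]:
    """Integer percentages of ``values`` that sum exactly to 100.

    Hamilton (largest-remainder) apportionment: floor each share, then
    hand the leftover points to the largest fractional remainders.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0) or v.sum() <= 0:
        raise ValueError("values must be non-negative with a positive sum")
    shares = 100.0 * v / v.sum()
    floors = np.floor(shares).astype(int)
    remainder = 100 - floors.sum()
    order = np.argsort(-(shares - floors))
    out = floors.copy()
    out[order[:remainder]] += 1
    return out.tolist()


def adduct_load(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    exclude: Sequence[str] = DEFAULT_LOAD_EXCLUDE,
    detection_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-tissue adduct load, species count, and percent of total.

    Load = sum over non-excluded species of the tissue's mean
    normalized intensity. Percentages use largest-remainder rounding so
    they always total 100.
    """
    keep = [s for s in matrix.index if s not in set(exclude)]
    sub = matrix.loc[keep]
    tissue_of = meta.set_index("sample_id")["tissue"]
    tissues = [t for t in meta.tissue.unique() if t != "none"]
    rows = {}
    for t in tissues:
        cols = [c for c in sub.columns if tissue_of.get(c) == t]
        means = sub[cols].mean(axis=1)
        rows[t] = {
            "load": float(means.sum()),
            "n_species": int((means > detection_threshold).sum()),
        }
    out = pd.DataFrame(rows).T
    out["percent"] = largest_remainder_percents(out["load"].to_numpy())
    out["n_species"] = out["n_species"].astype(int)
    return out


def estimate_pi0(
    p_values: Sequence[float], lambdas: Sequence[float] | None = None
) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` is computed on a
    lambda grid (default 0.05..0.95), smoothed with a cubic polynomial
    and read off at the largest lambda, then clipped to (1/m, 1]. Small
    inputs (m < 30) fall back to the conservative pi0 = 1.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    if m < 30 or p.max() < lambdas.min():
        return 1.0
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    return min(max(pi0, 1.0 / m), 1.0)


def q_values(
    p_values: Sequence[float],
    pi0: float | None = None,
    lambdas: Sequence[float] | None = None,
) -> np.ndarray:
    """Storey q-values.

    ``q_(i) = min_{j >= i} pi0 * m * p_(j) / j`` over the ranked
    p-values, with pi0 from :func:`estimate_pi0` unless given.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    if pi0 is None:
        pi0 = estimate_pi0(p, lambdas)
    order = np.argsort(p)
    ranked = p[order]
    q_ranked = pi0 * m * ranked / np.arange(1, m + 1)
    q_ranked = np.minimum.accumulate(q_ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_ranked, 0.0, 1.0)
    return q


def _mwu_p(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0  # constant across all samples: no information, tie warning
    try:
        return float(ss.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)
    except ValueError:
        return 1.0


@dataclass
class SexTestResult:
    table: pd.DataFrame                 # species, n_F, n_M, p, q, fold_change
    significant: dict[float, int]       # FDR threshold -> count

    def __len__(self) -> int:
        return len(self.table)


def sex_tests(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    tissue: str,
    fdr_thresholds: Sequence[float] = (0.10, 0.05, 0.01),
) -> SexTestResult:
    """Per-species female/male Mann-Whitney U tests within one tissue,
    with Storey q-values over the tissue's species."""
    sub = meta[(meta.tissue == tissue) & (meta.sample_type == "hydrolysate")]
    f_ids = list(sub.loc[sub.sex == "F", "sample_id"])
    m_ids = list(sub.loc[sub.sex == "M", "sample_id"])
    if len(f_ids) < 2 or len(m_ids) < 2:
        raise ValueError(f"need >= 2 samples per sex in tissue {tissue!r}")
    rows = []
    for sp in matrix.index:
        x = matrix.loc[sp, f_ids].to_numpy(dtype=float)
        y = matrix.loc[sp, m_ids].to_numpy(dtype=float)
        p = _mwu_p(x, y)
        fc = float(x.mean() / y.mean()) if y.mean() > 0 else np.nan
        rows.append({"species": sp, "n_F": len(x), "n_M": len(y),
                     "p_value": p, "fold_change_F_over_M": fc})
    table = pd.DataFrame(rows).set_index("species")
    table["q_value"] = q_values(table.p_value.to_numpy())
    sig = {thr: int((table.q_value < thr).sum()) for thr in fdr_thresholds}
    return SexTestResult(table=table, significant=sig)


def age_tests(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    tissue: str,
) -> pd.DataFrame:
    """Per-species one-way ANOVA across age groups within one tissue.

    Returns ANOVA F and p, Bonferroni-adjusted pairwise p-values (as a
    dict column keyed by age pair), and the oldest/youngest fold
    change. Species with zero variance everywhere report NaN.
    """
    sub = meta[(meta.tissue == tissue) & (meta.sample_type == "hydrolysate")]
    ages = sorted(sub.age.unique())
    if len(ages) < 2:
        raise ValueError("need >= 2 age groups")
    groups_ids = {a: list(sub.loc[sub.age == a, "sample_id"]) for a in ages}
    if any(len(v) < 2 for v in groups_ids.values()):
        raise ValueError("need >= 2 samples per age group")
    n_pairs = len(ages) * (len(ages) - 1) // 2
    rows = []
    for sp in matrix.index:
        groups = [matrix.loc[sp, ids].to_numpy(dtype=float) for a, ids in groups_ids.items()]
        if all(np.allclose(g, g[0]) for g in groups):
            rows.append({"species": sp, "F": np.nan, "p_value": np.nan,
                         "fold_change": np.nan, "pairwise_p": {}})
            continue
        F, p = ss.f_oneway(*groups)
        pw = {}
        for i in range(len(ages)):
            for j in range(i + 1, len(ages)):
                t = ss.ttest_ind(groups[i], groups[j])
                pw[(ages[i], ages[j])] = min(1.0, float(t.pvalue) * n_pairs)
        young, old = groups[0], groups[-1]
        fc = float(old.mean() / young.mean()) if young.mean() > 0 else np.nan
        rows.append({"species": sp, "F": float(F), "p_value": float(p),
                     "fold_change": fc, "pairwise_p": pw})
    return pd.DataFrame(rows).set_index("species")


def age_correlation(values: Sequence[float], ages: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation of adduct level with age (two-sided t-test p)."""
    x = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return (float("nan"), float("nan"))
    r, p = ss.pearsonr(y, x)
    return float(r), float(p)


#: sklearn covariance parameterizations used as GMM candidates; they
#: emulate the constraint families of the mclust workflow (per-cluster
#: spherical, diagonal, one shared full matrix, per-cluster full)
GMM_COVARIANCE_TYPES = ("spherical", "diag", "tied", "full")


@dataclass
class ClusteringResult:
    scores: np.ndarray                 # samples x n_pcs PCA scores
    cumulative_variance: np.ndarray
    n_components_used: int             # PCs fed to the mixture model
    labels: np.ndarray
    n_clusters: int
    covariance_type: str
    bic_table: pd.DataFrame            # candidate (k, cov_type) -> BIC
    sample_ids: list[str] = field(default_factory=list)


def cluster_profiles(
    matrix: pd.DataFrame,
    variance_threshold: float = 0.80,
    max_clusters: int = 9,
    covariance_types: Sequence[str] = GMM_COVARIANCE_TYPES,
    log_transform: bool = True,
    seed: int = 0,
) -> ClusteringResult:
    """PCA + Gaussian-mixture clustering with BIC model selection.

    Intensities are log10-transformed (pseudocount = half the smallest
    nonzero value) and autoscaled per species; samples are projected
    onto the smallest number of principal components whose cumulative
    explained variance reaches ``variance_threshold``; Gaussian
    mixtures with 1..``max_clusters`` components and each covariance
    parameterization are fitted, and the model maximizing BIC (mclust
    sign convention: higher is better) is returned.
    """
    X = matrix.to_numpy(dtype=float).T  # samples x species
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if log_transform:
        nz = X[X > 0]
        pseudo = nz.min() / 2.0 if len(nz) else 1.0
        X = np.log10(X + pseudo)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd

    n_max = min(X.shape)
    pca = PCA(n_components=n_max, random_state=seed)
    scores = pca.fit_transform(X)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    k_pcs = int(np.searchsorted(cumvar, variance_threshold) + 1)
    k_pcs = min(max(k_pcs, 1), n_max)
    Z = scores[:, :k_pcs]

    records = []
    best = None
    # floor component covariances at 1% of the score variance and use a
    # single k-means-initialized EM run: without both, a component can
    # shrink-wrap a few chance-close points, its likelihood diverges,
    # and BIC favors arbitrarily many clusters
    reg = 1e-2 * float(np.var(Z))
    for k in range(1, min(max_clusters, X.shape[0]) + 1):
        for cov in covariance_types:
            gmm = GaussianMixture(
                n_components=k,
                covariance_type=cov,
                n_init=1,
                random_state=seed,
                reg_covar=reg,
            )
            try:
                gmm.fit(Z)
            except ValueError:
                continue
            bic = -float(gmm.bic(Z))  # mclust convention: larger is better
            records.append({"n_clusters": k, "covariance_type": cov, "bic": bic})
            if best is None or bic > best[0]:
                best = (bic, k, cov, gmm)
    if best is None:
        raise RuntimeError("no mixture model could be fitted")
    _, k_best, cov_best, gmm_best = best
    labels = gmm_best.predict(Z)
    return ClusteringResult(
        scores=scores,
        cumulative_variance=cumvar,
        n_components_used=k_pcs,
        labels=labels,
        n_clusters=k_best,
        covariance_type=cov_best,
        bic_table=pd.DataFrame(records),
        sample_ids=list(matrix.columns),
    )
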