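"""Beta/alpha diversity, PERMANOVA and distance-decay regressions.

PERMANOVA here is the multi-term sequential (Type-I) sum-of-squares
variant on an arbitrary dissimilarity matrix: the matrix is
Gower-centred, each model term's SS is obtained by projection onto the
cumulative design, a pseudo-F is formed against the residual, and p
values come from free permutation of sample labels.  Continuous
covariates, categorical factors and interactions (``"a:b"``) are all
supported, matching the distance-based linear model convention.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity.alpha import faith_pd

from .core_io import CommunityTable

EARTH_RADIUS_KM = 6371.0088


def bray_curtis(table: CommunityTable) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity BC(x,y) = Σ|x−y| / Σ(x+y) on counts."""
    M = table.matrix.astype(float)
    if (M.sum(axis=0) == 0).any():
        raise ValueError("zero-total sample(s) in bray_curtis")
    X = M.T  # samples × taxa
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    out = num / den
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=table.sample_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _encode_single(meta: pd.DataFrame, name: str) -> np.ndarray:
    if name not in meta.columns:
        raise ValueError(f"term {name!r} not in metadata columns")
    col = meta[name]
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(float)[:, None]
    dummies = pd.get_dummies(col, drop_first=True)
    return dummies.to_numpy(float)


def _encode_term(meta: pd.DataFrame, term: str) -> np.ndarray:
    parts = term.split(":")
    blocks = [_encode_single(meta, p) for p in parts]
    X = blocks[0]
    for b in blocks[1:]:
        X = np.einsum("ij,ik->ijk", X, b).reshape(len(meta), -1)
    return X


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def permanova(
    D: pd.DataFrame,
    meta: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Sequential-SS PERMANOVA of a dissimilarity matrix on model terms.

    Terms enter in the order given (Type-I SS, so order matters for
    correlated covariates; total SS is order-invariant).  Returns one row
    per term plus Residual and Total, with Df, SS, R2, F and the
    permutation p value ``(1 + #{F* >= F}) / (n_perm + 1)``.
    """
    ids = list(meta.index)
    D = D.loc[ids, ids]
    G = _gower_center(D.to_numpy(float))
    n = len(ids)
    rng = np.random.default_rng(seed)

    X = np.ones((n, 1))
    hats = [X @ np.linalg.pinv(X)]  # intercept hat
    dfs = []
    rank_prev = 1
    for term in terms:
        X = np.hstack([X, _encode_term(meta, term)])
        rank = np.linalg.matrix_rank(X)
        df = rank - rank_prev
        if df == 0:
            raise ValueError(f"term {term!r} is collinear with earlier terms")
        Q, _ = np.linalg.qr(X)
        Q = Q[:, :rank]
        hats.append(Q @ Q.T)
        dfs.append(df)
        rank_prev = rank
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def term_stats(Gmat):
        tr = np.array([(H * Gmat).sum() for H in hats])
        ss = np.diff(tr)
        ss_total = np.trace(Gmat)
        # clamp float-precision negatives (e.g. a saturated model)
        ss_res = max(ss_total - tr[-1], 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss / np.array(dfs)) / (ss_res / df_res)
        return ss, ss_res, ss_total, F

    ss, ss_res, ss_total, F_obs = term_stats(G)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        Gp = G[np.ix_(p, p)]
        _, _, _, F_perm = term_stats(Gp)
        exceed += F_perm >= F_obs - 1e-12
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    rows = [
        {"term": t, "Df": dfs[k], "SS": ss[k], "R2": ss[k] / ss_total,
         "F": F_obs[k], "p": pvals[k]}
        for k, t in enumerate(terms)
    ]
    rows.append({"term": "Residual", "Df": df_res, "SS": ss_res,
                 "R2": ss_res / ss_total, "F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "Df": n - 1, "SS": ss_total, "R2": 1.0,
                 "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows).set_index("term")


def variance_inflation(meta: pd.DataFrame, terms: list[str]) -> pd.Series:
    """VIF diagnostic for continuous covariates (1/(1−R²) of each on the rest)."""
    X = np.column_stack([meta[t].to_numpy(float) for t in terms])
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    out = {}
    for k, t in enumerate(terms):
        y = X[:, k]
        others = np.delete(X, k, axis=1)
        A = np.hstack([np.ones((len(y), 1)), others])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        r2 = 1.0 - resid @ resid / (y @ y)
        out[t] = 1.0 / (1.0 - r2) if r2 < 1 else np.inf
    return pd.Series(out, name="VIF")


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: CommunityTable, tree=None) -> pd.DataFrame:
    """Richness, Shannon entropy (nats) and optionally Faith PD per sample.

    Faith PD is the total branch length of the rooted subtree spanning the
    sample's taxa, path to the root included.
    """
    M = table.matrix
    rel = M / M.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(rel > 0, rel * np.log(rel), 0.0)
    out = pd.DataFrame({
        "richness": (M > 0).sum(axis=0),
        "shannon": -plogp.sum(axis=0),
    }, index=table.sample_ids)
    if tree is not None:
        taxa = table.taxon_ids
        tips = {t.name for t in tree.tips()}
        missing = [t for t in taxa if t not in tips]
        if missing:
            raise ValueError(f"taxa missing from tree: {missing[:10]}")
        out["faith_pd"] = [
            faith_pd(M[:, i], taxa=taxa, tree=tree) for i in range(M.shape[1])
        ]
    return out


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Uses the exact distribution when min(n) <= 25 and there are no ties,
    otherwise the normal approximation with tie correction.  Identical
    multisets return p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------

def geographic_distance(meta: pd.DataFrame) -> pd.DataFrame:
    """Haversine great-circle distance (km) between sample coordinates."""
    lat = np.radians(meta["latitude"].to_numpy(float))
    lon = np.radians(meta["longitude"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=meta.index, columns=meta.index)


def salinity_distance(meta: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance on z-standardised salinity."""
    s = meta["salinity"].to_numpy(float)
    sd = s.std(ddof=0)
    z = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    d = np.abs(z[:, None] - z[None, :])
    return pd.DataFrame(d, index=meta.index, columns=meta.index)


def distance_decay(
    D_community: pd.DataFrame,
    D_predictor: pd.DataFrame,
    season_of=None,
    pooled: bool = True,
    mantel_permutations: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """OLS fits of community similarity (1 − Bray–Curtis) on a predictor.

    One fit per season stratum (pairs whose two samples share the season)
    plus a pooled fit over all pairs.  Strata with fewer than 3 pairs are
    skipped with a warning.  Pair-level OLS ignores the pseudo-replication
    of pairwise designs, so when ``mantel_permutations > 0`` a Mantel
    permutation p value (matrix-level) is reported alongside the pooled
    fit.
    """
    ids = list(D_community.index)
    Dp = D_predictor.loc[ids, ids]
    pairs = list(itertools.combinations(range(len(ids)), 2))
    sim = np.array([1.0 - D_community.iloc[i, j] for i, j in pairs])
    pred = np.array([Dp.iloc[i, j] for i, j in pairs])
    strata = {}
    if season_of is not None:
        seas = np.array([season_of[s] for s in ids])
        for season in pd.unique(seas):
            mask = np.array([seas[i] == season and seas[j] == season
                             for i, j in pairs])
            strata[season] = mask
    if pooled or not strata:
        strata["all"] = np.ones(len(pairs), bool)
    rows = []
    for name, mask in strata.items():
        if mask.sum() < 3:
            warnings.warn(f"stratum {name!r} has < 3 pairs; skipped")
            continue
        if np.ptp(pred[mask]) == 0:
            warnings.warn(f"stratum {name!r} has a constant predictor; skipped")
            continue
        fit = stats.linregress(pred[mask], sim[mask])
        row = {
            "stratum": name,
            "n_pairs": int(mask.sum()),
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.rvalue**2,
            "p_value": fit.pvalue,
            "mantel_p": np.nan,
        }
        if name == "all" and mantel_permutations > 0:
            from skbio.stats.distance import DistanceMatrix, mantel

            d1 = DistanceMatrix(D_community.loc[ids, ids].to_numpy(), ids)
            d2 = DistanceMatrix(Dp.to_numpy(), ids)
            r, p, _ = mantel(d1, d2, permutations=mantel_permutations,
                             seed=seed)
            row["mantel_p"] = p
        rows.append(row)
    return pd.DataFrame(rows)
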