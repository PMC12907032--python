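"""Phylogenetic and taxonomic null models of community assembly.

For every unordered sample pair the pipeline computes:

* βMNTD — between-community mean nearest-taxon phylogenetic distance
  (abundance-weighted by default),
* βNTI — the z-score of observed βMNTD against a null that shuffles taxon
  labels across the tips of the phylogeny (999 randomisations by default),
* RC_bray — the Raup–Crick metric on Bray–Curtis dissimilarity under a
  null that preserves each sample's richness and read total, drawing taxa
  with probability proportional to occupancy frequency and allocating the
  remaining reads (one per drawn taxon first, so richness is kept)
  proportionally to metacommunity relative abundance.

Pairs are then assigned one of five assembly processes:
βNTI > 2 → heterogeneous selection; βNTI < −2 → homogeneous selection;
otherwise RC_bray > 0.95 → dispersal limitation, RC_bray < −0.95 →
homogenising dispersal, and undominated in between.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_io import CommunityTable

logger = logging.getLogger(__name__)

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)
BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def patristic_matrix(tree: TreeNode, taxa=None) -> pd.DataFrame:
    """Tip-to-tip branch-length distance matrix, ordered like ``taxa``."""
    dm = tree.tip_tip_distances()
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    if taxa is not None:
        missing = [t for t in taxa if t not in df.index]
        if missing:
            raise ValueError(f"taxa missing from tree: {missing[:10]}"
                             + ("..." if len(missing) > 10 else ""))
        df = df.loc[list(taxa), list(taxa)]
    return df


def beta_mntd(x: np.ndarray, y: np.ndarray, D: np.ndarray,
              weighted: bool = True) -> float:
    """βMNTD between two community count/abundance vectors.

    Mean over taxa present in ``x`` of the minimum patristic distance to
    any taxon present in ``y``, and symmetrically, averaged.  When
    ``weighted``, each taxon's term is weighted by its relative abundance
    within its own community.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ix = np.flatnonzero(x > 0)
    iy = np.flatnonzero(y > 0)
    if len(ix) == 0 or len(iy) == 0:
        raise ValueError("empty community in beta_mntd")
    sub = D[np.ix_(ix, iy)]
    dmin_x = sub.min(axis=1)
    dmin_y = sub.min(axis=0)
    if weighted:
        fx = x[ix] / x[ix].sum()
        fy = y[iy] / y[iy].sum()
        return 0.5 * (float(fx @ dmin_x) + float(fy @ dmin_y))
    return 0.5 * (float(dmin_x.mean()) + float(dmin_y.mean()))


def beta_mntd_matrix(table: CommunityTable, D: pd.DataFrame,
                     weighted: bool = True) -> pd.DataFrame:
    """Pairwise βMNTD for all sample pairs."""
    Dm = D.loc[table.taxon_ids, table.taxon_ids].to_numpy()
    M = table.matrix.astype(float)
    ids = table.sample_ids
    n = len(ids)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        out[i, j] = out[j, i] = beta_mntd(M[:, i], M[:, j], Dm, weighted)
    return pd.DataFrame(out, index=ids, columns=ids)


def _pair_arrays(M: np.ndarray, weighted: bool):
    """Pre-computed per-sample presence indices and weights."""
    idx, wts = [], []
    for i in range(M.shape[1]):
        ii = np.flatnonzero(M[:, i] > 0)
        if len(ii) == 0:
            raise ValueError(f"sample column {i} is empty")
        idx.append(ii)
        wts.append(M[ii, i] / M[ii, i].sum() if weighted
                   else np.full(len(ii), 1.0 / len(ii)))
    return idx, wts


def _all_pairs_bmntd(Dm: np.ndarray, idx, wts, pairs):
    vals = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        sub = Dm[np.ix_(idx[i], idx[j])]
        vals[k] = 0.5 * (wts[i] @ sub.min(axis=1) + wts[j] @ sub.min(axis=0))
    return vals


def _bmntd_square(Dm: np.ndarray, idx, W: np.ndarray) -> np.ndarray:
    """All-pairs βMNTD as a square matrix in O(samples · taxa · richness).

    ``W`` is the dense (samples × taxa) weight matrix (relative abundance
    over present taxa, or 1/richness when unweighted).  For each sample j
    the vector ``dmin_j[t] = min over taxa present in j of D[t, ·]`` is
    computed once; the directional term from i to j is then the inner
    product ``W[i] · dmin_j``, and βMNTD is the symmetrised average.
    """
    n = W.shape[0]
    dmin = np.empty((n, Dm.shape[0]))
    for j in range(n):
        dmin[j] = Dm[:, idx[j]].min(axis=1)
    A = W @ dmin.T  # A[i, j] = sum_t W[i, t] * dmin_j[t]
    return 0.5 * (A + A.T)


def beta_nti(
    table: CommunityTable,
    tree: TreeNode,
    n_null: int = 999,
    weighted: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise βNTI matrix.

    The null shuffles taxon labels across the tips of the patristic
    distance matrix (taxa swap positions on the phylogeny; abundances are
    untouched) and recomputes βMNTD per pair per randomisation.  Pairs
    with zero null standard deviation yield NaN with a warning.
    """
    tab = table.drop_empty_taxa()
    D = patristic_matrix(tree, tab.taxon_ids)
    Dm = D.to_numpy()
    M = tab.matrix.astype(float)
    rng = np.random.default_rng(seed)
    n = M.shape[1]
    n_taxa = Dm.shape[0]
    idx, wts = _pair_arrays(M, weighted)
    W = np.zeros((n, n_taxa))
    for i in range(n):
        W[i, idx[i]] = wts[i]
    obs = _bmntd_square(Dm, idx, W)
    s1 = np.zeros((n, n))
    s2 = np.zeros((n, n))
    for _ in range(n_null):
        p = rng.permutation(n_taxa)
        Dp = Dm[np.ix_(p, p)]
        v = _bmntd_square(Dp, idx, W)
        s1 += v
        s2 += v * v
    mean = s1 / n_null
    var = s2 / n_null - mean**2
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mean) / sd
    np.fill_diagonal(z, 0.0)
    iu = np.triu_indices(n, 1)
    degenerate = sd[iu] == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} pair(s) with zero null sd; "
                      "βNTI set to NaN")
        z[sd == 0] = np.nan
        np.fill_diagonal(z, 0.0)
    return pd.DataFrame(z, index=tab.sample_ids, columns=tab.sample_ids)


def _null_sample_draws(rng, n_null, richness, reads, occ_freq, metacom):
    """Null communities for one sample: (n_null, n_taxa) count matrix.

    Taxa are drawn without replacement with probability proportional to
    occupancy frequency until the sample's richness is met (Gumbel top-k,
    equivalent to successive weighted sampling); each drawn taxon receives
    one read (so observed richness is preserved exactly) and the remaining
    reads are allocated multinomially with probability proportional to
    metacommunity relative abundance restricted to the drawn taxa.
    """
    S = len(occ_freq)
    logw = np.full(S, -np.inf)
    logw[occ_freq > 0] = np.log(occ_freq[occ_freq > 0])
    keys = rng.gumbel(size=(n_null, S)) + logw
    chosen = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    out = np.zeros((n_null, S), dtype=np.int64)
    for r in range(n_null):
        sel = chosen[r]
        p = metacom[sel]
        tot = p.sum()
        p = p / tot if tot > 0 else np.full(len(sel), 1.0 / len(sel))
        out[r, sel] = 1 + rng.multinomial(reads - richness, p)
    return out


def raup_crick_bray(table: CommunityTable, n_null: int = 999,
                    seed: int = 0) -> pd.DataFrame:
    """Pairwise RC_bray matrix in [−1, 1].

    RC_bray = 2·[#(null BC < obs BC) + ½·#(null BC = obs BC)]/n_null − 1,
    so values near +1 mean the two communities are less similar than the
    null expects (dispersal limitation) and values near −1 more similar
    (homogenising dispersal).
    """
    tab = table.drop_empty_taxa()
    M = tab.matrix
    if (M.sum(axis=0) == 0).any():
        raise ValueError("zero-read sample in raup_crick_bray")
    rng = np.random.default_rng(seed)
    n_taxa, n = M.shape
    occ_freq = (M > 0).sum(axis=1).astype(float)
    metacom = M.sum(axis=1).astype(float)
    metacom = metacom / metacom.sum()
    richness = (M > 0).sum(axis=0)
    reads = M.sum(axis=0)
    nulls = [
        _null_sample_draws(rng, n_null, int(richness[i]), int(reads[i]),
                           occ_freq, metacom)
        for i in range(n)
    ]
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        x, y = M[:, i].astype(float), M[:, j].astype(float)
        obs = np.abs(x - y).sum() / (x + y).sum()
        a, b = nulls[i].astype(float), nulls[j].astype(float)
        null_bc = np.abs(a - b).sum(axis=1) / (a + b).sum(axis=1)
        less = (null_bc < obs - 1e-12).sum()
        equal = (np.abs(null_bc - obs) <= 1e-12).sum()
        rc = 2.0 * ((less + 0.5 * equal) / n_null) - 1.0
        out[i, j] = out[j, i] = rc
    return pd.DataFrame(out, index=tab.sample_ids, columns=tab.sample_ids)


def classify_process(beta_nti_value: float, rc_bray_value: float) -> str:
    """Five-way assembly process from (βNTI, RC_bray); βNTI takes precedence."""
    if np.isnan(beta_nti_value) or np.isnan(rc_bray_value):
        return "unclassified"
    if beta_nti_value > BNTI_THRESHOLD:
        return "heterogeneous_selection"
    if beta_nti_value < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc_bray_value > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_bray_value < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "undominated"


def pairwise_assembly(
    table: CommunityTable,
    tree: TreeNode,
    n_null: int = 999,
    weighted: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-pair βMNTD, βNTI, RC_bray and assigned process (long format)."""
    ss = np.random.SeedSequence(seed).spawn(2)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    tab = table.drop_empty_taxa()
    D = patristic_matrix(tree, tab.taxon_ids)
    bm = beta_mntd_matrix(tab, D, weighted)
    z = beta_nti(tab, tree, n_null=n_null, weighted=weighted, seed=seeds[0])
    rc = raup_crick_bray(tab, n_null=n_null, seed=seeds[1])
    rows = []
    ids = tab.sample_ids
    for i, j in itertools.combinations(range(len(ids)), 2):
        a, b = ids[i], ids[j]
        rows.append({
            "sample_1": a,
            "sample_2": b,
            "beta_mntd": bm.loc[a, b],
            "beta_nti": z.loc[a, b],
            "rc_bray": rc.loc[a, b],
            "process": classify_process(z.loc[a, b], rc.loc[a, b]),
        })
    return pd.DataFrame(rows)


def summarize_processes(pairs: pd.DataFrame, meta: pd.DataFrame | None = None,
                        group_by: str = "all") -> pd.DataFrame:
    """Per-group fractions of assembly processes.

    ``group_by`` is ``"all"``, ``"salinity_category"`` or ``"site"``;
    grouped summaries use only pairs whose two samples share the group
    value (mixed pairs have no single category).  Empty groups are
    omitted with a warning.
    """
    if group_by == "all":
        groups = {"all": pairs}
    else:
        if meta is None:
            raise ValueError("meta required for grouped summaries")
        col = meta[group_by]
        g1 = pairs["sample_1"].map(col)
        g2 = pairs["sample_2"].map(col)
        same = pairs[g1 == g2]
        groups = {k: v for k, v in same.groupby(g1[g1 == g2])}
        for val in col.unique():
            if val not in groups:
                warnings.warn(f"no within-group pairs for {group_by}={val!r}; omitted")
    rows = []
    for key, sub in groups.items():
        counts = sub["process"].value_counts()
        total = counts.sum()
        for proc in PROCESSES:
            rows.append({"group": key, "process": proc,
                         "fraction": counts.get(proc, 0) / total if total else np.nan,
                         "n_pairs": int(total)})
    return pd.DataFrame(rows)
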