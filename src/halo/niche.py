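"""Niche-breadth indices and generalist/specialist classification.

Each taxon's habitat use is summarised by three indices computed from its
proportional read distribution ``p_i`` over environments (default: every
sample is its own environment; salinity categories are available as a
coarser grouping):

* Levins' niche width ``B_n = 1 / (R · Σ p_i²)`` with ``R`` environments,
  bounded in ``[1/R, 1]`` (1 = perfectly even habitat use),
* occurrence — the number of environments with reads,
* habitat Shannon entropy ``−Σ p_i ln p_i`` (nats).

Observed indices are compared to a permutation null that redistributes
each taxon's total reads across samples by a multinomial with
probabilities proportional to sample totals (taxon totals preserved
exactly, expected sample totals preserved).  A taxon is called a
generalist when its observed index exceeds the null 95% interval, a
specialist when it falls below, and non-significant otherwise; the
default "triple" mode requires all three indices to deviate in the same
direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CommunityTable

logger = logging.getLogger(__name__)

INDEX_NAMES = ("bn", "occurrence", "shannon")
LABELS = ("generalist", "specialist", "non_significant")


def _environment_matrix(table: CommunityTable, environment_of) -> tuple[np.ndarray, list]:
    """Aggregate counts (taxa × samples) into (taxa × environments)."""
    if environment_of is None or len(environment_of) == 0:
        raise ValueError("empty environment map")
    envs = []
    for s in table.sample_ids:
        if s not in environment_of:
            raise ValueError(f"sample {s!r} missing from environment map")
        envs.append(environment_of[s])
    env_index = pd.Index(envs, name="environment")
    agg = table.counts.T.groupby(env_index, sort=True).sum().T
    return agg.to_numpy(dtype=float), list(agg.columns)


def _indices_from_env_counts(env_counts: np.ndarray) -> np.ndarray:
    """Stacked (taxa, 3) array of (B_n, occurrence, shannon).

    ``env_counts`` may carry a leading batch axis (permutations).
    Zero-total taxa yield NaN rows.
    """
    total = env_counts.sum(axis=-1, keepdims=True)
    R = env_counts.shape[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = env_counts / total
        sum_p2 = (p**2).sum(axis=-1)
        bn = 1.0 / (R * sum_p2)
        occ = (env_counts > 0).sum(axis=-1).astype(float)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
        shannon = -plogp.sum(axis=-1)
    out = np.stack([bn, occ, shannon], axis=-1)
    out[np.squeeze(total, axis=-1) == 0] = np.nan
    return out


def niche_indices(table: CommunityTable, environment_of) -> pd.DataFrame:
    """Observed per-taxon niche indices.

    Zero-total taxa are excluded with a logged notice.  Warns when samples
    are not at equal depth (indices are depth-sensitive; rarefy first).
    """
    totals = table.sample_totals
    if totals.nunique() > 1:
        logger.warning("samples are not at equal depth; consider rarefying "
                       "before computing niche indices")
    env_counts, _ = _environment_matrix(table, environment_of)
    vals = _indices_from_env_counts(env_counts)
    df = pd.DataFrame(vals, index=table.counts.index.copy(), columns=INDEX_NAMES)
    empty = df.index[df["bn"].isna()]
    if len(empty):
        logger.info("excluding %d zero-total taxa from niche indices", len(empty))
        df = df.drop(index=empty)
    df["occurrence"] = df["occurrence"].astype(int)
    return df


@dataclass
class NullIndexDistributions:
    """Per-taxon null distributions of the three indices.

    ``values`` has shape (n_taxa, n_perm, 3) in INDEX_NAMES order.
    """

    taxon_ids: list
    values: np.ndarray

    def quantiles(self, alpha: float = 0.05) -> pd.DataFrame:
        lo = np.nanquantile(self.values, alpha / 2.0, axis=1)
        hi = np.nanquantile(self.values, 1.0 - alpha / 2.0, axis=1)
        cols = {}
        for k, name in enumerate(INDEX_NAMES):
            cols[f"{name}_null_low"] = lo[:, k]
            cols[f"{name}_null_high"] = hi[:, k]
        return pd.DataFrame(cols, index=pd.Index(self.taxon_ids, name="taxon_id"))

    def mean(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.mean(axis=1),
                            index=pd.Index(self.taxon_ids, name="taxon_id"),
                            columns=[f"{n}_null_mean" for n in INDEX_NAMES])


def _fixed_fixed_tables(counts: np.ndarray, n_perm: int, rng):
    """Exact fixed-fixed null: random tables with both margins preserved.

    Samples from the multivariate hypergeometric (Fisher) distribution of
    contingency tables with the observed row and column sums, via
    Patefield's algorithm (sensitivity alternative to the multinomial
    redistribution null).
    """
    from scipy.stats import random_table

    dist = random_table(counts.sum(axis=1), counts.sum(axis=0))
    for _ in range(n_perm):
        yield dist.rvs(random_state=rng)


def permutation_null(
    table: CommunityTable,
    environment_of,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "multinomial",
    chunk: int = 200,
) -> NullIndexDistributions:
    """Null distributions of the niche indices under read redistribution.

    The default scheme redistributes every taxon's total reads across
    samples by a multinomial with probabilities proportional to sample
    totals; ``scheme="swap"`` draws exact fixed-fixed tables (both margins
    preserved, Patefield sampling) instead, for sensitivity analysis.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    counts = table.matrix
    keep = counts.sum(axis=1) > 0
    counts = counts[keep]
    taxon_ids = [t for t, k in zip(table.taxon_ids, keep) if k]
    sub = CommunityTable(pd.DataFrame(counts, index=taxon_ids,
                                      columns=table.sample_ids))
    _, env_names = _environment_matrix(sub, environment_of)
    env_labels = np.array([environment_of[s] for s in table.sample_ids])
    env_pos = {e: i for i, e in enumerate(env_names)}
    env_idx = np.array([env_pos[e] for e in env_labels])
    n_env = len(env_names)

    totals = counts.sum(axis=1)
    sample_tot = counts.sum(axis=0).astype(float)
    pvals = sample_tot / sample_tot.sum()
    n_taxa, n_samples = counts.shape
    out = np.empty((n_taxa, n_perm, 3))

    if scheme == "multinomial":
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            # draw b permutations for every taxon at once
            draws = rng.multinomial(np.repeat(totals, b), pvals)
            draws = draws.reshape(n_taxa, b, n_samples)
            env_counts = np.zeros((n_taxa, b, n_env))
            np.add.at(env_counts.transpose(2, 0, 1), env_idx,
                      draws.transpose(2, 0, 1))
            out[:, done:done + b, :] = _indices_from_env_counts(env_counts)
            done += b
    elif scheme == "swap":
        for r, tab in enumerate(_fixed_fixed_tables(counts, n_perm, rng)):
            env_counts = np.zeros((n_taxa, n_env))
            np.add.at(env_counts.T, env_idx, tab.T.astype(float))
            out[:, r, :] = _indices_from_env_counts(env_counts)
    else:
        raise ValueError(f"unknown null scheme {scheme!r}")
    return NullIndexDistributions(taxon_ids, out)


def classify_taxa(
    observed: pd.DataFrame,
    null: NullIndexDistributions,
    alpha: float = 0.05,
    mode: str = "triple",
) -> pd.DataFrame:
    """Label taxa generalist / specialist / non_significant.

    ``mode="bn_only"`` applies the Levins rule alone (B_n above the null
    95% interval → generalist; below → specialist).  The default
    ``"triple"`` additionally requires occurrence and habitat Shannon to
    deviate in the same direction from their own intervals.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if mode not in ("bn_only", "triple"):
        raise ValueError(f"unknown mode {mode!r}")
    if set(observed.index) != set(null.taxon_ids):
        raise ValueError("observed and null must cover identical taxa")
    obs = observed.loc[null.taxon_ids]
    q = null.quantiles(alpha)
    profile = obs.join(q)
    above = np.column_stack([
        profile[name].to_numpy() > profile[f"{name}_null_high"].to_numpy()
        for name in INDEX_NAMES])
    below = np.column_stack([
        profile[name].to_numpy() < profile[f"{name}_null_low"].to_numpy()
        for name in INDEX_NAMES])
    if mode == "bn_only":
        gen = above[:, 0]
        spec = below[:, 0]
    else:
        gen = above.all(axis=1)
        spec = below.all(axis=1)
    label = np.where(gen, "generalist", np.where(spec, "specialist",
                                                 "non_significant"))
    profile["label"] = label
    return profile


def propagate_labels(asv_taxonomy: pd.DataFrame, genus_profile: pd.DataFrame,
                     rank: str = "genus") -> pd.Series:
    """Join genus-level labels back onto finer-grained taxa (a table join)."""
    mapping = genus_profile["label"]
    return asv_taxonomy[rank].map(mapping).fillna("non_significant")
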