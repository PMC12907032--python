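import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from halo.assembly import (beta_mntd, beta_mntd_matrix, beta_nti,
                           classify_process, pairwise_assembly,
                           patristic_matrix, raup_crick_bray,
                           summarize_processes)
from halo.core_io import CommunityTable, write_count_table, write_tree
from halo.synthetic import simulate_dataset, simulate_tree


def naive_beta_mntd(x, y, D, weighted=True):
    """Independent explicit-loop βMNTD for oracle comparisons."""
    ix = [i for i in range(len(x)) if x[i] > 0]
    iy = [j for j in range(len(y)) if y[j] > 0]
    dx = [min(D[i][j] for j in iy) for i in ix]
    dy = [min(D[i][j] for i in ix) for j in iy]
    if weighted:
        wx = [x[i] / sum(x[i] for i in ix) for i in ix]
        wy = [y[j] / sum(y[j] for j in iy) for j in iy]
        return 0.5 * (sum(w * d for w, d in zip(wx, dx))
                      + sum(w * d for w, d in zip(wy, dy)))
    return 0.5 * (sum(dx) / len(dx) + sum(dy) / len(dy))


class TestPatristic:
    def test_cherry(self, cherry_tree):
        D = patristic_matrix(cherry_tree)
        assert D.loc["A", "B"] == pytest.approx(2.0)

    def test_three_taxa(self, small_tree):
        D = patristic_matrix(small_tree)
        assert D.loc["A", "C"] == pytest.approx(4.0)

    def test_missing_taxon_errors(self, small_tree):
        with pytest.raises(ValueError, match="missing"):
            patristic_matrix(small_tree, ["A", "Z"])

    def test_matches_independent_implementation(self):
        """Random 20-tip tree: matrix equals dendropy's patristic distances."""
        import io as _io

        import dendropy

        tree = simulate_tree(20, seed=9)
        buf = _io.StringIO()
        tree.write(buf)
        dt = dendropy.Tree.get(data=buf.getvalue(), schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        D = patristic_matrix(tree)
        for a in dt.taxon_namespace:
            for b in dt.taxon_namespace:
                assert D.loc[a.label, b.label] == pytest.approx(
                    pdm.patristic_distance(a, b), abs=1e-9)


class TestBetaMNTD:
    def test_identical_communities_zero(self, small_tree):
        D = patristic_matrix(small_tree).to_numpy()
        assert beta_mntd([1, 2, 3], [1, 2, 3], D) == pytest.approx(0.0)

    def test_disjoint_cherry(self, cherry_tree):
        D = patristic_matrix(cherry_tree).to_numpy()
        assert beta_mntd([1, 0], [0, 1], D) == pytest.approx(2.0)

    def test_empty_community_errors(self, cherry_tree):
        D = patristic_matrix(cherry_tree).to_numpy()
        with pytest.raises(ValueError):
            beta_mntd([0, 0], [1, 1], D)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_bruteforce_scan(self, rng, weighted):
        tree = simulate_tree(6, seed=3)
        D = patristic_matrix(tree)
        x = rng.integers(0, 5, 6)
        y = rng.integers(0, 5, 6)
        x[0] += 1
        y[-1] += 1
        ours = beta_mntd(x, y, D.to_numpy(), weighted)
        assert ours == pytest.approx(
            naive_beta_mntd(list(x), list(y), D.to_numpy().tolist(), weighted))

    def test_weighted_matches_picante(self, rng, tmp_path):
        """Abundance-weighted βMNTD equals picante::comdistnt on a random
        8-taxon, 4-sample instance (independent R oracle)."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the picante oracle")
        tree = simulate_tree(8, seed=2)
        counts = rng.integers(0, 9, size=(8, 4))
        counts[:, 0] += 1
        counts[0, :] += 1
        taxa = [t.name for t in tree.tips()]
        tab = CommunityTable(pd.DataFrame(counts, index=taxa,
                                          columns=list("wxyz")))
        write_count_table(tab, tmp_path / "tab.tsv")
        write_tree(tree, tmp_path / "tree.nwk")
        rscript = f"""
        suppressMessages(library(picante))
        tab <- as.matrix(read.table("{tmp_path}/tab.tsv", header=TRUE,
                                    row.names=1, sep="\\t"))
        tree <- read.tree("{tmp_path}/tree.nwk")
        d <- comdistnt(t(tab), cophenetic(tree), abundance.weighted=TRUE)
        cat(as.vector(d), sep="\\n")
        """
        res = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, check=True)
        oracle = [float(v) for v in res.stdout.split()]
        ours = beta_mntd_matrix(tab, patristic_matrix(tree, taxa))
        flat = [ours.iloc[j, i] for i, j in itertools.combinations(range(4), 2)]
        assert np.allclose(flat, oracle, atol=1e-6)


class TestBetaNTI:
    def test_identical_samples_degenerate_null(self):
        """Identical taxon sets give obs βMNTD = 0 and a degenerate null
        (every shuffle also gives 0), reported as NaN with a warning."""
        tree = simulate_tree(10, seed=1)
        taxa = [t.name for t in tree.tips()]
        col = np.arange(1, 11)
        tab = CommunityTable(pd.DataFrame({"a": col, "b": col}, index=taxa))
        with pytest.warns(UserWarning, match="zero null sd"):
            z = beta_nti(tab, tree, n_null=99, seed=0)
        assert np.isnan(z.loc["a", "b"])

    def test_sister_taxon_turnover_forces_negative_sign(self):
        """Two samples sharing a taxon set except for the globally closest
        tip pair (sample a holds one, sample b the other): the observed
        unshared distance is the tree's minimum, so no null shuffle can
        fall below it and βNTI < 0."""
        tree = simulate_tree(30, seed=1)
        taxa = [t.name for t in tree.tips()]
        D = patristic_matrix(tree).loc[taxa, taxa].to_numpy()
        off = D + np.eye(30) * D.max()
        u, v = np.unravel_index(np.argmin(off), off.shape)
        cherry = (taxa[u], taxa[v])  # globally closest tip pair
        pos = {t: k for k, t in enumerate(taxa)}
        shared = [t for t in taxa if t not in cherry][:10]
        a = np.zeros(30, int)
        b = np.zeros(30, int)
        c = np.zeros(30, int)
        a[[pos[t] for t in shared]] = 5
        b[[pos[t] for t in shared]] = 5
        a[pos[cherry[0]]] = 5
        b[pos[cherry[1]]] = 5
        c[:] = 1  # holds the full null pool
        tab = CommunityTable(pd.DataFrame({"a": a, "b": b, "c": c}, index=taxa))
        z = beta_nti(tab, tree, n_null=199, seed=0)
        assert z.loc["a", "b"] < 0

    def test_invariant_to_branch_rescaling(self):
        tree = simulate_tree(12, seed=4)
        taxa = [t.name for t in tree.tips()]
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 6, size=(12, 5))
        counts[0] += 1
        tab = CommunityTable(pd.DataFrame(
            counts, index=taxa, columns=[f"s{i}" for i in range(5)]))
        z1 = beta_nti(tab, tree, n_null=199, seed=3)
        scaled = tree.copy()
        for node in scaled.traverse(include_self=False):
            node.length = (node.length or 0.0) * 7.5
        z2 = beta_nti(tab, scaled, n_null=199, seed=3)
        assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)

    def test_matches_naive_null_reimplementation(self):
        """βNTI within 0.05 of an explicit-loop null re-implementation."""
        tree = simulate_tree(8, seed=7)
        taxa = [t.name for t in tree.tips()]
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 8, size=(8, 4))
        counts[0] += 1
        tab = CommunityTable(pd.DataFrame(
            counts, index=taxa, columns=[f"s{i}" for i in range(4)]))
        n_null = 4000
        ours = beta_nti(tab, tree, n_null=n_null, seed=5)

        D = patristic_matrix(tree, taxa).to_numpy()
        M = counts.astype(float)
        rng_o = np.random.default_rng(12345)
        pairs = list(itertools.combinations(range(4), 2))
        obs = [naive_beta_mntd(M[:, i], M[:, j], D) for i, j in pairs]
        nulls = {p: [] for p in pairs}
        for _ in range(n_null):
            perm = rng_o.permutation(8)
            Dp = D[np.ix_(perm, perm)]
            for p in pairs:
                nulls[p].append(naive_beta_mntd(M[:, p[0]], M[:, p[1]], Dp))
        for k, p in enumerate(pairs):
            z_o = (obs[k] - np.mean(nulls[p])) / np.std(nulls[p])
            assert abs(ours.iloc[p[0], p[1]] - z_o) < 0.05


class TestRaupCrick:
    def test_identical_rich_samples_hit_lower_bound(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 50, 20)
        tab = CommunityTable(pd.DataFrame(
            {"a": col, "b": col}, index=[f"t{i}" for i in range(20)]))
        rc = raup_crick_bray(tab, n_null=199, seed=1)
        assert rc.loc["a", "b"] == pytest.approx(-1.0)

    def test_disjoint_samples_hit_upper_bound(self):
        # 10+10 disjoint taxa of 20: null assemblies overlap almost surely,
        # so the observed BC of 1 exceeds every null value
        a = np.r_[np.full(10, 30), np.zeros(10, int)]
        b = np.r_[np.zeros(10, int), np.full(10, 30)]
        tab = CommunityTable(pd.DataFrame(
            {"a": a, "b": b}, index=[f"t{i}" for i in range(20)]))
        rc = raup_crick_bray(tab, n_null=199, seed=1)
        assert rc.loc["a", "b"] == pytest.approx(1.0)

    def test_relabeling_invariance_distributional(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 10, size=(12, 3))
        counts[:, 0] += 1
        counts[0] += 1
        tab1 = CommunityTable(pd.DataFrame(
            counts, index=[f"t{i}" for i in range(12)], columns=list("abc")))
        perm = rng.permutation(12)
        tab2 = CommunityTable(pd.DataFrame(
            counts[perm], index=[f"t{i}" for i in range(12)],
            columns=list("abc")))
        rc1 = raup_crick_bray(tab1, n_null=4000, seed=3)
        rc2 = raup_crick_bray(tab2, n_null=4000, seed=4)
        assert np.abs(rc1.to_numpy() - rc2.to_numpy()).max() < 0.1

    def test_zero_read_sample_errors(self):
        tab = CommunityTable(pd.DataFrame({"a": [1], "b": [0]}, index=["t"]))
        with pytest.raises(ValueError):
            raup_crick_bray(tab, n_null=100, seed=0)


GRID_CASES = [
    (2.5, 0.0, "heterogeneous_selection"),
    (3.0, -1.0, "heterogeneous_selection"),
    (-2.5, 0.99, "homogeneous_selection"),  # βNTI takes precedence
    (-2.1, 0.0, "homogeneous_selection"),
    (0.3, 0.97, "dispersal_limitation"),
    (1.9, 0.96, "dispersal_limitation"),
    (0.0, -0.97, "homogenizing_dispersal"),
    (-1.9, -0.99, "homogenizing_dispersal"),
    (0.3, 0.0, "undominated"),
    (2.0, 0.95, "undominated"),    # thresholds are strict
    (-2.0, -0.95, "undominated"),
]


@pytest.mark.parametrize("z,rc,expected", GRID_CASES)
def test_process_thresholds(z, rc, expected):
    assert classify_process(z, rc) == expected


def test_process_nan_is_unclassified():
    assert classify_process(float("nan"), 0.0) == "unclassified"


class TestSummaries:
    def pairs(self):
        return pd.DataFrame({
            "sample_1": ["a", "a", "b"],
            "sample_2": ["b", "c", "c"],
            "process": ["homogeneous_selection"] * 3,
        })

    def test_single_process_fraction_one(self):
        out = summarize_processes(self.pairs())
        hs = out[out["process"] == "homogeneous_selection"]["fraction"].iloc[0]
        assert hs == 1.0

    def test_fractions_sum_to_one_per_group(self):
        table, tree, meta, _, _ = simulate_dataset(
            n_taxa=40, n_sites=6, n_seasons=1, library_size=1500, seed=5)
        pairs = pairwise_assembly(table, tree, n_null=49, seed=1)
        out = summarize_processes(pairs, meta=meta, group_by="salinity_category")
        sums = out.groupby("group")["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_cross_category_pairs_excluded(self):
        meta = pd.DataFrame({"salinity_category": ["low", "high", "high"]},
                            index=["a", "b", "c"])
        out = summarize_processes(self.pairs(), meta=meta,
                                  group_by="salinity_category")
        n = out.groupby("group")["n_pairs"].first()
        assert "low" not in n.index       # no within-low pair
        assert n["high"] == 1             # only (b, c)


class TestGenerativeExpectations:
    def test_strong_filtering_gives_negative_bnti_at_high_salinity(self):
        """w=0 with conserved narrow niches: within-high-salinity pairs are
        phylogenetically clustered (median βNTI < −2 over seeds)."""
        medians = []
        for seed in range(10):
            table, tree, meta, _, _ = simulate_dataset(
                n_taxa=1200, n_sites=9, n_seasons=1, n_replicates=1,
                library_size=4000, w=0.0, frac_generalist=0.0,
                seed=seed, sigma_specialist=6.0, sigma_jitter=0.05)
            # full table: the null pool is every taxon in the analysed table
            z = beta_nti(table, tree, n_null=299, seed=seed)
            high = meta.index[meta["salinity_category"] == "high"]
            block = z.loc[high, high].to_numpy()
            iu = np.triu_indices(len(high), 1)
            medians.append(np.median(block[iu]))
        assert np.median(medians) < -2
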