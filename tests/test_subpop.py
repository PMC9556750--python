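"""Binarized biclustering, nested cuts, AC-fraction continuous model."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

import scpcnet as s
from scpcnet.subpop import _binary_distance, linkage_to_newick


def _adata(counts, region=None, genes=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    genes = genes or [f"G{j}" for j in range(g)]
    obs = pd.DataFrame(
        {
            "sample": ["S1"] * n,
            "patient": ["P1"] * n,
            "region": region or ["AC"] * n,
        },
        index=[f"c{i}" for i in range(n)],
    )
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    return ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)


class TestBinarize:
    def test_threshold_two(self):
        adata = _adata([[0, 1], [2, 3]])
        B = s.binarize(adata, ["G0", "G1"])
        assert B.to_numpy().tolist() == [[False, False], [True, True]]

    def test_all_zero_matrix_all_off(self):
        B = s.binarize(_adata(np.zeros((4, 3), int)), ["G0", "G1", "G2"])
        assert not B.to_numpy().any()

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, (20, 20))
        genes = [f"G{j}" for j in range(20)]
        B = s.binarize(_adata(counts), genes, threshold=2)
        assert np.array_equal(B.to_numpy(), counts >= 2)

    def test_missing_gene_named(self):
        with pytest.raises(KeyError, match="NOPE"):
            s.binarize(_adata(np.zeros((2, 2), int)), ["G0", "NOPE"])


class TestBinaryDistance:
    def test_enumerated_example(self):
        # (1,0,1) vs (0,1,1): 1 both-on, 2 discordant -> d = 2/3
        B = np.array([[1, 0, 1], [0, 1, 1]], dtype=bool)
        assert _binary_distance(B)[0] == pytest.approx(2 / 3)

    def test_identical_vectors_distance_zero_and_merge_first(self):
        B = pd.DataFrame(
            np.array(
                [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0]],
                dtype=bool,
            ),
            index=list("abcd"),
            columns=list("wxyz"),
        )
        res = s.bicluster(B)
        first_merge = res.cell_linkage[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
        assert first_merge[2] == 0.0

    def test_all_off_pair_distance_zero(self):
        B = np.zeros((2, 3), dtype=bool)
        assert _binary_distance(B)[0] == 0.0


class TestBiclusterCuts:
    def _blocks(self, sizes=(30, 30, 30)):
        rng = np.random.default_rng(1)
        rows = []
        truth = []
        for b, n in enumerate(sizes):
            block = np.zeros((n, 30), dtype=int)
            block[:, 10 * b: 10 * (b + 1)] = rng.poisson(5.0, (n, 10)) + 2
            rows.append(block)
            truth += [b] * n
        return np.vstack(rows), np.array(truth)

    def test_two_planted_blocks_recovered(self):
        counts, truth = self._blocks((25, 25, 0))
        adata = _adata(counts[:50])
        B = s.binarize(adata, list(adata.var_names))
        res = s.bicluster(B)
        cuts = s.cut_subpopulations(res, 2)
        assert adjusted_rand_score(truth[:50], cuts["subpop"]) == 1.0

    def test_three_blocks_k3(self):
        counts, truth = self._blocks()
        adata = _adata(counts)
        res = s.bicluster(s.binarize(adata, list(adata.var_names)))
        cuts = s.cut_subpopulations(res, [3])
        assert adjusted_rand_score(truth, cuts["subpop"]) == 1.0

    def test_k1_single_and_kn_singletons(self):
        counts, _ = self._blocks((10, 10, 0))
        adata = _adata(counts[:20])
        res = s.bicluster(s.binarize(adata, list(adata.var_names)))
        assert s.cut_subpopulations(res, 1)["subpop"].nunique() == 1
        assert s.cut_subpopulations(res, 20)["subpop"].nunique() == 20

    def test_nesting_property(self):
        counts, _ = self._blocks()
        adata = _adata(counts)
        res = s.bicluster(s.binarize(adata, list(adata.var_names)))
        cuts = s.cut_subpopulations(res, [2, 3, 6])
        for fine, coarse in (("k6", "k3"), ("k3", "k2")):
            mapping = cuts.groupby(cuts[fine])[coarse].nunique()
            assert (mapping == 1).all()

    def test_excessive_k_rejected(self):
        counts, _ = self._blocks((5, 5, 0))
        adata = _adata(counts[:10])
        res = s.bicluster(s.binarize(adata, list(adata.var_names)))
        with pytest.raises(ValueError, match="exceeds"):
            s.cut_subpopulations(res, 11)


class TestAcFraction:
    def test_half_and_half(self):
        subpops = pd.Series([1] * 20, index=[f"c{i}" for i in range(20)])
        regions = pd.Series(["AC"] * 10 + ["PA"] * 10,
                            index=subpops.index)
        assert s.ac_fraction(subpops, regions)[1] == pytest.approx(0.5)

    def test_all_pa_is_zero(self):
        subpops = pd.Series([1, 1, 1], index=["a", "b", "c"])
        regions = pd.Series(["PA", "PA", "PA"], index=subpops.index)
        assert s.ac_fraction(subpops, regions)[1] == 0.0

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(2)
        idx = [f"c{i}" for i in range(200)]
        subpops = pd.Series(rng.integers(1, 5, 200), index=idx)
        regions = pd.Series(
            rng.choice(["AC", "PA"], 200), index=idx
        )
        fr = s.ac_fraction(subpops, regions)
        for k in fr.index:
            cells = subpops.index[subpops == k]
            assert fr[k] == pytest.approx(
                (regions.loc[cells] == "AC").sum() / len(cells)
            )


class TestContinuousModel:
    def _setup(self, slope=1.0, n=400, noise=0.3, seed=3):
        rng = np.random.default_rng(seed)
        half = n // 2
        region = ["AC"] * half + ["PA"] * half
        adata = _adata(rng.poisson(3.0, (n, 5)) + 1, region=region)
        subpops = pd.Series(
            [1] * (half // 2) + [2] * (half // 2)
            + [2] * (half // 2) + [3] * (half // 2),
            index=adata.obs_names,
        )
        fr = s.ac_fraction(subpops, adata.obs["region"])
        x = subpops.map(fr).to_numpy()
        norm = pd.DataFrame(
            {
                "flat": np.zeros(n),
                "lin": slope * x + noise * rng.standard_normal(n),
            },
            index=adata.obs_names,
        )
        return adata, subpops, norm

    def test_constant_gene_zero_coefficient(self):
        adata, subpops, norm = self._setup()
        coef = s.continuous_expression_model(adata, subpops, normalized=norm)
        assert coef["flat"] == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equals_mean_difference(self):
        rng = np.random.default_rng(4)
        adata = _adata(rng.poisson(3.0, (40, 3)) + 1,
                       region=["AC"] * 20 + ["PA"] * 20)
        subpops = pd.Series([1] * 20 + [2] * 20, index=adata.obs_names)
        # fractions are 1 and 0
        norm = pd.DataFrame(
            {"g": rng.standard_normal(40)}, index=adata.obs_names
        )
        coef = s.continuous_expression_model(adata, subpops, normalized=norm)
        diff = norm["g"][:20].mean() - norm["g"][20:].mean()
        assert coef["g"] == pytest.approx(diff)

    def test_planted_slope_recovered(self):
        adata, subpops, norm = self._setup(slope=1.0, n=2000, seed=5)
        coef = s.continuous_expression_model(adata, subpops, normalized=norm)
        assert coef["lin"] == pytest.approx(1.0, abs=0.1)

    def test_single_subpopulation_rejected(self):
        adata, subpops, norm = self._setup()
        with pytest.raises(ValueError):
            s.continuous_expression_model(
                adata, pd.Series(1, index=adata.obs_names),
                normalized=norm,
            )


def test_balanced_downsample_exact_counts():
    rng = np.random.default_rng(6)
    n = 2000
    adata = _adata(rng.poisson(1.0, (n, 4)),
                   region=list(rng.choice(["AC", "PA"], n)))
    adata.obs["cell_type"] = rng.choice(["VSMC", "EC"], n)
    out = s.balanced_downsample(adata, per_group=100,
                                by=["cell_type", "region"], seed=0)
    counts = out.obs.groupby(["cell_type", "region"]).size()
    assert (counts == 100).all()
    assert out.n_obs == 400


def test_newick_export_parses():
    import io

    from Bio import Phylo

    B = pd.DataFrame(
        np.array([[1, 0, 0], [1, 1, 0], [0, 1, 1], [0, 0, 1]], dtype=bool),
        index=list("abcd"), columns=list("xyz"),
    )
    res = s.bicluster(B)
    nwk = linkage_to_newick(res.cell_linkage, list(B.index))
    tree = Phylo.read(io.StringIO(nwk), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == list("abcd")
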