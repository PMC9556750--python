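"""Graph partitioning, marker criteria, marker-exclusion doublet filter."""

import logging

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

import scpcnet as s
from scpcnet.partitioning import Partitioning


def _adata(counts, genes=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    genes = genes or [f"G{j}" for j in range(g)]
    obs = pd.DataFrame(
        {"sample": ["S1"] * n, "patient": ["P1"] * n, "region": ["AC"] * n},
        index=[f"c{i}" for i in range(n)],
    )
    var = pd.DataFrame({"symbol": genes, "is_mito": [False] * g},
                       index=pd.Index(genes, name="gene"))
    return ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)


def _partition_of(labels, values):
    return Partitioning(labels=pd.Series(values, index=labels))


class TestPartitionCells:
    def test_two_disjoint_types_fully_separated(self):
        rng = np.random.default_rng(0)
        a = np.hstack([rng.poisson(5, (100, 20)), rng.poisson(0.05, (100, 20))])
        b = np.hstack([rng.poisson(0.05, (100, 20)), rng.poisson(5, (100, 20))])
        adata = _adata(np.vstack([a, b]))
        part = s.partition_cells(adata, n_pcs=10, k_neighbors=30, seed=0)
        truth = [0] * 100 + [1] * 100
        assert adjusted_rand_score(truth, part.labels) == 1.0
        assert part.labels.nunique() == 2

    def test_six_planted_types_recovered(self, six_type_dataset,
                                         six_type_partitioning):
        adata, truth = six_type_dataset
        part = six_type_partitioning
        singlet = ~truth.is_doublet
        ari = adjusted_rand_score(
            truth.cell_types[singlet], part.labels[singlet]
        )
        assert ari >= 0.9

    def test_identical_cells_give_single_partition(self):
        adata = _adata(np.tile([1, 2, 3, 0, 1], (20, 1)))
        part = s.partition_cells(adata, n_pcs=2, k_neighbors=5, seed=0)
        assert part.labels.nunique() == 1

    def test_every_cluster_contains_all_samples(self, six_type_dataset,
                                                six_type_partitioning):
        adata, _ = six_type_dataset
        part = six_type_partitioning
        big = [p for p, n in part.sizes.items() if n >= 50]
        ct = pd.crosstab(part.labels, adata.obs["sample"]).loc[big]
        assert (ct > 0).all().all()

    def test_excessive_n_pcs_rejected(self):
        adata = _adata(np.eye(10, dtype=int))
        with pytest.raises(ValueError, match="n_pcs"):
            s.partition_cells(adata, n_pcs=10, k_neighbors=3)

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        adata = _adata(rng.poisson(2.0, (150, 40)))
        p1 = s.partition_cells(adata, n_pcs=10, k_neighbors=10, seed=7)
        p2 = s.partition_cells(adata, n_pcs=10, k_neighbors=10, seed=7)
        assert p1.labels.equals(p2.labels)


class TestMarkers:
    def _toy(self):
        # partition 0: cells 0-19; partition 1: cells 20-39
        counts = np.zeros((40, 4), dtype=int)
        # gene A: on in 85% of partition 0 at mean 2.5
        counts[:17, 0] = [3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 3, 2, 2, 2, 2, 8]
        # gene B: on in exactly 80% of partition 0, high mean
        counts[:16, 1] = 10
        # gene C: high fraction but mean exactly 2.0
        counts[:20, 2] = 2
        # gene D: partition 1 marker
        counts[20:39, 3] = 5
        adata = _adata(counts, genes=["A", "B", "C", "D"])
        part = _partition_of(adata.obs_names, [0] * 20 + [1] * 20)
        return adata, part

    def test_threshold_boundaries_strict(self):
        adata, part = self._toy()
        mk = s.find_partition_markers(adata, part)
        p0 = mk[mk["partition"] == 0]["gene"].tolist()
        assert "A" in p0          # 85% > 80%, mean 2.5 > 2
        assert "B" not in p0      # exactly 80% excluded
        assert "C" not in p0      # mean exactly 2.0 excluded

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(1.5, (60, 30))
        adata = _adata(counts)
        part = _partition_of(adata.obs_names, [0] * 30 + [1] * 30)
        mk = s.find_partition_markers(adata, part, min_fraction=0.5,
                                      min_mean=1.0)
        got = {(r.gene, r.partition) for r in mk.itertuples()}
        expect = set()
        for p, rows in ((0, counts[:30]), (1, counts[30:])):
            for j in range(30):
                frac = (rows[:, j] > 0).mean()
                mean = rows[:, j].mean()
                if frac > 0.5 and mean > 1.0:
                    expect.add((f"G{j}", p))
        assert got == expect

    def test_assign_by_reference_majority(self):
        mk = pd.DataFrame(
            {
                "gene": ["CD2", "CD3E", "XYZ", "MYH11"],
                "partition": [0, 0, 0, 1],
                "fraction_expressing": [0.9, 0.88, 0.85, 0.95],
                "mean_count": [3, 3, 3, 4],
            }
        )
        ref = {"CD2": "T/NKT", "CD3E": "T/NKT", "MYH11": "VSMC"}
        labels = s.assign_cell_types(mk, ref)
        assert labels[0] == "T/NKT"
        assert labels[1] == "VSMC"

    def test_no_reference_overlap_unassigned(self):
        mk = pd.DataFrame(
            {"gene": ["AAA"], "partition": [0],
             "fraction_expressing": [0.9], "mean_count": [3.0]}
        )
        assert s.assign_cell_types(mk, {"ZZZ": "EC"})[0] == "unassigned"

    def test_synthetic_types_labeled_perfectly(self, six_type_dataset,
                                               six_type_partitioning):
        adata, truth = six_type_dataset
        part = six_type_partitioning
        ref = {g: t for t, gs in truth.type_markers.items() for g in gs}
        mk = s.find_partition_markers(adata, part)
        labels = s.assign_cell_types(mk, ref)
        big = [p for p, n in part.sizes.items() if n >= 50]
        singlet = ~truth.is_doublet
        for p in big:
            cells = part.labels.index[(part.labels == p)
                                      & singlet.reindex(part.labels.index)]
            majority = truth.cell_types.loc[cells].mode()[0]
            assert labels[p] == majority


class TestExclusionMarkers:
    def _toy(self):
        rng = np.random.default_rng(3)
        n = 120  # 60 per partition
        counts = rng.poisson(1.0, (n, 6))
        # gene 0: 95% in partition 0, 2% elsewhere
        counts[:, 0] = 0
        counts[:57, 0] = 2
        counts[60:61, 0] = 1
        # gene 1: exactly 90% in partition 0, absent elsewhere
        counts[:, 1] = 0
        counts[:54, 1] = 1
        # gene 2: 95% in partition 0 but 12% in partition 1
        counts[:, 2] = 0
        counts[:57, 2] = 1
        counts[60:68, 2] = 1   # 8/60 = 13.3% > 10%
        adata = _adata(counts)
        part = _partition_of(adata.obs_names, [0] * 60 + [1] * 60)
        return adata, part

    def test_ubiquity_and_rarity_boundaries(self):
        adata, part = self._toy()
        exc = s.discover_exclusion_markers(adata, part,
                                           min_partition_cells=1)
        assert "G0" in exc[0]          # 95% own, 2% foreign
        assert "G1" not in exc[0]      # exactly 90% is not > 90%
        assert "G2" not in exc[0]      # 13% foreign violates rarity

    def test_exclusion_sets_are_disjoint(self, six_type_dataset,
                                         six_type_partitioning):
        adata, _ = six_type_dataset
        exc = s.discover_exclusion_markers(adata, six_type_partitioning)
        all_genes = [g for gs in exc.values() for g in gs]
        assert len(all_genes) == len(set(all_genes))

    def test_single_partition_rejected(self):
        adata = _adata(np.ones((10, 3), int))
        part = _partition_of(adata.obs_names, [0] * 10)
        with pytest.raises(ValueError):
            s.discover_exclusion_markers(adata, part)


class TestFlagDoublets:
    def _setup(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0] = [5, 0, 0, 0]            # clean partition-0 cell
        counts[1] = [5, 0, 2, 3]            # expresses 2 foreign markers
        counts[2] = [5, 0, 2, 0]            # one foreign marker only
        counts[3] = [0, 0, 5, 5]            # clean partition-1 cell
        adata = _adata(counts, genes=["M0a", "M0b", "M1a", "M1b"])
        part = _partition_of(adata.obs_names, [0, 0, 0, 1])
        exc = {0: ["M0a", "M0b"], 1: ["M1a", "M1b"]}
        return adata, part, exc

    def test_threshold_two_markers(self):
        adata, part, exc = self._setup()
        flags = s.flag_doublets(adata, part, exc)
        assert flags.loc["c1", "flagged"]
        assert not flags.loc["c2", "flagged"]
        assert not flags.loc["c0", "flagged"]
        assert flags.loc["c1", "n_inappropriate"] == 2

    def test_monotone_adding_foreign_markers_never_unflags(self):
        adata, part, exc = self._setup()
        before = s.flag_doublets(adata, part, exc)
        boosted = adata.copy()
        X = boosted.X.toarray()
        X[:, 2] += 1   # everyone gains a partition-1 marker count
        boosted.X = sp.csr_matrix(X)
        after = s.flag_doublets(boosted, part, exc)
        assert (after["flagged"] | ~before["flagged"]).all()

    def test_spiked_doublets_recovered(self, six_type_dataset,
                                       six_type_partitioning):
        adata, truth = six_type_dataset
        part = six_type_partitioning
        exc = s.discover_exclusion_markers(adata, part)
        flags = s.flag_doublets(adata, part, exc)
        dbl = truth.is_doublet.to_numpy()
        recall = flags["flagged"].to_numpy()[dbl].mean()
        fpr = flags["flagged"].to_numpy()[~dbl].mean()
        assert recall >= 0.7
        assert fpr <= 0.05


class TestReadCountValidation:
    def test_spiked_doublets_shift_upward(self, six_type_dataset,
                                          six_type_partitioning):
        adata, truth = six_type_dataset
        part = six_type_partitioning
        exc = s.discover_exclusion_markers(adata, part)
        flags = s.flag_doublets(adata, part, exc)
        rep = s.validate_doublets_readcount(flags)
        assert rep.passed
        assert rep.mean_flagged > rep.mean_unflagged
        assert rep.p_value < 0.01

    def test_random_flags_rarely_significant(self):
        rng = np.random.default_rng(4)
        totals = rng.lognormal(6.0, 0.4, size=400).astype(int)
        hits = 0
        for rep in range(100):
            flagged = np.zeros(400, dtype=bool)
            flagged[rng.choice(400, 20, replace=False)] = True
            flags = pd.DataFrame(
                {"total_umi": totals, "flagged": flagged}
            )
            out = s.validate_doublets_readcount(flags)
            hits += int(out.p_value < 0.05)
        assert hits <= 10

    def test_single_flagged_cell_reports_p(self):
        flags = pd.DataFrame(
            {"total_umi": [100, 200, 300, 4000],
             "flagged": [False, False, False, True]}
        )
        rep = s.validate_doublets_readcount(flags)
        assert rep.n_flagged == 1
        assert np.isfinite(rep.p_value)

    def test_no_flags_warns_without_test(self, caplog):
        flags = pd.DataFrame(
            {"total_umi": [100, 200], "flagged": [False, False]}
        )
        with caplog.at_level(logging.WARNING):
            rep = s.validate_doublets_readcount(flags)
        assert rep.n_flagged == 0
        assert np.isnan(rep.p_value)
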