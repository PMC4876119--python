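"""CARD-FISH percentages, ARISA filtering/binning, Bray-Curtis, UPGMA."""

import io
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import thermosize as tz
from thermosize import community as cm


def _profile(lengths, rfis):
    return pd.DataFrame({"fragment_bp": lengths, "rfi": rfis})


class TestRelativeAbundance:
    def test_percent_arithmetic(self):
        table = pd.DataFrame({
            "SAR11": [10], "Rhodobacteraceae": [10],
            "Gammaproteobacteria": [10], "Bacteroidetes": [10],
            "dapi_total": [100],
        })
        out = cm.relative_abundance(table)
        assert out["SAR11_percent"].iloc[0] == pytest.approx(10.0)
        assert out["summed_coverage_percent"].iloc[0] == pytest.approx(40.0)

    def test_zero_count_probe(self):
        table = pd.DataFrame({
            "SAR11": [0], "Rhodobacteraceae": [5],
            "Gammaproteobacteria": [5], "Bacteroidetes": [5],
            "dapi_total": [100],
        })
        assert cm.relative_abundance(table)["SAR11_percent"].iloc[0] == 0.0

    def test_count_exceeding_dapi_rejected(self):
        table = pd.DataFrame({
            "SAR11": [101], "Rhodobacteraceae": [0],
            "Gammaproteobacteria": [0], "Bacteroidetes": [0],
            "dapi_total": [100],
        })
        with pytest.raises(ValueError):
            cm.relative_abundance(table)

    def test_generator_proportions_recovered(self):
        """Probe proportions summing to 0.704 yield ~70.4% mean summed
        coverage of DAPI."""
        design = tz.ExperimentDesign()
        card, _ = tz.generate_community_tables(design,
                                               tz.default_community_truth(), 3)
        out = cm.relative_abundance(card)
        assert out["summed_coverage_percent"].mean() == pytest.approx(70.4, abs=1.5)


class TestFilterPeaks:
    def test_length_window_boundaries(self):
        prof = _profile([99.9, 100.0, 500.0, 1000.0, 1005.0],
                        [1.0, 1.0, 1.0, 1.0, 1.0])
        out = cm.filter_peaks(prof, rfi_cutoff=0.0)
        assert sorted(out.peaks["fragment_bp"]) == [100.0, 500.0, 1000.0]

    def test_cutoff_inclusive_at_boundary(self):
        out = cm.filter_peaks(_profile([200, 300, 400], [0.5, 0.41, 0.09]))
        assert len(out.peaks) == 3  # the 0.09 peak is retained (>= cutoff)
        assert out.peaks["rfi"].sum() == pytest.approx(1.0)

    def test_cutoff_removes_and_renormalizes(self):
        out = cm.filter_peaks(_profile([200, 300, 400], [0.5, 0.42, 0.08]))
        assert len(out.peaks) == 2
        assert out.peaks["rfi"].sum() == pytest.approx(1.0)

    def test_all_below_cutoff_flagged_empty(self):
        out = cm.filter_peaks(_profile([200, 300], [1.0, 1.0]), rfi_cutoff=0.6)
        assert out.empty

    def test_cutoff_applies_to_normalized_intensities(self):
        # raw scale is arbitrary: x1000 must not change the outcome
        raw = _profile([200, 300, 400], [500.0, 420.0, 80.0])
        out = cm.filter_peaks(raw)
        assert len(out.peaks) == 2


class TestBinning:
    def test_toy_fragment_grouping(self):
        prof = {"s1": _profile([100.0, 101.0, 104.5], [0.4, 0.3, 0.3]),
                "s2": _profile([100.0, 101.0, 104.5], [0.4, 0.3, 0.3])}
        res = cm.bin_fragments(prof)
        row = res.otu_table.loc["s1"]
        occupied = row[row > 0]
        assert len(occupied) == 2  # {100.0, 101.0} share a bin, 104.5 apart
        assert occupied.max() == pytest.approx(0.7)

    def test_partition_and_mass_preservation(self):
        rng = np.random.default_rng(0)
        prof = {
            f"s{i}": _profile(rng.uniform(100, 400, 15), rng.dirichlet(np.ones(15)))
            for i in range(4)
        }
        res = cm.bin_fragments(prof)
        sums = res.otu_table.sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_selected_frame_beats_all_frames(self):
        """The chosen offset's mean pairwise similarity is maximal over the
        enumerated frames (brute-force re-check with independent code)."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(3, 15)
            base = rng.uniform(100, 300, n)
            prof = {}
            for s in range(rng.integers(2, 5)):
                lens = base + rng.normal(0, 0.4, n)
                prof[f"s{s}"] = _profile(lens, rng.dirichlet(np.ones(n)))
            res = cm.bin_fragments(prof)
            best = _brute_force_best_score(prof)
            assert res.frame_scores.max() == pytest.approx(best, abs=1e-12)
            assert res.frame_scores[res.offset] == pytest.approx(best, abs=1e-12)

    def test_identical_profiles_zero_distance_downstream(self):
        prof = {"a": _profile([150.0, 200.0], [0.5, 0.5]),
                "b": _profile([150.0, 200.0], [0.5, 0.5])}
        res = cm.bin_fragments(prof)
        dm = cm.bray_curtis(res.otu_table)
        assert dm.loc["a", "b"] == pytest.approx(0.0)

    def test_jittered_true_otus_cobinned(self):
        """Fragments of one true OTU, jittered by 0.4 bp across samples,
        land in a single bin for >= 95% of simulated communities."""
        rng = np.random.default_rng(2)
        hits = trials = 0
        reps = 40
        for _ in range(reps):
            # 4 well-separated true fragments per community
            centers = 110 + np.cumsum(rng.uniform(8, 60, 4))
            prof = {}
            for s in range(4):
                lens = centers + rng.normal(0, 0.4, centers.size)
                prof[f"s{s}"] = _profile(lens, np.full(centers.size, 1 / centers.size))
            res = cm.bin_fragments(prof)
            start = res.anchor + res.offset
            for k in range(centers.size):
                bins = {
                    int(np.floor((prof[f"s{s}"]["fragment_bp"].iloc[k] - start)
                                 / res.window))
                    for s in range(4)
                }
                trials += 1
                hits += len(bins) == 1
        assert hits / trials >= 0.95


def _brute_force_best_score(prof, window=3.0, shift=0.1, anchor=100.0):
    samples = sorted(prof)
    best = -np.inf
    k = 0
    while round(k * shift, 10) < window:
        start = anchor + round(k * shift, 10)
        vecs = []
        all_bins = set()
        tmp = {}
        for s in samples:
            d = {}
            for L, v in zip(prof[s]["fragment_bp"], prof[s]["rfi"]):
                b = int(np.floor((L - start) / window))
                d[b] = d.get(b, 0.0) + v
                all_bins.add(b)
            tmp[s] = d
        order = sorted(all_bins)
        for s in samples:
            vecs.append([tmp[s].get(b, 0.0) for b in order])
        sims = []
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                x, y = np.array(vecs[i]), np.array(vecs[j])
                bc = np.abs(x - y).sum() / (x + y).sum()
                sims.append(1 - bc)
        best = max(best, np.mean(sims))
        k += 1
    return best


class TestBrayCurtis:
    def test_hand_values(self):
        table = pd.DataFrame([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]], index=["x", "y"])
        assert cm.bray_curtis(table).loc["x", "y"] == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        table = pd.DataFrame([[1, 2, 0, 0], [1, 2, 0, 0], [0, 0, 3, 1]],
                             index=["a", "b", "c"], dtype=float)
        dm = cm.bray_curtis(table)
        assert dm.loc["a", "b"] == 0.0
        assert dm.loc["a", "c"] == 1.0

    def test_matrix_properties(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.uniform(0, 1, (6, 10)))
        dm = cm.bray_curtis(table).to_numpy()
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0.0)
        assert ((dm >= 0) & (dm <= 1)).all()

    def test_joint_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.uniform(0, 1, (3, 5)))
        dm1 = cm.bray_curtis(table)
        dm2 = cm.bray_curtis(table * 13.7)
        pd.testing.assert_frame_equal(dm1, dm2)

    def test_all_zero_pair_flagged(self):
        table = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]],
                             index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="all-zero"):
            dm = cm.bray_curtis(table)
        assert np.isnan(dm.loc["a", "b"])


class TestDendrogram:
    @staticmethod
    def _toy_dm():
        d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        return pd.DataFrame(d, index=list("ABC"), columns=list("ABC"))

    def test_forced_topology(self):
        dg = cm.cluster_dendrogram(self._toy_dm())
        compact = dg.newick.replace(" ", "")
        assert "(A:0.05,B:0.05):0.4" in compact or "(B:0.05,A:0.05):0.4" in compact
        assert "C:0.45" in compact

    def test_newick_round_trip(self):
        import skbio

        dg = cm.cluster_dendrogram(self._toy_dm())
        tree = skbio.TreeNode.read(io.StringIO(dg.newick))
        names = {t.name for t in tree.tips()}
        assert names == {"A", "B", "C"}
        # ultrametric: both deep tips at root height / 2
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        assert depths["A"] == pytest.approx(depths["C"])
        ab = tree.lca(["A", "B"])
        assert depths["A"] - ab.accumulate_to_ancestor(tree) == pytest.approx(0.05)

    def test_merge_heights_monotone_and_cophenetic_consistent(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, (8, 4))
        from scipy.spatial.distance import pdist, squareform
        dm = pd.DataFrame(squareform(pdist(pts, "braycurtis")))
        dg = cm.cluster_dendrogram(dm)
        heights = dg.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()
        assert dg.cophenetic.to_numpy().max() == pytest.approx(heights[-1])

    def test_small_matrix_trivial_tree(self):
        dm = pd.DataFrame([[0.0, 0.3], [0.3, 0.0]], index=["a", "b"],
                          columns=["a", "b"])
        with pytest.warns(UserWarning, match="trivial"):
            dg = cm.cluster_dendrogram(dm)
        assert dg.trivial

    def test_unsupported_linkage(self):
        with pytest.raises(ValueError):
            cm.cluster_dendrogram(self._toy_dm(), method="ward")


class TestConcordance:
    @staticmethod
    def _blocked_dm(groups, within=0.05, between=0.9):
        labels = [f"{g}{i}" for g in groups for i in range(groups[g])]
        n = len(labels)
        d = np.full((n, n), between)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if a[0] == b[0]:
                    d[i, j] = within
        np.fill_diagonal(d, 0.0)
        return pd.DataFrame(d, index=labels, columns=labels), {
            lab: lab[0] for lab in labels
        }

    def test_perfect_blocks_fully_concordant(self):
        dm, groups = self._blocked_dm({"a": 3, "b": 3, "c": 2})
        dg = cm.cluster_dendrogram(dm)
        res = cm.cluster_concordance(dg, groups)
        assert res.fraction == 1.0

    def test_planted_outlier_breaks_its_group(self):
        dm, groups = self._blocked_dm({"a": 3, "b": 3})
        # move b2 far from everything (an outlier sample)
        for lab in dm.index:
            if lab != "b2":
                dm.loc["b2", lab] = dm.loc[lab, "b2"] = 0.99
        dg = cm.cluster_dendrogram(dm)
        res = cm.cluster_concordance(dg, groups)
        assert res.concordant["a"]
        assert not res.concordant["b"]

    def test_singletons_reported_separately(self):
        dm, groups = self._blocked_dm({"a": 3, "b": 1})
        dg = cm.cluster_dendrogram(dm)
        res = cm.cluster_concordance(dg, groups)
        assert res.n_singletons == 1
        assert res.n_groups == 1

    def test_random_labels_match_permutation_null(self):
        """Near-star trees: observed concordance of random labels matches
        its own permutation distribution."""
        rng = np.random.default_rng(5)
        n = 8
        d = 0.5 + rng.uniform(-0.01, 0.01, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"s{i}" for i in range(n)]
        dm = pd.DataFrame(d, index=labels, columns=labels)
        dg = cm.cluster_dendrogram(dm)
        base = np.array(["g1"] * 4 + ["g2"] * 4)
        obs = cm.cluster_concordance(dg, dict(zip(labels, base))).fraction
        null = [
            cm.cluster_concordance(dg, dict(zip(labels, rng.permutation(base)))).fraction
            for _ in range(200)
        ]
        # observed should not be an outlier of its own null distribution
        assert np.quantile(null, 0.0) <= obs <= np.quantile(null, 1.0)
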