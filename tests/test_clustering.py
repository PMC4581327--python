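"""Identity computation, threshold-graph clustering, representatives and the
specific/common contrast."""

import itertools

import numpy as np
import pytest

from idrptm.clustering import (
    ClusterAssignment,
    ClusterCatalog,
    IdentityParams,
    build_clusters,
    category_contrast,
    category_counts,
    classify_clusters,
    global_identity,
    read_cluster_table,
    redundancy_content,
    select_representatives,
    write_cluster_table,
)
from idrptm.proteome import ProteinRecord


def nw_score_oracle(a: str, b: str, match=1.0, mismatch=0.0, gap=-1.0) -> float:
    """Plain quadratic Needleman-Wunsch optimal score."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1))
    dp[:, 0] = np.arange(n + 1) * gap
    dp[0, :] = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            dp[i, j] = max(dp[i - 1, j - 1] + sub, dp[i - 1, j] + gap, dp[i, j - 1] + gap)
    return float(dp[n, m])


def _recs(seqs, species="sp"):
    return [ProteinRecord(f"p{i}", species, s) for i, s in enumerate(seqs)]


class TestGlobalIdentity:
    def test_identical_sequences(self):
        assert global_identity("MKVLA", "MKVLA") == (100.0, 100.0)

    def test_exact_prefix(self):
        pi, pmatch = global_identity("MKVLA", "MKVLAXXXXX")
        assert pi == 100.0 and pmatch == 100.0

    def test_disjoint_residues_low_identity(self):
        pi, _ = global_identity("MKVD" * 5, "TTWC" * 5)
        assert pi <= 20.0

    def test_symmetry(self):
        a, b = "MKVLASTPDE", "MKVLSSTPD"
        assert global_identity(a, b) == global_identity(b, a)

    def test_alignment_score_matches_dp_oracle(self, rng):
        letters = list("ACDEFGHIKL")
        from idrptm.clustering import _aligner

        # linear gap costs so the straightforward DP below is the oracle
        aligner = _aligner(IdentityParams(open_gap_score=-1.0, extend_gap_score=-1.0))
        for _ in range(40):
            a = "".join(rng.choice(letters, size=int(rng.integers(3, 25))))
            b = "".join(rng.choice(letters, size=int(rng.integers(3, 25))))
            assert aligner.score(a, b) == pytest.approx(nw_score_oracle(a, b))


class TestBuildClusters:
    def test_identical_pair_joins(self):
        recs = _recs(["MKVLASTPDE" * 10, "MKVLASTPDE" * 10, "WWCCHHGGFF" * 10])
        catalog = build_clusters(recs)
        assert sorted(len(c) for c in catalog) == [1, 2]

    def test_dissimilar_records_stay_singletons(self, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        recs = _recs(
            "".join(rng.choice(letters, size=100)) for _ in range(8)
        )
        catalog = build_clusters(recs)
        assert len(catalog) == 8

    def test_transitive_chain_single_cluster(self, rng):
        """A~B and B~C above threshold pull A and C (below threshold) together."""
        letters = np.array(list("ACDEFGHIKLMNPQRSTVW"))
        base = rng.choice(letters, size=200)
        a, c = base.copy(), base.copy()
        pos = rng.choice(200, size=10, replace=False)
        for p in pos[:5]:
            a[p] = "Y"
        for p in pos[5:]:
            c[p] = "Y"
        recs = _recs(["".join(a), "".join(base), "".join(c)])
        params = IdentityParams(pi_cutoff=96.0, pmatch_cutoff=90.0)
        pi_ac, _ = global_identity(recs[0], recs[2], params)
        assert pi_ac < 96.0  # A and C alone would not connect
        catalog = build_clusters(recs, params)
        assert len(catalog) == 1 and len(catalog.clusters[0]) == 3

    def test_partition_property(self, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = ["".join(rng.choice(letters, size=60)) for _ in range(6)]
        seqs += [seqs[0], seqs[2]]  # exact duplicates
        recs = [ProteinRecord(f"p{i}", "sp", s) for i, s in enumerate(seqs)]
        catalog = build_clusters(recs)
        members = [m for c in catalog for m in c.members]
        assert len(members) == len(set(members)) == len(recs)

    def test_raising_cutoff_refines_partition(self, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVW"))
        base = rng.choice(letters, size=100)
        variants = []
        for k in (0, 3, 6, 9):
            v = base.copy()
            for p in range(k):
                v[p] = "Y"
            variants.append("".join(v))
        recs = _recs(variants)
        loose = build_clusters(recs, IdentityParams(pi_cutoff=90.0))
        strict = build_clusters(recs, IdentityParams(pi_cutoff=95.0))
        loose_of = {m: c.cluster_id for c in loose for m in c.members}
        # every strict cluster sits inside exactly one loose cluster
        for cluster in strict:
            assert len({loose_of[m] for m in cluster.members}) == 1


class TestRepresentatives:
    def test_longest_member_wins(self):
        recs = [
            ProteinRecord("x", "sp", "A" * 120),
            ProteinRecord("y", "sp", "A" * 200),
        ]
        catalog = ClusterCatalog([ClusterAssignment("c0", {("sp", "x"), ("sp", "y")})])
        (rep,) = select_representatives(catalog, recs)
        assert rep.protein_id == "y"

    def test_singleton_returns_sole_member(self):
        recs = [ProteinRecord("x", "sp", "AAA")]
        catalog = ClusterCatalog([ClusterAssignment("c0", {("sp", "x")})])
        assert select_representatives(catalog, recs)[0].protein_id == "x"

    def test_length_tie_smallest_id(self):
        recs = [ProteinRecord("b", "sp", "A" * 50), ProteinRecord("a", "sp", "C" * 50)]
        catalog = ClusterCatalog([ClusterAssignment("c0", {("sp", "a"), ("sp", "b")})])
        assert select_representatives(catalog, recs)[0].protein_id == "a"


class TestRedundancyContent:
    @pytest.mark.parametrize(
        "before,after,expected", [(100, 90, 0.10), (100, 100, 0.0), (50, 25, 0.5)]
    )
    def test_arithmetic(self, before, after, expected):
        assert redundancy_content(before, after) == pytest.approx(expected)

    def test_zero_before_signalled(self):
        with pytest.raises(ValueError):
            redundancy_content(0, 0)


class TestClassifyClusters:
    def _catalog(self, species_lists):
        return ClusterCatalog(
            [
                ClusterAssignment(f"c{i}", {(sp, f"{sp}_p{i}") for sp in sps})
                for i, sps in enumerate(species_lists)
            ]
        )

    def test_categories(self):
        panel = [f"s{i}" for i in range(20)]
        catalog = self._catalog([["s1"], panel, panel[:5]])
        cats = classify_clusters(catalog, panel)
        assert cats == {"c0": "specific", "c1": "common", "c2": "intermediate"}

    def test_counts_partition_clusters(self):
        panel = ["s1", "s2", "s3"]
        catalog = self._catalog([["s1"], ["s2"], panel, ["s1", "s2"], panel])
        counts = category_counts(classify_clusters(catalog, panel))
        assert sum(counts.values()) == len(catalog)
        assert counts == {"specific": 2, "common": 2, "intermediate": 1}

    def test_species_outside_panel_rejected(self):
        catalog = self._catalog([["weird"]])
        with pytest.raises(ValueError):
            classify_clusters(catalog, ["s1"])


class TestCategoryContrast:
    def test_ratio_from_printed_category_means(self):
        # disorder contrast: 34% specific vs 20% common
        res = category_contrast([34.0] * 4, [20.0] * 4)
        assert res.ratio_s_over_c == pytest.approx(1.7)

    def test_identical_multisets_symmetric(self):
        res = category_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.ratio_s_over_c == pytest.approx(1.0)
        assert res.p_one_tailed == pytest.approx(0.5)

    def test_welch_close_to_exhaustive_permutation_oracle(self):
        xs = [34.0, 30.0, 38.0, 33.0, 35.0]
        xc = [20.0, 22.0, 19.0, 24.0]
        # independent oracle: enumerate every reassignment of the pooled
        # values to the two group sizes
        pool = xs + xc
        obs = np.mean(xs) - np.mean(xc)
        hits = total = 0
        for idx in itertools.combinations(range(len(pool)), len(xs)):
            sel = [pool[i] for i in idx]
            rest = [pool[i] for i in range(len(pool)) if i not in idx]
            total += 1
            hits += np.mean(sel) - np.mean(rest) >= obs - 1e-12
        p_oracle = hits / total
        res = category_contrast(xs, xc)
        assert abs(res.p_one_tailed - p_oracle) < 0.02
        # the built-in permutation alternative is exhaustive here and must
        # agree with the oracle exactly
        perm = category_contrast(xs, xc, method="permutation", n_permutations=10000)
        assert perm.p_one_tailed == pytest.approx(p_oracle)

    def test_zero_common_mean_signalled(self):
        with pytest.raises(ZeroDivisionError):
            category_contrast([1.0], [0.0, 0.0])


def test_cluster_table_round_trip(tmp_path):
    catalog = ClusterCatalog(
        [
            ClusterAssignment("c0", {("s1", "a"), ("s2", "b")}),
            ClusterAssignment("c1", {("s1", "z")}),
        ]
    )
    path = tmp_path / "clusters.tsv"
    write_cluster_table(catalog, path)
    back = read_cluster_table(path)
    assert {frozenset(c.members) for c in back} == {frozenset(c.members) for c in catalog}
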