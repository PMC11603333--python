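import itertools
from collections import Counter

import numpy as np
import pytest
from scipy.cluster import hierarchy

from genodiag.io_formats import FormatError, GenomeLayout
from genodiag.sv_pangenome import (
    SvPresenceMatrix,
    SvRecord,
    pairwise_sv_distance,
    presence_from_deconstructed_vcf,
    private_sv_hotspots,
    robinson_foulds,
    subset_intersections,
    upgma,
    write_deconstructed_vcf,
)
from genodiag.synthetic_data import SimSpec, TreeNode, simulate_sv_matrix


def rec(presence, chrom="1", pos=100, sv_class="DEL", length=100):
    return SvRecord(chrom=chrom, pos=pos, sv_class=sv_class, length=length,
                    presence=tuple(presence))


def matrix(assemblies, rows, **kw):
    return SvPresenceMatrix(
        assemblies=tuple(assemblies),
        records=[rec(r, pos=10 * (i + 1), **kw) for i, r in enumerate(rows)],
    )


class TestPresenceFromVcf:
    def _write(self, path, lines, samples=("wisent", "bison", "yak")):
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        path.write_text(header + "".join(lines))

    def test_deletion_presence(self, tmp_path):
        p = tmp_path / "sv.vcf"
        ref = "A" * 1631
        self._write(p, [f"1\t100\t.\t{ref}\tA\t60\t.\t.\tGT\t1\t1\t0\n"])
        m = presence_from_deconstructed_vcf(str(p))
        (r,) = m.records
        assert r.sv_class == "DEL" and r.length == 1630
        assert r.presence == (True, True, False)

    def test_short_indel_dropped(self, tmp_path):
        p = tmp_path / "sv.vcf"
        self._write(p, [f"1\t100\t.\t{'A' * 31}\tA\t60\t.\t.\tGT\t1\t1\t1\n"])
        assert presence_from_deconstructed_vcf(str(p)).records == []

    def test_multiallelic_split_per_alt(self, tmp_path):
        p = tmp_path / "sv.vcf"
        alt1 = "A" * 101  # 100 bp insertion
        alt2 = "A" * 201  # 200 bp insertion
        self._write(p, [f"1\t100\t.\tA\t{alt1},{alt2}\t60\t.\t.\tGT\t1\t2\t0\n"])
        m = presence_from_deconstructed_vcf(str(p))
        assert len(m.records) == 2
        assert m.records[0].presence == (True, False, False)
        assert m.records[0].length == 100
        assert m.records[1].presence == (False, True, False)
        assert m.records[1].length == 200

    def test_missing_genotype_treated_absent(self, tmp_path):
        p = tmp_path / "sv.vcf"
        self._write(p, [f"1\t100\t.\t{'A' * 101}\tA\t60\t.\t.\tGT\t1\t.\t0\n"])
        (r,) = presence_from_deconstructed_vcf(str(p)).records
        assert r.presence == (True, False, False)

    def test_symbolic_allele_rejected(self, tmp_path):
        p = tmp_path / "sv.vcf"
        self._write(p, ["1\t100\t.\tA\t<DEL>\t60\t.\t.\tGT\t1\t1\t0\n"])
        with pytest.raises(FormatError, match="symbolic"):
            presence_from_deconstructed_vcf(str(p))

    def test_generator_roundtrip_200_records(self, tmp_path, layout_1mb):
        tree = TreeNode(
            None,
            (
                TreeNode(None, (TreeNode("A", (), 40), TreeNode("B", (), 40)), 40),
                TreeNode("C", (), 40),
            ),
            40,
        )
        spec = SimSpec(layout=layout_1mb, seed=11, sv_tree=tree)
        truth_matrix, _ = simulate_sv_matrix(spec)
        assert len(truth_matrix.records) == 200
        p = tmp_path / "sv.vcf"
        write_deconstructed_vcf(truth_matrix, str(p), layout_1mb)
        m = presence_from_deconstructed_vcf(str(p))
        assert m.assemblies == truth_matrix.assemblies
        got = [(r.chrom, r.pos, r.sv_class, r.length, r.presence) for r in m.records]
        exp = [(r.chrom, r.pos, r.sv_class, r.length, r.presence)
               for r in truth_matrix.records]
        assert got == exp


class TestSubsetIntersections:
    def test_trivial_patterns(self):
        m = matrix("AB", [(1, 1), (1, 0), (0, 1)])
        patterns, totals = subset_intersections(m)
        assert patterns == {
            frozenset("AB"): 1, frozenset("A"): 1, frozenset("B"): 1
        }
        assert totals == {"A": 2, "B": 2}

    def test_empty(self):
        patterns, totals = subset_intersections(matrix("AB", []))
        assert patterns == {} and totals == {"A": 0, "B": 0}

    def test_random_7x500_vs_brute_force(self, rng):
        labels = "ABCDEFG"
        rows = []
        while len(rows) < 500:
            row = tuple(bool(b) for b in rng.integers(0, 2, size=7))
            if any(row):
                rows.append(row)
        m = matrix(labels, rows)
        patterns, totals = subset_intersections(m)
        # brute force over all 2^7 - 1 candidate patterns
        for bits in itertools.product([False, True], repeat=7):
            if not any(bits):
                continue
            pat = frozenset(l for l, b in zip(labels, bits) if b)
            expected = sum(1 for row in rows if row == bits)
            assert patterns.get(pat, 0) == expected
        assert sum(patterns.values()) == 500
        for i, l in enumerate(labels):
            assert totals[l] == sum(1 for row in rows if row[i])
            assert totals[l] == sum(
                c for p, c in patterns.items() if l in p
            )


class TestHotspots:
    def test_no_private_svs_empty(self, layout_1mb):
        m = matrix("AB", [(1, 1)])
        assert private_sv_hotspots(m, "A", 100_000, layout_1mb) == []

    def test_fold_arithmetic_mirrors_27x(self):
        layout = GenomeLayout.from_pairs([("7", 16_200_000)])
        rows = [(1, 0)] * 27
        m = SvPresenceMatrix(
            assemblies=("w", "b"),
            records=[rec(r, chrom="7", pos=10_200_001 + i * 20_000)
                     for i, r in enumerate(rows)],
        )
        hits = private_sv_hotspots(m, "w", 600_000, layout, fold_threshold=1.0)
        (h,) = hits
        assert h.n_private == 27
        assert h.fold == pytest.approx(27.0)

    def test_uniform_placement_low_fold(self, rng):
        layout = GenomeLayout.from_pairs([("1", 10_000_000)])
        n = 1_000
        positions = np.sort(rng.integers(1, 10_000_001, size=n))
        m = SvPresenceMatrix(
            assemblies=("w", "b"),
            records=[rec((1, 0), pos=int(p)) for p in positions],
        )
        hits = private_sv_hotspots(m, "w", 100_000, layout, fold_threshold=0.0)
        assert max(h.fold for h in hits) <= 3.0

    def test_unknown_focal_rejected(self, layout_1mb):
        with pytest.raises(KeyError):
            private_sv_hotspots(matrix("AB", [(1, 0)]), "Z", 1000, layout_1mb)


class TestPairwiseDistance:
    def test_reciprocal_of_shared(self):
        rows = [(1, 1)] * 10 + [(1, 0)] * 5
        labels, D = pairwise_sv_distance(matrix("AB", rows))
        assert D[0, 1] == pytest.approx(0.1)
        assert D[0, 0] == D[1, 1] == 0.0

    def test_identical_rows_minimal_distance(self):
        rows = [(1, 1, 0)] * 20 + [(1, 0, 1)] * 5 + [(0, 1, 1)] * 5
        _, D = pairwise_sv_distance(matrix("ABC", rows))
        off = D[np.triu_indices(3, k=1)]
        assert D[0, 1] == off.min()

    def test_sentinel_for_disjoint_pair(self):
        rows = [(1, 0, 1)] * 4 + [(0, 1, 1)] * 2
        _, D = pairwise_sv_distance(matrix("ABC", rows))
        finite_max = max(D[0, 2], D[1, 2])
        assert D[0, 1] == pytest.approx(2 * finite_max)

    def test_random_vs_brute_force(self, rng):
        labels = "ABCDE"
        rows = []
        while len(rows) < 200:
            row = tuple(bool(b) for b in rng.integers(0, 2, size=5))
            if any(row):
                rows.append(row)
        m = matrix(labels, rows)
        _, D = pairwise_sv_distance(m)
        for i in range(5):
            for j in range(5):
                if i == j:
                    assert D[i, j] == 0
                    continue
                shared = sum(1 for row in rows if row[i] and row[j])
                if shared:
                    assert D[i, j] == pytest.approx(1 / shared)

    def test_discordant_mode(self):
        rows = [(1, 1), (1, 0), (0, 1), (1, 1)]
        _, D = pairwise_sv_distance(matrix("AB", rows), mode="discordant")
        assert D[0, 1] == pytest.approx(2 / 4)

    def test_single_assembly_rejected(self):
        with pytest.raises(ValueError):
            pairwise_sv_distance(matrix("A", [(1,)]))


class TestUpgma:
    def test_two_leaves(self):
        d = np.array([[0.0, 0.2], [0.2, 0.0]])
        t = upgma(["A", "B"], d)
        assert t.root.height == pytest.approx(0.1)
        assert sorted(t.root.leaves()) == ["A", "B"]

    def test_three_leaf_hand_case(self):
        # d(A,B)=2, d(A,C)=d(B,C)=8 -> join (A,B) at 1, then C at 4
        d = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float)
        t = upgma(["A", "B", "C"], d)
        assert [h for _, _, h in t.merges] == pytest.approx([1.0, 4.0])
        assert frozenset("AB") in t.clades()
        assert t.is_ultrametric()

    def test_newick_shape(self):
        d = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float)
        nwk = upgma(["A", "B", "C"], d).to_newick()
        assert nwk.startswith("((A:1.000000,B:1.000000):3.000000,C:4.000000)")

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            upgma(["A", "B"], d)

    def test_random_vs_scipy_reference(self, rng):
        """Merge heights and partitions match scipy average linkage."""
        for _ in range(50):
            n = 6
            pts = rng.random((n, 3))
            D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            labels = [f"L{i}" for i in range(n)]
            t = upgma(labels, D)
            condensed = D[np.triu_indices(n, k=1)]
            Z = hierarchy.linkage(condensed, method="average")
            ours = sorted(2 * h for _, _, h in t.merges)
            theirs = sorted(Z[:, 2])
            assert np.allclose(ours, theirs)
            # cluster composition at each merge
            our_clades = {c for c in t.clades() if 1 < len(c) < n}
            scipy_clades = set()
            members = {i: frozenset([labels[i]]) for i in range(n)}
            for k, (a, b, _, _) in enumerate(Z):
                merged = members[int(a)] | members[int(b)]
                members[n + k] = merged
                if 1 < len(merged) < n:
                    scipy_clades.add(merged)
            assert our_clades == scipy_clades

    def test_label_permutation_preserves_topology(self, rng):
        n = 5
        pts = rng.random((n, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"L{i}" for i in range(n)]
        t1 = upgma(labels, D)
        perm = rng.permutation(n)
        t2 = upgma([labels[i] for i in perm], D[np.ix_(perm, perm)])
        assert t1.clades() == t2.clades()

    def test_tie_break_deterministic(self):
        # equilateral: merges fully tied; lexicographic pair wins
        d = np.ones((3, 3)) - np.eye(3)
        t = upgma(["B", "A", "C"], d)
        assert frozenset("AB") in t.clades()


class TestTreeRecovery:
    def _seven_taxon_tree(self, n_branch=30):
        leaf = lambda n: TreeNode(n, (), n_branch)  # noqa: E731
        return TreeNode(
            None,
            (
                TreeNode(
                    None,
                    (TreeNode(None, (leaf("cat1"), leaf("cat2")), n_branch),
                     leaf("cat3")),
                    n_branch,
                ),
                TreeNode(
                    None,
                    (
                        TreeNode(None, (leaf("bis1"), leaf("bis2")), n_branch),
                        TreeNode(None, (leaf("yak1"), leaf("yak2")), n_branch),
                    ),
                    n_branch,
                ),
            ),
            n_branch,
        )

    def test_recovery_20_replicates(self, layout_1mb):
        tree = self._seven_taxon_tree()
        for seed in range(20):
            spec = SimSpec(layout=layout_1mb, seed=seed, sv_tree=tree)
            m, truth = simulate_sv_matrix(spec)
            labels, D = pairwise_sv_distance(m)
            t = upgma(labels, D)
            assert t.is_ultrametric()
            truth_clades = {
                frozenset(node.leaves()) for node in truth.iter_nodes()
            }
            assert robinson_foulds(t.clades(), truth_clades) == 0
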