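"""Domain pipeline: hit filtering, overlap resolution, redundancy
reduction, k-mer distances, neighbor joining, MSA ordering, pipeline runs.

Independent oracles: exhaustive subset search for overlap resolution, a
hand-written Needleman-Wunsch DP for alignment identity, set enumeration
for k-mer distances, and a recompute-everything NJ for tree construction.
"""

import itertools

import numpy as np
import pytest

import phylotracks as pt
from phylotracks.domains import pairwise_identity, run_external_tool
from phylotracks.fixtures import FixtureSpec, synth_tree_and_sequences
from phylotracks.model import (
    DistanceMatrix,
    FeatureHit,
    FeatureKind,
    FeatureSource,
)


def hit(start, end, score, evalue=1e-10, kind=FeatureKind.DOMAIN, acc=None):
    return FeatureHit(
        protein_id="P1",
        kind=kind,
        source=FeatureSource.PFAM,
        accession=acc or f"PF{start:05d}",
        name="dom",
        start=start,
        end=end,
        bit_score=score,
        evalue=evalue,
    )


class TestFilterHits:
    def test_evalue_threshold(self):
        hits = [hit(1, 50, 80, evalue=1e-20), hit(60, 90, 40, evalue=0.1)]
        kept = pt.filter_hits(hits, pt.DomainsConfig())
        assert len(kept) == 1 and kept[0].evalue == 1e-20

    def test_empty_in_empty_out(self):
        assert pt.filter_hits([], pt.DomainsConfig()) == []

    def test_tm_bypasses_filter(self):
        tm = hit(5, 25, 0, evalue=None, kind=FeatureKind.TRANSMEMBRANE)
        assert pt.filter_hits([tm], pt.DomainsConfig()) == [tm]


def brute_force_best_subset(hits, max_frac):
    """Max-total-bit-score subset of pairwise-compatible hits (oracle)."""
    best, best_score = (), -1.0
    for r in range(len(hits) + 1):
        for combo in itertools.combinations(hits, r):
            ok = all(
                a.overlap(b) <= max_frac * min(len(a), len(b))
                for a, b in itertools.combinations(combo, 2)
            )
            if ok:
                score = sum(h.bit_score for h in combo)
                if score > best_score:
                    best, best_score = combo, score
    return set(best)


class TestResolveOverlaps:
    def test_conflicting_pair_keeps_higher_score(self):
        a, b = hit(1, 100, 80), hit(50, 150, 60)
        arch = pt.resolve_overlaps([a, b], pt.DomainsConfig())
        assert arch.features == [a]  # overlap 51 > 0.2 * 101

    def test_disjoint_hits_both_kept_in_order(self):
        a, b = hit(101, 200, 60), hit(1, 100, 80)
        arch = pt.resolve_overlaps([a, b], pt.DomainsConfig())
        assert [h.start for h in arch.features] == [1, 101]

    def test_three_mutual_overlaps_greedy_equals_bruteforce(self):
        hits = [hit(1, 100, 90), hit(30, 130, 80), hit(60, 160, 70)]
        arch = pt.resolve_overlaps(hits, pt.DomainsConfig())
        expected = brute_force_best_subset(hits, 0.2)
        assert set(arch.features) == expected == {hits[0]}

    def test_never_increases_hits_and_invariant_holds(self, hits):
        config = pt.DomainsConfig()
        by_protein = {}
        for h in pt.filter_hits(hits, config):
            by_protein.setdefault(h.protein_id, []).append(h)
        for phits in by_protein.values():
            arch = pt.resolve_overlaps(phits, config)
            assert len(arch.features) <= len(phits)
            doms = [f for f in arch.features if f.kind is FeatureKind.DOMAIN]
            for a, b in itertools.combinations(doms, 2):
                assert a.overlap(b) <= config.overlap_fraction_max * min(
                    len(a), len(b)
                )


def nw_identity_oracle(a, b):
    """Needleman-Wunsch with match=1, mismatch=0, linear gap -1;
    returns matches / alignment length of one optimal alignment."""
    n, m = len(a), len(b)
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = -i
    for j in range(1, m + 1):
        score[0][j] = -j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            score[i][j] = max(
                score[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1] else 0),
                score[i - 1][j] - 1,
                score[i][j - 1] - 1,
            )
    i, j, matches, length = n, m, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + (
            1 if a[i - 1] == b[j - 1] else 0
        ):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and score[i][j] == score[i - 1][j] - 1:
            i -= 1
        else:
            j -= 1
        length += 1
    return matches / length


class TestReduceRedundancy:
    def test_identical_sequences_collapse(self):
        recs = [pt.SequenceRecord("a", "MKTLLV"), pt.SequenceRecord("b", "MKTLLV")]
        reps, members = pt.reduce_redundancy(recs, 0.9)
        assert len(reps) == 1
        assert members == {"a": reps[0].id, "b": reps[0].id}

    def test_half_identity_stays_separate(self):
        # oracle: optimal global alignment is gapless, 5/10 matches
        a, b = "AAAAAAAAAA", "AAAAACCCCC"
        assert nw_identity_oracle(a, b) == pytest.approx(0.5)
        assert pairwise_identity(a, b) == pytest.approx(0.5)
        recs = [pt.SequenceRecord("a", a), pt.SequenceRecord("b", b)]
        reps, _ = pt.reduce_redundancy(recs, 0.9)
        assert len(reps) == 2

    def test_identity_matches_dp_oracle(self):
        pairs = [("MKTLLVAAGG", "MKTLLV"), ("ACDEFGHIK", "ACDFGHIK"),
                 ("MMMM", "KKKK")]
        for a, b in pairs:
            assert pairwise_identity(a, b) == pytest.approx(
                nw_identity_oracle(a, b)
            )

    def test_single_sequence_is_own_representative(self):
        recs = [pt.SequenceRecord("a", "MKTLLV")]
        reps, members = pt.reduce_redundancy(recs, 0.5)
        assert reps == recs and members == {"a": "a"}

    def test_gapped_input_error(self):
        recs = [pt.SequenceRecord("a", "MK-L"), pt.SequenceRecord("b", "MKLL")]
        with pytest.raises(ValueError, match="reduce before aligning"):
            pt.reduce_redundancy(recs, 0.9)

    def test_threshold_one_collapses_exactly_duplicates(self):
        recs = [
            pt.SequenceRecord("a", "MKTLLV"),
            pt.SequenceRecord("b", "MKTLLV"),
            pt.SequenceRecord("c", "MKTLLA"),
        ]
        reps, members = pt.reduce_redundancy(recs, 1.0)
        assert {r.id for r in reps} == {"a", "c"}
        assert members["b"] == "a"


class TestKmerDistance:
    def test_identical_sequences_zero(self):
        recs = [pt.SequenceRecord(i, "MKTLLVAA") for i in "abc"]
        dm = pt.kmer_distance_matrix(recs, k=3)
        assert np.allclose(dm.d, 0.0)

    def test_disjoint_kmers_distance_one(self):
        recs = [
            pt.SequenceRecord("a", "AAAA"),
            pt.SequenceRecord("b", "CCCC"),
            pt.SequenceRecord("c", "DDDD"),
        ]
        dm = pt.kmer_distance_matrix(recs, k=3)
        assert dm.d[0, 1] == 1.0

    def test_hand_enumerated_example(self):
        # 3-mers of MKTLLV: {MKT,KTL,TLL,LLV}; of MKTLAV: {MKT,KTL,TLA,LAV}
        # shared 2, min size 4 -> d = 1 - 2/4 = 0.5
        recs = [
            pt.SequenceRecord("a", "MKTLLV"),
            pt.SequenceRecord("b", "MKTLAV"),
            pt.SequenceRecord("c", "MKTLLV"),
        ]
        dm = pt.kmer_distance_matrix(recs, k=3)
        assert dm.d[0, 1] == pytest.approx(0.5)

    def test_short_sequence_error(self):
        recs = [pt.SequenceRecord(i, "MK") for i in "abc"]
        with pytest.raises(ValueError, match="shorter than k"):
            pt.kmer_distance_matrix(recs, k=3)


# ---------------------------------------------------------------------------
# Neighbor joining


def brute_force_nj(labels, d):
    """Independent NJ oracle: plain dict/loop implementation, recomputing
    all sums each iteration; same Q-criterion, clamping and tie-break."""
    import skbio

    d = {a: {b: float(d[i][j]) for j, b in enumerate(labels) if b != a}
         for i, a in enumerate(labels)}
    nodes = {a: skbio.TreeNode(name=a) for a in labels}
    tags = {a: a for a in labels}
    counter = [0]
    while len(d) > 3:
        n = len(d)
        keys = sorted(d)
        best = None
        for a in keys:
            for b in keys:
                if b <= a:
                    continue
                q = (n - 2) * d[a][b] - sum(d[a].values()) - sum(d[b].values())
                tag_pair = tuple(sorted((tags[a], tags[b])))
                if best is None or (q, tag_pair) < (best[0], best[1]):
                    best = (q, tag_pair, a, b)
        _, _, a, b = best
        la = 0.5 * d[a][b] + (sum(d[a].values()) - sum(d[b].values())) / (2 * (n - 2))
        lb = d[a][b] - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        new = f"__int{counter[0]}"
        counter[0] += 1
        nodes[a].length, nodes[b].length = la, lb
        nodes[new] = skbio.TreeNode(children=[nodes[a], nodes[b]])
        tags[new] = min(tags[a], tags[b])
        dn = {}
        for c in d:
            if c in (a, b):
                continue
            dn[c] = 0.5 * (d[a][c] + d[b][c] - d[a][b])
        for c in list(d):
            d[c].pop(a, None)
            d[c].pop(b, None)
        del d[a], d[b]
        for c, v in dn.items():
            d[c][new] = v
        d[new] = dn
    a, b, c = sorted(d, key=lambda x: tags[x])
    root = skbio.TreeNode()
    for x, ln in (
        (a, 0.5 * (d[a][b] + d[a][c] - d[b][c])),
        (b, 0.5 * (d[a][b] + d[b][c] - d[a][c])),
        (c, 0.5 * (d[a][c] + d[b][c] - d[a][b])),
    ):
        nodes[x].length = max(ln, 0.0)
        root.append(nodes[x])
    return root


def tip_distances(tree):
    tips = sorted(t.name for t in tree.tips())
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            out[(a, b)] = tree.find(a).distance(tree.find(b))
    return out


class TestNeighborJoining:
    def test_three_leaf_closed_form(self):
        # d(A,B)=2, d(A,C)=d(B,C)=4 -> branches A:1, B:1, C:3
        dm = DistanceMatrix(
            labels=["A", "B", "C"],
            d=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
        )
        tree = pt.nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_asymmetric_matrix_error(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=list("ABC"), d=[[0, 1, 2], [9, 0, 1], [2, 1, 0]])

    def test_nonfinite_matrix_error(self):
        bad = np.zeros((3, 3))
        bad[0, 1] = bad[1, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            DistanceMatrix(labels=list("ABC"), d=bad)

    def test_recovers_planted_5_leaf_topology(self):
        tree, _, dmat = synth_tree_and_sequences(FixtureSpec(seed=3, tree_leaves=5))
        labels = [t.name for t in tree.tips()]
        nj = pt.nj_tree(DistanceMatrix(labels=labels, d=dmat))
        assert nj.compare_rfd(tree) == 0.0
        # additive matrix: NJ reproduces the exact path lengths
        got = tip_distances(nj)
        for (a, b), dist in tip_distances(tree).items():
            assert got[(a, b)] == pytest.approx(dist, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle_on_additive_matrices(self, seed):
        n_leaves = 4 + (seed % 9)
        tree, _, dmat = synth_tree_and_sequences(
            FixtureSpec(seed=100 + seed, tree_leaves=n_leaves)
        )
        labels = [t.name for t in tree.tips()]
        ours = pt.nj_tree(DistanceMatrix(labels=labels, d=dmat))
        oracle = brute_force_nj(labels, dmat)
        assert ours.compare_rfd(oracle) == 0.0
        got, want = tip_distances(ours), tip_distances(oracle)
        for key in want:
            assert got[key] == pytest.approx(want[key], abs=1e-9)


# ---------------------------------------------------------------------------
# MSA ordering / enumeration


def make_alignment(ids):
    seqs = {"A": "MK-L", "B": "M-KL", "C": "MKL-"}
    return pt.Alignment(
        records=[pt.SequenceRecord(i, seqs[i]) for i in ids], aligned=True
    )


class TestSortAlignment:
    def test_rows_follow_leaf_order(self):
        tree = pt.read_newick("(B,(A,C));")
        out = pt.sort_alignment_by_tree(make_alignment(["A", "B", "C"]), tree)
        assert out.ids == ["B", "A", "C"]

    def test_identity_when_already_sorted(self):
        tree = pt.read_newick("(A,(B,C));")
        aln = make_alignment(["A", "B", "C"])
        assert pt.sort_alignment_by_tree(aln, tree).ids == ["A", "B", "C"]

    def test_missing_leaf_error_names_difference(self):
        tree = pt.read_newick("(B,(A,C));")
        with pytest.raises(ValueError, match="C"):
            pt.sort_alignment_by_tree(make_alignment(["A", "B"]), tree)

    def test_pure_permutation(self):
        tree = pt.read_newick("(C,(B,A));")
        aln = make_alignment(["A", "B", "C"])
        out = pt.sort_alignment_by_tree(aln, tree)
        assert sorted(r.residues for r in out.records) == sorted(
            r.residues for r in aln.records
        )


class TestEnumerateLeaves:
    def test_indices_match_display_order(self):
        tree = pt.read_newick("(B,(A,C));")
        aln = pt.sort_alignment_by_tree(make_alignment(["A", "B", "C"]), tree)
        etree, ealn = pt.enumerate_leaves(tree, aln)
        assert [t.name for t in etree.tips()] == ["1. B", "2. A", "3. C"]
        assert ealn.ids == ["1. B", "2. A", "3. C"]

    def test_unsorted_alignment_error(self):
        tree = pt.read_newick("(B,(A,C));")
        with pytest.raises(ValueError, match="sorted"):
            pt.enumerate_leaves(tree, make_alignment(["A", "B", "C"]))

    def test_reenumeration_error(self):
        tree = pt.read_newick("(B,(A,C));")
        aln = pt.sort_alignment_by_tree(make_alignment(["A", "B", "C"]), tree)
        etree, ealn = pt.enumerate_leaves(tree, aln)
        with pytest.raises(ValueError, match="already enumerated"):
            pt.enumerate_leaves(etree, ealn)


# ---------------------------------------------------------------------------
# Pipeline driver


class TestDomainsPipeline:
    def test_full_mode_on_fixture(self, genome_fixture):
        config = pt.DomainsConfig()
        hits = pt.read_hits_tsv(genome_fixture.hits_tsv)
        recs = pt.read_fasta(genome_fixture.fasta)[:6]
        fasta = pt.write_fasta(recs)
        result = pt.run_domains_pipeline(fasta, config, hits=hits)
        assert result.tree.count(tips=True) == 6
        assert result.alignment is not None and len(result.alignment) == 6
        assert set(result.alignment.ids) == {r.id for r in recs}
        for rec in recs:
            assert rec.id in result.architectures or not any(
                h.protein_id == rec.id for h in hits
            )
        assert result.metadata["tree_source"] == "builtin_nj"
        assert result.metadata["evalue_max"] == 0.01

    def test_partial_mode_uses_tree_verbatim(self, genome_fixture):
        recs = pt.read_fasta(genome_fixture.fasta)[:4]
        tree_text = pt.write_newick(
            pt.nj_tree(pt.kmer_distance_matrix(recs, k=3))
        )
        result = pt.run_domains_pipeline(
            pt.write_fasta(recs),
            pt.DomainsConfig(mode="partial"),
            tree_text=tree_text,
        )
        assert pt.write_newick(result.tree) == tree_text
        assert result.metadata["tree_source"] == "user"

    def test_partial_mode_without_tree_error(self):
        with pytest.raises(ValueError, match="tree"):
            pt.run_domains_pipeline(
                ">A\nMKTLLV\n>B\nMKTLAV\n", pt.DomainsConfig(mode="partial")
            )

    def test_two_area_mode_joins_by_id(self, genome_fixture):
        recs = pt.read_fasta(genome_fixture.fasta)[:4]
        fragments = [
            pt.SequenceRecord(r.id, r.residues[:50]) for r in recs
        ]
        hits = pt.read_hits_tsv(genome_fixture.hits_tsv)
        result = pt.run_domains_pipeline(
            pt.write_fasta(recs),
            pt.DomainsConfig(),
            hits=hits,
            fragments_text=pt.write_fasta(fragments),
        )
        # tree from fragments; every leaf has a full-length architecture
        for tip in result.tree.tips():
            assert tip.name in result.architectures

    def test_two_area_mode_id_mismatch_error(self):
        with pytest.raises(ValueError, match="identical ids"):
            pt.run_domains_pipeline(
                ">A\nMKTLLVAA\n>B\nMKTLAVAA\n>C\nMKWLAVAA\n",
                pt.DomainsConfig(),
                fragments_text=">A\nMKTL\n>X\nMKTL\n>C\nMKWL\n",
            )

    def test_prealigned_input_skips_aligner(self):
        msa = ">A\nMKTLL-\n>B\nMKTL-V\n>C\nMK-LAV\n"
        result = pt.run_domains_pipeline(msa, pt.DomainsConfig())
        assert result.metadata["alignment_source"] == "user"
        assert result.alignment.aligned

    def test_deterministic_output(self, genome_fixture):
        fasta = pt.write_fasta(pt.read_fasta(genome_fixture.fasta)[:5])
        hits = pt.read_hits_tsv(genome_fixture.hits_tsv)
        r1 = pt.run_domains_pipeline(fasta, pt.DomainsConfig(), hits=hits)
        r2 = pt.run_domains_pipeline(fasta, pt.DomainsConfig(), hits=hits)
        assert pt.export_json(r1) == pt.export_json(r2)
        assert pt.write_newick(r1.tree) == pt.write_newick(r2.tree)


class TestExternalAdapter:
    def test_template_runs_and_reads_output(self, tmp_path):
        out = run_external_tool("cp {input} {output}", ">A\nMK\n")
        assert out == ">A\nMK\n"

    def test_failure_raises(self):
        with pytest.raises(RuntimeError, match="external tool failed"):
            run_external_tool("false {input} {output}", "x")
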