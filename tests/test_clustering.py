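"""Clustering tests, including the exhaustive alignment oracle.

The oracle never uses the production fast paths: it scores every ordered
pair with a full Biopython local alignment and then replays the same greedy
first-fit rule on that exhaustive containment graph.
"""

import numpy as np
import pytest
from Bio import Align

from mvi import clustering as cl
from mvi.io_model import ContigRecord, ValidationError

from conftest import make_contig, random_seq


def _mutate(rng, seq, rate):
    bases = "ACGT"
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(bases[int(rng.integers(4))])
        else:
            out.append(ch)
    return "".join(out)


# -- independent oracle -----------------------------------------------------

_oracle_aligner = Align.PairwiseAligner(
    mode="local", match_score=1, mismatch_score=-1, open_gap_score=-2, extend_gap_score=-0.5
)


def oracle_containment(query: str, target: str):
    """Identity/coverage of query in target from a full local alignment."""
    aln = _oracle_aligner.align(target, query)
    if len(aln) == 0:
        return 0.0, 0.0
    best = aln[0]
    blocks_t, blocks_q = best.aligned
    if len(blocks_q) == 0:
        return 0.0, 0.0
    q_span = int(blocks_q[-1][1] - blocks_q[0][0])
    t_span = int(blocks_t[-1][1] - blocks_t[0][0])
    cols = max(q_span, t_span)
    identity = best.counts().identities / cols if cols else 0.0
    return identity, q_span / len(query)


def oracle_cluster(contigs, identity_min=0.95, coverage_min=0.90):
    """Greedy first-fit on the exhaustive all-pairs containment graph."""
    ordered = sorted(contigs, key=lambda c: (-c.length_bp, c.contig_id))
    clusters = []
    for c in ordered:
        placed = False
        for cluster in clusters:
            rep = cluster[0]
            ident, cov = oracle_containment(c.sequence, rep.sequence)
            if ident >= identity_min and cov >= coverage_min:
                cluster.append(c)
                placed = True
                break
        if not placed:
            clusters.append([c])
    return [frozenset(m.contig_id for m in cluster) for cluster in clusters]


# -- unit tests -------------------------------------------------------------


class TestContainmentHit:
    def test_identical_sequences(self, rng):
        seq = random_seq(rng, 5000)
        hit = cl.containment_hit("a", "b", seq, seq)
        assert hit.identity == 1.0 and hit.coverage_of_smaller == 1.0

    def test_embedded_subsequence(self, rng):
        inner = random_seq(rng, 1000)
        outer = random_seq(rng, 4000) + inner + random_seq(rng, 5000)
        hit = cl.containment_hit("q", "t", inner, outer)
        assert hit is not None
        assert (hit.target_start, hit.target_end) == (4000, 5000)

    def test_mutated_containment_found_by_anchor_path(self, rng):
        inner = random_seq(rng, 3000)
        mutated = _mutate(rng, inner, 0.02)
        outer = random_seq(rng, 2000) + inner + random_seq(rng, 2000)
        hit = cl.containment_hit("q", "t", mutated, outer)
        assert hit is not None
        assert 0.95 <= hit.identity < 1.0
        assert hit.coverage_of_smaller == 1.0

    def test_random_pair_rejected(self, rng):
        a, b = random_seq(rng, 5000), random_seq(rng, 5000)
        assert cl.containment_hit("a", "b", a, b) is None

    def test_random_pair_identity_far_below_threshold(self, rng):
        # oracle view of the same fixture: expected local identity ~0.25 regime
        a, b = random_seq(rng, 1000), random_seq(rng, 1000)
        ident, cov = oracle_containment(a, b)
        assert ident * cov < 0.5  # nowhere near 0.95 x 0.90


class TestContainmentCluster:
    def test_identical_pair_single_cluster(self, rng):
        seq = random_seq(rng, 5000)
        contigs = [
            make_contig("a", 5000, seq, is_viral=True),
            make_contig("b", 5000, seq, is_viral=True),
        ]
        res = cl.containment_cluster(contigs)
        assert len(res.clusters) == 1
        assert set(res.clusters[0].members) == {"a", "b"}

    def test_embedded_contig_joins_host_cluster(self, rng):
        inner = random_seq(rng, 1000)
        outer = random_seq(rng, 4500) + inner + random_seq(rng, 4500)
        contigs = [
            make_contig("viral", 1000, inner, is_viral=True),
            make_contig("host", 10000, outer),
        ]
        res = cl.containment_cluster(contigs)
        assert len(res.clusters) == 1
        hit = res.clusters[0].hits[0]
        assert hit.identity == 1.0 and hit.coverage_of_smaller == 1.0

    def test_independent_contigs_stay_separate(self, rng):
        contigs = [
            make_contig("a", 5000, random_seq(rng, 5000)),
            make_contig("b", 5000, random_seq(rng, 5000)),
        ]
        res = cl.containment_cluster(contigs)
        assert len(res.clusters) == 2

    def test_partition_property(self, small_community):
        com, _ = small_community
        res = cl.containment_cluster(com.contigs)
        members = [m for p in res.partition() for m in p]
        assert sorted(members) == sorted(c.contig_id for c in com.contigs)

    def test_missing_sequence_rejected(self):
        with pytest.raises(ValidationError, match="noseq"):
            cl.containment_cluster([make_contig("noseq", 100)])

    def test_deterministic_given_input_shuffle(self, rng):
        seqs = [random_seq(rng, 800 + 100 * i) for i in range(8)]
        contigs = [make_contig(f"c{i}", len(s), s) for i, s in enumerate(seqs)]
        p1 = cl.containment_cluster(contigs).partition()
        shuffled = [contigs[i] for i in rng.permutation(len(contigs))]
        p2 = cl.containment_cluster(shuffled).partition()
        assert p1 == p2

    def test_monotone_in_identity_threshold(self, rng):
        inner = random_seq(rng, 2000)
        variants = [
            make_contig("v1", 2000, _mutate(rng, inner, 0.02), is_viral=True),
            make_contig("v2", 2000, _mutate(rng, inner, 0.08), is_viral=True),
        ]
        base = make_contig("base", 6000, random_seq(rng, 2000) + inner + random_seq(rng, 2000))
        contigs = [base] + variants
        n_clusters = [
            len(cl.containment_cluster(contigs, identity_min=t).clusters)
            for t in (0.99, 0.95, 0.85)
        ]
        assert n_clusters == sorted(n_clusters, reverse=True)

    def test_oracle_equivalence_small_fixture(self, rng):
        # <=50 contigs with embeddings, duplicates, mutations and noise
        contigs = []
        for i in range(6):
            seq = random_seq(rng, int(rng.integers(400, 900)))
            contigs.append(make_contig(f"base{i}", len(seq), seq))
            if i < 3:  # exact and mutated containments
                sub = seq[50 : 50 + 300]
                contigs.append(make_contig(f"sub{i}", 300, sub))
                mut = _mutate(rng, sub, 0.02)
                contigs.append(make_contig(f"mut{i}", 300, mut))
        for i in range(8):
            seq = random_seq(rng, int(rng.integers(300, 700)))
            contigs.append(make_contig(f"noise{i}", len(seq), seq))
        assert len(contigs) <= 50
        greedy = set(cl.containment_cluster(contigs).partition())
        oracle = set(oracle_cluster(contigs))
        assert greedy == oracle


class TestClassifySource:
    def test_mixed_cluster_is_both(self, rng):
        seq = random_seq(rng, 3000)
        contigs = [
            make_contig("mv", 3000, seq, source="metavirome", is_viral=True),
            make_contig("mg", 3000, seq, source="metagenome", is_viral=True),
        ]
        res = cl.containment_cluster(contigs)
        labels = cl.classify_source(res, contigs)
        assert list(labels.values()) == ["both"]

    def test_singleton_keeps_its_source(self, rng):
        contigs = [make_contig("mv", 1000, random_seq(rng, 1000), source="metavirome")]
        labels = cl.classify_source(cl.containment_cluster(contigs), contigs)
        assert labels == {"mv": "metavirome"}

    def test_generator_source_recovery(self, small_community):
        com, _ = small_community
        res = cl.containment_cluster(com.contigs)
        totals = cl.source_totals(cl.classify_source(res, com.contigs))
        t = com.truth.phages["lifestyle"].value_counts()
        assert totals["both"] == t.get("prophage_active", 0)
        assert totals["metagenome"] == t.get("prophage_inactive", 0)
        assert totals["metavirome"] == t.get("free", 0)
        assert totals["total"] == len(com.truth.phages)


class TestClassifyIntegration:
    def test_mv_contained_in_nonviral_is_ic(self, rng):
        inner = random_seq(rng, 1500)
        host_seq = random_seq(rng, 3000) + inner + random_seq(rng, 3000)
        vc = make_contig("vc", 1500, inner, source="metavirome", is_viral=True)
        host = make_contig("h1", 7500, host_seq)
        res = cl.containment_cluster([vc])
        cls_, hits = cl.classify_integration(res, [vc], [host])
        assert cls_[0].integration_class == "IC"
        assert cls_[0].evidence == "contained_in_nonviral"
        assert cls_[0].linked_host_contigs == {"h1"}
        assert len(hits) == 1

    def test_free_phage_is_ni(self, rng):
        vc = make_contig("vc", 1000, random_seq(rng, 1000), source="metavirome", is_viral=True)
        host = make_contig("h1", 4000, random_seq(rng, 4000))
        cls_, hits = cl.classify_integration(cl.containment_cluster([vc]), [vc], [host])
        assert cls_[0].integration_class == "NI"
        assert cls_[0].evidence == "none"
        assert not cls_[0].linked_host_contigs

    def test_pruned_flag_is_ic_evidence(self, rng):
        vc = make_contig(
            "vc", 1000, random_seq(rng, 1000),
            source="metagenome", is_viral=True, pruned_from="h9",
        )
        cls_, _ = cl.classify_integration(cl.containment_cluster([vc]), [vc], [])
        assert cls_[0].integration_class == "IC"
        assert cls_[0].evidence == "pruned_flanks"
        assert cls_[0].linked_host_contigs == {"h9"}

    def test_recovers_all_planted_prophages(self, small_community):
        com, _ = small_community
        res = cl.containment_cluster(com.contigs)
        cls_, _ = cl.classify_integration(res, com.contigs, com.nonviral_contigs)
        from mvi.synthetic import canonical_vc_id

        predicted_ic = {canonical_vc_id(c.vc_id) for c in cls_ if c.integration_class == "IC"}
        truth_ic = set(com.truth.phages[com.truth.phages.lifestyle != "free"].index)
        assert predicted_ic == truth_ic

    def test_invariant_enforced(self):
        with pytest.raises(ValidationError):
            cl.VCClassification("v", "metavirome", "IC", "none")
        with pytest.raises(ValidationError):
            cl.VCClassification("v", "metavirome", "IC", "pruned_flanks", set())


class TestMasking:
    def test_single_span_masked(self, rng):
        seq = random_seq(rng, 10000)
        host = make_contig("h", 10000, seq)
        # 1-based [2001, 3000] == 0-based half-open [2000, 3000)
        hit = cl.ContainmentHit("vc", "h", 1.0, 1.0, 2000, 3000)
        masked, masked_bp = cl.mask_prophage_regions([host], [hit])
        out = masked[0].sequence
        assert out[2000:3000] == "N" * 1000
        assert out[:2000] == seq[:2000] and out[3000:] == seq[3000:]
        assert masked_bp["h"] == 1000
        assert masked[0].length_bp == 10000  # unmasked length retained

    def test_no_spans_unchanged(self, rng):
        seq = random_seq(rng, 3000)
        host = make_contig("h", 3000, seq)
        masked, masked_bp = cl.mask_prophage_regions([host], [])
        assert masked[0].sequence == seq
        assert masked_bp["h"] == 0

    def test_overlapping_spans_merged(self, rng):
        seq = random_seq(rng, 1000)
        host = make_contig("h", 1000, seq)
        # 1-based [100,200] and [150,250] -> merged run of 151 positions
        hits = [
            cl.ContainmentHit("a", "h", 1.0, 1.0, 99, 200),
            cl.ContainmentHit("b", "h", 1.0, 1.0, 149, 250),
        ]
        masked, masked_bp = cl.mask_prophage_regions([host], hits)
        assert masked_bp["h"] == 151
        assert masked[0].sequence.count("N") == 151

    def test_merge_intervals(self):
        assert cl.merge_intervals([(5, 9), (1, 3), (2, 6)]) == [(1, 9)]
        assert cl.merge_intervals([]) == []
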