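"""Containment clustering of contigs and cross-dataset classification.

A smaller contig is *contained* in a larger one when it aligns at
>= ``identity_min`` identity over >= ``coverage_min`` of its own length.
Clustering is greedy and deterministic: contigs are visited in
length-descending (then id-ascending) order and join the first existing
cluster whose representative contains them, else found a new cluster.

Containment of a query in a target is established through a cascade:

1. exact substring (identity 1.0, coverage 1.0);
2. shared-k-mer anchor voting followed by an ungapped comparison at the
   modal offset (handles near-identical containment at any length);
3. full local alignment (Biopython) when the dynamic-programming matrix is
   small enough.

Candidate pairs are prescreened with FracMinHash k-mer sketches so that
unrelated random pairs are rejected in O(sketch) time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from mvi.io_model import ContigRecord, ValidationError

_K = 21
_SKETCH_SCALE = 32  # keep ~1/32 of k-mers
_PRESCREEN_MIN = 0.05
_MAX_DP_CELLS = 4_000_000

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


@dataclass(frozen=True)
class ContainmentHit:
    """Evidence that *query* is contained in the longer *target*."""

    query_id: str
    target_id: str
    identity: float
    coverage_of_smaller: float
    target_start: int  # 0-based half-open span on the target
    target_end: int


@dataclass
class Cluster:
    representative: str
    members: list[str] = field(default_factory=list)
    hits: list[ContainmentHit] = field(default_factory=list)


@dataclass
class ClusterResult:
    clusters: list[Cluster]

    @property
    def cluster_of(self) -> dict[str, int]:
        return {m: i for i, cl in enumerate(self.clusters) for m in cl.members}

    @property
    def representatives(self) -> list[str]:
        return [cl.representative for cl in self.clusters]

    def partition(self) -> list[frozenset[str]]:
        return [frozenset(cl.members) for cl in self.clusters]


@dataclass
class VCClassification:
    vc_id: str
    source: str
    integration_class: str  # "IC" | "NI"
    evidence: str  # "pruned_flanks" | "contained_in_nonviral" | "none"
    linked_host_contigs: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if (self.integration_class == "IC") != (self.evidence != "none"):
            raise ValidationError(f"{self.vc_id}: IC class requires evidence and vice versa")
        if self.integration_class == "IC" and not self.linked_host_contigs:
            raise ValidationError(f"{self.vc_id}: IC class requires linked host contigs")


# ---------------------------------------------------------------------------
# k-mer machinery
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        # non-ACGT (e.g. masked N runs) break k-mers; map to a sentinel base
        codes = np.where(codes == 255, 0, codes).astype(np.uint8)
    return codes


def _kmers(seq: str, k: int = _K) -> np.ndarray:
    """All k-mers of *seq* packed 2 bits/base into uint64."""
    codes = _encode(seq).astype(np.uint64)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(k):
            out = (out << np.uint64(2)) | codes[j : j + n]
    return out


def _mix64(x: np.ndarray) -> np.ndarray:
    # splitmix64 finalizer; uniformizes packed k-mers for sketching
    with np.errstate(over="ignore"):
        x = x.copy()
        x ^= x >> np.uint64(30)
        x *= np.uint64(0xBF58476D1CE4E5B9)
        x ^= x >> np.uint64(27)
        x *= np.uint64(0x94D049BB133111EB)
        x ^= x >> np.uint64(31)
    return x


def sketch(seq: str, k: int = _K, scale: int = _SKETCH_SCALE) -> frozenset[int]:
    """FracMinHash sketch: the k-mers whose hash falls in the bottom 1/scale."""
    km = np.unique(_kmers(seq, k))
    if km.size == 0:
        return frozenset()
    h = _mix64(km)
    kept = km[(h & np.uint64(scale - 1)) == 0]
    return frozenset(int(v) for v in kept)


def sketch_containment(query_sketch: frozenset[int], target_sketch: frozenset[int]) -> float:
    """Estimated fraction of query k-mers present in the target."""
    if not query_sketch:
        return 1.0  # too short to sketch; cannot rule out
    return len(query_sketch & target_sketch) / len(query_sketch)


# ---------------------------------------------------------------------------
# containment of one sequence in another
# ---------------------------------------------------------------------------


def _anchor_hit(query: str, target: str, k: int = _K) -> tuple[float, float, int, int] | None:
    """Ungapped containment at the modal shared-k-mer offset, or None."""
    qk = _kmers(query, k)
    tk = _kmers(target, k)
    if qk.size == 0 or tk.size == 0:
        return None
    qu, qi = np.unique(qk, return_index=True)
    tu, ti = np.unique(tk, return_index=True)
    common, iq, it = np.intersect1d(qu, tu, assume_unique=True, return_indices=True)
    if common.size == 0:
        return None
    offsets = ti[it].astype(np.int64) - qi[iq].astype(np.int64)
    vals, counts = np.unique(offsets, return_counts=True)
    off = int(vals[np.argmax(counts)])

    q = _encode(query)
    t = _encode(target)
    q_start = max(0, -off)
    q_end = min(len(q), len(t) - off)
    if q_end - q_start <= 0:
        return None
    compared = q_end - q_start
    matches = int((q[q_start:q_end] == t[q_start + off : q_end + off]).sum())
    identity = matches / compared
    coverage = compared / len(q)
    return identity, coverage, q_start + off, q_end + off


_aligner = Align.PairwiseAligner(
    mode="local",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-0.5,
)


def _dp_hit(query: str, target: str) -> tuple[float, float, int, int] | None:
    """Full local alignment for pairs small enough to afford the DP matrix."""
    aln = _aligner.align(target, query)
    if len(aln) == 0:
        return None
    best = aln[0]
    blocks_t, blocks_q = best.aligned
    if len(blocks_q) == 0:
        return None
    q_span = int(blocks_q[-1][1] - blocks_q[0][0])
    t_span = int(blocks_t[-1][1] - blocks_t[0][0])
    counts = best.counts()
    cols = max(q_span, t_span)
    if cols == 0:
        return None
    identity = counts.identities / cols
    coverage = q_span / len(query)
    return identity, coverage, int(blocks_t[0][0]), int(blocks_t[-1][1])


def containment_hit(
    query_id: str,
    target_id: str,
    query: str,
    target: str,
    identity_min: float = 0.95,
    coverage_min: float = 0.90,
    max_dp_cells: int = _MAX_DP_CELLS,
) -> ContainmentHit | None:
    """Test whether *query* is contained in *target* at the thresholds.

    Assumes ``len(query) <= len(target)`` (the caller orients the pair).
    """
    pos = target.find(query)
    if pos >= 0:
        return ContainmentHit(query_id, target_id, 1.0, 1.0, pos, pos + len(query))

    anchored = _anchor_hit(query, target)
    if anchored is not None:
        identity, coverage, t_start, t_end = anchored
        if identity >= identity_min and coverage >= coverage_min:
            return ContainmentHit(query_id, target_id, identity, coverage, t_start, t_end)

    if len(query) * len(target) <= max_dp_cells:
        dp = _dp_hit(query, target)
        if dp is not None:
            identity, coverage, t_start, t_end = dp
            if identity >= identity_min and coverage >= coverage_min:
                return ContainmentHit(query_id, target_id, identity, coverage, t_start, t_end)
    return None


# ---------------------------------------------------------------------------
# greedy clustering
# ---------------------------------------------------------------------------


def _ordered(contigs: Sequence[ContigRecord]) -> list[ContigRecord]:
    return sorted(contigs, key=lambda c: (-c.length_bp, c.contig_id))


def containment_cluster(
    contigs: Sequence[ContigRecord],
    identity_min: float = 0.95,
    coverage_min: float = 0.90,
) -> ClusterResult:
    """Greedy containment clustering (length-descending, first-fit)."""
    for c in contigs:
        if c.sequence is None:
            raise ValidationError(f"contig {c.contig_id} has no sequence; cannot cluster")

    clusters: list[Cluster] = []
    rep_seqs: list[str] = []
    rep_sketches: list[frozenset[int]] = []

    for contig in _ordered(contigs):
        q_sketch = sketch(contig.sequence)
        joined = False
        for idx, cluster in enumerate(clusters):
            if sketch_containment(q_sketch, rep_sketches[idx]) < _PRESCREEN_MIN:
                continue
            hit = containment_hit(
                contig.contig_id,
                cluster.representative,
                contig.sequence,
                rep_seqs[idx],
                identity_min,
                coverage_min,
            )
            if hit is not None:
                cluster.members.append(contig.contig_id)
                cluster.hits.append(hit)
                joined = True
                break
        if not joined:
            clusters.append(Cluster(representative=contig.contig_id, members=[contig.contig_id]))
            rep_seqs.append(contig.sequence)
            rep_sketches.append(q_sketch)
    return ClusterResult(clusters=clusters)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_source(
    cluster_result: ClusterResult, contigs: Sequence[ContigRecord]
) -> dict[str, str]:
    """Per-VC source label: which assembly dataset(s) the cluster draws on."""
    by_id = {c.contig_id: c for c in contigs}
    labels: dict[str, str] = {}
    for cl in cluster_result.clusters:
        sources = {by_id[m].source for m in cl.members}
        if "both" in sources or {"metavirome", "metagenome"} <= sources:
            labels[cl.representative] = "both"
        else:
            (only,) = sources
            labels[cl.representative] = only
    return labels


def source_totals(labels: Mapping[str, str] | Iterable[str]) -> dict[str, int]:
    """Accounting of VCs per source category, plus the grand total."""
    values = list(labels.values()) if isinstance(labels, Mapping) else list(labels)
    totals = {
        "metavirome": sum(1 for v in values if v == "metavirome"),
        "metagenome": sum(1 for v in values if v == "metagenome"),
        "both": sum(1 for v in values if v == "both"),
    }
    totals["total"] = sum(totals.values())
    return totals


def classify_integration(
    cluster_result: ClusterResult,
    contigs: Sequence[ContigRecord],
    nonviral_contigs: Sequence[ContigRecord],
    identity_min: float = 0.95,
    coverage_min: float = 0.90,
) -> tuple[list[VCClassification], list[ContainmentHit]]:
    """Split VCs into integration-capable (IC) vs non-integrated (NI).

    A VC is IC when (a) its cluster includes a metagenome-derived member
    flagged as pruned from a longer contig, or (b) one of its
    metavirome-derived members is contained within a non-viral contig at the
    clustering thresholds.  A VC may link to several host contigs and a host
    may carry several VCs.

    Returns the per-VC classifications and all member-in-host containment
    hits (used downstream for prophage masking).
    """
    by_id = {c.contig_id: c for c in contigs}
    source_labels = classify_source(cluster_result, contigs)

    host_seqs = []
    host_sketches = []
    for h in nonviral_contigs:
        if h.sequence is None:
            raise ValidationError(f"non-viral contig {h.contig_id} has no sequence")
        host_seqs.append(h.sequence)
        host_sketches.append(sketch(h.sequence))

    classifications = []
    all_host_hits: list[ContainmentHit] = []
    for cl in cluster_result.clusters:
        linked: set[str] = set()
        pruned_evidence = False
        contained_evidence = False
        for member_id in cl.members:
            member = by_id[member_id]
            if member.pruned_from is not None:
                pruned_evidence = True
                linked.add(member.pruned_from)
            if member.sequence is None:
                continue
            q_sketch = sketch(member.sequence)
            for h, host in enumerate(nonviral_contigs):
                if member.length_bp > host.length_bp:
                    continue
                if sketch_containment(q_sketch, host_sketches[h]) < _PRESCREEN_MIN:
                    continue
                hit = containment_hit(
                    member_id,
                    host.contig_id,
                    member.sequence,
                    host_seqs[h],
                    identity_min,
                    coverage_min,
                )
                if hit is not None:
                    all_host_hits.append(hit)
                    if member.source == "metavirome":
                        contained_evidence = True
                        linked.add(host.contig_id)

        if pruned_evidence:
            evidence = "pruned_flanks"
        elif contained_evidence:
            evidence = "contained_in_nonviral"
        else:
            evidence = "none"
            linked = set()
        classifications.append(
            VCClassification(
                vc_id=cl.representative,
                source=source_labels[cl.representative],
                integration_class="IC" if evidence != "none" else "NI",
                evidence=evidence,
                linked_host_contigs=linked,
            )
        )
    return classifications, all_host_hits


# ---------------------------------------------------------------------------
# prophage masking
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def mask_prophage_regions(
    nonviral_contigs: Sequence[ContigRecord],
    host_hits: Sequence[ContainmentHit],
) -> tuple[list[ContigRecord], dict[str, int]]:
    """Replace prophage spans in host contigs with N runs.

    Overlapping spans are merged before masking so no position is counted
    twice.  ``length_bp`` of the returned records is unchanged: host
    length-normalization continues to use the unmasked length.  The second
    return value maps host id to the number of masked positions.
    """
    spans_by_host: dict[str, list[tuple[int, int]]] = {}
    for hit in host_hits:
        spans_by_host.setdefault(hit.target_id, []).append((hit.target_start, hit.target_end))

    masked: list[ContigRecord] = []
    masked_bp: dict[str, int] = {}
    for host in nonviral_contigs:
        spans = merge_intervals(spans_by_host.get(host.contig_id, []))
        if not spans or host.sequence is None:
            masked.append(host)
            masked_bp[host.contig_id] = 0
            continue
        seq = list(host.sequence)
        total = 0
        for start, end in spans:
            end = min(end, len(seq))
            seq[start:end] = "N" * (end - start)
            total += end - start
        masked.append(
            ContigRecord(
                contig_id=host.contig_id,
                length_bp=host.length_bp,
                sequence="".join(seq),
                source=host.source,
                is_viral=host.is_viral,
                quality=host.quality,
                taxonomy_order=host.taxonomy_order,
                taxonomy_family=host.taxonomy_family,
            )
        )
        masked_bp[host.contig_id] = total
    return masked, masked_bp
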