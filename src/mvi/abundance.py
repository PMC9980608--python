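"""Breadth-filtered, length-normalized relative abundance (NRA) and QC.

For contig *i* in a sample, ``x_i`` is mapped reads divided by contig length
(reads per bp) and ``NRA_i = x_i / sum_j x_j`` over every contig in that
dataset's mapping universe (viral and non-viral alike).  The breadth filter
is applied to metagenome and metavirome tables *before* normalization;
metatranscriptome tables pass through unfiltered.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mvi.io_model import ContigRecord, OmicsMatrix, ValidationError

logger = logging.getLogger(__name__)

BREADTH_MIN_DEFAULT = 0.75


def _length_map(contigs: Sequence[ContigRecord] | Mapping[str, int]) -> Mapping[str, int]:
    if isinstance(contigs, Mapping):
        return contigs
    return {c.contig_id: c.length_bp for c in contigs}


def _viral_map(contigs: Sequence[ContigRecord]) -> Mapping[str, bool]:
    return {c.contig_id: c.is_viral for c in contigs}


def apply_breadth_filter(
    matrix: OmicsMatrix,
    breadth_min: float = BREADTH_MIN_DEFAULT,
    datasets: frozenset[str] | set[str] = frozenset({"MG", "MV"}),
) -> OmicsMatrix:
    """Zero out cells whose breadth of coverage falls below the threshold.

    Only matrices whose dataset is in *datasets* are filtered; others (the
    metatranscriptome by default) are returned as an unmodified copy.  The
    input matrix is never mutated.
    """
    for ds in datasets:
        if ds not in ("MG", "MV", "MT"):
            raise ValidationError(f"unknown dataset label {ds!r} in filter set")
    out = matrix.copy()
    if matrix.dataset not in datasets:
        return out
    below = out.breadth.to_numpy() < breadth_min
    counts = out.counts.to_numpy().copy()
    breadth = out.breadth.to_numpy().copy()
    counts[below] = 0
    breadth[below] = 0.0
    out.counts = pd.DataFrame(counts, index=out.counts.index, columns=out.counts.columns)
    out.breadth = pd.DataFrame(breadth, index=out.breadth.index, columns=out.breadth.columns)
    out.validate()
    return out


def compute_nra(
    matrix: OmicsMatrix,
    contigs: Sequence[ContigRecord] | Mapping[str, int],
) -> pd.DataFrame:
    """Length-normalize counts and renormalize per sample to sum to 1.

    For masked host contigs, pass the *unmasked* length.  All-zero samples
    yield all-zero NRA columns with a warning rather than dividing by zero.
    """
    lengths = _length_map(contigs)
    missing = [cid for cid in matrix.contig_ids if cid not in lengths]
    if missing:
        raise ValidationError(f"no length for contigs: {missing[:5]}")
    lvec = np.array([lengths[cid] for cid in matrix.contig_ids], dtype=float)
    if (lvec <= 0).any():
        raise ValidationError("non-positive contig length")
    x = matrix.counts.to_numpy(dtype=float) / lvec[:, None]
    totals = x.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        logger.warning(
            "all-zero samples in %s NRA: %s",
            matrix.dataset,
            [s for s, z in zip(matrix.sample_ids, zero_cols) if z],
        )
    safe = np.where(zero_cols, 1.0, totals)
    nra = x / safe
    return pd.DataFrame(nra, index=matrix.counts.index, columns=matrix.counts.columns)


def viral_fraction(
    nra: pd.DataFrame, contigs: Sequence[ContigRecord]
) -> tuple[pd.Series, float]:
    """Share of each sample's NRA carried by viral contigs, plus the mean."""
    viral = _viral_map(contigs)
    mask = np.array([viral.get(cid, False) for cid in nra.index])
    per_sample = nra.loc[mask].sum(axis=0)
    per_sample.name = "viral_fraction"
    return per_sample, float(per_sample.mean())


def viral_only_nra(nra: pd.DataFrame, contigs: Sequence[ContigRecord]) -> pd.DataFrame:
    """Derived view: NRA renormalized over viral contigs only (for ecology)."""
    viral = _viral_map(contigs)
    mask = np.array([viral.get(cid, False) for cid in nra.index])
    sub = nra.loc[mask]
    totals = sub.sum(axis=0)
    safe = totals.replace(0, 1.0)
    return sub / safe


def contamination_qc(qc_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample contamination QC summary.

    *qc_table* has one row per sample with columns ``sample_id``,
    ``dataset``, ``site``, ``participant``, ``total_reads``, ``host_reads``,
    ``marker_reads``.  Returns the table augmented with ``host_fraction``
    and ``marker_per_million`` plus, for each (participant, site) with both
    MG and MV rows, the marker-rate fold change MG/MV.  A zero MV marker
    rate yields an infinite fold change with the ``fold_change_inf`` flag.
    """
    df = qc_table.copy()
    if (df["host_reads"] > df["total_reads"]).any():
        raise ValidationError("host_reads exceeds total_reads")
    df["host_fraction"] = df["host_reads"] / df["total_reads"]
    df["marker_per_million"] = 1e6 * df["marker_reads"] / df["total_reads"]

    fold_rows = []
    for (participant, site), grp in df.groupby(["participant", "site"]):
        mg = grp[grp["dataset"] == "MG"]
        mv = grp[grp["dataset"] == "MV"]
        if mg.empty or mv.empty:
            continue
        mg_rate = float(mg["marker_per_million"].iloc[0])
        mv_rate = float(mv["marker_per_million"].iloc[0])
        inf = mv_rate == 0
        fold = np.inf if inf else mg_rate / mv_rate
        fold_rows.append(
            {
                "participant": participant,
                "site": site,
                "fold_change_MG_vs_MV": fold,
                "fold_change_inf": inf,
            }
        )
    folds = pd.DataFrame(fold_rows)
    return df.merge(folds, on=["participant", "site"], how="left")
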