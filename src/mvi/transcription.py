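"""Transcriptional-activity calls and transcription-ratio statistics.

A complete/high-quality VC is transcriptionally active (TA) in a sample when
its metatranscriptome NRA reaches the activity threshold (default 1e-6, i.e.
0.0001%).  Genes of TA VCs with more than one metatranscriptome count in
that sample are "transcribed"; genes of non-TA VCs are "not_evaluated",
which is distinct from "not_transcribed".  The ">1 counts" rule is applied
per sample (recorded in the output header by the CLI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mvi.io_model import ContigRecord, GeneRecord, SampleMeta, ValidationError

logger = logging.getLogger(__name__)

TA_THRESHOLD_DEFAULT = 1e-6
TA_QUALITY = frozenset({"complete", "high"})


@dataclass
class ActivityCall:
    vc_id: str
    sample_id: str
    is_present_MG: bool
    is_present_MV: bool
    is_TA: bool
    nra_MT: float
    transcription_ratio: float | None  # None when NRA_MG == 0


def sample_pairing(samples: Sequence[SampleMeta]) -> dict[tuple[str, str], dict[str, str]]:
    """Map (participant, site) -> {dataset: sample_id}."""
    pairing: dict[tuple[str, str], dict[str, str]] = {}
    for s in samples:
        pairing.setdefault((s.participant, s.site), {})[s.dataset] = s.sample_id
    return pairing


def call_ta(
    nra_mt: pd.DataFrame,
    contigs: Sequence[ContigRecord],
    samples: Sequence[SampleMeta],
    detection_mg: pd.DataFrame | None = None,
    detection_mv: pd.DataFrame | None = None,
    nra_mg: pd.DataFrame | None = None,
    ta_threshold: float = TA_THRESHOLD_DEFAULT,
    quality_filter: frozenset[str] = TA_QUALITY,
    strict: bool = False,
) -> pd.DataFrame:
    """Call transcriptional activity per (VC, metatranscriptome sample).

    Restricted to VCs whose quality tier is in *quality_filter*.  The
    threshold comparison is ``>=`` by default; pass ``strict=True`` for a
    strictly-greater convention.  ``detection_mg``/``detection_mv`` are
    boolean presence frames from breadth-filtered matrices, matched to MT
    samples through the shared (participant, site).
    """
    if nra_mt.shape[1] == 0:
        logger.warning("no metatranscriptome samples; no activity calls")
        return pd.DataFrame(
            columns=[
                "vc_id", "sample_id", "is_present_MG", "is_present_MV",
                "is_TA", "nra_MT", "transcription_ratio",
            ]
        )
    quality = {c.contig_id: c.quality for c in contigs}
    eligible = [cid for cid in nra_mt.index if quality.get(cid) in quality_filter]
    by_sample = {s.sample_id: s for s in samples}
    pairing = sample_pairing(samples)

    rows = []
    for mt_sample in nra_mt.columns:
        meta = by_sample.get(mt_sample)
        paired = pairing.get((meta.participant, meta.site), {}) if meta else {}
        mg_sample = paired.get("MG")
        mv_sample = paired.get("MV")
        for cid in eligible:
            value = float(nra_mt.at[cid, mt_sample])
            is_ta = value > ta_threshold if strict else value >= ta_threshold
            present_mg = bool(
                detection_mg is not None
                and mg_sample in getattr(detection_mg, "columns", [])
                and cid in detection_mg.index
                and detection_mg.at[cid, mg_sample]
            )
            present_mv = bool(
                detection_mv is not None
                and mv_sample in getattr(detection_mv, "columns", [])
                and cid in detection_mv.index
                and detection_mv.at[cid, mv_sample]
            )
            ratio: float | None = None
            if nra_mg is not None and mg_sample in nra_mg.columns and cid in nra_mg.index:
                denom = float(nra_mg.at[cid, mg_sample])
                if denom > 0:
                    ratio = value / denom
            rows.append(
                {
                    "vc_id": cid,
                    "sample_id": mt_sample,
                    "is_present_MG": present_mg,
                    "is_present_MV": present_mv,
                    "is_TA": is_ta,
                    "nra_MT": value,
                    "transcription_ratio": ratio,
                }
            )
    return pd.DataFrame(rows)


def call_transcribed_genes(
    gene_counts_mt: pd.DataFrame,
    genes: Sequence[GeneRecord],
    activity: pd.DataFrame,
    min_count: int = 2,
) -> pd.DataFrame:
    """Per (gene, MT sample) transcription status.

    Status is ``transcribed`` when the gene sits on a VC that is TA in that
    sample and has ``>= min_count`` metatranscriptome counts (the default 2
    encodes the strictly-more-than-one rule); ``not_transcribed`` when the
    VC is TA but the gene falls short; ``not_evaluated`` when the VC is not
    TA in that sample or is outside the evaluated quality tiers.
    """
    gene_contig = {g.gene_id: g.contig_id for g in genes}
    ta_lookup: dict[tuple[str, str], bool] = {
        (r.vc_id, r.sample_id): bool(r.is_TA) for r in activity.itertuples(index=False)
    }
    rows = []
    for gene_id in gene_counts_mt.index:
        cid = gene_contig.get(gene_id)
        if cid is None:
            raise ValidationError(f"gene {gene_id} in count table but not in gene records")
        for sample_id in gene_counts_mt.columns:
            key = (cid, sample_id)
            if key not in ta_lookup or not ta_lookup[key]:
                status = "not_evaluated"
            elif int(gene_counts_mt.at[gene_id, sample_id]) >= min_count:
                status = "transcribed"
            else:
                status = "not_transcribed"
            rows.append(
                {
                    "gene_id": gene_id,
                    "contig_id": cid,
                    "sample_id": sample_id,
                    "status": status,
                }
            )
    return pd.DataFrame(rows)


def transcription_ratio_table(
    nra_mt: pd.DataFrame,
    nra_mg: pd.DataFrame,
    samples: Sequence[SampleMeta],
) -> pd.DataFrame:
    """MT/MG NRA ratio per entity per (participant, site).

    Ratios are computed strictly within a (participant, site) pairing —
    never pooled across participants, since NRA denominators differ per
    sample.  Cells with zero metagenome NRA are NaN (undefined) and the
    per-entity ``n_undefined`` column counts them.
    """
    pairing = sample_pairing(samples)
    shared = [cid for cid in nra_mt.index if cid in nra_mg.index]
    cols = []
    data = {}
    for (participant, site), ds_map in sorted(pairing.items()):
        if "MT" not in ds_map or "MG" not in ds_map:
            continue
        mt_s, mg_s = ds_map["MT"], ds_map["MG"]
        if mt_s not in nra_mt.columns or mg_s not in nra_mg.columns:
            continue
        label = f"{participant}_{site}"
        cols.append(label)
        mt = nra_mt.loc[shared, mt_s].to_numpy(dtype=float)
        mg = nra_mg.loc[shared, mg_s].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(mg > 0, mt / np.where(mg > 0, mg, 1.0), np.nan)
        data[label] = ratio
    table = pd.DataFrame(data, index=shared)
    table["n_undefined"] = table[cols].isna().sum(axis=1) if cols else 0
    table["mean_ratio"] = table[cols].mean(axis=1, skipna=True) if cols else np.nan
    return table


def compare_ratio_groups(
    ratio_table: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> dict[str, float]:
    """Two-group Wilcoxon rank-sum comparison of per-entity mean ratios."""
    a = ratio_table.loc[[i for i in group_a if i in ratio_table.index], "mean_ratio"].dropna()
    b = ratio_table.loc[[i for i in group_b if i in ratio_table.index], "mean_ratio"].dropna()
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("empty group in ratio comparison")
    stat, p = stats.ranksums(a, b)
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "statistic": float(stat),
        "p_value": float(p),
    }


def multiomic_correlations(
    nra_by_dataset: Mapping[str, pd.DataFrame],
    samples: Sequence[SampleMeta],
    log_transform: bool = False,
) -> pd.DataFrame:
    """Pairwise Pearson correlations of VC NRAs across dataset pairs.

    Observations are (VC, participant-site) cells present in both datasets
    of a pair.  With ``log_transform`` the correlation is computed on
    log10 of the values restricted to cells positive in both datasets.
    Pairs with fewer than 3 observations or zero variance are undefined
    (NaN) and flagged.
    """
    pairing = sample_pairing(samples)
    names = sorted(nra_by_dataset)
    rows = []
    for i, ds_a in enumerate(names):
        for ds_b in names[i + 1 :]:
            xs: list[float] = []
            ys: list[float] = []
            shared_rows = [
                cid
                for cid in nra_by_dataset[ds_a].index
                if cid in nra_by_dataset[ds_b].index
            ]
            for ds_map in pairing.values():
                if ds_a not in ds_map or ds_b not in ds_map:
                    continue
                sa, sb = ds_map[ds_a], ds_map[ds_b]
                if sa not in nra_by_dataset[ds_a].columns or sb not in nra_by_dataset[ds_b].columns:
                    continue
                va = nra_by_dataset[ds_a].loc[shared_rows, sa].to_numpy(dtype=float)
                vb = nra_by_dataset[ds_b].loc[shared_rows, sb].to_numpy(dtype=float)
                if log_transform:
                    keep = (va > 0) & (vb > 0)
                    va, vb = np.log10(va[keep]), np.log10(vb[keep])
                xs.extend(va)
                ys.extend(vb)
            undefined = len(xs) < 3 or np.std(xs) == 0 or np.std(ys) == 0
            if undefined:
                r = p = np.nan
            else:
                r, p = stats.pearsonr(xs, ys)
            rows.append(
                {
                    "dataset_a": ds_a,
                    "dataset_b": ds_b,
                    "pearson_r": float(r) if not undefined else np.nan,
                    "p_value": float(p) if not undefined else np.nan,
                    "n_obs": len(xs),
                    "undefined": undefined,
                    "log_transform": log_transform,
                }
            )
    return pd.DataFrame(rows)
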