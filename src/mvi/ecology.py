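"""Alpha/beta diversity, rarefaction, set overlaps, and host-pair statistics.

Diversity indices follow the classical definitions: Chao1 is
``S0 + a1^2 / (2 a2)`` with the bias-corrected fallback
``S0 + a1 (a1 - 1) / 2`` when no doubletons exist, and Shannon is
``-sum_i P_i ln P_i``.  Indices are intended to be computed on rarefied
counts; rarefaction is a single seeded draw without replacement whose
column sums equal the target depth exactly.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.ordination import pcoa as _skbio_pcoa

from mvi.io_model import SampleMeta, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# rarefaction and alpha diversity
# ---------------------------------------------------------------------------


def rarefy(
    counts: pd.DataFrame, depth: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Subsample each sample column to *depth* reads without replacement.

    Default depth is the smallest column total.  Samples with fewer reads
    than the requested depth are dropped with a warning.
    """
    totals = counts.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValidationError(f"rarefaction depth must be positive, got {depth}")
    keep = [s for s in counts.columns if totals[s] >= depth]
    dropped = [s for s in counts.columns if totals[s] < depth]
    if dropped:
        logger.warning("dropping %d samples below rarefaction depth %d: %s", len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    out = {}
    for s in keep:
        col = counts[s].to_numpy(dtype=np.int64)
        out[s] = rng.multivariate_hypergeometric(col, depth, method="marginals")
    return pd.DataFrame(out, index=counts.index)


def chao1(counts: Sequence[int] | np.ndarray) -> float:
    """Chao1 richness: S0 + a1^2/(2 a2), bias-corrected when a2 == 0."""
    arr = np.asarray(counts)
    if arr.size == 0:
        logger.warning("chao1 of empty vector")
        return 0.0
    if (arr < 0).any():
        raise ValidationError("negative counts")
    s0 = int((arr > 0).sum())
    a1 = int((arr == 1).sum())
    a2 = int((arr == 2).sum())
    if a2 > 0:
        return s0 + a1 * a1 / (2.0 * a2)
    return s0 + a1 * (a1 - 1) / 2.0


def shannon(counts: Sequence[float] | np.ndarray) -> float:
    """Shannon index on proportions (natural log); zero terms contribute 0."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValidationError("negative counts")
    total = arr.sum()
    if total == 0:
        return np.nan
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def population_variance(nra: Sequence[float] | np.ndarray) -> float:
    """Variance of the NRA vector over detected (nonzero) entries.

    An evenness proxy: 0 for a perfectly even community, larger when a few
    entries dominate.  Undefined (NaN) with fewer than 2 detected entries.
    """
    arr = np.asarray(nra, dtype=float)
    detected = arr[arr > 0]
    if detected.size < 2:
        return np.nan
    return float(np.var(detected))


def alpha_diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Chao1, Shannon and population variance per sample column."""
    rows = []
    for s in counts.columns:
        col = counts[s].to_numpy()
        total = col.sum()
        rows.append(
            {
                "sample_id": s,
                "chao1": chao1(col),
                "shannon": shannon(col),
                "population_variance": population_variance(col / total if total else col),
                "observed": int((col > 0).sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------


def bray_curtis_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample columns."""
    mat = profiles.to_numpy(dtype=float).T
    dist = squareform(pdist(mat, metric="braycurtis"))
    return pd.DataFrame(dist, index=profiles.columns, columns=profiles.columns)


def pcoa_coordinates(distance: pd.DataFrame, n_axes: int = 2) -> pd.DataFrame:
    """Classical MDS (PCoA) coordinates of a dissimilarity matrix."""
    result = _skbio_pcoa(distance.to_numpy(), number_of_dimensions=n_axes)
    coords = result.samples.iloc[:, :n_axes].to_numpy()
    return pd.DataFrame(
        coords, index=distance.index, columns=[f"PCo{i + 1}" for i in range(n_axes)]
    )


def bray_curtis_contrasts(
    profiles: pd.DataFrame, samples: Sequence[SampleMeta]
) -> dict[str, object]:
    """Bray-Curtis dissimilarities with intra/inter-individual contrasts.

    Returns the distance matrix, a long table of pairwise comparisons
    annotated as intra- vs inter-individual and (within individuals)
    colon-colon vs colon-stool, Wilcoxon rank-sum p-values for both
    contrasts, and PCoA coordinates.
    """
    if profiles.shape[1] < 2:
        raise ValidationError("need at least 2 samples for beta diversity")
    meta = {s.sample_id: s for s in samples}
    dist = bray_curtis_matrix(profiles)
    rows = []
    cols = list(profiles.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            ma, mb = meta.get(a), meta.get(b)
            if ma is None or mb is None:
                raise ValidationError(f"sample metadata missing for {a if ma is None else b}")
            intra = ma.participant == mb.participant
            sites = {ma.site, mb.site}
            if sites <= {"PC", "DC"}:
                site_contrast = "MLI-MLI"
            elif "STL" in sites and sites & {"PC", "DC"}:
                site_contrast = "MLI-STL"
            else:
                site_contrast = "STL-STL"
            rows.append(
                {
                    "sample_a": a,
                    "sample_b": b,
                    "distance": float(dist.at[a, b]),
                    "comparison": "intra" if intra else "inter",
                    "site_contrast": site_contrast,
                }
            )
    pairs = pd.DataFrame(rows)

    result: dict[str, object] = {"distance": dist, "pairs": pairs}
    intra_d = pairs.loc[pairs["comparison"] == "intra", "distance"]
    inter_d = pairs.loc[pairs["comparison"] == "inter", "distance"]
    if len(intra_d) and len(inter_d):
        stat, p = stats.ranksums(intra_d, inter_d)
        result["intra_vs_inter"] = {
            "median_intra": float(intra_d.median()),
            "median_inter": float(inter_d.median()),
            "p_value": float(p),
        }
    within = pairs[pairs["comparison"] == "intra"]
    mli = within.loc[within["site_contrast"] == "MLI-MLI", "distance"]
    stl = within.loc[within["site_contrast"] == "MLI-STL", "distance"]
    if len(mli) and len(stl):
        stat, p = stats.ranksums(mli, stl)
        result["pcdc_vs_mlistl"] = {
            "median_PC_DC": float(mli.median()),
            "median_MLI_STL": float(stl.median()),
            "p_value": float(p),
        }
    result["pcoa"] = pcoa_coordinates(dist)
    return result


# ---------------------------------------------------------------------------
# shared-VC set overlaps
# ---------------------------------------------------------------------------

_REGIONS = (
    ("PC",),
    ("DC",),
    ("STL",),
    ("PC", "DC"),
    ("PC", "STL"),
    ("DC", "STL"),
    ("PC", "DC", "STL"),
)


def shared_vc_sets(
    detection: pd.DataFrame, samples: Sequence[SampleMeta]
) -> pd.DataFrame:
    """Per-participant 3-set (PC/DC/STL) overlap partition of detected VCs.

    *detection* is a boolean frame (VC x sample).  Counts for each exclusive
    Euler region sum to the participant's total detected VCs.  Participants
    missing a site get a reduced partition with the ``reduced`` flag set.
    """
    meta = {s.sample_id: s for s in samples}
    per_participant: dict[str, dict[str, set[str]]] = {}
    for col in detection.columns:
        m = meta.get(col)
        if m is None:
            continue
        detected = set(detection.index[detection[col].astype(bool)])
        per_participant.setdefault(m.participant, {})[m.site] = detected

    rows = []
    for participant, site_sets in sorted(per_participant.items()):
        available = set(site_sets)
        reduced = available != {"PC", "DC", "STL"}
        union: set[str] = set().union(*site_sets.values()) if site_sets else set()
        row: dict[str, object] = {
            "participant": participant,
            "n_total": len(union),
            "reduced": reduced,
        }
        for region in _REGIONS:
            if not set(region) <= available:
                row["|".join(region)] = np.nan
                continue
            inside = set.intersection(*(site_sets[s] for s in region))
            outside: set[str] = set().union(
                *(site_sets[s] for s in available - set(region)), set()
            )
            row["|".join(region)] = len(inside - outside)
        triple = row.get("PC|DC|STL")
        row["frac_all_sites"] = (
            triple / len(union) if not reduced and union and not pd.isna(triple) else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# host-pair correlations
# ---------------------------------------------------------------------------


def host_pair_correlations(
    nra_vc: pd.DataFrame,
    nra_host: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    sample_pairs: Sequence[tuple[str, str]],
    n_null: int = 1000,
    seed: int = 0,
) -> dict[str, object]:
    """Matched VC-host Spearman correlations vs a random re-pairing null.

    *pairs* are (vc_id, host_id); *sample_pairs* aligns one dataset's sample
    columns with the other's (e.g. the MV and MG samples of one participant
    site).  The null draws ``n_null`` seeded random VC-host re-pairings from
    the same id pools.  Requires at least 3 aligned sample pairs and 2
    matched pairs.
    """
    if len(pairs) < 2:
        raise ValidationError("need at least 2 matched pairs")
    if len(sample_pairs) < 3:
        raise ValidationError("need at least 3 paired samples for correlations")
    vc_cols = [a for a, _ in sample_pairs]
    host_cols = [b for _, b in sample_pairs]

    def rho(vc_id: str, host_id: str) -> float:
        x = nra_vc.loc[vc_id, vc_cols].to_numpy(dtype=float)
        y = nra_host.loc[host_id, host_cols].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            return np.nan
        return float(stats.spearmanr(x, y).statistic)

    matched = [rho(v, h) for v, h in pairs]
    matched = [r for r in matched if not np.isnan(r)]

    rng = np.random.default_rng(seed)
    vc_ids = sorted({v for v, _ in pairs})
    host_ids = sorted({h for _, h in pairs})
    existing = set(pairs)
    null: list[float] = []
    while len(null) < n_null:
        v = vc_ids[rng.integers(len(vc_ids))]
        h = host_ids[rng.integers(len(host_ids))]
        if (v, h) in existing:
            continue
        r = rho(v, h)
        if not np.isnan(r):
            null.append(r)
    stat, p = stats.ranksums(matched, null)
    return {
        "matched_rho": matched,
        "null_rho": null,
        "median_matched": float(np.median(matched)),
        "median_null": float(np.median(null)),
        "p_value": float(p),
    }
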