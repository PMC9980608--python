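"""Integrase detection and integration likelihood-ratio statistics.

A VC carries an integrase when any of its genes has a term name matching the
(case-insensitive, substring) pattern "integrase"; an explicit term list can
be supplied instead.  Gene-family statistics contrast integration-capable
(IC) vs non-integrated (NI) VCs: ``LR = sensitivity / (1 - specificity)``
where sensitivity is the family's presence rate among IC VCs and
specificity is one minus its presence rate among NI VCs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mvi.clustering import VCClassification
from mvi.io_model import ContigRecord, GeneRecord, ValidationError

INTEGRASE_PATTERN = "integrase"
MIN_PREVALENCE_DEFAULT = 0.10
HQ_TIERS = frozenset({"complete", "high"})


@dataclass
class GeneFamilyStats:
    """Presence counts of one gene family in IC vs NI VCs and derived rates."""

    term_id: str
    term_name: str
    n_IC_with: int
    n_IC_total: int
    n_NI_with: int
    n_NI_total: int
    freq_per_kb_IC: float = np.nan
    freq_per_kb_NI: float = np.nan

    def __post_init__(self) -> None:
        if self.n_IC_total == 0 or self.n_NI_total == 0:
            raise ValidationError(f"{self.term_id}: empty IC or NI group")
        if not (0 <= self.n_IC_with <= self.n_IC_total and 0 <= self.n_NI_with <= self.n_NI_total):
            raise ValidationError(f"{self.term_id}: inconsistent counts")

    @property
    def sensitivity(self) -> float:
        return self.n_IC_with / self.n_IC_total

    @property
    def specificity(self) -> float:
        return 1.0 - self.n_NI_with / self.n_NI_total

    @property
    def likelihood_ratio(self) -> float:
        fpr = 1.0 - self.specificity
        if fpr == 0:
            return np.inf
        return self.sensitivity / fpr


def detect_integrase(
    genes: Sequence[GeneRecord],
    pattern: str = INTEGRASE_PATTERN,
    terms: Sequence[str] | None = None,
) -> tuple[dict[str, bool], pd.DataFrame]:
    """Flag contigs carrying an integrase gene and census the matched terms.

    By default a gene matches when *pattern* occurs (case-insensitively) in
    its term name; pass *terms* (exact term ids) to override.  The census
    lists every matched term with its database and gene count.
    """
    flags: dict[str, bool] = {}
    census: dict[tuple[str, str, str], int] = {}
    for g in genes:
        flags.setdefault(g.contig_id, False)
        if g.term_id is None:
            continue
        if terms is not None:
            matched = g.term_id in terms
        else:
            matched = pattern.lower() in (g.term_name or "").lower()
        if matched:
            flags[g.contig_id] = True
            key = (g.term_id, g.term_name or "", g.db)
            census[key] = census.get(key, 0) + 1
    census_df = pd.DataFrame(
        [
            {"term_id": t, "term_name": n, "db": d, "n_genes": c}
            for (t, n, d), c in sorted(census.items(), key=lambda kv: -kv[1])
        ]
    )
    return flags, census_df


def _vc_scope(
    classifications: Sequence[VCClassification],
    contigs: Sequence[ContigRecord],
    quality_filter: frozenset[str],
    taxonomy_order: str | None,
) -> tuple[list[str], list[str], dict[str, int]]:
    """IC and NI VC id lists restricted to the quality/taxon scope."""
    by_id = {c.contig_id: c for c in contigs}
    ic, ni = [], []
    lengths = {}
    for cls in classifications:
        contig = by_id.get(cls.vc_id)
        if contig is None:
            raise ValidationError(f"classification for unknown VC {cls.vc_id}")
        if contig.quality not in quality_filter:
            continue
        if taxonomy_order is not None and contig.taxonomy_order != taxonomy_order:
            continue
        lengths[cls.vc_id] = contig.length_bp
        (ic if cls.integration_class == "IC" else ni).append(cls.vc_id)
    return ic, ni, lengths


def family_frequency(
    genes: Sequence[GeneRecord],
    classifications: Sequence[VCClassification],
    contigs: Sequence[ContigRecord],
    quality_filter: frozenset[str] = HQ_TIERS,
    taxonomy_order: str | None = "Caudovirales",
    min_prevalence: float = MIN_PREVALENCE_DEFAULT,
) -> list[GeneFamilyStats]:
    """Per-family presence and per-kb frequency statistics in IC vs NI VCs.

    Families are kept when present on at least *min_prevalence* (inclusive)
    of the in-scope VCs.  Per-kb frequencies are ORF counts divided by the
    summed contig length of each group in kb; they are reported alongside
    the presence-based counts but do not enter the likelihood ratio.
    """
    ic, ni, lengths = _vc_scope(classifications, contigs, quality_filter, taxonomy_order)
    if not ic or not ni:
        raise ValidationError("empty IC or NI group within the requested scope")
    scope = set(ic) | set(ni)
    ic_set, ni_set = set(ic), set(ni)
    ic_kb = sum(lengths[v] for v in ic) / 1000.0
    ni_kb = sum(lengths[v] for v in ni) / 1000.0

    present: dict[str, set[str]] = {}
    orf_counts: dict[str, dict[str, int]] = {}
    names: dict[str, str] = {}
    for g in genes:
        if g.term_id is None or g.contig_id not in scope:
            continue
        present.setdefault(g.term_id, set()).add(g.contig_id)
        grp = "IC" if g.contig_id in ic_set else "NI"
        orf_counts.setdefault(g.term_id, {"IC": 0, "NI": 0})[grp] += 1
        names.setdefault(g.term_id, g.term_name or "")

    stats = []
    n_scope = len(scope)
    for term_id, vcs in sorted(present.items()):
        if len(vcs) / n_scope < min_prevalence:
            continue
        stats.append(
            GeneFamilyStats(
                term_id=term_id,
                term_name=names[term_id],
                n_IC_with=len(vcs & ic_set),
                n_IC_total=len(ic),
                n_NI_with=len(vcs & ni_set),
                n_NI_total=len(ni),
                freq_per_kb_IC=orf_counts[term_id]["IC"] / ic_kb,
                freq_per_kb_NI=orf_counts[term_id]["NI"] / ni_kb,
            )
        )
    return stats


def integration_lr(stats: Sequence[GeneFamilyStats]) -> pd.DataFrame:
    """Rank families by integration likelihood ratio, descending.

    Infinite ratios (families absent from every NI VC) sort first, resolved
    among themselves by sensitivity.
    """
    rows = [
        {
            "term_id": s.term_id,
            "term_name": s.term_name,
            "sensitivity": s.sensitivity,
            "specificity": s.specificity,
            "likelihood_ratio": s.likelihood_ratio,
            "infinite": np.isinf(s.likelihood_ratio),
            "freq_per_kb_IC": s.freq_per_kb_IC,
            "freq_per_kb_NI": s.freq_per_kb_NI,
        }
        for s in stats
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values(
        ["likelihood_ratio", "sensitivity", "term_id"],
        ascending=[False, False, True],
    ).reset_index(drop=True)


def transcribed_fraction_contrast(
    gene_status: pd.DataFrame,
    genes: Sequence[GeneRecord],
    classifications: Sequence[VCClassification],
) -> pd.DataFrame:
    """Fraction of evaluated gene instances transcribed, per family, IC vs NI.

    Only ``transcribed``/``not_transcribed`` rows count as evaluated.  The
    output is sorted by the IC-minus-NI difference (descending, term id
    ascending); families lacking evaluated genes in either group have an
    undefined fraction there and are excluded from the sorted difference.
    """
    term_of = {g.gene_id: g.term_id for g in genes}
    name_of = {g.term_id: g.term_name or "" for g in genes if g.term_id}
    group_of = {c.vc_id: c.integration_class for c in classifications}

    tallies: dict[str, dict[str, list[int]]] = {}
    for row in gene_status.itertuples(index=False):
        if row.status == "not_evaluated":
            continue
        term = term_of.get(row.gene_id)
        grp = group_of.get(row.contig_id)
        if term is None or grp is None:
            continue
        cell = tallies.setdefault(term, {"IC": [0, 0], "NI": [0, 0]})[grp]
        cell[0] += 1
        if row.status == "transcribed":
            cell[1] += 1

    rows = []
    for term, groups in tallies.items():
        frac = {}
        for grp in ("IC", "NI"):
            evaluated, transcribed = groups[grp]
            frac[grp] = transcribed / evaluated if evaluated else np.nan
        rows.append(
            {
                "term_id": term,
                "term_name": name_of.get(term, ""),
                "n_evaluated_IC": groups["IC"][0],
                "n_evaluated_NI": groups["NI"][0],
                "transcribed_fraction_IC": frac["IC"],
                "transcribed_fraction_NI": frac["NI"],
                "difference": frac["IC"] - frac["NI"],
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    defined = df[df["difference"].notna()].sort_values(
        ["difference", "term_id"], ascending=[False, True]
    )
    undefined = df[df["difference"].isna()].sort_values("term_id")
    return pd.concat([defined, undefined]).reset_index(drop=True)
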