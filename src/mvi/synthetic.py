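"""Ground-truthed synthetic multiomic community generator.

Builds a community of free phages, prophages embedded in host contigs, and
bacterial host contigs, with log-normal abundance profiles structured as
participants x sites, dataset-specific detection (free vs integrated vs
transcribed states), planted integrase/repressor/capsid gene content, and
inflammation-graded host contamination.  Every latent state is recorded so
downstream classification can be scored against truth.

Contig naming convention: a phage with canonical id ``P0001`` may surface as
a metavirome assembly ``P0001.MV`` and/or a metagenome assembly
``P0001.MG``; count tables and gene records use the canonical id (the
dereplicated catalog unit), while the raw per-dataset contigs feed the
clustering module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mvi.io_model import (
    ContigRecord,
    GeneRecord,
    HostScore,
    OmicsMatrix,
    SampleMeta,
    ValidationError,
    write_contig_table,
    write_counts,
    write_fasta,
    write_genes,
    write_samples,
)

LIFESTYLES = ("free", "prophage_inactive", "prophage_active")

# (term_id, term_name, db, planting probability) for non-integrase families
_GENE_FAMILIES = (
    ("VOG06177", "Repressor protein cI", "VOG", 0.50),
    ("VOG00029", "Major capsid protein", "VOG", 0.80),
    ("VOG01032", "Packaging protein 1", "VOG", 0.35),
    ("VOG00419", "Terminase large subunit", "VOG", 0.50),
    ("VOG00031", "Portal protein", "VOG", 0.40),
)
_INTEGRASE = ("VOG00035", "Integrase", "VOG")

_GRADE_PATTERNS = ((2, 2), (0, 1), (0, 2))  # (PC, DC) grade per participant, cycled


@dataclass
class CommunitySpec:
    """Parameters of the synthetic community; seeded runs are reproducible."""

    n_participants: int = 3
    sites: tuple[str, ...] = ("PC", "DC", "STL")
    n_free_phages: int = 300
    n_prophages: int = 200
    n_host_contigs: int = 50
    fraction_temperate_active: float = 0.65
    ta_fraction: float = 0.30

    # genome lengths: long tailed Caudovirales-like vs small circular-like
    frac_small_genome: float = 0.20
    caudo_meanlog: float = float(np.log(25_000))
    caudo_sdlog: float = 0.45
    small_meanlog: float = float(np.log(5_000))
    small_sdlog: float = 0.12
    flank_bp: int = 2_500
    host_extra_bp: int = 10_000
    host_max_bp: int = 500_000

    # abundance model: shared participant effect, correlated across sites
    abundance_sigma: float = 1.2
    rho_site: float = 0.8
    prophage_abundance_noise: float = 0.3
    assigned_pair_noise: float = 0.8
    assigned_fraction: float = 0.30

    # gene content
    p_integrase_ic: float = 0.70
    p_integrase_ni: float = 0.50
    transcription_base_p: float = 0.80
    transcription_overrides: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"Packaging protein 1": {"IC": 0.90, "NI": 0.55}}
    )

    # sequencing model
    library_size: Mapping[str, int] = field(
        default_factory=lambda: {"MG": 3_000_000, "MV": 2_000_000, "MT": 2_000_000}
    )
    viral_share: Mapping[str, float] = field(
        default_factory=lambda: {"MG": 0.05, "MV": 0.75, "MT": 0.20}
    )
    mg_free_weight: float = 0.05
    mv_inactive_weight: float = 0.0
    # extra per-(contig, sample) lognormal jitter decoupling MV from the
    # shared latent abundance that MG and MT both track
    mv_abundance_noise: float = 0.0
    read_len: int = 150
    gene_mt_mean: float = 30.0

    contamination_by_grade: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.02, 1: 0.037, 2: 0.70}
    )
    marker_per_million: Mapping[str, float] = field(
        default_factory=lambda: {"MG": 172.0, "MV": 1.0, "MT": 5.0}
    )
    mt_missing: tuple[tuple[str, str], ...] = ()

    quality_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "complete": 0.15,
            "high": 0.25,
            "medium": 0.30,
            "low": 0.20,
            "not_determined": 0.10,
        }
    )

    seed: int = 42

    def __post_init__(self) -> None:
        for name in (
            "fraction_temperate_active",
            "ta_fraction",
            "frac_small_genome",
            "rho_site",
            "p_integrase_ic",
            "p_integrase_ni",
            "transcription_base_p",
            "mg_free_weight",
            "mv_inactive_weight",
            "assigned_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.abundance_sigma <= 0:
            raise ValidationError("abundance_sigma must be positive")
        for f in self.contamination_by_grade.values():
            if not 0.0 <= f < 1.0:
                raise ValidationError("contamination fractions must be in [0, 1)")
        if abs(sum(self.quality_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("quality tier probabilities must sum to 1")

    @classmethod
    def small(cls, seed: int = 42, **overrides) -> "CommunitySpec":
        """A fast, low-footprint community for unit and Monte-Carlo tests."""
        defaults = dict(
            n_free_phages=24,
            n_prophages=16,
            n_host_contigs=8,
            caudo_meanlog=float(np.log(6_000)),
            caudo_sdlog=0.35,
            small_meanlog=float(np.log(2_000)),
            flank_bp=2_000,
            host_extra_bp=3_000,
            library_size={"MG": 400_000, "MV": 300_000, "MT": 300_000},
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class GroundTruth:
    """Latent per-contig states plus the abundance surfaces behind them."""

    phages: pd.DataFrame  # index vc_id: lifestyle, host_contig, length_bp, ...
    gene_truth: pd.DataFrame  # index gene_id: contig_id, term, transcribed
    phage_abundance: pd.DataFrame  # vc_id x "participant_site"
    host_abundance: pd.DataFrame  # host_id x "participant_site"
    host_lengths: pd.Series
    assigned_pairs: list[tuple[str, str]]

    def vc_contig_records(self) -> list[ContigRecord]:
        """Catalog-level (canonical, sequence-free) records, one per phage."""
        recs = []
        for vc_id, row in self.phages.iterrows():
            recs.append(
                ContigRecord(
                    contig_id=str(vc_id),
                    length_bp=int(row.length_bp),
                    source="metavirome" if row.lifestyle == "free" else "both"
                    if row.lifestyle == "prophage_active" else "metagenome",
                    is_viral=True,
                    quality=row.quality,
                    taxonomy_order=row.taxonomy_order,
                    taxonomy_family=row.taxonomy_family,
                )
            )
        return recs


@dataclass
class Community:
    spec: CommunitySpec
    truth: GroundTruth
    contigs: list[ContigRecord]  # raw per-dataset contigs (with sequences when built)
    nonviral_contigs: list[ContigRecord]
    genes: list[GeneRecord]  # on canonical vc ids
    samples: list[SampleMeta]
    host_scores: list[HostScore]


def canonical_vc_id(contig_id: str) -> str:
    """Strip the per-dataset assembly suffix from a synthetic contig id."""
    if contig_id.endswith((".MV", ".MG")):
        return contig_id[:-3]
    return contig_id


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n).tobytes().decode()


def _sample_grades(spec: CommunitySpec) -> dict[tuple[str, str], int]:
    grades: dict[tuple[str, str], int] = {}
    for i in range(spec.n_participants):
        participant = f"U{i + 1}"
        pc, dc = _GRADE_PATTERNS[i % len(_GRADE_PATTERNS)]
        grades[(participant, "PC")] = pc
        grades[(participant, "DC")] = dc
        grades[(participant, "STL")] = max(pc, dc)
    return grades


def _make_samples(spec: CommunitySpec) -> list[SampleMeta]:
    grades = _sample_grades(spec)
    samples = []
    for i in range(spec.n_participants):
        participant = f"U{i + 1}"
        for site in spec.sites:
            for dataset in ("MG", "MV"):
                samples.append(
                    SampleMeta(
                        sample_id=f"{participant}_{site}_{dataset}",
                        participant=participant,
                        site=site,
                        dataset=dataset,
                        inflammation_grade=grades.get((participant, site)),
                    )
                )
            # metatranscriptome exists only for colonic (MLI) sites
            if site in ("PC", "DC") and (participant, site) not in spec.mt_missing:
                samples.append(
                    SampleMeta(
                        sample_id=f"{participant}_{site}_MT",
                        participant=participant,
                        site=site,
                        dataset="MT",
                        inflammation_grade=grades.get((participant, site)),
                    )
                )
    return samples


def _lognormal_profiles(
    rng: np.random.Generator, n: int, spec: CommunitySpec, columns: list[str]
) -> pd.DataFrame:
    """Per-entity abundance with site correlation > inter-participant."""
    sigma = spec.abundance_sigma
    rho = spec.rho_site
    data = np.empty((n, len(columns)))
    participants = sorted({c.rsplit("_", 1)[0] for c in columns})
    z_part = {p: rng.normal(0.0, sigma, size=n) for p in participants}
    for j, col in enumerate(columns):
        participant = col.rsplit("_", 1)[0]
        eps = rng.normal(0.0, sigma, size=n)
        z = np.sqrt(rho) * z_part[participant] + np.sqrt(1.0 - rho) * eps
        data[:, j] = np.exp(z)
    return pd.DataFrame(data, columns=columns)


def generate_community(spec: CommunitySpec, with_sequences: bool = True) -> Community:
    """Generate genomes, gene records, samples, and the ground truth.

    With ``with_sequences=False`` the raw contigs carry no nucleotide
    strings (clustering is then unavailable) which makes large Monte-Carlo
    count simulations cheap.
    """
    rng = np.random.default_rng(spec.seed)
    n_phages = spec.n_free_phages + spec.n_prophages
    if spec.n_prophages > 0 and spec.n_host_contigs == 0:
        raise ValidationError("prophages require host contigs")

    vc_ids = [f"P{i + 1:04d}" for i in range(n_phages)]
    lifestyles = ["free"] * spec.n_free_phages
    n_active = int(round(spec.n_prophages * spec.fraction_temperate_active))
    lifestyles += ["prophage_active"] * n_active
    lifestyles += ["prophage_inactive"] * (spec.n_prophages - n_active)

    small = rng.random(n_phages) < spec.frac_small_genome
    lengths = np.where(
        small,
        rng.lognormal(spec.small_meanlog, spec.small_sdlog, n_phages),
        rng.lognormal(spec.caudo_meanlog, spec.caudo_sdlog, n_phages),
    ).astype(int)
    lengths = np.maximum(lengths, 500)

    tiers = list(spec.quality_probs)
    quality = rng.choice(tiers, size=n_phages, p=[spec.quality_probs[t] for t in tiers])
    order = np.where(small, "unassigned", "Caudovirales")
    caudo_families = rng.choice(["Siphoviridae", "Myoviridae", "Podoviridae"], size=n_phages)
    family = np.where(small, "Microviridae", caudo_families)

    is_prophage = np.array([ls != "free" for ls in lifestyles])
    p_int = np.where(is_prophage, spec.p_integrase_ic, spec.p_integrase_ni)
    has_integrase = (rng.random(n_phages) < p_int) & (order == "Caudovirales")
    true_ta = rng.random(n_phages) < spec.ta_fraction

    # prophage -> host assignment
    host_ids = [f"H{i + 1:03d}" for i in range(spec.n_host_contigs)]
    host_of: dict[str, str] = {}
    prophages_of: dict[str, list[str]] = {h: [] for h in host_ids}
    for i, vc_id in enumerate(vc_ids):
        if is_prophage[i]:
            h = host_ids[rng.integers(spec.n_host_contigs)]
            host_of[vc_id] = h
            prophages_of[h].append(vc_id)

    phages = pd.DataFrame(
        {
            "lifestyle": lifestyles,
            "host_contig": [host_of.get(v, "") for v in vc_ids],
            "length_bp": lengths,
            "quality": quality,
            "taxonomy_order": order,
            "taxonomy_family": family,
            "true_ta": true_ta,
            "true_integrase": has_integrase,
        },
        index=pd.Index(vc_ids, name="vc_id"),
    )

    # abundance surfaces
    samples = _make_samples(spec)
    cols = sorted({f"{s.participant}_{s.site}" for s in samples})
    host_ab = _lognormal_profiles(rng, spec.n_host_contigs, spec, cols)
    host_ab.index = pd.Index(host_ids, name="host_id")
    phage_ab = _lognormal_profiles(rng, n_phages, spec, cols)
    phage_ab.index = pd.Index(vc_ids, name="vc_id")
    # prophage abundance tracks its host's, with small per-sample noise
    for vc_id, h in host_of.items():
        noise = rng.normal(0.0, spec.prophage_abundance_noise, size=len(cols))
        phage_ab.loc[vc_id] = host_ab.loc[h].to_numpy() * np.exp(noise)

    # score-assigned pairs: a subset of free phages loosely coupled to a host
    assigned_pairs: list[tuple[str, str]] = []
    host_scores: list[HostScore] = []
    free_ids = [v for v in vc_ids if host_of.get(v) is None]
    n_assigned = int(round(len(free_ids) * spec.assigned_fraction))
    for vc_id in list(rng.permutation(free_ids))[:n_assigned]:
        h = host_ids[rng.integers(spec.n_host_contigs)]
        noise = rng.normal(0.0, spec.assigned_pair_noise, size=len(cols))
        phage_ab.loc[vc_id] = host_ab.loc[h].to_numpy() * np.exp(noise)
        assigned_pairs.append((str(vc_id), h))
        host_scores.append(HostScore(str(vc_id), h, float(rng.normal(-1300, 50)), 1e-8))

    # gene records on canonical ids
    genes: list[GeneRecord] = []
    gene_rows = []
    for i, vc_id in enumerate(vc_ids):
        length = int(lengths[i])
        n_genes = max(4, length // 1200)
        planted: list[tuple[str, str, str]] = []
        if has_integrase[i]:
            planted.append(_INTEGRASE)
        for term_id, term_name, db, p in _GENE_FAMILIES:
            if order[i] == "Caudovirales" and rng.random() < p:
                planted.append((term_id, term_name, db))
        step = length // n_genes
        for g in range(n_genes):
            start0 = g * step
            end0 = min(start0 + max(step - 50, 90), length)
            gene_id = f"{vc_id}_g{g + 1:03d}"
            if g < len(planted):
                term_id, term_name, db = planted[g]
            else:
                term_id = term_name = None
                db = "none"
            if true_ta[i]:
                base = spec.transcription_base_p
                override = spec.transcription_overrides.get(term_name or "")
                if override is not None:
                    grp = "IC" if is_prophage[i] else "NI"
                    base = override.get(grp, base)
                transcribed = bool(rng.random() < base)
            else:
                transcribed = False
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=str(vc_id),
                    start=start0 + 1,
                    end=end0,
                    strand="+" if rng.random() < 0.5 else "-",
                    db=db,
                    term_id=term_id,
                    term_name=term_name,
                )
            )
            gene_rows.append(
                {
                    "gene_id": gene_id,
                    "contig_id": str(vc_id),
                    "term_id": term_id or "",
                    "term_name": term_name or "",
                    "transcribed": transcribed,
                }
            )
    gene_truth = pd.DataFrame(gene_rows).set_index("gene_id")

    # host contig layout: flank + prophage + spacer ... + tail
    host_lengths = {}
    layouts: dict[str, list[tuple[str, int]]] = {}  # host -> [(vc_id, offset)]
    for h in host_ids:
        offset = spec.flank_bp + int(rng.integers(0, 2_000))
        layout = []
        for vc_id in prophages_of[h]:
            layout.append((vc_id, offset))
            offset += int(phages.at[vc_id, "length_bp"]) + spec.flank_bp
        total = offset + spec.host_extra_bp + int(rng.integers(0, 5_000))
        if total > spec.host_max_bp:
            raise ValidationError(
                f"host {h} needs {total} bp (> host_max_bp={spec.host_max_bp}); "
                "reduce prophage count or lengths"
            )
        layouts[h] = layout
        host_lengths[h] = total

    # raw per-dataset contigs
    contigs: list[ContigRecord] = []
    nonviral: list[ContigRecord] = []
    phage_seq: dict[str, str] = {}
    if with_sequences:
        for i, vc_id in enumerate(vc_ids):
            phage_seq[vc_id] = _random_seq(rng, int(lengths[i]))

    for i, vc_id in enumerate(vc_ids):
        common = dict(
            length_bp=int(lengths[i]),
            is_viral=True,
            quality=str(quality[i]),
            taxonomy_order=str(order[i]),
            taxonomy_family=str(family[i]),
        )
        seq = phage_seq.get(vc_id)
        if lifestyles[i] in ("free", "prophage_active"):
            contigs.append(
                ContigRecord(
                    contig_id=f"{vc_id}.MV", sequence=seq, source="metavirome", **common
                )
            )
        if lifestyles[i] in ("prophage_active", "prophage_inactive"):
            contigs.append(
                ContigRecord(
                    contig_id=f"{vc_id}.MG",
                    sequence=seq,
                    source="metagenome",
                    pruned_from=host_of[vc_id],
                    **common,
                )
            )

    bacterial_orders = rng.choice(
        ["Clostridiales", "Bacteroidales", "Lactobacillales"], size=spec.n_host_contigs
    )
    for j, h in enumerate(host_ids):
        seq = None
        if with_sequences:
            buf = list(_random_seq(rng, host_lengths[h]))
            for vc_id, off in layouts[h]:
                sub = phage_seq[vc_id]
                buf[off : off + len(sub)] = sub
            seq = "".join(buf)
        nonviral.append(
            ContigRecord(
                contig_id=h,
                length_bp=host_lengths[h],
                sequence=seq,
                source="metagenome",
                is_viral=False,
                quality="not_determined",
                taxonomy_order=str(bacterial_orders[j]),
                taxonomy_family="unassigned",
            )
        )

    truth = GroundTruth(
        phages=phages,
        gene_truth=gene_truth,
        phage_abundance=phage_ab,
        host_abundance=host_ab,
        host_lengths=pd.Series(host_lengths, name="length_bp"),
        assigned_pairs=assigned_pairs,
    )
    return Community(
        spec=spec,
        truth=truth,
        contigs=contigs,
        nonviral_contigs=nonviral,
        genes=genes,
        samples=samples,
        host_scores=host_scores,
    )


# backwards-friendly aliases matching the operation vocabulary
generate_genomes = generate_community


@dataclass
class SimulatedCounts:
    matrices: dict[str, OmicsMatrix]
    gene_counts_mt: pd.DataFrame
    qc: pd.DataFrame


def simulate_counts(
    spec: CommunitySpec, truth: GroundTruth, samples: Sequence[SampleMeta] | None = None,
    seed: int | None = None,
) -> SimulatedCounts:
    """Draw tri-omic count tables from the ground-truth abundance surfaces.

    Per sample, expected reads split between viral contigs and bacterial
    hosts according to the dataset's viral share, then within each group
    proportionally to abundance x length; observed counts are Poisson.
    Breadth follows the Poisson-coverage form from the per-bp depth.
    Host-read (human) and marker-gene contamination tallies are emitted in
    the QC table, graded by inflammation.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    if samples is None:
        samples = _make_samples(spec)

    vc_ids = list(truth.phages.index)
    host_ids = list(truth.host_abundance.index)
    all_ids = vc_ids + host_ids
    vlen = truth.phages["length_bp"].to_numpy(dtype=float)
    hlen = truth.host_lengths.loc[host_ids].to_numpy(dtype=float)
    lifestyle = truth.phages["lifestyle"].to_numpy()
    ta = truth.phages["true_ta"].to_numpy(dtype=bool)
    host_of = truth.phages["host_contig"].to_dict()

    by_dataset: dict[str, list[SampleMeta]] = {"MG": [], "MV": [], "MT": []}
    for s in samples:
        by_dataset[s.dataset].append(s)

    matrices: dict[str, OmicsMatrix] = {}
    qc_rows = []
    read_bases = 2.0 * spec.read_len

    for dataset, ds_samples in by_dataset.items():
        if not ds_samples:
            continue
        lib = int(spec.library_size[dataset])
        share = float(spec.viral_share[dataset])
        counts = {}
        for s in ds_samples:
            col = f"{s.participant}_{s.site}"
            pab = truth.phage_abundance[col].to_numpy(dtype=float)
            hab = truth.host_abundance[col].to_numpy(dtype=float)

            if dataset == "MG":
                host_linked = np.array(
                    [
                        truth.host_abundance.at[host_of[v], col] if host_of[v] else 0.0
                        for v in vc_ids
                    ]
                )
                vw = np.where(
                    lifestyle == "free", spec.mg_free_weight * pab, host_linked
                ) * vlen
            elif dataset == "MV":
                mv_ab = np.where(
                    lifestyle == "prophage_inactive", spec.mv_inactive_weight * pab, pab
                )
                if spec.mv_abundance_noise > 0:
                    mv_ab = mv_ab * np.exp(
                        rng.normal(0.0, spec.mv_abundance_noise, size=mv_ab.size)
                    )
                vw = mv_ab * vlen
            else:  # MT
                vw = np.where(ta, pab, 0.0) * vlen
            hw = hab * hlen

            # `share` is the *NRA* share viral contigs should carry; since
            # NRA is length-normalized, solve for the read split producing
            # it: per-read x-mass is beta = sum(w_i/len_i)/sum(w_i) per group
            expected = np.zeros(len(all_ids))
            if vw.sum() == 0:
                expected[len(vc_ids) :] = lib * hw / hw.sum()
            elif hw.sum() == 0:
                expected[: len(vc_ids)] = lib * vw / vw.sum()
            else:
                beta_v = float((vw / vlen).sum() / vw.sum())
                beta_h = float((hw / hlen).sum() / hw.sum())
                odds = (share / (1.0 - share)) * (beta_h / beta_v)
                r = odds / (1.0 + odds)
                expected[: len(vc_ids)] = r * lib * vw / vw.sum()
                expected[len(vc_ids) :] = (1.0 - r) * lib * hw / hw.sum()
            counts[s.sample_id] = rng.poisson(expected)

            grade = s.inflammation_grade if s.inflammation_grade is not None else 0
            if dataset == "MG":
                frac = spec.contamination_by_grade.get(grade, 0.02)
            elif dataset == "MV":
                frac = 0.001
            else:
                frac = 0.02
            human = int(rng.poisson(lib * frac / (1.0 - frac)))
            total = lib + human
            marker = int(rng.poisson(total * spec.marker_per_million.get(dataset, 0.0) / 1e6))
            qc_rows.append(
                {
                    "sample_id": s.sample_id,
                    "participant": s.participant,
                    "site": s.site,
                    "dataset": dataset,
                    "inflammation_grade": grade,
                    "total_reads": total,
                    "host_reads": human,
                    "marker_reads": marker,
                }
            )

        count_df = pd.DataFrame(counts, index=all_ids)
        lens = np.concatenate([vlen, hlen])
        depth_per_bp = count_df.to_numpy(dtype=float) * read_bases / lens[:, None]
        breadth = 1.0 - np.exp(-depth_per_bp)
        breadth[count_df.to_numpy() == 0] = 0.0
        matrices[dataset] = OmicsMatrix(
            counts=count_df,
            breadth=pd.DataFrame(breadth, index=all_ids, columns=count_df.columns),
            dataset=dataset,
        )

    # gene-level MT counts: transcribed genes of TA phages draw Poisson reads
    mt_samples = [s.sample_id for s in by_dataset["MT"]]
    gene_ids = list(truth.gene_truth.index)
    transcribed = truth.gene_truth["transcribed"].to_numpy(dtype=bool)
    gene_counts = pd.DataFrame(0, index=gene_ids, columns=mt_samples, dtype=np.int64)
    for s in mt_samples:
        lam = np.where(transcribed, spec.gene_mt_mean, 0.0)
        gene_counts[s] = rng.poisson(lam)
    return SimulatedCounts(
        matrices=matrices,
        gene_counts_mt=gene_counts,
        qc=pd.DataFrame(qc_rows),
    )


# ---------------------------------------------------------------------------
# truth table round trip and full-bundle export
# ---------------------------------------------------------------------------


def truth_report(truth: GroundTruth, path: str | Path) -> None:
    """Write the flat latent-label table used by recovery tests."""
    truth.phages.to_csv(path, sep="\t")


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", index_col="vc_id",
        dtype={"host_contig": str}, keep_default_na=False,
    )
    df["true_ta"] = df["true_ta"].astype(str).str.lower().isin(("true", "1"))
    df["true_integrase"] = df["true_integrase"].astype(str).str.lower().isin(("true", "1"))
    df["length_bp"] = df["length_bp"].astype(int)
    return df


def write_community(community: Community, sim: SimulatedCounts, outdir: str | Path) -> None:
    """Export the full fixture bundle as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if community.contigs and community.contigs[0].sequence is not None:
        write_fasta(community.contigs + community.nonviral_contigs, outdir / "contigs.fasta")
    write_contig_table(
        community.contigs + community.nonviral_contigs, outdir / "contigs.tsv"
    )
    # dereplicated catalog matching the count-table row universe
    write_contig_table(
        community.truth.vc_contig_records() + community.nonviral_contigs,
        outdir / "catalog.tsv",
    )
    write_genes(community.genes, outdir / "genes.tsv")
    write_samples(community.samples, outdir / "samples.tsv")
    for dataset, matrix in sim.matrices.items():
        write_counts(matrix, outdir / f"counts_{dataset}.tsv")
    sim.gene_counts_mt.rename_axis("gene_id").to_csv(outdir / "gene_counts_MT.tsv", sep="\t")
    sim.qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    truth_report(community.truth, outdir / "truth.tsv")
    if community.host_scores:
        pd.DataFrame(
            [
                {
                    "vc_id": hs.vc_id,
                    "host_contig_id": hs.host_contig_id,
                    "score": hs.score,
                    "p_adjusted": hs.p_adjusted,
                }
                for hs in community.host_scores
            ]
        ).to_csv(outdir / "host_scores.tsv", sep="\t", index=False)
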