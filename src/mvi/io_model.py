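"""Core data model, file readers/writers, and bundle validation.

All on-disk tables are tab-separated UTF-8 with ``#``-prefixed comment lines.
Gene coordinates are 1-based inclusive on disk (GFF3 convention); the helpers
:func:`to_internal` / :func:`to_file_coords` centralize the conversion to
0-based half-open used internally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

QUALITY_TIERS = ("complete", "high", "medium", "low", "not_determined")
SITES = ("PC", "DC", "STL")
DATASETS = ("MG", "MV", "MT")
SOURCES = ("metavirome", "metagenome", "both")
DATABASES = ("VOG", "pVOG", "PFAM", "KEGG", "TIGRFAM", "none")
UNASSIGNED = "unassigned"


class ValidationError(ValueError):
    """Raised when an input file violates a model invariant."""


def to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def to_file_coords(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ContigRecord:
    """A nucleotide contig with its catalog metadata.

    ``source`` is the assembly dataset of origin; the value ``both`` is only
    assigned at the cluster level after cross-dataset clustering.
    ``pruned_from`` records, for a viral contig excised from a longer
    assembly, the id of the non-viral contig it was pruned from (flanking
    host evidence).
    """

    contig_id: str
    length_bp: int
    sequence: str | None = None
    source: str = "metagenome"
    is_viral: bool = False
    quality: str = "not_determined"
    taxonomy_order: str = UNASSIGNED
    taxonomy_family: str = UNASSIGNED
    pruned_from: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValidationError(f"{self.contig_id}: non-positive length {self.length_bp}")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise ValidationError(
                f"{self.contig_id}: metadata length {self.length_bp} != "
                f"sequence length {len(self.sequence)}"
            )
        if self.quality not in QUALITY_TIERS:
            raise ValidationError(f"{self.contig_id}: unknown quality tier {self.quality!r}")
        if self.source not in SOURCES:
            raise ValidationError(f"{self.contig_id}: unknown source {self.source!r}")


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing sample: a (participant, site, dataset) cell.

    Absence of a dataset for a site (e.g. no stool metatranscriptome) is
    modeled by the sample simply not existing, never by zero-filled columns.
    """

    sample_id: str
    participant: str
    site: str
    dataset: str
    inflammation_grade: int | None = None

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValidationError(f"{self.sample_id}: unknown site {self.site!r}")
        if self.dataset not in DATASETS:
            raise ValidationError(f"{self.sample_id}: unknown dataset {self.dataset!r}")
        if self.inflammation_grade is not None and not 0 <= self.inflammation_grade <= 2:
            raise ValidationError(
                f"{self.sample_id}: inflammation grade {self.inflammation_grade} outside 0-2"
            )


@dataclass
class OmicsMatrix:
    """Per-contig read counts and breadth of coverage for one dataset.

    ``counts`` and ``breadth`` are dataframes with contig rows and sample
    columns of identical shape.  Breadth is the fraction of contig positions
    with depth >= 1; a cell has zero breadth iff it has zero counts.
    """

    counts: pd.DataFrame
    breadth: pd.DataFrame
    dataset: str

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.dataset not in DATASETS:
            raise ValidationError(f"unknown dataset {self.dataset!r}")
        if self.counts.shape != self.breadth.shape:
            raise ValidationError("counts and breadth shapes differ")
        if not self.counts.index.equals(self.breadth.index) or not self.counts.columns.equals(
            self.breadth.columns
        ):
            raise ValidationError("counts and breadth are not aligned")
        c = self.counts.to_numpy()
        b = self.breadth.to_numpy()
        if (c < 0).any():
            raise ValidationError("negative counts")
        if (b < 0).any() or (b > 1).any():
            raise ValidationError("breadth outside [0, 1]")
        if ((b == 0) != (c == 0)).any():
            raise ValidationError("breadth == 0 must hold exactly where counts == 0")

    @property
    def contig_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.counts.copy(), self.breadth.copy(), self.dataset)


@dataclass
class GeneRecord:
    """One ORF with its preferred annotation (single database + term)."""

    gene_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    db: str = "none"
    term_id: str | None = None
    term_name: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValidationError(f"{self.gene_id}: bad coordinates {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.db not in DATABASES:
            raise ValidationError(f"{self.gene_id}: unknown database {self.db!r}")
        if (self.db == "none") != (self.term_id is None):
            raise ValidationError(f"{self.gene_id}: db == none must pair with term_id == none")


@dataclass(frozen=True)
class HostScore:
    """A (virus, candidate host) assignment score with its adjusted p-value."""

    vc_id: str
    host_contig_id: str
    score: float
    p_adjusted: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_adjusted <= 1.0:
            raise ValidationError(
                f"{self.vc_id}/{self.host_contig_id}: p_adjusted {self.p_adjusted} outside [0,1]"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={0: str}, **kwargs)


def _opt(value) -> str | None:
    """Empty/NaN table cell -> None."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return value


def write_fasta(contigs: Iterable[ContigRecord], path: str | Path) -> None:
    records = []
    for c in contigs:
        if c.sequence is None:
            raise ValidationError(f"{c.contig_id}: cannot write FASTA without sequence")
        records.append(SeqRecord(Seq(c.sequence), id=c.contig_id, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_contig_table(contigs: Iterable[ContigRecord], path: str | Path) -> None:
    rows = [
        {
            "contig_id": c.contig_id,
            "length_bp": c.length_bp,
            "source": c.source,
            "is_viral": c.is_viral,
            "quality": c.quality,
            "taxonomy_order": c.taxonomy_order,
            "taxonomy_family": c.taxonomy_family,
            "pruned_from": c.pruned_from or "",
        }
        for c in contigs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_contigs(fasta_path: str | Path, metadata_path: str | Path) -> list[ContigRecord]:
    """Load contigs from a FASTA plus a matching metadata table.

    The two inputs must carry the same ids; lengths from the metadata table
    are cross-checked against the sequences.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        logger.warning("empty FASTA %s", fasta_path)
        warnings.warn(f"empty FASTA {fasta_path}", stacklevel=2)
        return []

    meta = _read_tsv(metadata_path)
    if meta["contig_id"].duplicated().any():
        dups = sorted(meta.loc[meta["contig_id"].duplicated(), "contig_id"])
        raise ValidationError(f"duplicate metadata ids: {dups}")
    fasta_ids = set(seqs)
    meta_ids = set(meta["contig_id"])
    if fasta_ids != meta_ids:
        missing = sorted(fasta_ids ^ meta_ids)
        raise ValidationError(f"FASTA/metadata id mismatch: {missing}")

    contigs = []
    for row in meta.itertuples(index=False):
        contigs.append(
            ContigRecord(
                contig_id=row.contig_id,
                length_bp=int(row.length_bp),
                sequence=seqs[row.contig_id],
                source=row.source,
                is_viral=bool(row.is_viral) if not isinstance(row.is_viral, str)
                else row.is_viral.lower() in ("true", "1"),
                quality=row.quality,
                taxonomy_order=row.taxonomy_order,
                taxonomy_family=row.taxonomy_family,
                pruned_from=_opt(getattr(row, "pruned_from", None)),
            )
        )
    return contigs


def read_contig_table(metadata_path: str | Path) -> list[ContigRecord]:
    """Load contig metadata without sequences."""
    meta = _read_tsv(metadata_path)
    out = []
    for row in meta.itertuples(index=False):
        out.append(
            ContigRecord(
                contig_id=row.contig_id,
                length_bp=int(row.length_bp),
                source=row.source,
                is_viral=bool(row.is_viral) if not isinstance(row.is_viral, str)
                else row.is_viral.lower() in ("true", "1"),
                quality=row.quality,
                taxonomy_order=row.taxonomy_order,
                taxonomy_family=row.taxonomy_family,
                pruned_from=_opt(getattr(row, "pruned_from", None)),
            )
        )
    return out


def write_samples(samples: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "participant": s.participant,
            "site": s.site,
            "dataset": s.dataset,
            "inflammation_grade": "" if s.inflammation_grade is None else s.inflammation_grade,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path) -> list[SampleMeta]:
    df = _read_tsv(path)
    samples = []
    seen = set()
    for row in df.itertuples(index=False):
        key = (row.participant, row.site, row.dataset)
        if key in seen:
            raise ValidationError(f"duplicate (participant, site, dataset): {key}")
        seen.add(key)
        grade = _opt(row.inflammation_grade)
        samples.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                participant=str(row.participant),
                site=row.site,
                dataset=row.dataset,
                inflammation_grade=None if grade is None else int(grade),
            )
        )
    return samples


_COUNT_SUFFIX = ".count"
_BREADTH_SUFFIX = ".breadth"


def write_counts(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write paired per-sample count/breadth columns to one table."""
    out = pd.DataFrame(index=matrix.counts.index)
    out.index.name = "contig_id"
    for sid in matrix.sample_ids:
        out[sid + _COUNT_SUFFIX] = matrix.counts[sid].astype(int)
        out[sid + _BREADTH_SUFFIX] = matrix.breadth[sid].map(lambda v: format(v, ".12g"))
    out.to_csv(path, sep="\t")


def read_counts(tsv_path: str | Path, samples: Sequence[SampleMeta]) -> OmicsMatrix:
    """Read a count/breadth table into an :class:`OmicsMatrix`.

    Column headers are ``<sample_id>.count`` / ``<sample_id>.breadth`` and
    must resolve against *samples*, which must all belong to one dataset.
    Missing cells are zero-filled.
    """
    datasets = {s.dataset for s in samples}
    if len(datasets) != 1:
        raise ValidationError(f"samples span multiple datasets: {sorted(datasets)}")
    (dataset,) = datasets
    known = {s.sample_id for s in samples}

    df = _read_tsv(tsv_path).set_index("contig_id")
    count_cols = [c for c in df.columns if c.endswith(_COUNT_SUFFIX)]
    sids = [c[: -len(_COUNT_SUFFIX)] for c in count_cols]
    unknown = sorted(set(sids) - known)
    if unknown:
        raise ValidationError(f"count columns for unknown samples: {unknown}")
    counts = pd.DataFrame(index=df.index)
    breadth = pd.DataFrame(index=df.index)
    for sid in sids:
        counts[sid] = pd.to_numeric(df[sid + _COUNT_SUFFIX]).fillna(0).astype(np.int64)
        bcol = sid + _BREADTH_SUFFIX
        if bcol not in df.columns:
            raise ValidationError(f"missing breadth column for sample {sid}")
        breadth[sid] = pd.to_numeric(df[bcol]).fillna(0.0).astype(float)
    return OmicsMatrix(counts=counts, breadth=breadth, dataset=dataset)


def write_genes(genes: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "contig_id": g.contig_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "db": g.db,
            "term_id": g.term_id or "",
            "term_name": g.term_name or "",
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path) -> list[GeneRecord]:
    df = _read_tsv(path)
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                contig_id=str(row.contig_id),
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                db=row.db,
                term_id=_opt(row.term_id),
                term_name=_opt(row.term_name),
            )
        )
    return genes


def read_host_scores(path: str | Path, p_max: float = 1e-5) -> list[HostScore]:
    """Read virus-host scores, keeping only adjusted p-values below *p_max*."""
    df = _read_tsv(path)
    scores = []
    seen = set()
    for row in df.itertuples(index=False):
        key = (row.vc_id, row.host_contig_id)
        if key in seen:
            raise ValidationError(f"duplicate host score pair {key}")
        seen.add(key)
        hs = HostScore(
            vc_id=str(row.vc_id),
            host_contig_id=str(row.host_contig_id),
            score=float(row.score),
            p_adjusted=float(row.p_adjusted),
        )
        if hs.p_adjusted < p_max:
            scores.append(hs)
    return scores


# ---------------------------------------------------------------------------
# bundle validation
# ---------------------------------------------------------------------------


@dataclass
class Finding:
    level: str  # "fatal" | "warning"
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def fatal(self) -> bool:
        return any(f.level == "fatal" for f in self.findings)

    @property
    def ok(self) -> bool:
        return not self.findings

    def add(self, level: str, message: str) -> None:
        self.findings.append(Finding(level, message))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok:
            return "validation: OK"
        return "\n".join(f"[{f.level}] {f.message}" for f in self.findings)


def validate_bundle(
    contigs: Sequence[ContigRecord],
    samples: Sequence[SampleMeta],
    matrices: Mapping[str, OmicsMatrix],
    genes: Sequence[GeneRecord] = (),
) -> ValidationReport:
    """Cross-check a loaded bundle; returns a report, never raises.

    Fatal findings: orphan genes, gene coordinates beyond contig ends,
    matrix rows for unknown contigs, matrix columns for unknown samples.
    Non-fatal: contigs absent from every matrix, datasets with no samples
    (the corresponding analysis module is simply disabled).
    """
    report = ValidationReport()
    contig_ids = {c.contig_id for c in contigs}
    lengths = {c.contig_id: c.length_bp for c in contigs}
    sample_ids = {s.sample_id for s in samples}

    for g in genes:
        if g.contig_id not in contig_ids:
            report.add("fatal", f"gene {g.gene_id} on unknown contig {g.contig_id}")
        elif g.end > lengths[g.contig_id]:
            report.add(
                "fatal",
                f"gene {g.gene_id} ends at {g.end} beyond contig "
                f"{g.contig_id} length {lengths[g.contig_id]}",
            )

    covered: set[str] = set()
    for name, matrix in matrices.items():
        unknown_rows = sorted(set(matrix.contig_ids) - contig_ids)
        if unknown_rows:
            report.add("fatal", f"matrix {name}: rows for unknown contigs {unknown_rows[:5]}")
        unknown_cols = sorted(set(matrix.sample_ids) - sample_ids)
        if unknown_cols:
            report.add("fatal", f"matrix {name}: columns for unknown samples {unknown_cols[:5]}")
        covered.update(matrix.contig_ids)

    orphans = sorted(contig_ids - covered)
    if matrices and orphans:
        report.add("warning", f"{len(orphans)} contigs absent from every matrix")

    present = {s.dataset for s in samples}
    for ds in DATASETS:
        if ds not in present:
            report.add("warning", f"no {ds} samples; {ds}-dependent analyses disabled")
    return report
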