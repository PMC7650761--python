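"""Readers and writers for every external format the pipeline touches.

Coordinate convention: everything in memory is 0-based half-open.  The
BLAST tabular dialect on disk is 1-based inclusive; conversion happens
only here, at the I/O boundary.  Minus-strand nucleotide hits arrive with
qstart > qend and are normalised to a forward-strand span plus a strand
flag.

All readers raise :class:`FormatError` (with file and line) rather than
silently coercing malformed rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

HOMOLOGY_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

VALID_PROCEDURES = frozenset({"whole-body", "head-only"})

#: Keyword map used to tag conserved-domain hits as viral or not when the
#: domain table carries no explicit tag.  Overridable per call.
DEFAULT_VIRAL_DOMAIN_KEYWORDS = (
    "rdrp", "rna-dependent rna polymerase", "viral", "virus",
    "capsid", "coat protein", "peptidase c3", "mononeg",
)


class FormatError(ValueError):
    """Malformed input file; message carries file and line number."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


@dataclass(frozen=True)
class ContigRecord:
    """An assembled contig from one sequencing library."""

    contig_id: str
    library_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HomologyHit:
    """A BLASTn/BLASTx-style hit of a contig against a reference virus.

    ``align_start``/``align_end`` are on the query contig, 0-based
    half-open on the forward strand; ``strand`` records hits that arrived
    with reversed coordinates.
    """

    query_id: str
    subject_accession: str
    percent_identity: float
    align_length: int
    mismatch: int
    gapopen: int
    align_start: int
    align_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float
    strand: str = "+"
    subject_name: str = ""


@dataclass(frozen=True)
class DomainHit:
    """A conserved-domain (CD-search style) hit on a contig."""

    query_id: str
    domain_accession: str
    description: str
    is_viral: bool
    start: int
    end: int
    evalue: float


@dataclass(frozen=True)
class LibraryMeta:
    """Identity and sampling context of one sequencing library."""

    library_id: str
    termite_species: str
    termite_family: str
    country: str
    diet: str
    procedure: str
    total_reads: int

    def __post_init__(self):
        if self.procedure not in VALID_PROCEDURES:
            raise ValueError(
                f"procedure must be one of {sorted(VALID_PROCEDURES)}, "
                f"got {self.procedure!r}"
            )
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")


@dataclass(frozen=True)
class ReferenceVirus:
    """Annotation for a reference (closest-relative) virus."""

    accession: str
    name: str
    host_category: str
    genome_length: int
    clade: str
    group: str
    nucleic_acid: str  # "RNA" or "DNA"


def _library_of(contig_id: str) -> str:
    # contig ids are "<library>__<contig>"; bare ids map to an empty library
    return contig_id.split("__", 1)[0] if "__" in contig_id else ""


def read_fasta(path) -> list[ContigRecord]:
    """Read contigs from FASTA, normalising sequence to uppercase.

    Order is preserved.  Duplicate IDs raise ``FormatError`` naming the
    offending ID; an empty file yields an empty list.
    """
    path = Path(path)
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(path, 0, f"duplicate contig ID {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FormatError(
                path, 0, f"contig {rec.id!r} has non-ACGTN characters {sorted(bad)}"
            )
        records.append(ContigRecord(rec.id, _library_of(rec.id), seq))
    return records


def write_fasta(records: Iterable[ContigRecord], path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_homology_table(path) -> list[HomologyHit]:
    """Read a 12-column tab-separated homology table.

    1-based inclusive qstart/qend become 0-based half-open; rows with
    qstart > qend are normalised with ``strand='-'``.
    """
    path = Path(path)
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    path, line_no, f"expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                length = int(fields[3])
                mismatch = int(fields[4])
                gapopen = int(fields[5])
                qstart = int(fields[6])
                qend = int(fields[7])
                sstart = int(fields[8])
                send = int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(path, line_no, f"non-numeric field: {exc}") from None
            if not 0.0 <= pident <= 100.0:
                raise FormatError(path, line_no, f"percent identity {pident} outside [0,100]")
            if evalue < 0:
                raise FormatError(path, line_no, f"negative e-value {evalue}")
            strand = "+"
            if qstart > qend:
                qstart, qend = qend, qstart
                strand = "-"
            hits.append(
                HomologyHit(
                    query_id=fields[0],
                    subject_accession=fields[1],
                    percent_identity=pident,
                    align_length=length,
                    mismatch=mismatch,
                    gapopen=gapopen,
                    align_start=qstart - 1,
                    align_end=qend,
                    subject_start=sstart,
                    subject_end=send,
                    evalue=evalue,
                    bitscore=bitscore,
                    strand=strand,
                )
            )
    return hits


def write_homology_table(hits: Iterable[HomologyHit], path) -> None:
    """Write hits back to the 12-column dialect, restoring 1-based inclusive
    coordinates (and the reversed qstart/qend of minus-strand rows)."""
    path = Path(path)
    with open(path, "w") as fh:
        for h in hits:
            qstart, qend = h.align_start + 1, h.align_end
            if h.strand == "-":
                qstart, qend = qend, qstart
            row = [
                h.query_id, h.subject_accession, f"{h.percent_identity:g}",
                str(h.align_length), str(h.mismatch), str(h.gapopen),
                str(qstart), str(qend), str(h.subject_start), str(h.subject_end),
                f"{h.evalue:g}", f"{h.bitscore:g}",
            ]
            fh.write("\t".join(row) + "\n")


def _infer_is_viral(description: str, keywords=DEFAULT_VIRAL_DOMAIN_KEYWORDS) -> bool:
    d = description.lower()
    return any(k in d for k in keywords)


def read_domain_table(path, viral_keywords=DEFAULT_VIRAL_DOMAIN_KEYWORDS) -> list[DomainHit]:
    """Read conserved-domain hits.

    Columns: query_id, domain_accession, description, is_viral, start,
    end, evalue — coordinates 0-based half-open on disk as well (domain
    tables are emitted by this package, not by external tools).  An empty
    ``is_viral`` cell falls back to the keyword map over descriptions.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with open(path) as fh:
        header = fh.readline()
        if header and not header.startswith("query_id\t"):
            raise FormatError(path, 1, "missing domain-table header")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(path, line_no, f"expected 7 columns, got {len(fields)}")
            qid, acc, desc, viral_s, start_s, end_s, ev_s = fields
            if not acc:
                raise FormatError(path, line_no, "empty domain accession")
            try:
                start, end, ev = int(start_s), int(end_s), float(ev_s)
            except ValueError as exc:
                raise FormatError(path, line_no, f"non-numeric field: {exc}") from None
            if viral_s == "":
                is_viral = _infer_is_viral(desc, viral_keywords)
            elif viral_s.lower() in {"true", "1", "yes"}:
                is_viral = True
            elif viral_s.lower() in {"false", "0", "no"}:
                is_viral = False
            else:
                raise FormatError(path, line_no, f"bad is_viral flag {viral_s!r}")
            if not 0 <= start < end:
                raise FormatError(path, line_no, f"bad span ({start}, {end})")
            hits.append(DomainHit(qid, acc, desc, is_viral, start, end, ev))
    return hits


def write_domain_table(hits: Iterable[DomainHit], path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("query_id\tdomain_accession\tdescription\tis_viral\tstart\tend\tevalue\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.domain_accession}\t{h.description}\t"
                f"{str(h.is_viral).lower()}\t{h.start}\t{h.end}\t{h.evalue:g}\n"
            )


def read_count_matrix(path) -> pd.DataFrame:
    """Read a virus × library count matrix (rows viruses, columns libraries).

    Counts must be non-negative integers; integer-valued floats ("3.0")
    are accepted as integers; missing cells are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(path, 0, f"duplicate row label {dup!r}")
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise FormatError(path, 0, f"missing cell in row {row!r}")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise FormatError(path, 0, "negative count")
    if (values != values.round()).any():
        raise FormatError(path, 0, "non-integer count")
    out = df.astype("int64")
    out.index.name = "virus"
    return out


def write_count_matrix(matrix: pd.DataFrame, path) -> None:
    matrix = matrix.copy()
    matrix.index.name = "virus"
    matrix.to_csv(path, sep="\t")


def read_library_metadata(path) -> list[LibraryMeta]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = [
        "library_id", "termite_species", "termite_family",
        "country", "diet", "procedure", "total_reads",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(path, 1, f"missing metadata columns {missing}")
    metas = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            metas.append(
                LibraryMeta(
                    library_id=str(row.library_id),
                    termite_species=str(row.termite_species),
                    termite_family=str(row.termite_family),
                    country=str(row.country),
                    diet=str(row.diet),
                    procedure=str(row.procedure),
                    total_reads=int(row.total_reads),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(path, line_no, str(exc)) from None
    ids = [m.library_id for m in metas]
    if len(set(ids)) != len(ids):
        raise FormatError(path, 0, "duplicate library_id")
    return metas


def write_library_metadata(metas: Iterable[LibraryMeta], path) -> None:
    rows = [
        {
            "library_id": m.library_id,
            "termite_species": m.termite_species,
            "termite_family": m.termite_family,
            "country": m.country,
            "diet": m.diet,
            "procedure": m.procedure,
            "total_reads": m.total_reads,
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_reference_table(path) -> dict[str, ReferenceVirus]:
    """Read reference-virus annotations keyed by accession."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = [
        "accession", "name", "host_category", "genome_length",
        "clade", "group", "nucleic_acid",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(path, 1, f"missing reference columns {missing}")
    refs: dict[str, ReferenceVirus] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        acc = str(row.accession)
        if acc in refs:
            raise FormatError(path, line_no, f"duplicate accession {acc!r}")
        refs[acc] = ReferenceVirus(
            accession=acc,
            name=str(row.name),
            host_category=str(row.host_category),
            genome_length=int(row.genome_length),
            clade=str(row.clade),
            group=str(row.group),
            nucleic_acid=str(row.nucleic_acid),
        )
    return refs


def write_reference_table(refs: Iterable[ReferenceVirus], path) -> None:
    rows = [
        {
            "accession": r.accession,
            "name": r.name,
            "host_category": r.host_category,
            "genome_length": r.genome_length,
            "clade": r.clade,
            "group": r.group,
            "nucleic_acid": r.nucleic_acid,
        }
        for r in refs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write named result tables as TSV files under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
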