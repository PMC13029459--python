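"""Readers and writers for the pipeline's on-disk formats.

FASTA headers use the dialect ``strain|replicon|circular={0,1}`` with an
optional trailing ``role={chromosome,plasmid}`` token; headers that do not
parse fall back to a single-replicon linear interpretation. Alignments are
accepted either as minimal SAM (flags 0/16 primary, 256 secondary, 2048
supplementary-treated-as-primary) or as a 6-column TSV dialect::

    read_id  contig  start  end  strand  is_secondary

with 0-based half-open coordinates. Everything tabular goes through pandas;
SAM goes through pysam; FASTA through Biopython.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO

from .errors import FormatError
from .genome import Genome, Replicon
from .simulate import AlignmentRecord
from .topology import AnnotationSet

logger = logging.getLogger(__name__)

ALN_TSV_COLUMNS = ["read_id", "contig", "start", "end", "strand",
                   "is_secondary"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _parse_header(header: str, fallback_strain: str
                  ) -> tuple[str, str, bool, str | None]:
    parts = header.split("|")
    if len(parts) >= 3 and parts[2].startswith("circular="):
        strain, rep_id = parts[0], parts[1]
        circular = parts[2].split("=", 1)[1] == "1"
        role = None
        for tok in parts[3:]:
            if tok.startswith("role="):
                role = tok.split("=", 1)[1]
        return strain, rep_id, circular, role
    return fallback_strain, header, False, None


def read_fasta(path: str | Path) -> Genome:
    """Read one genome (all records) from a FASTA file.

    Lowercase bases are uppercased with a warning; empty files and
    non-ACGT sequences raise FormatError. Replicon roles come from the
    header dialect when present, otherwise the longest record is taken as
    the chromosome candidate and the rest as plasmids.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    fallback = path.stem
    parsed = []
    strain_id = None
    for i, rec in enumerate(records):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {i + 1} ({rec.id}) is empty")
        if seq != seq.upper():
            logger.warning("%s: record %s contains lowercase bases; "
                           "uppercasing", path, rec.id)
            seq = seq.upper()
        strain, rep_id, circular, role = _parse_header(rec.id, fallback)
        strain_id = strain_id or strain
        parsed.append((rep_id, seq, circular, role))
    has_roles = any(role for _, _, _, role in parsed)
    longest = max(range(len(parsed)), key=lambda i: len(parsed[i][1]))
    replicons = []
    for i, (rep_id, seq, circular, role) in enumerate(parsed):
        if role is None:
            role = "chromosome" if (not has_roles and i == longest) \
                else "plasmid"
        try:
            replicons.append(Replicon(rep_id, seq, circular, role))
        except ValueError as exc:
            raise FormatError(f"{path}: record {i + 1}: {exc}") from exc
    if not any(r.role_truth == "chromosome" for r in replicons):
        replicons[longest].role_truth = "chromosome"
    return Genome(strain_id=strain_id, replicons=replicons)


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rep in genome.replicons:
            fh.write(f">{genome.strain_id}|{rep.id}|"
                     f"circular={int(rep.circular)}|role={rep.role_truth}\n")
            for i in range(0, len(rep.seq), width):
                fh.write(rep.seq[i: i + width] + "\n")


# ---------------------------------------------------------------------------
# alignments: minimal SAM and the TSV dialect
# ---------------------------------------------------------------------------

def write_sam(records: list[AlignmentRecord],
              contig_lengths: dict[str, int], path: str | Path) -> None:
    """Minimal SAM: flags 0/16 for primary +/-, 256 for secondary;
    CIGAR is a single M run over the span, SEQ is '*'."""
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": name, "LN": length}
                     for name, length in contig_lengths.items()]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.reference_name = rec.contig_id
            a.reference_start = rec.start
            a.cigarstring = f"{rec.span}M"
            a.mapping_quality = 60
            flag = 0
            if rec.strand == "-":
                flag |= 16
            if rec.is_secondary:
                flag |= 256
            a.flag = flag
            out.write(a)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read alignment records from SAM. Flags interpreted: 16 (reverse),
    256 (secondary); 2048 (supplementary) is treated as primary, since
    mappers may encode an origin wrap that way. Unmapped records are
    skipped."""
    out: list[AlignmentRecord] = []
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for a in fh:
                if a.is_unmapped or a.reference_name is None:
                    continue
                out.append(AlignmentRecord(
                    read_id=a.query_name,
                    contig_id=a.reference_name,
                    start=int(a.reference_start),
                    end=int(a.reference_end),
                    strand="-" if a.is_reverse else "+",
                    is_secondary=bool(a.is_secondary)))
    except ValueError as exc:
        raise FormatError(f"{path}: not parseable as SAM: {exc}") from exc
    return out


def write_alignment_tsv(records: list[AlignmentRecord],
                        path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.read_id, r.contig_id, r.start, r.end, r.strand,
          int(r.is_secondary)) for r in records],
        columns=ALN_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_alignment_tsv(path: str | Path) -> list[AlignmentRecord]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable TSV: {exc}") from exc
    missing = set(ALN_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [AlignmentRecord(str(r.read_id), str(r.contig), int(r.start),
                            int(r.end), str(r.strand), bool(r.is_secondary))
            for r in df.itertuples()]


def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Dispatch on extension: .sam -> SAM, anything else -> TSV dialect."""
    if str(path).endswith(".sam"):
        return read_sam(path)
    return read_alignment_tsv(path)


# ---------------------------------------------------------------------------
# annotations and matrices
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> dict[str, AnnotationSet]:
    """TSV of (contig_id, gene) pairs -> AnnotationSet per contig."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable TSV: {exc}") from exc
    if not {"contig_id", "gene"} <= set(df.columns):
        raise FormatError(f"{path}: need columns contig_id, gene")
    out: dict[str, AnnotationSet] = {}
    for contig, group in df.groupby("contig_id"):
        out[str(contig)] = AnnotationSet(str(contig),
                                         set(group["gene"].astype(str)))
    return out


def write_ani_pairs(pairs: list[dict], path: str | Path) -> None:
    pd.DataFrame(pairs).to_csv(path, sep="\t", index=False,
                               float_format="%.4f")


def write_ani_af_matrix(strains: list[str], ani: pd.DataFrame,
                        af: pd.DataFrame, path: str | Path) -> None:
    """All-vs-all matrix with ANI in the lower triangle and AF in the
    upper, '-' on the diagonal."""
    out = pd.DataFrame("-", index=strains, columns=strains)
    for i, a in enumerate(strains):
        for j, b in enumerate(strains):
            if i > j:
                out.loc[a, b] = f"{float(ani.loc[a, b]):.2f}"
            elif i < j:
                out.loc[a, b] = f"{float(af.loc[a, b]):.1f}"
    out.index.name = "strain"
    out.to_csv(path, sep="\t")


def read_ani_matrix(path: str | Path) -> pd.DataFrame:
    """Square or rectangular numeric ANI matrix TSV, first column = row
    labels (e.g. type strains), remaining columns = strains."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable matrix TSV: {exc}") from exc
    return df.apply(pd.to_numeric, errors="coerce")
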