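"""Candidate signal-peptide records: parsing, QC, translation, deduplication.

A candidate is a paired amino-acid / CDS-nucleotide record for one signal
peptide (SP).  Records arrive either as a TSV table or as a pair of FASTA
files (``<name>.aa.fasta`` + ``<name>.nt.fasta``) sharing one accession set.
Quality control mirrors the availability-and-validity checks applied when
nucleotide sequences are fetched for UniProt-annotated SPs: the CDS must be
present, in frame, start with ATG, and translate exactly to the protein
sequence.  Coordinates are 0-based half-open internally; reports are 1-based.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

log = logging.getLogger("spscreen")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
NT_ALPHABET = set("ACGT")

TSV_COLUMNS = [
    "uniprot_accession",
    "species",
    "protein_name",
    "aa_sequence",
    "nt_sequence",
    "source_db",
    "source_accession",
]

_CODON_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
_FORWARD = _CODON_TABLE.forward_table
_STOPS = set(_CODON_TABLE.stop_codons)


class RecordError(ValueError):
    """A malformed input row/record; carries the offending identifier."""

    def __init__(self, message: str, identifier: str = ""):
        super().__init__(message)
        self.identifier = identifier


class TranslationError(ValueError):
    """CDS cannot be translated; ``position`` is the 0-based nt offset."""

    def __init__(self, message: str, position: int):
        super().__init__(message)
        self.position = position


@dataclass
class SPRecord:
    """One candidate signal peptide: protein sequence plus its CDS.

    ``nt_sequence`` may be ``None`` to represent a failed retrieval; such a
    record can never pass QC.  The CDS is stored without a stop codon (the SP
    is internal to the fusion ORF), so any stop codon is a QC failure.
    """

    uniprot_accession: str
    species: str = ""
    protein_name: str = ""
    aa_sequence: str = ""
    nt_sequence: str | None = None
    source_db: str = ""
    source_accession: str = ""

    def __post_init__(self) -> None:
        self.aa_sequence = self.aa_sequence.strip().upper()
        if not self.aa_sequence:
            raise RecordError(
                f"{self.uniprot_accession}: empty amino-acid sequence",
                self.uniprot_accession,
            )
        bad = set(self.aa_sequence) - AA_ALPHABET
        if bad:
            raise RecordError(
                f"{self.uniprot_accession}: invalid amino-acid symbols {sorted(bad)}",
                self.uniprot_accession,
            )
        if self.nt_sequence is not None:
            self.nt_sequence = self.nt_sequence.strip().upper() or None


@dataclass
class QCReport:
    """Availability/validity flags for one record.

    ``overall_pass`` is true iff all four criterion flags are true.
    """

    retrieved: bool
    in_frame: bool
    starts_with_start_codon: bool
    translation_matches: bool

    @property
    def overall_pass(self) -> bool:
        return (
            self.retrieved
            and self.in_frame
            and self.starts_with_start_codon
            and self.translation_matches
        )


def translate_cds(nt_sequence: str) -> str:
    """Translate a complete CDS with the standard codon table.

    Raises :class:`TranslationError` for a trailing partial codon, an
    ambiguous base (anything outside ACGT), or an in-frame stop codon —
    each identifying the offending nucleotide position.  A stop anywhere is
    an error because SP CDSs are stored stop-free.
    """
    nt = nt_sequence.upper()
    if len(nt) < 3:
        raise TranslationError(f"CDS shorter than one codon ({len(nt)} nt)", 0)
    if len(nt) % 3:
        raise TranslationError(
            f"trailing partial codon: length {len(nt)} not divisible by 3",
            3 * (len(nt) // 3),
        )
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if codon in _STOPS:
            raise TranslationError(f"in-frame stop codon {codon} at nt {i + 1}", i)
        try:
            out.append(_FORWARD[codon])
        except KeyError:
            raise TranslationError(f"ambiguous/invalid codon {codon} at nt {i + 1}", i)
    return "".join(out)


def validate_record(record: SPRecord) -> QCReport:
    """Run the four availability/validity checks on one record.

    All failures are report flags, never exceptions: a record with an
    untranslatable CDS simply fails ``translation_matches``.
    """
    nt = record.nt_sequence
    retrieved = nt is not None and len(nt) > 0
    in_frame = bool(retrieved and len(nt) % 3 == 0)
    starts = bool(retrieved and nt.startswith("ATG"))
    matches = False
    if retrieved and in_frame:
        try:
            matches = translate_cds(nt) == record.aa_sequence
        except TranslationError:
            matches = False
    return QCReport(retrieved, in_frame, starts, matches)


def dedup_records(
    records: Sequence[SPRecord], sort_by: str | None = None
) -> tuple[list[SPRecord], int]:
    """Drop records whose exact CDS string was already seen.

    The first occurrence in input order is retained; pass
    ``sort_by="accession"`` to sort on UniProt accession first, making the
    survivor set independent of input order.  Returns ``(unique, removed)``.
    """
    if sort_by == "accession":
        records = sorted(records, key=lambda r: r.uniprot_accession)
    elif sort_by is not None:
        raise ValueError(f"unknown sort key {sort_by!r}")
    seen: set[str] = set()
    unique: list[SPRecord] = []
    for rec in records:
        key = rec.nt_sequence or ""
        if key in seen:
            continue
        seen.add(key)
        unique.append(rec)
    return unique, len(records) - len(unique)


# ---------------------------------------------------------------------------
# File ingest
# ---------------------------------------------------------------------------

def parse_records(
    path: str | Path,
    format: str = "tsv",
    errors: list[RecordError] | None = None,
) -> list[SPRecord]:
    """Parse candidate records from ``path`` in input order.

    ``format`` is ``"tsv"`` (seven-column table, header row required) or
    ``"paired-fasta"`` (``<name>.aa.fasta`` + ``<name>.nt.fasta``; ``path``
    may be the common stem or either member of the pair).  Malformed rows are
    collected into ``errors`` (if given) and logged; parsing continues.  An
    unreadable file raises.
    """
    path = Path(path)
    if format == "tsv":
        return _parse_tsv(path, errors)
    if format == "paired-fasta":
        return _parse_paired_fasta(path, errors)
    raise ValueError(f"unknown record format {format!r}")


def _collect(errors: list[RecordError] | None, err: RecordError) -> None:
    log.warning("skipping record %s: %s", err.identifier, err)
    if errors is not None:
        errors.append(err)


def _parse_tsv(path: Path, errors: list[RecordError] | None) -> list[SPRecord]:
    records: list[SPRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise RecordError(f"{path}: empty file, no header row", str(path))
        missing = [c for c in TSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise RecordError(f"{path}: missing columns {missing}", str(path))
        for lineno, row in enumerate(reader, start=2):
            acc = (row.get("uniprot_accession") or "").strip()
            try:
                if not acc:
                    raise RecordError(f"line {lineno}: blank accession", str(lineno))
                records.append(
                    SPRecord(
                        uniprot_accession=acc,
                        species=(row.get("species") or "").strip(),
                        protein_name=(row.get("protein_name") or "").strip(),
                        aa_sequence=(row.get("aa_sequence") or "").strip(),
                        nt_sequence=(row.get("nt_sequence") or "").strip() or None,
                        source_db=(row.get("source_db") or "").strip(),
                        source_accession=(row.get("source_accession") or "").strip(),
                    )
                )
            except RecordError as err:
                _collect(errors, err)
    return records


def _paired_fasta_paths(path: Path) -> tuple[Path, Path]:
    name = path.name
    if name.endswith(".aa.fasta"):
        stem = path.with_name(name[: -len(".aa.fasta")])
    elif name.endswith(".nt.fasta"):
        stem = path.with_name(name[: -len(".nt.fasta")])
    else:
        stem = path
    return (
        stem.with_name(stem.name + ".aa.fasta"),
        stem.with_name(stem.name + ".nt.fasta"),
    )


def _description_fields(description: str) -> dict[str, str]:
    # "ACC species=Homo sapiens protein=BMP2 source_db=NCBI" style metadata
    fields: dict[str, str] = {}
    tokens = description.split()[1:]
    key = None
    for tok in tokens:
        if "=" in tok:
            key, _, val = tok.partition("=")
            fields[key] = val
        elif key:
            fields[key] += " " + tok
    return fields


def _parse_paired_fasta(path: Path, errors: list[RecordError] | None) -> list[SPRecord]:
    aa_path, nt_path = _paired_fasta_paths(path)
    aa_recs = {r.id: r for r in SeqIO.parse(str(aa_path), "fasta")}
    nt_recs = {r.id: r for r in SeqIO.parse(str(nt_path), "fasta")}
    records: list[SPRecord] = []
    for acc, aa_rec in aa_recs.items():
        meta = _description_fields(aa_rec.description)
        nt_rec = nt_recs.get(acc)
        try:
            records.append(
                SPRecord(
                    uniprot_accession=acc,
                    species=meta.get("species", "").replace("_", " "),
                    protein_name=meta.get("protein", "").replace("_", " "),
                    aa_sequence=str(aa_rec.seq),
                    nt_sequence=str(nt_rec.seq) if nt_rec is not None else None,
                    source_db=meta.get("source_db", ""),
                    source_accession=meta.get("source_accession", ""),
                )
            )
        except RecordError as err:
            _collect(errors, err)
    extra = set(nt_recs) - set(aa_recs)
    if extra:
        _collect(
            errors,
            RecordError(
                f"nucleotide FASTA has IDs absent from amino-acid FASTA: {sorted(extra)}",
                str(nt_path),
            ),
        )
    return records


def write_qc_report(
    records: Iterable[SPRecord], reports: Iterable[QCReport], path: str | Path
) -> None:
    """Write one TSV row per record with the four flags and overall verdict."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "uniprot_accession\tretrieved\tin_frame\t"
            "starts_with_start_codon\ttranslation_matches\toverall_pass\n"
        )
        for rec, rep in zip(records, reports):
            fh.write(
                f"{rec.uniprot_accession}\t{rep.retrieved}\t{rep.in_frame}\t"
                f"{rep.starts_with_start_codon}\t{rep.translation_matches}\t"
                f"{rep.overall_pass}\n"
            )
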