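"""I/O and canonical representations for ORF and ramp-reporter sequence tables.

The package works on spliced gene sequences (5'UTR / CDS / 3'UTR) and on
nine-nucleotide ramp-reporter variants.  Everything is canonicalized to the
DNA alphabet on ingest: RNA notation (U) is accepted anywhere and mapped to
T, so mRNA-style and genomic-style inputs mix freely.  IUPAC ambiguity
codes collapse to N; any other character is a validation error that names
the offending (1-based) position.

Coordinates are 1-based and inclusive throughout the package; CDS
nucleotide 1 is the A of the annotated start AUG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")
START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVN")
_BIN_FRACTION_COLUMNS = tuple(f"frac_bin{i}" for i in range(1, 6))


class SequenceValidationError(ValueError):
    """An input sequence violates the nucleotide alphabet or a length rule."""


def canonicalize_sequence(raw: str) -> str:
    """Map a raw nucleotide string to the internal {A,C,G,T,N} alphabet.

    Uppercases, maps U to T, and collapses IUPAC ambiguity codes to N.
    Raises :class:`SequenceValidationError` naming the 1-based position of
    the first invalid character.
    """
    if not raw:
        raise SequenceValidationError("empty sequence")
    out = []
    for i, ch in enumerate(raw.upper(), start=1):
        if ch in "ACGT":
            out.append(ch)
        elif ch == "U":
            out.append("T")
        elif ch in _IUPAC_AMBIGUITY:
            out.append("N")
        else:
            raise SequenceValidationError(f"invalid nucleotide {ch!r} at position {i}")
    return "".join(out)


@dataclass(frozen=True)
class OrfRecord:
    """One gene's spliced sequences plus expression annotations.

    ``complete_cds`` marks a CDS that is a whole number of codons, starts
    with ATG and ends with a stop codon; incomplete CDSs are retained but
    excluded from stop-anchored alignments.
    """

    gene_id: str
    utr5: str = ""
    cds: str = ""
    utr3: str = ""
    expression: float | None = None
    msms_detected: bool = False
    complete_cds: bool = False

    @classmethod
    def from_raw(
        cls,
        gene_id: str,
        utr5: str = "",
        cds: str = "",
        utr3: str = "",
        expression: float | None = None,
        msms_detected: bool = False,
    ) -> "OrfRecord":
        """Build a record from raw strings, canonicalizing and validating."""
        utr5 = canonicalize_sequence(utr5) if utr5 else ""
        utr3 = canonicalize_sequence(utr3) if utr3 else ""
        cds = canonicalize_sequence(cds)
        if len(cds) < 3:
            raise SequenceValidationError(
                f"{gene_id}: CDS shorter than 3 nt ({len(cds)})"
            )
        complete = (
            len(cds) % 3 == 0
            and cds.startswith(START_CODON)
            and cds[-3:] in STOP_CODONS
        )
        return cls(
            gene_id=gene_id,
            utr5=utr5,
            cds=cds,
            utr3=utr3,
            expression=None if expression is None else float(expression),
            msms_detected=bool(msms_detected),
            complete_cds=complete,
        )

    @property
    def spanning(self) -> str:
        """utr5 + cds + utr3 as one string (the gene's mRNA-like span)."""
        return self.utr5 + self.cds + self.utr3


@dataclass(frozen=True)
class NineMerRecord:
    """A 9-nt (three-codon) ramp-reporter variant and its expression.

    ``expression`` is either a real on the library's bounded scale (1-5 for
    the sorted-bin design) or a categorical bin label (e.g. "low").
    ``codon_offset`` records which codon of the reporter ORF the nine-mer's
    first codon occupies (3 for the codons-3-5 design, 6 for codons 6-8).
    """

    sequence: str
    expression: float | str
    structured: bool = False
    codon_offset: int = 3
    bin_fractions: tuple[float, ...] | None = None

    @classmethod
    def from_raw(
        cls,
        sequence: str,
        expression: float | str,
        structured: bool = False,
        codon_offset: int = 3,
        bin_fractions: Sequence[float] | None = None,
    ) -> "NineMerRecord":
        seq = canonicalize_sequence(str(sequence))
        if len(seq) != 9:
            raise SequenceValidationError(
                f"nine-mer must be 9 nt, got {len(seq)}: {seq!r}"
            )
        for i in (0, 3, 6):
            if seq[i : i + 3] in STOP_CODONS:
                raise SequenceValidationError(
                    f"in-frame stop codon {seq[i:i + 3]} at codon {i // 3 + 1}: {seq}"
                )
        fractions: tuple[float, ...] | None = None
        if bin_fractions is not None:
            fractions = tuple(float(f) for f in bin_fractions)
            if len(fractions) != 5:
                raise ValueError("bin_fractions must have 5 entries")
            if any(f < 0 for f in fractions):
                raise ValueError("bin_fractions must be nonnegative")
            if abs(sum(fractions) - 1.0) > 1e-9:
                raise ValueError(f"bin_fractions sum to {sum(fractions)}, not 1")
        expr: float | str
        try:
            expr = float(expression)
        except (TypeError, ValueError):
            expr = str(expression)
        return cls(seq, expr, bool(structured), int(codon_offset), fractions)

    @property
    def codons(self) -> tuple[str, str, str]:
        s = self.sequence
        return (s[0:3], s[3:6], s[6:9])


@dataclass
class NineMerLoad:
    """Result of loading a nine-mer table: kept records plus rejection counts."""

    records: list[NineMerRecord]
    n_rows: int
    n_rejected_stop: int


def _parse_bool(value: str | bool) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in {"1", "true", "t", "yes"}


def _records_from_frame(df: pd.DataFrame) -> list[OrfRecord]:
    required = {"gene_id", "utr5", "cds", "utr3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    records: list[OrfRecord] = []
    seen: set[str] = set()
    n_incomplete = 0
    for row in df.itertuples(index=False):
        gid = str(row.gene_id)
        if gid in seen:
            raise ValueError(f"duplicate gene_id: {gid}")
        seen.add(gid)
        expression = None
        if "expression" in df.columns:
            raw = getattr(row, "expression")
            if raw not in ("", None) and not pd.isna(raw):
                expression = float(raw)
                if expression < 0:
                    raise ValueError(f"{gid}: negative expression {expression}")
        msms = False
        if "msms_detected" in df.columns:
            msms = _parse_bool(getattr(row, "msms_detected"))
        rec = OrfRecord.from_raw(
            gid, str(row.utr5), str(row.cds), str(row.utr3), expression, msms
        )
        if not rec.complete_cds:
            n_incomplete += 1
            log.warning("%s: incomplete CDS retained (length %d)", gid, len(rec.cds))
        records.append(rec)
    log.info(
        "loaded %d ORF records (%d complete CDS, %d incomplete)",
        len(records),
        len(records) - n_incomplete,
        n_incomplete,
    )
    return records


def read_orf_table(path: str | Path, format: str = "tsv") -> list[OrfRecord]:
    """Read a gene-sequence table (tab-delimited or triplet FASTA).

    The TSV dialect has columns ``gene_id, utr5, cds, utr3`` plus optional
    ``expression`` (empty = missing) and ``msms_detected``.  The FASTA
    dialect tags each region in the header as ``geneid|utr5`` etc.; only
    the ``|cds`` record is mandatory per gene.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return _records_from_frame(df)
    if format == "fasta_triplet":
        parts: dict[str, dict[str, str]] = {}
        order: list[str] = []
        for rec in SeqIO.parse(str(path), "fasta"):
            if "|" not in rec.id:
                raise ValueError(f"fasta_triplet header without region tag: {rec.id}")
            gid, region = rec.id.rsplit("|", 1)
            if region not in {"utr5", "cds", "utr3"}:
                raise ValueError(f"unknown region tag {region!r} in {rec.id}")
            if gid not in parts:
                parts[gid] = {}
                order.append(gid)
            if region in parts[gid]:
                raise ValueError(f"duplicate {region} record for gene_id: {gid}")
            parts[gid][region] = str(rec.seq)
        df = pd.DataFrame(
            {
                "gene_id": order,
                "utr5": [parts[g].get("utr5", "") for g in order],
                "cds": [parts[g].get("cds", "") for g in order],
                "utr3": [parts[g].get("utr3", "") for g in order],
            }
        )
        return _records_from_frame(df)
    raise ValueError(f"unknown format: {format!r}")


def write_orf_table(records: Iterable[OrfRecord], path: str | Path) -> None:
    """Write ORF records as TSV (round-trips exactly through read_orf_table)."""
    rows = [
        {
            "gene_id": r.gene_id,
            "utr5": r.utr5,
            "cds": r.cds,
            "utr3": r.utr3,
            "expression": "" if r.expression is None else repr(r.expression),
            "msms_detected": str(r.msms_detected),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_orf_fasta(records: Iterable[OrfRecord], path: str | Path) -> None:
    """Write records in the triplet-FASTA dialect (empty regions omitted)."""
    out = []
    for r in records:
        for region, seq in (("utr5", r.utr5), ("cds", r.cds), ("utr3", r.utr3)):
            if seq:
                out.append(SeqRecord(Seq(seq), id=f"{r.gene_id}|{region}", description=""))
    SeqIO.write(out, str(path), "fasta")


def read_ninemer_table(path: str | Path) -> NineMerLoad:
    """Read a nine-mer reporter table, rejecting in-frame-stop variants.

    Expected columns: ``sequence``, ``expression`` (numeric or bin label),
    optional ``structured``, ``codon_offset`` and five bin-fraction columns
    ``frac_bin1`` .. ``frac_bin5``.  Variants containing a stop codon in
    their own frame are dropped and counted, not errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sequence" not in df.columns or "expression" not in df.columns:
        raise ValueError("nine-mer table needs 'sequence' and 'expression' columns")
    has_fracs = all(c in df.columns for c in _BIN_FRACTION_COLUMNS)
    records: list[NineMerRecord] = []
    n_stop = 0
    for row in df.itertuples(index=False):
        fractions = None
        if has_fracs:
            raw = [getattr(row, c) for c in _BIN_FRACTION_COLUMNS]
            if any(v != "" for v in raw):
                fractions = [float(v) for v in raw]
        kwargs = dict(
            sequence=row.sequence,
            expression=row.expression,
            structured=_parse_bool(getattr(row, "structured", False)),
            codon_offset=int(getattr(row, "codon_offset", 3) or 3),
            bin_fractions=fractions,
        )
        try:
            records.append(NineMerRecord.from_raw(**kwargs))
        except SequenceValidationError as err:
            if "stop codon" in str(err):
                n_stop += 1
            else:
                raise
    log.info(
        "loaded %d nine-mer records, rejected %d with in-frame stops",
        len(records),
        n_stop,
    )
    return NineMerLoad(records=records, n_rows=len(df), n_rejected_stop=n_stop)


def write_ninemer_table(records: Iterable[NineMerRecord], path: str | Path) -> None:
    """Write nine-mer records as TSV (round-trips through read_ninemer_table)."""
    rows = []
    for r in records:
        row = {
            "sequence": r.sequence,
            "expression": repr(r.expression) if isinstance(r.expression, float) else r.expression,
            "structured": str(r.structured),
            "codon_offset": str(r.codon_offset),
        }
        for i, col in enumerate(_BIN_FRACTION_COLUMNS):
            row[col] = "" if r.bin_fractions is None else repr(r.bin_fractions[i])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
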