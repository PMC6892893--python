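"""Sequence input/output and coordinate bookkeeping.

Parents of a chimera library are carried as paired protein + CDS records;
the multiple sequence alignment over their proteins is consumed (built by
any external aligner), never computed here.  Coordinate conventions used
throughout the package: sequence intervals are 0-based half-open; alignment
columns are 1-based, as alignment viewers display them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

GAP_CHARS = ("-", ".")

__all__ = [
    "ParentRecord",
    "Msa",
    "CdsValidation",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "validate_cds",
    "translate_cds",
    "residue_to_nt",
    "load_parents",
    "load_msa",
]


class FastaFormatError(ValueError):
    """Raised for malformed FASTA/FASTQ input."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ParentRecord:
    """One parental nuclease: protein sequence plus its coding sequence.

    The CDS must translate (standard genetic code, terminal stop trimmed)
    to the protein exactly; ``validate()`` enforces this.
    """

    id: str
    protein_seq: str
    cds_seq: str
    organism: str = ""

    def validate(self) -> None:
        report = validate_cds(self.protein_seq, self.cds_seq)
        if not report.ok:
            raise ValueError(
                f"parent {self.id!r}: " + "; ".join(m for _, m in report.errors)
            )

    @property
    def cds_len(self) -> int:
        """CDS length excluding any retained terminal stop codon."""
        return 3 * len(self.protein_seq)


@dataclass(frozen=True)
class Msa:
    """A protein multiple sequence alignment over the parents.

    ``rows`` preserves input order; gap characters are normalized to '-'.
    """

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("empty alignment")
        norm = []
        width = None
        seen = set()
        for rid, seq in self.rows:
            if rid in seen:
                raise ValueError(f"duplicate alignment row id {rid!r}")
            seen.add(rid)
            s = seq.upper()
            for g in GAP_CHARS[1:]:
                s = s.replace(g, "-")
            if width is None:
                width = len(s)
            elif len(s) != width:
                raise ValueError(
                    f"row {rid!r} has length {len(s)}, expected {width}"
                )
            norm.append((rid, s))
        object.__setattr__(self, "rows", tuple(norm))

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.rows)

    def row(self, row_id: str) -> str:
        for rid, seq in self.rows:
            if rid == row_id:
                return seq
        raise KeyError(f"unknown alignment row {row_id!r}")

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace("-", "")

    def aln_to_seq(self, row_id: str, column: int) -> int | None:
        """Map a 1-based alignment column to the 0-based residue index.

        Returns None when the row carries a gap at that column.
        """
        seq = self.row(row_id)
        if not 1 <= column <= self.n_columns:
            raise IndexError(f"column {column} out of range 1..{self.n_columns}")
        if seq[column - 1] == "-":
            return None
        return column - 1 - seq.count("-", 0, column - 1)

    def seq_to_aln(self, row_id: str, residue_index: int) -> int:
        """Map a 0-based residue index back to its 1-based alignment column."""
        seq = self.row(row_id)
        if residue_index < 0:
            raise IndexError("negative residue index")
        n = -1
        for col, ch in enumerate(seq, start=1):
            if ch != "-":
                n += 1
                if n == residue_index:
                    return col
        raise IndexError(
            f"residue {residue_index} beyond row {row_id!r} "
            f"({n + 1} residues)"
        )


@dataclass(frozen=True)
class CdsValidation:
    """Outcome of a CDS-vs-protein consistency check.

    ``errors`` holds (code, message) pairs; codes are ``length``,
    ``internal-stop`` and ``mismatch``.
    """

    ok: bool
    errors: tuple[tuple[str, str], ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of (id, uppercased sequence).

    Duplicate ids, empty sequences and non-FASTA content are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise FastaFormatError(f"{path}: not FASTA (no '>' header)")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty header")
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(f"{path}: empty sequence for {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream (id, sequence, Phred+33 quality string) records from FASTQ.

    Biopython enforces sequence/quality length agreement and record
    structure; errors surface as ValueError.
    """
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        yield rec.id, str(rec.seq).upper(), qual


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(f"{rid}: sequence/quality length mismatch")
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# CDS validation and coordinate helpers


def translate_cds(cds_seq: str) -> str:
    """Translate a CDS with the standard code; a terminal stop is trimmed."""
    prot = str(Seq(cds_seq).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def validate_cds(protein_seq: str, cds_seq: str) -> CdsValidation:
    """Check that ``cds_seq`` encodes ``protein_seq`` exactly.

    Length-not-multiple-of-3, internal stop codons and residue mismatches
    are each reported distinctly; a terminal stop codon is tolerated.
    """
    if not protein_seq or not cds_seq:
        raise ValueError("protein and CDS must be non-empty")
    errors: list[tuple[str, str]] = []
    if len(cds_seq) % 3 != 0:
        errors.append(
            ("length", f"CDS length {len(cds_seq)} is not a multiple of 3")
        )
        return CdsValidation(False, tuple(errors))
    prot = str(Seq(cds_seq).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        pos = prot.index("*")
        errors.append(
            ("internal-stop", f"internal stop codon at residue {pos + 1}")
        )
    if len(prot) != len(protein_seq):
        errors.append(
            (
                "mismatch",
                f"translation length {len(prot)} != protein length "
                f"{len(protein_seq)}",
            )
        )
    else:
        diffs = [
            i + 1 for i, (x, y) in enumerate(zip(prot, protein_seq)) if x != y
        ]
        if diffs:
            errors.append(
                (
                    "mismatch",
                    "translation differs at residue(s) "
                    + ",".join(map(str, diffs[:10]))
                    + ("…" if len(diffs) > 10 else ""),
                )
            )
    return CdsValidation(not errors, tuple(errors))


def residue_to_nt(residue_index: int) -> tuple[int, int]:
    """Half-open nucleotide interval [3i, 3i+3) of residue ``i`` on its CDS."""
    if residue_index < 0:
        raise ValueError("residue index must be >= 0")
    return 3 * residue_index, 3 * residue_index + 3


# ---------------------------------------------------------------------------
# higher-level loaders


def load_parents(protein_fasta: str | Path, cds_fasta: str | Path) -> list[ParentRecord]:
    """Pair protein and CDS FASTA files into validated ParentRecords.

    Records are matched by id; every protein must have a CDS and vice versa.
    """
    prots = dict(read_fasta(protein_fasta))
    cdss = dict(read_fasta(cds_fasta))
    missing = sorted(set(prots) ^ set(cdss))
    if missing:
        raise ValueError(f"ids not present in both files: {missing}")
    parents = []
    for rid, pseq in read_fasta(protein_fasta):
        rec = ParentRecord(id=rid, protein_seq=pseq, cds_seq=cdss[rid])
        rec.validate()
        parents.append(rec)
    return parents


def load_msa(path: str | Path, parents: list[ParentRecord] | None = None) -> Msa:
    """Read an aligned FASTA into an Msa; optionally check it matches parents."""
    msa = Msa(rows=tuple(read_fasta(path)))
    if parents is not None:
        by_id = {p.id: p for p in parents}
        for rid in msa.ids:
            if rid not in by_id:
                raise ValueError(f"alignment row {rid!r} has no parent record")
            if msa.ungapped(rid) != by_id[rid].protein_seq:
                raise ValueError(
                    f"alignment row {rid!r} does not reproduce its protein"
                )
        absent = sorted(set(by_id) - set(msa.ids))
        if absent:
            warnings.warn(f"parents missing from alignment: {absent}")
    return msa
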