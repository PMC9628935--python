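"""Sequence and panel I/O.

Reads per-locus FASTA files and a tab-separated strain metadata table, and
assembles them into a :class:`StrainPanel` — the strains × loci grid of
sequences every downstream statistic is computed over.

The FASTA reader is a small validating parser rather than a wrapper around
``Bio.SeqIO`` because the error contract requires line numbers for malformed
headers and illegal characters; writing goes through Biopython.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO
from skbio import TreeNode

from .errors import (
    DuplicateRecordError,
    FastaFormatError,
    LookupResolutionError,
    MarkerscanError,
    SchemaError,
)

ALPHABET = set("ACGTN-")

METADATA_COLUMNS = ["strain_id", "species", "locus", "fasta_path", "seq_id"]


@dataclass(frozen=True)
class SeqEntry:
    """A single named DNA sequence (uppercase, U→T, alphabet ACGTN-)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("sequence id must be non-empty")
        if not self.seq:
            raise FastaFormatError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise FastaFormatError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class StrainPanel:
    """Strains with species labels and per-locus sequences.

    ``strains`` preserves first-appearance order from the metadata table;
    all downstream outputs are sorted by that order. Missing (strain, locus)
    cells are allowed and simply absent from ``sequences``; statistics skip
    the strain at that locus rather than dropping it panel-wide.
    """

    strains: list[tuple[str, str]]  # (strain_id, species_label)
    loci: list[str]
    sequences: dict[tuple[str, str], SeqEntry] = field(default_factory=dict)
    reference_strain: str | None = None

    def __post_init__(self) -> None:
        seen = set()
        for sid, sp in self.strains:
            if not sp:
                raise SchemaError(f"strain {sid!r} has an empty species label")
            if sid in seen:
                raise DuplicateRecordError(f"duplicate strain id {sid!r}")
            seen.add(sid)
        if self.reference_strain is not None and self.reference_strain not in seen:
            raise LookupResolutionError(
                f"reference strain {self.reference_strain!r} is not in the panel"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def strain_ids(self) -> list[str]:
        return [s for s, _ in self.strains]

    def species_of(self, strain_id: str) -> str:
        for sid, sp in self.strains:
            if sid == strain_id:
                return sp
        raise KeyError(strain_id)

    @property
    def species_labels(self) -> list[str]:
        """Distinct species labels, first-appearance order."""
        out: list[str] = []
        for _, sp in self.strains:
            if sp not in out:
                out.append(sp)
        return out

    def strains_for_species(self, species: str) -> list[str]:
        return [sid for sid, sp in self.strains if sp == species]

    def locus_seqs(self, locus: str) -> dict[str, str]:
        """Map strain_id → sequence string at *locus* (missing cells skipped),
        in panel strain order."""
        if locus not in self.loci:
            raise KeyError(f"unknown locus {locus!r}")
        out: dict[str, str] = {}
        for sid in self.strain_ids:
            entry = self.sequences.get((sid, locus))
            if entry is not None:
                out[sid] = entry.seq
        return out

    def has_cell(self, strain_id: str, locus: str) -> bool:
        return (strain_id, locus) in self.sequences


def _normalize_seq(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SeqEntry]:
    """Parse a FASTA file into a list of :class:`SeqEntry`, in file order.

    Sequences are uppercased, U is mapped to T, and whitespace stripped.
    Malformed headers, illegal characters, and duplicate ids raise
    :class:`FastaFormatError` / :class:`DuplicateRecordError` naming the line.
    """
    path = Path(path)
    entries: list[SeqEntry] = []
    seen_ids: set[str] = set()
    cur_id: str | None = None
    cur_desc = ""
    cur_chunks: list[str] = []
    header_line = 0

    def _flush() -> None:
        if cur_id is None:
            return
        seq = _normalize_seq("".join(cur_chunks))
        if not seq:
            raise FastaFormatError(
                f"{path}: record {cur_id!r} (header at line {header_line}) has no sequence"
            )
        entries.append(SeqEntry(id=cur_id, seq=seq, description=cur_desc))

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                if not header:
                    raise FastaFormatError(f"{path}: empty FASTA header at line {lineno}")
                parts = header.split(None, 1)
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
                if cur_id in seen_ids:
                    raise DuplicateRecordError(
                        f"{path}: duplicate sequence id {cur_id!r} at line {lineno}"
                    )
                seen_ids.add(cur_id)
                cur_chunks = []
                header_line = lineno
            else:
                if cur_id is None:
                    raise FastaFormatError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                chunk = _normalize_seq("".join(line.split()))
                bad = set(chunk) - ALPHABET
                if bad:
                    raise FastaFormatError(
                        f"{path}: illegal character(s) {sorted(bad)} at line {lineno}"
                    )
                cur_chunks.append(chunk)
        _flush()
    return entries


def write_fasta(entries: list[SeqEntry], path: str | Path, width: int = 70) -> None:
    """Write entries as FASTA (fixed line width) via Biopython."""
    records = [
        SeqRecord(Seq(e.seq), id=e.id, description=e.description) for e in entries
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_strain_table(path: str | Path) -> pd.DataFrame:
    """Read the 5-column strain metadata TSV.

    Columns: strain_id, species, locus, fasta_path, seq_id. Lines starting
    with '#' are comments. Species labels are trimmed; duplicate
    (strain_id, locus) rows are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty metadata table") from exc
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in METADATA_COLUMNS]
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra}")
    df = df[METADATA_COLUMNS].copy()
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise SchemaError(f"{path}: empty field(s) in row(s) {rows}")
    for col in METADATA_COLUMNS:
        df[col] = df[col].str.strip()
    if (df["species"] == "").any():
        raise SchemaError(f"{path}: empty species label")
    dup = df.duplicated(subset=["strain_id", "locus"], keep=False)
    if dup.any():
        pairs = sorted(set(map(tuple, df.loc[dup, ["strain_id", "locus"]].values)))
        raise DuplicateRecordError(f"{path}: duplicate (strain, locus) rows: {pairs}")
    return df.reset_index(drop=True)


def build_panel(
    table: pd.DataFrame,
    entries: dict[str, list[SeqEntry]] | None = None,
    base_dir: str | Path | None = None,
    reference_strain: str | None = None,
) -> StrainPanel:
    """Assemble a :class:`StrainPanel` from a metadata table.

    *entries* may pre-supply parsed FASTA files keyed by their ``fasta_path``
    string; any path not present is read from disk (relative paths resolved
    against *base_dir*). Strain and locus order is first appearance in the
    table. An unresolvable seq_id raises :class:`LookupResolutionError`
    naming the offending row.
    """
    cache: dict[str, dict[str, SeqEntry]] = {}
    if entries:
        for p, ents in entries.items():
            cache[str(p)] = {e.id: e for e in ents}

    strains: list[tuple[str, str]] = []
    loci: list[str] = []
    sequences: dict[tuple[str, str], SeqEntry] = {}

    for row in table.itertuples(index=True):
        key = str(row.fasta_path)
        if key not in cache:
            fp = Path(key)
            if base_dir is not None and not fp.is_absolute():
                fp = Path(base_dir) / fp
            try:
                cache[key] = {e.id: e for e in read_fasta(fp)}
            except FileNotFoundError as exc:
                raise LookupResolutionError(
                    f"row {row.Index}: FASTA file {key!r} not found"
                ) from exc
        lookup = cache[key]
        if row.seq_id not in lookup:
            raise LookupResolutionError(
                f"row {row.Index}: seq_id {row.seq_id!r} not found in {key!r} "
                f"(strain {row.strain_id!r}, locus {row.locus!r})"
            )
        if (row.strain_id, row.species) not in strains:
            known = {s for s, _ in strains}
            if row.strain_id in known:
                raise DuplicateRecordError(
                    f"strain {row.strain_id!r} appears with conflicting species labels"
                )
            strains.append((row.strain_id, row.species))
        if row.locus not in loci:
            loci.append(row.locus)
        sequences[(row.strain_id, row.locus)] = lookup[row.seq_id]

    return StrainPanel(
        strains=strains, loci=loci, sequences=sequences, reference_strain=reference_strain
    )


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize a tree as Newick with branch lengths, ';'-terminated."""
    names = [t.name for t in tree.tips()]
    dups = {n for n in names if names.count(n) > 1}
    if dups:
        raise DuplicateRecordError(f"duplicate leaf label(s): {sorted(dups)}")
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue().strip()
    if not text.endswith(";"):
        text += ";"
    Path(path).write_text(text + "\n", encoding="utf-8")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN- alphabet."""
    try:
        return str(Seq(seq).reverse_complement())
    except Exception as exc:  # pragma: no cover
        raise MarkerscanError(f"cannot reverse-complement {seq!r}") from exc
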