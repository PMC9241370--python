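"""Readers and writers for every on-disk format the pipeline touches.

FASTA and aligned FASTA go through Biopython; the PSI-BLAST ASCII PSSM and
AAindex flat-file dialects have no reader in the installed stack and are
parsed here directly.  Tabular inputs (SAAS tables, annotation tables) are
plain TSV via pandas.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Tuple

import pandas as pd
from Bio import SeqIO

from .records import (
    AMINO_ACIDS,
    AA_SET,
    AaindexEntry,
    Annotation,
    Msa,
    ProteinRecord,
    Pssm,
    SaasError,
    SaasRecord,
)

logger = logging.getLogger(__name__)

_PathLike = str | Path


def _normalise_seq(seq: str) -> str:
    return seq.upper().replace(".", "-")


def read_fasta(path: _PathLike) -> List[ProteinRecord]:
    """Read a protein FASTA file; ids are the first whitespace token.

    Sequences are uppercased; characters outside the 20 residues plus ``X``
    raise an error naming the offending record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalise_seq(str(rec.seq)).replace("-", "")
        records.append(ProteinRecord(protein_id=rec.id, sequence=seq))
    if not records:
        raise SaasError(f"no FASTA records in {path}")
    return records


def write_fasta(path: _PathLike, records: Iterable[ProteinRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n{rec.sequence}\n")


def read_msa(path: _PathLike, query_index: int = 0) -> Msa:
    """Read an aligned FASTA file into an :class:`Msa`.

    The first row is the query unless ``query_index`` says otherwise.
    Ragged rows raise an error.
    """
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(_normalise_seq(str(rec.seq)))
    if not rows:
        raise SaasError(f"no alignment rows in {path}")
    return Msa(ids=ids, rows=rows, query_index=query_index)


def write_msa(path: _PathLike, msa: Msa) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n{row}\n")


def read_pssm_ascii(path: _PathLike) -> Pssm:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file (log-odds block).

    The file prints, after two header lines, one row per query position:
    position, residue, 20 log-odds integers, then (optionally) 20 weighted
    observed percentages and information content, which are ignored.  The
    residue order of the log-odds block is taken from the column header.
    """
    lines = Path(path).read_text().splitlines()
    header_residues: List[str] = []
    scores: Dict[int, Dict[str, float]] = {}
    for line in lines:
        parts = line.split()
        if not header_residues:
            # header: 40 residue letters (two blocks) or 20 (one block)
            if len(parts) >= 20 and all(p in AA_SET for p in parts[:20]):
                header_residues = parts[:20]
            continue
        if len(parts) >= 2 and parts[0].isdigit():
            pos = int(parts[0])
            nums = parts[2:]
            if len(nums) < 20:
                raise SaasError(
                    f"PSSM row for position {pos} has only {len(nums)} "
                    f"score columns (need 20)"
                )
            row = {aa: float(v) for aa, v in zip(header_residues, nums[:20])}
            scores[pos] = row
    if not scores:
        raise SaasError(f"no PSSM rows found in {path}")
    return Pssm(scores=scores)


def write_pssm_ascii(path: _PathLike, pssm: Pssm, sequence: str) -> None:
    """Write a PSSM in the PSI-BLAST ``-out_ascii_pssm`` dialect (log-odds
    block only); useful for fixtures and round-trip checks."""
    order = list(AMINO_ACIDS)
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("            " + "   ".join(order) + "\n")
        for pos in sorted(pssm.scores):
            residue = sequence[pos - 1] if pos <= len(sequence) else "X"
            row = pssm.scores[pos]
            fh.write(f"{pos:5d} {residue}  " +
                     " ".join(f"{row[aa]:5.1f}" for aa in order) + "\n")


def read_aaindex(path: _PathLike) -> List[AaindexEntry]:
    """Parse an AAindex flat file (AAindex1/2/3 dialects).

    Records start with ``H <accession>`` and end with ``//``.  ``I`` blocks
    hold 20 per-residue values (AAindex1); ``M`` blocks hold matrices
    (AAindex2/3).  Entries with ``NA`` values are flagged ``has_missing``;
    asymmetric matrices are dropped with a logged count; lower-triangular
    matrices are completed to full symmetric form.
    """
    text = Path(path).read_text()
    entries: List[AaindexEntry] = []
    n_asymmetric = 0
    for block in text.split("//"):
        block = block.strip("\n")
        if not block.strip():
            continue
        entry = _parse_aaindex_record(block)
        if entry is None:
            n_asymmetric += 1
        else:
            entries.append(entry)
    if n_asymmetric:
        logger.info("read_aaindex: dropped %d asymmetric matrix entries", n_asymmetric)
    if not entries and not n_asymmetric:
        raise SaasError(f"no AAindex records in {path}")
    return entries


def _parse_aaindex_record(block: str) -> AaindexEntry | None:
    """One AAindex record; ``None`` signals an asymmetric matrix (dropped)."""
    lines = block.splitlines()
    accession = None
    i_lines: List[str] = []
    m_lines: List[str] = []
    mode = None
    m_rows_spec = m_cols_spec = None
    for line in lines:
        if line.startswith("H "):
            accession = line[2:].strip()
            mode = None
        elif line.startswith("I "):
            mode = "I"
        elif line.startswith("M "):
            mode = "M"
            # e.g. "M rows = ARNDCQEGHILKMFPSTWYV, cols = ARNDCQEGHILKMFPSTWYV"
            spec = line[2:].replace(",", " ").replace("=", " = ").split()
            for j, tok in enumerate(spec):
                if tok == "rows" and j + 2 < len(spec) and spec[j + 1] == "=":
                    m_rows_spec = spec[j + 2]
                if tok == "cols" and j + 2 < len(spec) and spec[j + 1] == "=":
                    m_cols_spec = spec[j + 2]
        elif line.startswith(" ") or line.startswith("\t"):
            if mode == "I":
                i_lines.append(line)
            elif mode == "M":
                m_lines.append(line)
        else:
            mode = None
    if accession is None:
        raise SaasError("AAindex record without an H (accession) line")

    if i_lines:
        vals: List[float | None] = []
        for line in i_lines:
            for tok in line.split():
                vals.append(None if tok.upper() == "NA" else float(tok))
        # AAindex1 order: A/L R/K N/M D/F C/P Q/S E/T G/W H/Y I/V (col-major pairs)
        order = "ARNDCQEGHILKMFPSTWYV"
        values = {}
        has_missing = False
        for aa, v in zip(order, vals):
            if v is None:
                has_missing = True
            else:
                values[aa] = v
        return AaindexEntry(accession=accession, kind="index1",
                            values=values, has_missing=has_missing)

    if m_lines:
        rows_order = m_rows_spec or "ARNDCQEGHILKMFPSTWYV"
        cols_order = m_cols_spec or rows_order
        grid: List[List[float | None]] = []
        for line in m_lines:
            row = [None if tok.upper() == "NA" else float(tok)
                   for tok in line.split()]
            grid.append(row)
        values: Dict[Tuple[str, str], float] = {}
        has_missing = False
        lower_triangular = all(len(r) == i + 1 for i, r in enumerate(grid))
        for i, row in enumerate(grid):
            for j, v in enumerate(row):
                a, b = rows_order[i], cols_order[j]
                if v is None:
                    has_missing = True
                    continue
                key = tuple(sorted((a, b)))
                if key in values and abs(values[key] - v) > 1e-9:
                    return None  # asymmetric: conflicting (a,b) vs (b,a)
                values[key] = v
        if not lower_triangular and m_rows_spec == m_cols_spec:
            # full square matrix: every symmetric pair must have matched above
            pass
        kind = "matrix2"
        return AaindexEntry(accession=accession, kind=kind,
                            values=values, has_missing=has_missing)

    raise SaasError(f"AAindex record {accession!r} has no I or M block")


def read_saas_table(path: _PathLike) -> List[SaasRecord]:
    """Read a TSV SAAS table: protein_id, wt, position, mut[, label]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["protein_id", "wt", "position", "mut"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SaasError(f"SAAS table {path} missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        label = getattr(row, "label", None)
        if isinstance(label, float) or label in ("", None) or pd.isna(label):
            label = None
        source = getattr(row, "source", None)
        if isinstance(source, float) or source in ("", None) or pd.isna(source):
            source = None
        records.append(SaasRecord(
            protein_id=row.protein_id, wt=row.wt.upper(),
            position=int(row.position), mut=row.mut.upper(),
            label=label, source=source,
        ))
    return records


def write_saas_table(path: _PathLike, records: Iterable[SaasRecord]) -> None:
    rows = [
        {"protein_id": r.protein_id, "wt": r.wt, "position": r.position,
         "mut": r.mut, "label": r.label or "", "source": r.source or ""}
        for r in records
    ]
    pd.DataFrame(rows, columns=["protein_id", "wt", "position", "mut",
                                "label", "source"]).to_csv(
        path, sep="\t", index=False)


def read_annotation_table(path: _PathLike) -> Dict[str, List[Annotation]]:
    """Read a TSV annotation table: protein_id, type, start, end."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["protein_id", "type", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SaasError(f"annotation table {path} missing columns {missing}")
    out: Dict[str, List[Annotation]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.protein_id, []).append(
            Annotation(type=row.type, start=int(row.start), end=int(row.end))
        )
    return out


def write_annotation_table(path: _PathLike,
                           annotations: Dict[str, List[Annotation]]) -> None:
    rows = [
        {"protein_id": pid, "type": a.type, "start": a.start, "end": a.end}
        for pid, anns in annotations.items() for a in anns
    ]
    pd.DataFrame(rows, columns=["protein_id", "type", "start", "end"]).to_csv(
        path, sep="\t", index=False)
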