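"""Core domain types for single amino acid substitution (SAAS) analysis.

Positions are 1-based everywhere in user-facing records, matching the
``G87D`` notation used throughout the plant-variant literature.  The protein
alphabet is the 20 standard residues; ``X`` is tolerated in sequences but
excluded from every frequency count, and ``-`` is the only gap character
(``.`` is normalised to ``-`` on read).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
GAP = "-"

#: annotation keys transferred from annotated reference proteins, grouped by
#: the five categories used for the merged distance features
ANNOTATION_CATEGORIES: Dict[str, Tuple[str, ...]] = {
    "Function": ("BINDING", "ACT_SITE", "SITE", "METAL", "DNA_BIND",
                 "NP_BIND", "CA_BIND", "EC"),
    "PTM": ("LIPID", "DISULFID", "MOD_RES", "CARBOHYD", "PROPEP",
            "SIGNAL", "TRANSIT"),
    "Subloc": ("TOPO_DOM", "TRANSMEM", "INTRAMEM"),
    "Family": ("MOTIF", "DOMAIN", "REGION", "ZN_FING"),
    "Structure": ("HELIX", "STRAND", "TURN"),
}

ANNOTATION_TYPES: Tuple[str, ...] = tuple(
    k for keys in ANNOTATION_CATEGORIES.values() for k in keys
)

FUNCTIONAL = "functional"
NEUTRAL = "neutral"


class SaasError(ValueError):
    """Raised for malformed substitutions, sequences or alignments."""


@dataclass(frozen=True)
class Annotation:
    """One annotated feature span on a protein (1-based, inclusive)."""

    type: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.type not in ANNOTATION_TYPES:
            raise SaasError(f"unknown annotation type {self.type!r}")
        if not (1 <= self.start <= self.end):
            raise SaasError(
                f"bad annotation span {self.start}..{self.end} for {self.type}"
            )


@dataclass
class ProteinRecord:
    protein_id: str
    sequence: str
    annotations: List[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SaasError(f"empty sequence for {self.protein_id!r}")
        bad = set(self.sequence) - AA_SET - {"X"}
        if bad:
            raise SaasError(
                f"record {self.protein_id!r} contains non-amino-acid "
                f"characters {sorted(bad)}"
            )
        for a in self.annotations:
            if a.end > len(self.sequence):
                raise SaasError(
                    f"annotation {a.type} {a.start}..{a.end} outside "
                    f"{self.protein_id!r} (length {len(self.sequence)})"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SaasRecord:
    """A single amino acid substitution event, e.g. G87D on protein P.

    ``label`` is ``"functional"`` / ``"neutral"`` when known; ``source``
    records whether the label is experimentally curated or produced by the
    pseudoneutral simulator.
    """

    protein_id: str
    wt: str
    position: int
    mut: str
    label: Optional[str] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if self.wt not in AA_SET or self.mut not in AA_SET:
            raise SaasError(f"non-standard residue in {self.wt}>{self.mut}")
        if self.wt == self.mut:
            raise SaasError(
                f"wildtype equals mutant ({self.wt}{self.position}{self.mut})"
            )
        if self.position < 1:
            raise SaasError(f"position must be 1-based positive, got {self.position}")
        if self.label is not None and self.label not in (FUNCTIONAL, NEUTRAL):
            raise SaasError(f"unknown label {self.label!r}")

    @property
    def substitution(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"

    def check_against(self, protein: ProteinRecord) -> None:
        """Validate that wt matches the protein sequence at ``position``."""
        if self.position > len(protein):
            raise SaasError(
                f"position {self.position} beyond {protein.protein_id!r} "
                f"(length {len(protein)})"
            )
        seen = protein.sequence[self.position - 1]
        if seen != self.wt:
            raise SaasError(
                f"{protein.protein_id}: substitution states wildtype "
                f"{self.wt} at position {self.position} but the sequence "
                f"has {seen}"
            )


_SUB_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def parse_substitution(text: str) -> Tuple[str, int, str]:
    """Parse ``"G87D"`` into ``('G', 87, 'D')``.

    Raises :class:`SaasError` on malformed input, position 0, non-standard
    residues, or a wildtype equal to the mutant.
    """
    m = _SUB_RE.match(text.strip())
    if not m:
        raise SaasError(f"malformed substitution {text!r} (expected e.g. G87D)")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if wt not in AA_SET or mut not in AA_SET:
        raise SaasError(f"non-standard residue in substitution {text!r}")
    if pos == 0:
        raise SaasError("substitution position must be 1-based (got 0)")
    if wt == mut:
        raise SaasError(f"wildtype equals mutant in {text!r}")
    return wt, pos, mut


def format_substitution(wt: str, position: int, mut: str) -> str:
    return f"{wt}{position}{mut}"


@dataclass
class Msa:
    """A multiple sequence alignment with a designated query row.

    Rows are equal-length gapped strings over the residue alphabet plus
    ``-``.  Column indices are 1-based in the public accessors, mirroring
    substitution positions.
    """

    ids: List[str]
    rows: List[str]
    query_index: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise SaasError("empty alignment")
        width = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise SaasError(
                    f"ragged alignment: row {rid!r} has length {len(row)}, "
                    f"expected {width}"
                )
        if not (0 <= self.query_index < len(self.rows)):
            raise SaasError(f"query_index {self.query_index} out of range")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def query_row(self) -> str:
        return self.rows[self.query_index]

    @property
    def query_sequence(self) -> str:
        return self.query_row.replace(GAP, "")

    def column(self, col: int) -> str:
        """All residues (incl. gaps) in 1-based alignment column ``col``."""
        return "".join(row[col - 1] for row in self.rows)

    def column_counts(self, col: int) -> Dict[str, int]:
        """Residue counts at a column; gaps and X excluded."""
        counts: Dict[str, int] = {}
        for row in self.rows:
            c = row[col - 1]
            if c in AA_SET:
                counts[c] = counts.get(c, 0) + 1
        return counts

    def query_position_of_column(self, col: int) -> Optional[int]:
        """De-gapped 1-based query position at alignment column ``col``.

        ``None`` if the query has a gap there.
        """
        q = self.query_row
        if q[col - 1] == GAP:
            return None
        return len(q[:col].replace(GAP, ""))

    def column_of_query_position(self, pos: int) -> int:
        """Alignment column (1-based) holding query position ``pos``."""
        seen = 0
        for i, c in enumerate(self.query_row, start=1):
            if c != GAP:
                seen += 1
                if seen == pos:
                    return i
        raise SaasError(
            f"query position {pos} beyond de-gapped query length {seen}"
        )


@dataclass
class Pssm:
    """Position-specific scoring matrix: per-position residue log-odds.

    ``scores[i]`` maps each of the 20 residues to a real score for 1-based
    position ``i``.
    """

    scores: Dict[int, Dict[str, float]]

    def __post_init__(self) -> None:
        for pos, row in self.scores.items():
            if set(row) != AA_SET:
                raise SaasError(
                    f"PSSM position {pos} does not score exactly the 20 "
                    f"standard residues"
                )

    @property
    def length(self) -> int:
        return len(self.scores)

    def score(self, position: int, residue: str) -> float:
        if position not in self.scores:
            raise SaasError(f"position {position} outside PSSM (length {self.length})")
        return self.scores[position][residue]


@dataclass
class AaindexEntry:
    """One AAindex record: a per-residue index or a residue-pair matrix."""

    accession: str
    kind: str  # "index1" | "matrix2" | "matrix3"
    values: Dict  # residue -> float, or (a, b) frozenset-keyed pair -> float
    has_missing: bool = False

    def index_value(self, residue: str) -> Optional[float]:
        return self.values.get(residue)

    def pair_value(self, a: str, b: str) -> Optional[float]:
        """Symmetric lookup: M[a][b] == M[b][a] by construction."""
        return self.values.get(tuple(sorted((a, b))))
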