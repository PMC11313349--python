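"""Readers and writers for the external formats the pipeline touches.

Covers FASTA, the AAindex flat-file dialects (kinds 1-3), PSI-BLAST
ASCII position-specific scoring matrices, SIFT4G-style per-variant
tables and the package's tab-separated mutation-table dialect.

All readers are deterministic and order-preserving.  Each format also
has a writer; the writers exist so test fixtures can be generated
programmatically and every reader can be checked by round-trip.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    PSIBLAST_ORDER,
    Condition,
    MutationRecord,
    ProteinRecord,
    SequenceAlphabetError,
    ThermoshiftError,
    parse_mutation,
)

logger = logging.getLogger(__name__)

_ORDER_INDEX = {res: i for i, res in enumerate(PSIBLAST_ORDER)}


class FormatError(ThermoshiftError):
    """Raised for files violating their declared dialect."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Record ids are the first whitespace-delimited header token;
    sequences are uppercased with line breaks joined.  Records whose
    sequences contain non-canonical letters are skipped with a logged
    warning (they cannot feed the property lookups downstream).
    Duplicate ids and empty files are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        try:
            records.append(ProteinRecord(rec.id, str(rec.seq)))
        except SequenceAlphabetError as exc:
            logger.warning("skipping FASTA record: %s", exc)
    if not seen:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, proteins: Iterable[ProteinRecord]) -> None:
    recs = [SeqRecord(Seq(p.sequence), id=p.id, description="") for p in proteins]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# AAindex flat files

#: Row/column layout of the kind-1 ``I`` line in AAindex releases:
#: first numeric row A R N D C Q E G H I, second row L K M F P S T W Y V.
_AAINDEX1_ROW1 = "ARNDCQEGHI"
_AAINDEX1_ROW2 = "LKMFPSTWYV"


@dataclass
class AAindexEntry:
    """One AAindex entry: a 20-value residue index (kind 1) or a
    20x20 residue-pair matrix (kinds 2 and 3, symmetrized on load).

    Matrix cells that the source leaves empty (``NA`` or ``-``) are
    stored as NaN; such entries are only rejected if a NaN cell is
    actually queried at feature-extraction time.
    """

    accession: str
    kind: int
    description: str = ""
    index: dict[str, float] | None = None
    matrix: np.ndarray | None = None  # 20x20 in PSIBLAST_ORDER

    def pair_value(self, wild: str, mutant: str) -> float:
        if self.matrix is None:
            raise ValueError(f"{self.accession}: not a matrix entry")
        return float(self.matrix[_ORDER_INDEX[wild], _ORDER_INDEX[mutant]])


def _parse_float(tok: str) -> float:
    if tok in ("NA", "-", "NA.", "na"):
        return math.nan
    return float(tok)


def read_aaindex(path: str | Path, kind: int) -> list[AAindexEntry]:
    """Parse an AAindex flat file of the given kind (1, 2 or 3).

    Kind-1 entries containing any missing value are dropped (the
    standard elimination rule for building difference features); the
    number dropped is logged.  Kind-2/3 matrices keep NaN cells and
    lower-triangular matrices are symmetrized.
    """
    if kind not in (1, 2, 3):
        raise ValueError(f"unknown AAindex kind {kind}")
    path = Path(path)
    entries: list[AAindexEntry] = []
    dropped = 0
    block: list[str] = []
    for raw in path.read_text().splitlines():
        if raw.strip() == "//":
            entry = _parse_aaindex_block(block, kind, path)
            block = []
            if entry is None:
                dropped += 1
            else:
                entries.append(entry)
        elif raw.strip() or block:
            block.append(raw)
    if block and any(line.strip() for line in block):
        raise FormatError(f"{path}: trailing unterminated AAindex block")
    if dropped:
        logger.info(
            "%s: dropped %d kind-%d entries with missing values; retained %d",
            path, dropped, kind, len(entries),
        )
    return entries


def _parse_aaindex_block(
    lines: list[str], kind: int, path: Path
) -> AAindexEntry | None:
    accession = ""
    description = ""
    data: list[str] = []
    in_data = False
    header = ""
    for line in lines:
        tag, _, rest = line.partition(" ")
        if line[:1] not in (" ", "\t"):
            in_data = False
        if tag == "H":
            accession = rest.strip()
        elif tag == "D":
            description = rest.strip()
        elif tag == "I" and kind == 1:
            in_data = True
        elif tag == "M" and kind in (2, 3):
            in_data = True
            header = rest.strip()
        elif in_data and line[:1] in (" ", "\t"):
            data.append(line)
    if not accession:
        raise FormatError(f"{path}: AAindex block without H line")
    if kind == 1:
        return _finish_kind1(accession, description, data, path)
    return _finish_matrix(accession, kind, description, header, data, path)


def _finish_kind1(
    accession: str, description: str, data: list[str], path: Path
) -> AAindexEntry | None:
    values = [_parse_float(tok) for line in data for tok in line.split()]
    if len(values) != 20:
        raise FormatError(
            f"{path}:{accession}: expected 20 index values, got {len(values)}"
        )
    order = _AAINDEX1_ROW1 + _AAINDEX1_ROW2
    index = dict(zip(order, values))
    if any(math.isnan(v) for v in index.values()):
        return None  # elimination rule: entries with missing values drop
    return AAindexEntry(accession, 1, description, index=index)


def _finish_matrix(
    accession: str,
    kind: int,
    description: str,
    header: str,
    data: list[str],
    path: Path,
) -> AAindexEntry:
    rows_order = cols_order = PSIBLAST_ORDER
    # header like "rows = ARNDCQEGHILKMFPSTWYV, cols = ARNDCQEGHILKMFPSTWYV"
    for part in header.split(","):
        key, _, val = part.partition("=")
        val = val.strip().replace(" ", "")
        if "rows" in key:
            rows_order = val
        elif "cols" in key:
            cols_order = val
    if sorted(rows_order) != sorted(PSIBLAST_ORDER) or sorted(cols_order) != sorted(
        PSIBLAST_ORDER
    ):
        raise FormatError(f"{path}:{accession}: matrix orders must cover 20 residues")
    parsed = [[_parse_float(tok) for tok in line.split()] for line in data]
    if len(parsed) != 20:
        raise FormatError(
            f"{path}:{accession}: expected 20 matrix rows, got {len(parsed)}"
        )
    mat = np.full((20, 20), np.nan)
    triangular = all(len(row) == i + 1 for i, row in enumerate(parsed))
    for i, row in enumerate(parsed):
        if not triangular and len(row) != 20:
            raise FormatError(
                f"{path}:{accession}: row {i + 1} has {len(row)} values"
            )
        for j, v in enumerate(row):
            ri = _ORDER_INDEX[rows_order[i]]
            cj = _ORDER_INDEX[cols_order[j]]
            mat[ri, cj] = v
            if triangular:
                mat[cj, ri] = v
    if not triangular:
        # symmetrize any one-sided gaps
        hole = np.isnan(mat) & ~np.isnan(mat.T)
        mat[hole] = mat.T[hole]
    return AAindexEntry(accession, kind, description, matrix=mat)


def write_aaindex(path: str | Path, entries: Iterable[AAindexEntry]) -> None:
    """Fixture writer emitting the AAindex flat-file dialect."""
    lines: list[str] = []
    for e in entries:
        lines.append(f"H {e.accession}")
        if e.description:
            lines.append(f"D {e.description}")
        if e.kind == 1:
            assert e.index is not None
            lines.append(
                "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T"
                "     G/W     H/Y     I/V"
            )
            for row_order in (_AAINDEX1_ROW1, _AAINDEX1_ROW2):
                vals = []
                for res in row_order:
                    v = e.index[res]
                    vals.append("NA" if math.isnan(v) else f"{v:g}")
                lines.append("  " + "  ".join(f"{v:>7s}" for v in vals))
        else:
            assert e.matrix is not None
            lines.append(
                f"M rows = {PSIBLAST_ORDER}, cols = {PSIBLAST_ORDER}"
            )
            for i in range(20):
                vals = []
                for j in range(20):
                    v = e.matrix[i, j]
                    vals.append("-" if math.isnan(v) else f"{v:g}")
                lines.append("  " + " ".join(f"{v:>6s}" for v in vals))
        lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PSSM


@dataclass
class PSSM:
    """Per-position log-odds over the 20 residues.

    ``scores`` has one row per sequence position and 20 columns in
    :data:`~thermoshift.core.PSIBLAST_ORDER`.  ``provenance`` records
    whether the matrix came from a PSI-BLAST run or the
    substitution-matrix fallback.
    """

    protein_id: str
    residues: str
    scores: np.ndarray
    provenance: str = "psiblast_ascii"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.residues), 20):
            raise ValueError(
                f"{self.protein_id}: PSSM shape {self.scores.shape} does not "
                f"match sequence length {len(self.residues)}"
            )


def read_ascii_pssm(path: str | Path, protein: ProteinRecord) -> PSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file for *protein*.

    Only the first 20 (log-odds) score columns are used; the column
    header is read so any residue ordering is mapped onto the canonical
    one.  Row count and per-row residue letters must match the protein.
    """
    path = Path(path)
    header_order: str | None = None
    rows: list[tuple[int, str, list[float]]] = []
    for line in path.read_text().splitlines():
        toks = line.split()
        if header_order is None:
            if len(toks) >= 20 and all(len(t) == 1 and t.isalpha() for t in toks[:20]):
                letters = "".join(toks[:20])
                if sorted(letters) == sorted(PSIBLAST_ORDER):
                    header_order = letters
            continue
        if len(toks) >= 22 and toks[0].isdigit() and len(toks[1]) == 1:
            pos = int(toks[0])
            res = toks[1].upper()
            scores = [float(t) for t in toks[2:22]]
            rows.append((pos, res, scores))
    if header_order is None:
        raise FormatError(f"{path}: no PSSM column header found")
    if len(rows) != len(protein):
        raise FormatError(
            f"{path}: {len(rows)} PSSM rows but sequence {protein.id} has "
            f"{len(protein)} residues"
        )
    mat = np.zeros((len(rows), 20))
    residues = []
    for i, (pos, res, scores) in enumerate(rows):
        if pos != i + 1:
            raise FormatError(f"{path}: non-contiguous position {pos} at row {i + 1}")
        if res != protein.sequence[i]:
            raise FormatError(
                f"{path}: residue {res} at position {pos} does not match "
                f"{protein.id} ({protein.sequence[i]})"
            )
        residues.append(res)
        for letter, val in zip(header_order, scores):
            mat[i, _ORDER_INDEX[letter]] = val
    return PSSM(protein.id, "".join(residues), mat, provenance="psiblast_ascii")


def write_ascii_pssm(path: str | Path, pssm: PSSM) -> None:
    """Fixture writer emitting the PSI-BLAST ASCII PSSM dialect."""
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted, observed",
        "            " + "  ".join(PSIBLAST_ORDER),
    ]
    for i, res in enumerate(pssm.residues):
        vals = " ".join(f"{v:3.0f}" for v in pssm.scores[i])
        # pad two dummy trailing columns so the row shape matches real output
        lines.append(f"{i + 1:5d} {res}  {vals}  0.00 0.00")
    Path(path).write_text("\n".join(lines) + "\n")


def fallback_pssm(protein: ProteinRecord, matrix: str = "BLOSUM62") -> PSSM:
    """Build a PSSM substitute from a named substitution matrix.

    Row *i* is the substitution-matrix row of ``sequence[i]``; the
    result is flagged ``fallback:<name>`` in provenance so feature
    tables can record that no homology search backed it.
    """
    try:
        sub = substitution_matrices.load(matrix)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {matrix!r}") from exc
    mat = np.zeros((len(protein), 20))
    for i, res in enumerate(protein.sequence):
        for j, col in enumerate(PSIBLAST_ORDER):
            mat[i, j] = sub[res, col]
    return PSSM(protein.id, protein.sequence, mat, provenance=f"fallback:{matrix}")


# ---------------------------------------------------------------------------
# SIFT4G-style variant tables


@dataclass(frozen=True)
class SiftRecord:
    """Deleteriousness annotations for one substitution."""

    sift_score: float
    sift_median: float
    num_seq: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.sift_score <= 1.0):
            raise ValueError(f"sift_score {self.sift_score} outside [0, 1]")
        if self.num_seq < 0:
            raise ValueError("num_seq must be nonnegative")


def read_sift_output(path: str | Path) -> dict[tuple[str, str], SiftRecord]:
    """Read a tab-delimited per-variant SIFT table.

    Expected columns: ``protein_id``, ``mutation``, ``sift_score``,
    ``sift_median``, ``num_seq``.  Malformed rows are skipped with a
    warning; duplicate variants keep the last row seen (warned).
    """
    path = Path(path)
    out: dict[tuple[str, str], SiftRecord] = {}
    skipped = 0
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            try:
                key = (row["protein_id"], str(parse_mutation(row["mutation"])))
                rec = SiftRecord(
                    float(row["sift_score"]),
                    float(row["sift_median"]),
                    int(row["num_seq"]),
                )
            except (KeyError, TypeError, ValueError, ThermoshiftError):
                skipped += 1
                continue
            if key in out:
                logger.warning("%s: duplicate SIFT row for %s (last wins)", path, key)
            out[key] = rec
    if skipped:
        logger.warning("%s: skipped %d malformed SIFT rows", path, skipped)
    return out


def write_sift_output(
    path: str | Path, records: Mapping[tuple[str, str], SiftRecord]
) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["protein_id", "mutation", "sift_score", "sift_median", "num_seq"])
        for (pid, mut), rec in records.items():
            w.writerow([pid, mut, rec.sift_score, rec.sift_median, rec.num_seq])


# ---------------------------------------------------------------------------
# Amino-acid scale tables


@dataclass
class ScaleSet:
    """Named amino-acid scales; every scale defines all 20 residues."""

    scales: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for name, table in self.scales.items():
            missing = sorted(set(PSIBLAST_ORDER) - set(table))
            if missing:
                raise FormatError(
                    f"scale {name!r} missing residues {''.join(missing)}"
                )

    def __len__(self) -> int:
        return len(self.scales)

    def names(self) -> list[str]:
        return list(self.scales)


def read_scales(path: str | Path) -> ScaleSet:
    """Read a scale table: TSV with a ``scale`` column and one column
    per residue letter."""
    path = Path(path)
    scales: dict[str, dict[str, float]] = {}
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            name = row.pop("scale")
            scales[name] = {res: float(val) for res, val in row.items()}
    if not scales:
        raise FormatError(f"{path}: no scales found")
    return ScaleSet(scales)


def write_scales(path: str | Path, scales: ScaleSet) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["scale", *PSIBLAST_ORDER])
        for name, table in scales.scales.items():
            w.writerow([name, *(f"{table[res]:g}" for res in PSIBLAST_ORDER)])


def default_scales() -> ScaleSet:
    """The bundled 57-scale default set.

    Fourteen published scales transcribed from the literature
    (hydropathy, hydrophobicity, polarity, bulkiness, secondary-
    structure propensities, ...) plus deterministic synthetic stand-in
    scales (``synthetic_*``) filling out the default slot count; real
    deployments should point :func:`read_scales` at a full published
    scale export instead.
    """
    from importlib import resources

    pkg = resources.files("thermoshift.data")
    merged: dict[str, dict[str, float]] = {}
    for fname in ("scales_published.tsv", "scales_synthetic.tsv"):
        merged.update(read_scales(pkg / fname).scales)
    return ScaleSet(merged)


def bundled_aaindex(kind: int) -> list[AAindexEntry]:
    """The bundled AAindex fixture subset for the given kind.

    Kind 1 holds published entries (plus one synthetic entry with a
    missing value, dropped on load by the elimination rule); kinds 2
    and 3 are small synthetic matrices exercising the matrix dialect.
    """
    from importlib import resources

    names = {
        1: "aaindex1_fixture.txt",
        2: "aaindex2_synthetic.txt",
        3: "aaindex3_synthetic.txt",
    }
    pkg = resources.files("thermoshift.data")
    return read_aaindex(pkg / names[kind], kind)


# ---------------------------------------------------------------------------
# Mutation tables (TSV dialect)

MUTATION_TSV_COLUMNS = ("protein_id", "mutation", "ph", "tm", "dtm", "source")


def read_mutation_rows(path: str | Path) -> list[dict[str, str]]:
    """Read the raw rows of a mutation TSV (no parsing or validation).

    Used by the curation layer, which must count and report rows that
    fail to parse rather than raise on the first one.
    """
    with Path(path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "protein_id" not in reader.fieldnames:
            raise FormatError(f"{path}: missing mutation TSV header")
        return [dict(row) for row in reader]


def row_to_record(row: Mapping[str, str | None]) -> MutationRecord:
    """Build a :class:`MutationRecord` from one TSV row (strict)."""

    def _opt(key: str) -> float | None:
        val = row.get(key)
        if val is None or str(val).strip() == "":
            return None
        return float(val)

    return MutationRecord(
        protein_id=str(row["protein_id"]),
        mutation=parse_mutation(str(row["mutation"])),
        condition=Condition(ph=_opt("ph"), tm_wild=_opt("tm")),
        delta_tm=_opt("dtm"),
        source=str(row.get("source") or ""),
    )


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Strictly read a mutation TSV; any malformed row raises."""
    return [row_to_record(row) for row in read_mutation_rows(path)]


def write_mutation_table(path: str | Path, records: Iterable[MutationRecord]) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(MUTATION_TSV_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.protein_id,
                    str(r.mutation),
                    "" if r.condition.ph is None else f"{r.condition.ph:g}",
                    "" if r.condition.tm_wild is None else f"{r.condition.tm_wild:g}",
                    "" if r.delta_tm is None else f"{r.delta_tm:g}",
                    r.source,
                ]
            )
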