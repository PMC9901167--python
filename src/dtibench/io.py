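"""Readers, writers and the canonical in-memory data model.

Bioactivity tables are delimited text files with a header naming a compound
id column, a protein id column and an activity column (pChEMBL / pKd units,
i.e. -log10 of a molar measurement).  Duplicate (compound, protein)
measurements are aggregated by their median activity on load, so a
:class:`BioactivityTable` holds at most one record per pair.
"""

from __future__ import annotations

import csv
import json
import statistics
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

from dtibench.errors import (
    ConsistencyError,
    DtibenchError,
    FormatError,
    InputError,
    ParseError,
)

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

COMPOUND_ID_COLUMNS = ("compound_id", "compound", "ligand_id", "molecule_chembl_id")
PROTEIN_ID_COLUMNS = ("protein_id", "protein", "target_id", "target_chembl_id")
ACTIVITY_COLUMNS = ("pchembl_value", "pkd", "activity")
SMILES_COLUMNS = ("smiles", "canonical_smiles")


@dataclass(frozen=True)
class BioactivityRecord:
    """One measured (compound, protein) pair with its activity in pChEMBL units."""

    record_id: int
    compound_id: str
    protein_id: str
    activity: float

    def __post_init__(self):
        if not self.compound_id or not self.protein_id:
            raise InputError("compound_id and protein_id must be nonempty")
        if not np.isfinite(self.activity):
            raise InputError(
                f"activity must be finite for ({self.compound_id}, {self.protein_id})"
            )


class BioactivityTable:
    """Ordered collection of unique (compound, protein, activity) records.

    Record ids are contiguous integers starting at 0.  Secondary indices map
    compound and protein ids to the record ids they participate in.
    """

    def __init__(self, records: Sequence[BioactivityRecord]):
        self.records: List[BioactivityRecord] = list(records)
        for i, rec in enumerate(self.records):
            if rec.record_id != i:
                raise ConsistencyError(
                    f"record_id {rec.record_id} at position {i}: ids must be contiguous"
                )
        self.compound_index: Dict[str, List[int]] = {}
        self.protein_index: Dict[str, List[int]] = {}
        seen_pairs = set()
        for rec in self.records:
            pair = (rec.compound_id, rec.protein_id)
            if pair in seen_pairs:
                raise ConsistencyError(f"duplicate (compound, protein) pair {pair}")
            seen_pairs.add(pair)
            self.compound_index.setdefault(rec.compound_id, []).append(rec.record_id)
            self.protein_index.setdefault(rec.protein_id, []).append(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, record_id: int) -> BioactivityRecord:
        return self.records[record_id]

    @property
    def compound_ids(self) -> List[str]:
        return list(self.compound_index)

    @property
    def protein_ids(self) -> List[str]:
        return list(self.protein_index)

    def activities(self) -> np.ndarray:
        return np.array([r.activity for r in self.records], dtype=float)

    def subset(self, record_ids: Iterable[int]) -> "BioactivityTable":
        """New table containing the given records, re-indexed contiguously."""
        ids = sorted(set(record_ids))
        return BioactivityTable(
            [
                BioactivityRecord(i, self.records[rid].compound_id,
                                  self.records[rid].protein_id,
                                  self.records[rid].activity)
                for i, rid in enumerate(ids)
            ]
        )

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple]
    ) -> "BioactivityTable":
        """Build a table from (compound_id, protein_id, activity) triples,
        aggregating duplicate pairs by median activity.  First-appearance
        order of pairs is preserved."""
        order: List[tuple] = []
        grouped: Dict[tuple, List[float]] = {}
        for cid, pid, act in pairs:
            key = (cid, pid)
            if key not in grouped:
                grouped[key] = []
                order.append(key)
            grouped[key].append(float(act))
        records = [
            BioactivityRecord(i, cid, pid, statistics.median(grouped[(cid, pid)]))
            for i, (cid, pid) in enumerate(order)
        ]
        return cls(records)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20-letter amino-acid alphabet."""

    protein_id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise InputError(f"empty sequence for protein {self.protein_id}")


@dataclass
class CompoundRecord:
    """A compound known by SMILES, a precomputed fingerprint, or both."""

    compound_id: str
    smiles: Optional[str] = None
    fingerprint: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.smiles is None and self.fingerprint is None:
            raise InputError(
                f"compound {self.compound_id} needs a SMILES or a fingerprint"
            )
        if self.fingerprint is not None:
            self.fingerprint = np.asarray(self.fingerprint, dtype=np.uint8)


@dataclass
class ClusterMap:
    """protein_id -> cluster_id membership (UniRef50-style); proteins in the
    same cluster are treated as similar."""

    assignments: Dict[str, str] = field(default_factory=dict)

    def cluster_of(self, protein_id: str) -> Optional[str]:
        return self.assignments.get(protein_id)

    def clusters(self) -> Dict[str, List[str]]:
        """cluster_id -> member protein ids, members in insertion order."""
        out: Dict[str, List[str]] = {}
        for pid, cid in self.assignments.items():
            out.setdefault(cid, []).append(pid)
        return out

    def __len__(self) -> int:
        return len(self.assignments)


class FeatureTable:
    """id -> fixed-length numeric vector map for proteins or compounds."""

    def __init__(self, vectors: Mapping[str, np.ndarray], kind: str):
        if kind not in ("protein", "compound"):
            raise InputError(f"kind must be 'protein' or 'compound', got {kind!r}")
        self.kind = kind
        self.vectors: Dict[str, np.ndarray] = {}
        self.dimension: Optional[int] = None
        for key, vec in vectors.items():
            arr = np.asarray(vec, dtype=float)
            if arr.ndim != 1:
                raise InputError(f"vector for {key} is not 1-D")
            if self.dimension is None:
                self.dimension = arr.shape[0]
            elif arr.shape[0] != self.dimension:
                raise InputError(
                    f"vector for {key} has length {arr.shape[0]}, expected {self.dimension}"
                )
            if not np.all(np.isfinite(arr)):
                raise InputError(f"non-finite value in vector for {key}")
            self.vectors[key] = arr

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, key: str) -> bool:
        return key in self.vectors

    def __getitem__(self, key: str) -> np.ndarray:
        return self.vectors[key]

    @property
    def ids(self) -> List[str]:
        return list(self.vectors)

    def matrix(self, ids: Optional[Sequence[str]] = None) -> np.ndarray:
        """Stack vectors into a (n_ids, dimension) array."""
        if ids is None:
            ids = self.ids
        return np.stack([self.vectors[i] for i in ids])


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def _sniff_delimiter(first_line: str, dialect: Optional[str]) -> str:
    if dialect is not None:
        return dialect
    return "\t" if "\t" in first_line else ","


def _find_column(header: Sequence[str], candidates: Sequence[str]) -> Optional[int]:
    lowered = [h.strip().lower() for h in header]
    for cand in candidates:
        if cand in lowered:
            return lowered.index(cand)
    return None


def read_bioactivity_table(path, dialect: Optional[str] = None) -> BioactivityTable:
    """Load a delimited bioactivity file into a :class:`BioactivityTable`.

    The header must contain a compound id, protein id and activity column
    (activity accepted as ``pchembl_value``, ``pkd`` or ``activity``).
    Duplicate (compound, protein) pairs are aggregated by median activity.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0], dialect)
    rows = list(csv.reader(lines, delimiter=delim))
    header = rows[0]
    ci = _find_column(header, COMPOUND_ID_COLUMNS)
    pi = _find_column(header, PROTEIN_ID_COLUMNS)
    ai = _find_column(header, ACTIVITY_COLUMNS)
    if ci is None or pi is None or ai is None:
        missing = [
            name
            for name, idx in (("compound id", ci), ("protein id", pi), ("activity", ai))
            if idx is None
        ]
        raise FormatError(f"{path}: header lacks column(s): {', '.join(missing)}")
    triples = []
    for row_no, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(f"{path}: row {row_no} has {len(row)} fields, expected {len(header)}")
        try:
            act = float(row[ai])
        except ValueError as exc:
            raise ParseError(
                f"{path}: row {row_no}: non-numeric activity {row[ai]!r}"
            ) from exc
        triples.append((row[ci].strip(), row[pi].strip(), act))
    return BioactivityTable.from_pairs(triples)


def read_smiles_column(path, dialect: Optional[str] = None) -> Dict[str, str]:
    """Extract compound_id -> SMILES from a bioactivity file that carries a
    SMILES column; returns an empty dict when the column is absent."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        return {}
    delim = _sniff_delimiter(lines[0], dialect)
    rows = list(csv.reader(lines, delimiter=delim))
    ci = _find_column(rows[0], COMPOUND_ID_COLUMNS)
    si = _find_column(rows[0], SMILES_COLUMNS)
    if ci is None or si is None:
        return {}
    return {row[ci].strip(): row[si].strip() for row in rows[1:] if row[si].strip()}


def sanitize_sequence(protein_id: str, raw: str, max_noncanonical: float = 0.10) -> str:
    """Uppercase a sequence and strip non-canonical residues.

    Sequences whose non-canonical fraction exceeds ``max_noncanonical`` are
    rejected; otherwise the offending residues are removed with a warning.
    """
    seq = raw.upper().replace("*", "")
    if not seq:
        raise FormatError(f"protein {protein_id}: empty sequence")
    bad = sum(1 for c in seq if c not in CANONICAL_RESIDUES)
    if bad / len(seq) > max_noncanonical:
        raise FormatError(
            f"protein {protein_id}: {bad}/{len(seq)} non-canonical residues (> {max_noncanonical:.0%})"
        )
    if bad:
        warnings.warn(
            f"protein {protein_id}: dropped {bad} non-canonical residue(s)",
            stacklevel=2,
        )
        seq = "".join(c for c in seq if c in CANONICAL_RESIDUES)
    return seq


def read_fasta(path) -> List[ProteinRecord]:
    """Parse a FASTA file into sanitized :class:`ProteinRecord` entries.

    The id is the first whitespace-delimited token of the header line.
    """
    from Bio import SeqIO

    path = Path(path)
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise FormatError(f"{path}: no FASTA entries found")
    records = []
    for entry in entries:
        seq = sanitize_sequence(entry.id, str(entry.seq))
        records.append(ProteinRecord(entry.id, seq))
    return records


def read_cluster_map(path, dialect: Optional[str] = None) -> ClusterMap:
    """Load a two-column (protein_id, cluster_id) delimited file."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    assignments: Dict[str, str] = {}
    if not lines:
        return ClusterMap(assignments)
    delim = _sniff_delimiter(lines[0], dialect or "\t")
    for row_no, line in enumerate(lines, start=1):
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) != 2:
            raise FormatError(f"{path}: line {row_no}: expected 2 fields, got {len(parts)}")
        pid, cid = parts
        if pid in assignments and assignments[pid] != cid:
            raise ConsistencyError(
                f"{path}: protein {pid} assigned to both {assignments[pid]} and {cid}"
            )
        assignments[pid] = cid
    return ClusterMap(assignments)


def read_vector_table(path, kind: str, dialect: Optional[str] = None) -> FeatureTable:
    """Load a delimited id + numeric-columns file into a :class:`FeatureTable`."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0], dialect)
    rows = list(csv.reader(lines, delimiter=delim))
    # optional header: first row whose numeric fields fail to parse
    start = 0
    if len(rows[0]) >= 2:
        try:
            [float(v) for v in rows[0][1:]]
        except ValueError:
            start = 1
    width = None
    vectors: Dict[str, np.ndarray] = {}
    for row_no, row in enumerate(rows[start:], start=start + 1):
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise FormatError(
                f"{path}: row {row_no} has {len(row)} fields, expected {width}"
            )
        key = row[0].strip()
        if key in vectors:
            raise ConsistencyError(f"{path}: duplicate id {key!r}")
        try:
            vec = np.array([float(v) for v in row[1:]], dtype=float)
        except ValueError as exc:
            raise ParseError(f"{path}: row {row_no}: non-numeric value") from exc
        if np.isnan(vec).any():
            raise InputError(f"{path}: NaN in vector for {key!r}")
        vectors[key] = vec
    return FeatureTable(vectors, kind=kind)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id"] + [f"f{i}" for i in range(table.dimension or 0)])
        for key, vec in table.vectors.items():
            writer.writerow([key] + [repr(float(v)) for v in vec])


def write_split(table: BioactivityTable, split, out_dir,
                smiles: Optional[Mapping[str, str]] = None) -> Dict[str, Path]:
    """Write train/test/discarded folds of ``split`` as CSV plus a manifest.

    Each fold file carries the original columns plus a ``fold`` label and
    round-trips losslessly through :func:`read_bioactivity_table`.
    """
    folds = {"train": split.train, "test": split.test, "discarded": split.discarded}
    all_ids = sorted(set().union(*folds.values()))
    if sum(len(v) for v in folds.values()) != len(all_ids):
        raise ConsistencyError("folds overlap: a record appears in more than one fold")
    if all_ids != list(range(len(table))):
        raise ConsistencyError("split does not partition the table's record ids")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    has_smiles = bool(smiles)
    for fold_name, ids in folds.items():
        fold_path = out_dir / f"{fold_name}.csv"
        with fold_path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            header = ["compound_id", "protein_id", "pchembl_value", "fold"]
            if has_smiles:
                header.insert(1, "smiles")
            writer.writerow(header)
            for rid in sorted(ids):
                rec = table[rid]
                row = [rec.compound_id, rec.protein_id, repr(rec.activity), fold_name]
                if has_smiles:
                    row.insert(1, smiles.get(rec.compound_id, ""))
                writer.writerow(row)
        written[fold_name] = fold_path
    manifest = {
        "n_records": len(table),
        "fold_sizes": {k: len(v) for k, v in folds.items()},
        "params": dict(getattr(split, "params", {})),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    written["manifest"] = manifest_path
    return written


def write_fasta(records: Sequence[ProteinRecord], path) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n{rec.sequence}\n")


def write_cluster_map(cluster_map: ClusterMap, path) -> None:
    with Path(path).open("w") as fh:
        for pid, cid in cluster_map.assignments.items():
            fh.write(f"{pid}\t{cid}\n")


def write_bioactivity_table(table: BioactivityTable, path,
                            smiles: Optional[Mapping[str, str]] = None) -> None:
    path = Path(path)
    has_smiles = bool(smiles)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["compound_id", "protein_id", "pchembl_value"]
        if has_smiles:
            header.insert(1, "smiles")
        writer.writerow(header)
        for rec in table:
            row = [rec.compound_id, rec.protein_id, repr(rec.activity)]
            if has_smiles:
                row.insert(1, smiles.get(rec.compound_id, ""))
            writer.writerow(row)
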