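"""Readers and writers for every on-disk artifact the pipeline touches.

Formats handled here:

* multi-record FASTA (via Biopython),
* PSI-BLAST ASCII PSSM files (the ``-out_ascii_pssm`` layout),
* tab-separated annotation tables (domains, GO terms per level, disorder
  intervals, class labels),
* feature matrices as TSV with a header row.

Internal conventions fixed here and used by every other module:

* the canonical amino-acid order is alphabetical by one-letter code
  (:data:`AMINO_ACIDS`); all 20- and 400-dimensional vectors and the
  co-occurrence matrix follow it,
* residue coordinates are 0-based half-open intervals; 1-based indices
  appear only while parsing PSI-BLAST files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

#: Canonical alphabet: the 20 standard amino acids, alphabetical by letter.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Letters that may appear in sequences but are not standard residues.
NONSTANDARD = set("BJOUXZ")

#: Class labels: 1=non-hub, 2=intermediately connected, 3=party hub, 4=date hub.
CLASS_LABELS = (1, 2, 3, 4)
CLASS_NAMES = {1: "NH", 2: "IC", 3: "PH", 4: "DH"}


class FormatError(ValueError):
    """A file did not match its declared on-disk format."""


@dataclass
class PSSMProfile:
    """Position-specific scoring matrix aligned to a sequence.

    Stored positions-by-residue-types (L x 20), the transpose of the
    motif-literature convention, because PSI-BLAST ASCII files are one row
    per sequence position.  Columns follow :data:`AMINO_ACIDS`.
    """

    sequence: str
    scores: np.ndarray  # (L, 20) log-odds
    percentages: np.ndarray | None = None  # (L, 20), values in [0, 100]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sequence), 20):
            raise ValueError(
                f"scores shape {self.scores.shape} does not match sequence "
                f"length {len(self.sequence)}"
            )
        if self.percentages is not None:
            self.percentages = np.asarray(self.percentages, dtype=float)
            if self.percentages.shape != self.scores.shape:
                raise ValueError("percentage block shape mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DomainAnnotation:
    """Ordered list of domain identifiers along a protein.

    Order matters: repeated domains are detected from adjacency in this list.
    """

    domains: list[str] = field(default_factory=list)


@dataclass
class GoAnnotation:
    """GO terms grouped by (aspect, level); terms keep input order."""

    #: mapping level -> list of term ids (aspect is encoded in the term id
    #: prefix by the synthetic generator; real tables may use bare GO ids).
    terms_by_level: dict[int, list[str]] = field(default_factory=dict)


@dataclass
class DisorderMask:
    """Half-open 0-based residue intervals flagged as disordered."""

    intervals: list[tuple[int, int]] = field(default_factory=list)

    def normalized(self) -> "DisorderMask":
        """Sort and merge overlapping / touching intervals."""
        merged: list[tuple[int, int]] = []
        for start, end in sorted(self.intervals):
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        return DisorderMask(merged)


@dataclass
class Annotations:
    domains: DomainAnnotation | None = None
    go: GoAnnotation | None = None
    disorder: DisorderMask | None = None
    pssm: PSSMProfile | None = None


@dataclass
class ProteinRecord:
    """One protein: identifier, amino-acid sequence, optional annotations."""

    id: str
    sequence: str
    annotations: Annotations = field(default_factory=Annotations)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be nonempty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: sequence must be nonempty")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file.

    Sequences are uppercased and whitespace-stripped; the record id is the
    first whitespace-delimited header token.  Raises :class:`FormatError`
    naming the offending record for empty headers or empty sequences.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for ordinal, (header, seq) in enumerate(SimpleFastaParser(handle), 1):
            tokens = header.split()
            if not tokens:
                raise FormatError(f"{path}: record {ordinal}: empty FASTA header")
            seq = "".join(seq.split()).upper()
            if not seq:
                raise FormatError(
                    f"{path}: record {ordinal} ({tokens[0]!r}): empty sequence"
                )
            if tokens[0] in seen:
                raise FormatError(
                    f"{path}: record {ordinal}: duplicate id {tokens[0]!r}"
                )
            seen.add(tokens[0])
            records.append(ProteinRecord(id=tokens[0], sequence=seq))
    return records


def write_fasta(path: str | Path, records: Iterable[ProteinRecord], width: int = 60) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def read_pssm(path: str | Path) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM file (``-out_ascii_pssm`` layout).

    The file's amino-acid header order is arbitrary; columns are remapped to
    the canonical :data:`AMINO_ACIDS` order, so the parsed matrix is
    invariant to column permutations in the file.

    The first line whose tokens are 20 (or 40) single amino-acid letters is
    taken as the column header; every following line starting with an
    integer index is a residue row: index, residue letter, 20 log-odds
    scores, optionally 20 percentage columns.  Trailing per-row statistics
    beyond the declared columns are ignored, as are footer lines.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    header_cols: list[str] | None = None
    header_line_no = 0
    for line_no, line in enumerate(lines, 1):
        tokens = line.split()
        if tokens and all(len(t) == 1 and t in AA_INDEX for t in tokens) and len(tokens) in (20, 40):
            header_cols = tokens
            header_line_no = line_no
            break
    if header_cols is None:
        raise FormatError(f"{path}: no amino-acid column header found")
    has_pct = len(header_cols) == 40
    n_cols = len(header_cols)

    seq_chars: list[str] = []
    score_rows: list[list[float]] = []
    pct_rows: list[list[float]] = []
    expected_index = 1
    for line_no, line in enumerate(lines[header_line_no:], header_line_no + 1):
        tokens = line.split()
        if len(tokens) < 2 or not tokens[0].lstrip("-").isdigit():
            continue  # footer (Lambda/K statistics) or blank
        index = int(tokens[0])
        if index != expected_index:
            raise FormatError(
                f"{path}:{line_no}: residue index {index}, expected {expected_index}"
            )
        residue = tokens[1]
        values = tokens[2 : 2 + n_cols]
        if len(values) < n_cols:
            raise FormatError(
                f"{path}:{line_no}: truncated row ({len(values)} of {n_cols} values)"
            )
        try:
            numeric = [float(v) for v in values]
        except ValueError as exc:
            raise FormatError(f"{path}:{line_no}: non-numeric cell: {exc}") from None
        seq_chars.append(residue)
        score_rows.append(numeric[:20])
        if has_pct:
            pct_rows.append(numeric[20:40])
        expected_index += 1

    if not score_rows:
        raise FormatError(f"{path}: no residue rows found")

    # remap file column order -> canonical order
    order = np.array([AA_INDEX[a] for a in header_cols[:20]])
    inv = np.empty(20, dtype=int)
    inv[order] = np.arange(20)
    scores = np.asarray(score_rows)[:, inv]
    percentages = None
    if has_pct:
        order2 = np.array([AA_INDEX[a] for a in header_cols[20:40]])
        inv2 = np.empty(20, dtype=int)
        inv2[order2] = np.arange(20)
        percentages = np.asarray(pct_rows)[:, inv2]
    return PSSMProfile(sequence="".join(seq_chars), scores=scores, percentages=percentages)


def write_pssm(path: str | Path, profile: PSSMProfile) -> None:
    """Write a profile in the PSI-BLAST ASCII layout :func:`read_pssm` reads."""
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        cols = "  ".join(AMINO_ACIDS)
        if profile.percentages is not None:
            fh.write(f"            {cols}   {cols}\n")
        else:
            fh.write(f"            {cols}\n")
        for i, residue in enumerate(profile.sequence):
            row = [f"{i + 1:5d} {residue}"]
            row += [f"{v:6.0f}" if float(v).is_integer() else f"{v:6.2f}"
                    for v in profile.scores[i]]
            if profile.percentages is not None:
                row += [f"{v:4.0f}" if float(v).is_integer() else f"{v:6.2f}"
                        for v in profile.percentages[i]]
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# Annotation tables (TSV)
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> dict[str, int]:
    """Labels TSV: ``protein_id TAB label`` with label in 1..4."""
    table = pd.read_csv(path, sep="\t", header=None, names=["id", "label"],
                        dtype={"id": str}, comment="#")
    labels: dict[str, int] = {}
    for row in table.itertuples(index=False):
        label = int(row.label)
        if label not in CLASS_LABELS:
            raise FormatError(f"{path}: label {label} for {row.id!r} not in 1..4")
        labels[row.id] = label
    return labels


def write_labels(path: str | Path, labels: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        for pid, label in labels.items():
            fh.write(f"{pid}\t{label}\n")


def read_annotations(
    domains_path: str | Path | None = None,
    go_path: str | Path | None = None,
    disorder_path: str | Path | None = None,
) -> dict[str, Annotations]:
    """Read domain / GO / disorder TSV tables into per-protein annotations.

    Dialects: domains ``id TAB dom1;dom2;...`` (order preserved);
    GO ``id TAB level TAB term``; disorder ``id TAB start TAB end`` with
    0-based half-open intervals (overlaps merged).  Unknown protein ids are
    kept (the caller decides what to do with ids missing from its dataset).
    """
    out: dict[str, Annotations] = {}

    def entry(pid: str) -> Annotations:
        return out.setdefault(pid, Annotations())

    if domains_path is not None:
        table = pd.read_csv(domains_path, sep="\t", header=None,
                            names=["id", "domains"], dtype=str, comment="#")
        for row in table.itertuples(index=False):
            doms = [d for d in str(row.domains).split(";") if d] if pd.notna(row.domains) else []
            entry(row.id).domains = DomainAnnotation(doms)

    if go_path is not None:
        table = pd.read_csv(go_path, sep="\t", header=None,
                            names=["id", "level", "term"], dtype=str, comment="#")
        for row in table.itertuples(index=False):
            ann = entry(row.id)
            if ann.go is None:
                ann.go = GoAnnotation()
            ann.go.terms_by_level.setdefault(int(row.level), []).append(row.term)

    if disorder_path is not None:
        table = pd.read_csv(disorder_path, sep="\t", header=None,
                            names=["id", "start", "end"], comment="#",
                            dtype={"id": str, "start": int, "end": int})
        masks: dict[str, list[tuple[int, int]]] = {}
        for row in table.itertuples(index=False):
            if row.start >= row.end:
                raise FormatError(
                    f"{disorder_path}: bad interval [{row.start}, {row.end}) for {row.id!r}"
                )
            masks.setdefault(row.id, []).append((int(row.start), int(row.end)))
        for pid, intervals in masks.items():
            entry(pid).disorder = DisorderMask(intervals).normalized()

    return out


def read_vocabulary(path: str | Path) -> list[str]:
    """Plain-text vocabulary: one identifier per line, order = vector position."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def write_vocabulary(path: str | Path, vocab: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for term in vocab:
            fh.write(term + "\n")


# ---------------------------------------------------------------------------
# Feature matrices (TSV)
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Named (proteins x features) matrix for one encoding."""

    name: str
    protein_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_ids), len(self.feature_names)):
            raise ValueError(
                f"feature set {self.name!r}: values shape {self.values.shape} does not "
                f"match {len(self.protein_ids)} proteins x {len(self.feature_names)} features"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def write_feature_matrix(path: str | Path, fs: FeatureSet) -> None:
    """Write a feature matrix as TSV; round-trips to >= 12 significant digits."""
    if fs.values.size and not np.all(np.isfinite(fs.values)):
        raise FormatError(f"feature set {fs.name!r}: non-finite cell, refusing to write")
    with open(path, "w") as fh:
        fh.write("protein_id\t" + "\t".join(fs.feature_names) + "\n")
        for pid, row in zip(fs.protein_ids, fs.values):
            fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_feature_matrix(path: str | Path, name: str | None = None) -> FeatureSet:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "protein_id":
            raise FormatError(f"{path}: first header column must be 'protein_id'")
        feature_names = header[1:]
        ids: list[str] = []
        rows: list[list[float]] = []
        for line_no, line in enumerate(fh, 2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise FormatError(
                    f"{path}:{line_no}: ragged row ({len(cells)} cells, expected {len(header)})"
                )
            try:
                values = [float(c) for c in cells[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: non-numeric cell: {exc}") from None
            if any(math.isnan(v) or math.isinf(v) for v in values):
                raise FormatError(f"{path}:{line_no}: non-finite cell")
            ids.append(cells[0])
            rows.append(values)
    values = np.asarray(rows, dtype=float) if rows else np.empty((0, len(feature_names)))
    return FeatureSet(name=name or path.stem, protein_ids=ids,
                      feature_names=feature_names, values=values)
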