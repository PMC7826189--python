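"""Readers/writers and in-memory containers for the formats the pipeline touches.

Conventions enforced here, once, for every consumer:

* All genomic intervals are 0-based half-open (BED convention); SAM input is
  converted at this boundary. Interval length is always ``end - start``.
* Branch supports are normalised to the percentage scale [0, 100]; readers
  accept an explicit declaration of the input scale.
* Strand is ignored throughout — coverage and region arithmetic downstream
  are strand-agnostic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("chromaforge")

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET_X = PROTEIN_ALPHABET + "X"
NUCLEOTIDE_ALPHABET = "ACGTN"

# Reference-consuming CIGAR operations (SAM spec): M, D, N, =, X.
_CIGAR_REF_OPS = set("MDN=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A named sequence (protein or nucleotide).

    Parameters
    ----------
    id : str
        Unique identifier within a file.
    seq : str
        Residue string; proteins over the 20 amino acids plus X,
        nucleotides over ACGTN.
    description : str
        Free-text description (FASTA header remainder).
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved; whitespace inside sequences is stripped.
    Duplicate ids and empty sequences are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).replace(" ", "").replace("\t", "")
        if not seq:
            raise FormatError(f"empty sequence for id {rec.id!r} in {path}")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, seq=seq, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with LF line endings."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of a rooted phylogeny with optional support and branch length.

    A node is a leaf iff it has no children iff its label is non-empty.
    Support is carried on internal nodes only, on the [0, 100] scale.
    """

    children: list["TreeNode"] = field(default_factory=list)
    label: str = ""
    support: float | None = None
    branch_length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def validate(self) -> None:
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dup}")
        for n in self.postorder():
            if n.is_leaf and not n.label:
                raise ValueError("leaf with empty label")
            if n.support is not None and not (0 <= n.support <= 100):
                raise ValueError(f"support {n.support} outside [0, 100]")


class NewickParseError(FormatError):
    """Newick syntax error, carrying the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at position {position}")
        self.position = position


def parse_newick(text: str, support_scale: str = "percent") -> TreeNode:
    """Parse a single Newick string into a :class:`TreeNode`.

    Numeric internal-node labels are interpreted as branch supports.
    ``support_scale`` declares the scale of those numbers: ``"percent"``
    ([0, 100], the default) or ``"fractional"`` ([0, 1], rescaled to
    percent). Polytomies are preserved.
    """
    if support_scale not in ("percent", "fractional"):
        raise ValueError(f"unknown support_scale {support_scale!r}")
    s = text.strip()
    pos = 0

    def error(msg: str) -> NewickParseError:
        return NewickParseError(msg, pos)

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def parse_length() -> float | None:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),;":
                pos += 1
            try:
                bl = float(s[start:pos])
            except ValueError:
                raise error(f"invalid branch length {s[start:pos]!r}")
            if bl < 0:
                raise error("negative branch length")
            return bl
        return None

    def parse_subtree() -> TreeNode:
        nonlocal pos
        if pos >= len(s):
            raise error("unexpected end of input")
        if s[pos] == "(":
            pos += 1
            children = [parse_subtree()]
            while pos < len(s) and s[pos] == ",":
                pos += 1
                children.append(parse_subtree())
            if pos >= len(s) or s[pos] != ")":
                raise error("unbalanced parentheses: expected ')'")
            pos += 1
            raw = parse_label()
            node = TreeNode(children=children)
            if raw:
                try:
                    sup = float(raw)
                except ValueError:
                    node.label = ""  # non-numeric internal label discarded
                else:
                    if support_scale == "fractional":
                        sup *= 100.0
                    node.support = sup
            node.branch_length = parse_length()
            return node
        label = parse_label()
        if not label:
            raise error("expected leaf label")
        return TreeNode(label=label, branch_length=parse_length())

    root = parse_subtree()
    if pos >= len(s) or s[pos] != ";":
        raise NewickParseError("expected ';' terminator", pos)
    root.validate()
    return root


def read_newick(path: str | Path, support_scale: str = "percent") -> TreeNode:
    """Read a single-tree Newick file."""
    text = Path(path).read_text()
    return parse_newick(text, support_scale=support_scale)


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialise a tree to Newick (supports on the percent scale)."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            out = node.label
        else:
            out = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.support is not None:
                out += format(node.support, "g")
        if node.branch_length is not None:
            out += ":" + format(node.branch_length, "g")
        return out

    text = fmt(tree) + ";"
    if path is not None:
        Path(path).write_text(text + "\n", newline="\n")
    return text


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval [start, end) on a contig."""

    contig: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _read_bed(path: str | Path) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line with <3 columns")
            contig, start_s, end_s = parts[0], parts[1], parts[2]
            label = parts[3] if len(parts) > 3 else ""
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: invalid coordinates {start}-{end}"
                )
            out.append(Interval(contig, start, end, label))
    return out


def cigar_reference_span(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string."""
    if cigar == "*":
        return 0
    span = 0
    consumed = 0
    for m in _CIGAR_RE.finditer(cigar):
        consumed += len(m.group(0))
        if m.group(2) in _CIGAR_REF_OPS:
            span += int(m.group(1))
    if consumed != len(cigar):
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return span


def _read_sam(path: str | Path) -> list[Interval]:
    out: list[Interval] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            parts = line.split("\t")
            if len(parts) < 11:
                raise FormatError(f"{path}:{lineno}: SAM line with <11 fields")
            qname, flag_s, rname, pos_s, _mapq, cigar = parts[0], parts[1], parts[2], parts[3], parts[4], parts[5]
            try:
                flag, pos1 = int(flag_s), int(pos_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer FLAG/POS")
            if flag & 0x4 or rname == "*":
                skipped += 1
                continue
            if pos1 < 1:
                raise FormatError(f"{path}:{lineno}: POS {pos1} < 1")
            span = cigar_reference_span(cigar)
            if span == 0:
                skipped += 1
                continue
            start = pos1 - 1  # SAM POS is 1-based
            out.append(Interval(rname, start, start + span, qname))
    if skipped:
        logger.info("read_intervals: skipped %d unmapped/unaligned SAM records", skipped)
    return out


def read_intervals(path: str | Path, format: str = "BED") -> list[Interval]:
    """Read intervals from BED (0-based half-open) or SAM.

    SAM alignments are converted using reference-consuming CIGAR operations
    only; unmapped records are skipped (count logged).
    """
    fmt = format.upper()
    if fmt == "BED":
        return _read_bed(path)
    if fmt == "SAM":
        return _read_sam(path)
    raise ValueError(f"unknown interval format {format!r}")


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# Orthologous gene families
# ---------------------------------------------------------------------------

@dataclass
class FamilyMatrix:
    """Presence/absence of orthologous gene families (OGFs) across species.

    ``presence[i, j]`` is True iff family ``families[i]`` has at least one
    gene in species ``species[j]``. ``gene_map`` retains the family ->
    species -> gene-id lists, and every gene id belongs to exactly one family.
    """

    families: list[str]
    species: list[str]
    presence: np.ndarray  # bool, shape (n_families, n_species)
    gene_map: dict[str, dict[str, list[str]]]

    def __post_init__(self) -> None:
        if len(set(self.families)) != len(self.families):
            raise ValueError("duplicate family ids")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species ids")
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.families), len(self.species)):
            raise ValueError("presence matrix shape mismatch")
        if not self.presence.any(axis=1).all():
            bad = [f for f, row in zip(self.families, self.presence) if not row.any()]
            raise ValueError(f"families present in zero species: {bad}")

    def presence_set(self, family: str) -> set[str]:
        i = self.families.index(family)
        return {sp for sp, p in zip(self.species, self.presence[i]) if p}

    def family_of_gene(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for fam, per_sp in self.gene_map.items():
            for genes in per_sp.values():
                for g in genes:
                    out[g] = fam
        return out


def read_ogf_table(path: str | Path) -> FamilyMatrix:
    """Read an OrthoFinder-style orthogroup TSV.

    Header row names the species (first column = family id); each cell holds
    comma-separated gene ids or is empty. A family with all cells empty is
    rejected with a warning; a gene id appearing in two families is an error.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: OGF table needs >=2 columns")
        species = header[1:]
        families: list[str] = []
        rows: list[list[bool]] = []
        gene_map: dict[str, dict[str, list[str]]] = {}
        gene_owner: dict[str, str] = {}
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}"
                )
            fam = parts[0]
            cells = parts[1:]
            per_sp: dict[str, list[str]] = {}
            row: list[bool] = []
            for sp, cell in zip(species, cells):
                genes = [g.strip() for g in cell.split(",") if g.strip()]
                row.append(bool(genes))
                if genes:
                    per_sp[sp] = genes
                for g in genes:
                    if g in gene_owner:
                        raise FormatError(
                            f"{path}:{lineno}: gene {g!r} appears in families "
                            f"{gene_owner[g]!r} and {fam!r}"
                        )
                    gene_owner[g] = fam
            if not any(row):
                logger.warning("read_ogf_table: family %s present in zero species; rejected", fam)
                continue
            families.append(fam)
            rows.append(row)
            gene_map[fam] = per_sp
    return FamilyMatrix(
        families=families,
        species=species,
        presence=np.array(rows, dtype=bool) if rows else np.zeros((0, len(species)), bool),
        gene_map=gene_map,
    )


def write_ogf_table(matrix: FamilyMatrix, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("Orthogroup\t" + "\t".join(matrix.species) + "\n")
        for fam in matrix.families:
            per_sp = matrix.gene_map.get(fam, {})
            cells = [", ".join(per_sp.get(sp, [])).replace(", ", ",") for sp in matrix.species]
            fh.write(fam + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Expression count matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """(condition, timepoint in hours, replicate index) of one RNA-seq sample."""

    condition: str
    timepoint_h: float
    replicate: int

    @property
    def name(self) -> str:
        tp = format(self.timepoint_h, "g")
        return f"{self.condition}_T{tp}_R{self.replicate}"

    @classmethod
    def from_name(cls, name: str) -> "SampleMeta":
        m = re.fullmatch(r"(.+)_T([0-9.]+)_R(\d+)", name)
        if not m:
            raise FormatError(
                f"sample name {name!r} does not encode (condition, timepoint, replicate)"
            )
        return cls(m.group(1), float(m.group(2)), int(m.group(3)))


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative expression values."""

    genes: list[str]
    samples: list[SampleMeta]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sample ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape mismatch")
        if (self.values < 0).any() or not np.isfinite(self.values).all():
            raise ValueError("values must be finite and non-negative")

    def subset_condition(self, condition: str) -> "CountMatrix":
        idx = [j for j, s in enumerate(self.samples) if s.condition == condition]
        return CountMatrix(
            genes=list(self.genes),
            samples=[self.samples[j] for j in idx],
            values=self.values[:, idx],
        )


def read_counts(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix whose column names encode sample metadata."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = [SampleMeta.from_name(c) for c in df.columns]
    return CountMatrix(genes=list(df.index), samples=samples, values=df.to_numpy(float))


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        matrix.values,
        index=pd.Index(matrix.genes, name="gene_id"),
        columns=[s.name for s in matrix.samples],
    )
    df.to_csv(path, sep="\t", lineterminator="\n")
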