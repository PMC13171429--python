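"""Readers, writers and the shared data model.

Conventions used throughout the package:

* coordinates are 0-based, half-open (``[start, end)``); GFF3 input/output is
  converted at the boundary;
* genome sequences are uppercase strings over ``{A, C, G, T, N}``; ``N`` is
  tolerated (draft assemblies) but excluded from every composition count;
* CDS sequences are supplied already strand-resolved (5'->3'); loci carry a
  strand only for neighborhood display;
* trees are `dendropy.Tree` objects read as rooted Newick.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("vertitrace")

NUCLEOTIDES = frozenset("ACGTN")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY*X-")


class SeqFormatError(ValueError):
    """Raised on malformed sequence/locus/tree input."""


@dataclass(frozen=True)
class GenomeRecord:
    """A genome (or contig) sequence.

    Sequence is uppercase over {A,C,G,T,N}; anything else is rejected at load.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqFormatError("empty genome id")
        if not self.sequence:
            raise SeqFormatError(f"empty sequence for genome {self.id!r}")
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            raise SeqFormatError(
                f"illegal nucleotide characters {sorted(bad)} in {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneLocus:
    """A gene location on a genome, 0-based half-open, strand '+' or '-'."""

    genome_id: str
    gene_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SeqFormatError(
                f"invalid interval [{self.start}, {self.end}) for {self.gene_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise SeqFormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


class SeqSet:
    """An ordered id -> sequence map (nucleotide CDS or amino-acid).

    For CDS sets each sequence length must be divisible by 3 unless
    ``partial=True``.
    """

    def __init__(
        self,
        entries: "OrderedDict[str, str] | dict[str, str] | Iterable[tuple[str, str]]",
        alphabet: str = "nt",
        partial: bool = False,
    ) -> None:
        if alphabet not in ("nt", "aa"):
            raise ValueError(f"alphabet must be 'nt' or 'aa', got {alphabet!r}")
        self.alphabet = alphabet
        self.partial = partial
        self.entries: "OrderedDict[str, str]" = OrderedDict()
        items = entries.items() if hasattr(entries, "items") else entries
        for sid, seq in items:
            if sid in self.entries:
                raise SeqFormatError(f"duplicate sequence id {sid!r}")
            seq = seq.upper()
            if not seq:
                raise SeqFormatError(f"empty sequence for {sid!r}")
            allowed = NUCLEOTIDES | {"-"} if alphabet == "nt" else AMINO_ACIDS
            bad = set(seq) - allowed
            if bad:
                raise SeqFormatError(
                    f"illegal {alphabet} characters {sorted(bad)} in {sid!r}"
                )
            if alphabet == "nt" and not partial and len(seq.replace("-", "")) % 3:
                raise SeqFormatError(
                    f"CDS length {len(seq)} of {sid!r} not divisible by 3 "
                    "(pass partial=True to allow)"
                )
            self.entries[sid] = seq

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, sid: str) -> str:
        return self.entries[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self.entries

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def items(self):
        return self.entries.items()

    def ids(self) -> list[str]:
        return list(self.entries)


def read_fasta(path, alphabet: str = "nt", genomes: bool = False, partial: bool = False):
    """Read a FASTA file.

    With ``genomes=True`` returns a list of :class:`GenomeRecord`; otherwise a
    :class:`SeqSet`. Sequence case is normalized to uppercase; ids must be
    unique and records non-empty.
    """
    records = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqFormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise SeqFormatError(f"no records in {path}")
    if genomes:
        return [GenomeRecord(i, s) for i, s in records]
    return SeqSet(records, alphabet=alphabet, partial=partial)


def write_fasta(path, seqs, width: int = 70) -> None:
    """Write a SeqSet, GenomeRecord list, or id->seq mapping as FASTA."""
    if isinstance(seqs, SeqSet):
        items = list(seqs.items())
    elif isinstance(seqs, dict):
        items = list(seqs.items())
    else:
        items = [(r.id, r.sequence) for r in seqs]
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in items]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_loci(path, dialect: str = "gff3", genomes=None) -> list[GeneLocus]:
    """Read gene loci from GFF3 or a 3+-column BED-like TSV.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open;
    BED coordinates pass through. Strand defaults to '+' when absent.
    When ``genomes`` (iterable of GenomeRecord) is given, loci referencing
    unknown genomes or exceeding sequence bounds are rejected.
    """
    dialect = dialect.lower()
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"dialect must be 'gff3' or 'bed', got {dialect!r}")
    lengths = {g.id: len(g) for g in genomes} if genomes is not None else None
    loci: list[GeneLocus] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if dialect == "gff3":
                if len(parts) < 9:
                    raise SeqFormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
                genome_id, start1, end1, strand = parts[0], parts[3], parts[4], parts[6]
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                gene_id = attrs.get("ID", f"gene_{lineno}")
                start = int(start1) - 1
                end = int(end1)
            else:
                if len(parts) < 3:
                    raise SeqFormatError(f"{path}:{lineno}: expected >=3 BED columns")
                genome_id, start, end = parts[0], int(parts[1]), int(parts[2])
                gene_id = parts[3] if len(parts) > 3 else f"gene_{lineno}"
                strand = parts[5] if len(parts) > 5 else "+"
            if strand in (".", ""):
                strand = "+"
            if start >= end:
                raise SeqFormatError(
                    f"{path}:{lineno}: start {start} >= end {end} after conversion"
                )
            key = (genome_id, gene_id)
            if key in seen:
                raise SeqFormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(key)
            if lengths is not None:
                if genome_id not in lengths:
                    raise SeqFormatError(
                        f"{path}:{lineno}: unknown genome {genome_id!r}"
                    )
                if end > lengths[genome_id]:
                    raise SeqFormatError(
                        f"{path}:{lineno}: locus end {end} beyond genome "
                        f"length {lengths[genome_id]}"
                    )
            loci.append(GeneLocus(genome_id, gene_id, start, end, strand))
    return loci


def write_loci_bed(path, loci: Iterable[GeneLocus]) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(
                f"{loc.genome_id}\t{loc.start}\t{loc.end}\t{loc.gene_id}\t0\t{loc.strand}\n"
            )


def read_newick(path_or_string, require_rooted: bool = False) -> dendropy.Tree:
    """Read a single Newick tree.

    Branch lengths absent from the file default to 0 with a warning. A basal
    polytomy is permitted but triggers a warning when ``require_rooted``.
    Duplicate tip labels are an error.
    """
    src = str(path_or_string)
    try:
        if src.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=src, schema="newick")
        else:
            tree = dendropy.Tree.get(path=src, schema="newick")
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        msg = str(exc)
        if "multiple" in msg.lower() or "duplicate" in msg.lower():
            raise SeqFormatError(f"duplicate tip labels: {msg}") from exc
        raise SeqFormatError(f"unparseable newick: {msg}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise SeqFormatError(f"duplicate tip labels {dupes}")
    missing_bl = False
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            missing_bl = True
        elif edge.length < 0:
            raise SeqFormatError("negative branch length")
    if missing_bl:
        warnings.warn("missing branch lengths defaulted to 0", stacklevel=2)
    tree.is_rooted = True
    if require_rooted and len(tree.seed_node.child_nodes()) > 2:
        warnings.warn("basal polytomy: tree may be unrooted", stacklevel=2)
    return tree


def read_trait_table(path, tree: dendropy.Tree | None = None) -> dict[str, int]:
    """Read a tip<TAB>0/1 presence/absence table.

    When a tree is supplied, every tip must have a state and states restricted
    to tree tips.
    """
    traits: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SeqFormatError(f"{path}:{lineno}: expected tip<TAB>state")
            tip, state = parts[0], parts[1]
            if state not in ("0", "1"):
                raise SeqFormatError(f"{path}:{lineno}: state must be 0 or 1")
            if tip in traits:
                raise SeqFormatError(f"{path}:{lineno}: duplicate tip {tip!r}")
            traits[tip] = int(state)
    if tree is not None:
        tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
        missing = tips - set(traits)
        if missing:
            raise SeqFormatError(f"tips without a trait state: {sorted(missing)}")
        traits = {t: s for t, s in traits.items() if t in tips}
    return traits


def write_trait_table(path, traits: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for tip, state in traits.items():
            fh.write(f"{tip}\t{state}\n")


@dataclass
class Report:
    """Structured record of pipeline stage outputs with provenance.

    Serializes losslessly to JSON; every stage payload carries the parameters
    it was computed with, and the top level records the master seed.
    """

    inputs: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = "0.1.0"
    stages: dict = field(default_factory=dict)
    verdict: dict = field(default_factory=dict)

    def add_stage(self, name: str, payload: dict) -> None:
        self.stages[name] = payload

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Report":
        return cls(**json.loads(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())
            fh.write("\n")
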