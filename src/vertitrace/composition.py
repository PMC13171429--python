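"""GC-content statistics: gene vs genome, across a strain set.

A laterally acquired gene often retains the base composition of its donor, so
the first screen compares the GC fraction of the focal gene with the GC
fraction of its host genome in every strain. GC is computed over counted
bases only (``N`` excluded from numerator and denominator); genome GC pools
counts over all contigs rather than averaging per-contig fractions.
Fractions are used internally; percentages appear only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, stdev

from .seqio import GeneLocus, GenomeRecord, SeqSet


@dataclass(frozen=True)
class GcRecord:
    strain: str
    gene_gc: float
    genome_gc: float

    @property
    def deviation(self) -> float:
        return self.gene_gc - self.genome_gc


@dataclass(frozen=True)
class GcSummary:
    n: int
    gene_mean: float
    gene_sd: float | None  # sample sd (n-1); None when n < 2
    genome_mean: float
    genome_sd: float | None
    deviation_mean: float


def gc_content(sequence: str) -> float:
    """GC fraction (#G + #C) / (#A + #C + #G + #T); N excluded."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("no counted (non-N) bases")
    return gc / (gc + at)


def _genome_gc(contigs: list[GenomeRecord]) -> float:
    gc = at = 0
    for rec in contigs:
        s = rec.sequence
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("no counted bases in genome")
    return gc / (gc + at)


def gene_vs_genome_gc(
    loci: list[GeneLocus],
    genomes: list[GenomeRecord],
    gene_seqs: SeqSet | None = None,
    strain_of=None,
) -> tuple[list[GcRecord], GcSummary]:
    """One gene-vs-genome GC record per locus, plus a summary over strains.

    The gene sequence is sliced from its genome contig unless an explicit CDS
    set keyed by gene id is supplied. Genome GC pools counts over all contigs
    of a strain; by default each contig id is its own strain, override with
    ``strain_of`` (contig id -> strain id) for multi-contig assemblies.
    """
    by_id = {g.id: g for g in genomes}
    if strain_of is None:
        strain_of = {g.id: g.id for g in genomes}
    contigs_of: dict[str, list[GenomeRecord]] = {}
    for g in genomes:
        contigs_of.setdefault(strain_of[g.id], []).append(g)
    records = []
    for loc in loci:
        if loc.genome_id not in by_id:
            raise KeyError(f"no genome {loc.genome_id!r} for locus {loc.gene_id!r}")
        if gene_seqs is not None and loc.gene_id in gene_seqs:
            gene_seq = gene_seqs[loc.gene_id]
        else:
            gene_seq = by_id[loc.genome_id].sequence[loc.start : loc.end]
        strain = strain_of[loc.genome_id]
        records.append(
            GcRecord(
                strain=strain,
                gene_gc=gc_content(gene_seq),
                genome_gc=_genome_gc(contigs_of[strain]),
            )
        )
    return records, summarize_gc(records)


def summarize_gc(records: list[GcRecord]) -> GcSummary:
    if not records:
        raise ValueError("no records")
    gene = [r.gene_gc for r in records]
    genome = [r.genome_gc for r in records]
    n = len(records)
    return GcSummary(
        n=n,
        gene_mean=mean(gene),
        gene_sd=stdev(gene) if n >= 2 else None,
        genome_mean=mean(genome),
        genome_sd=stdev(genome) if n >= 2 else None,
        deviation_mean=mean(r.deviation for r in records),
    )


def gc_deviation_z(gene_gc: float, background_gene_gcs: list[float]) -> float:
    """Z-score of one gene's GC against a background of gene GC values."""
    if len(background_gene_gcs) < 2:
        raise ValueError("background needs n >= 2")
    sd = stdev(background_gene_gcs)
    if sd == 0:
        raise ValueError("zero-variance background")
    return (gene_gc - mean(background_gene_gcs)) / sd
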