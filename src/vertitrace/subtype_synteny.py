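"""Protein-variant identity analysis, subtype clustering, and gene-neighborhood synteny.

Variants of a protein family are compared on a trimmed multiple sequence
alignment: pairwise percent identity is computed over mutually ungapped
columns, and variants are grouped into subtypes by single-linkage clustering
at an identity threshold (default 85%). Subtypes are numbered largest first,
variants within a subtype in input order, giving the hierarchical
``subtype.variant`` labels (``1.1``, ``1.2``, ``2.1``, ...).

Gene neighborhoods around the focal locus (default window 10 kb) are
summarized as ordered gene-family profiles and compared by a symmetric score
mixing shared gene content (Jaccard index) with preserved gene-order
adjacency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .seqio import GeneLocus


@dataclass
class Msa:
    """An amino-acid multiple sequence alignment (gap '-')."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate ids in MSA")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows of unequal length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_seqset(cls, seqs) -> "Msa":
        return cls(ids=list(seqs.ids()), rows=[s for _, s in seqs.items()])


@dataclass
class IdentityMatrix:
    ids: list[str]
    values: np.ndarray  # percent identity; NaN where undefined
    denominator: str = "mutually_ungapped_columns"

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                if np.isnan(self.values[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out


@dataclass
class SubtypeAssignment:
    subtype_of: dict[str, int]  # id -> subtype index (1-based)
    label_of: dict[str, str]  # id -> "subtype.variant"
    threshold: float


@dataclass
class NeighborhoodProfile:
    focal: GeneLocus
    window_bp: int
    genes: list[tuple[str, str, int]]  # (family label, strand, offset from focal start)


def trim_alignment(msa: Msa, drop_nterm_cols: int = 30, drop_range: tuple[int, int] | None = (475, 549)) -> Msa:
    """Drop poorly aligned terminal columns from all rows.

    ``drop_nterm_cols`` leading columns are removed, plus the 1-based
    inclusive column range ``drop_range`` (both in original coordinates).
    """
    width = msa.width
    if drop_nterm_cols < 0 or drop_nterm_cols > width:
        raise ValueError("drop_nterm_cols out of bounds")
    drop = set(range(drop_nterm_cols))
    if drop_range is not None:
        lo, hi = drop_range
        if lo > hi:
            raise ValueError(f"invalid drop range ({lo}, {hi})")
        if lo < 1 or hi > width:
            raise ValueError("drop range outside alignment width")
        rng = set(range(lo - 1, hi))
        if rng & drop:
            raise ValueError("drop ranges overlap")
        drop |= rng
    keep = [i for i in range(width) if i not in drop]
    return Msa(ids=list(msa.ids), rows=["".join(r[i] for i in keep) for r in msa.rows])


def identity_matrix(msa: Msa) -> IdentityMatrix:
    """Pairwise percent identity over mutually ungapped columns.

    Columns gapped in either row are excluded from numerator and denominator;
    a pair with no mutually ungapped column gets a NaN entry (reported via
    :meth:`IdentityMatrix.undefined_pairs`).
    """
    if len(msa.ids) < 2:
        raise ValueError("need >= 2 rows")
    arr = np.array([list(r) for r in msa.rows])
    gap = arr == "-"
    n = len(msa.ids)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            denom = int(both.sum())
            if denom == 0:
                values[i, j] = values[j, i] = np.nan
                continue
            ident = 100.0 * int((arr[i][both] == arr[j][both]).sum()) / denom
            values[i, j] = values[j, i] = ident
    mat = IdentityMatrix(ids=list(msa.ids), values=values)
    if mat.undefined_pairs():
        warnings.warn(
            f"{len(mat.undefined_pairs())} pair(s) share no ungapped columns",
            stacklevel=2,
        )
    return mat


def cluster_subtypes(mat: IdentityMatrix, threshold: float = 85.0) -> SubtypeAssignment:
    """Single-linkage subtype clustering at a percent-identity threshold.

    Two variants share a subtype iff connected by a chain of pairs with
    identity >= threshold. Subtypes are numbered by decreasing size, ties by
    first appearance; variants are numbered within subtype in input order.
    """
    if mat.undefined_pairs():
        raise ValueError(f"undefined identity entries: {mat.undefined_pairs()}")
    n = len(mat.ids)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if mat.values[i, j] >= threshold:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    ordered = sorted(clusters.values(), key=lambda m: (-len(m), min(m)))
    subtype_of, label_of = {}, {}
    for s_idx, members in enumerate(ordered, 1):
        for v_idx, m in enumerate(sorted(members), 1):
            subtype_of[mat.ids[m]] = s_idx
            label_of[mat.ids[m]] = f"{s_idx}.{v_idx}"
    return SubtypeAssignment(subtype_of=subtype_of, label_of=label_of, threshold=threshold)


def build_neighborhood(
    loci: list[GeneLocus],
    focal_gene_id: str,
    families: dict[str, str],
    window_bp: int = 10_000,
) -> NeighborhoodProfile:
    """Ordered gene-family profile within a window around the focal locus.

    ``families`` maps gene id -> family label; genes without a label are
    skipped. Offsets are gene start minus focal start.
    """
    focal = next((l for l in loci if l.gene_id == focal_gene_id), None)
    if focal is None:
        raise KeyError(f"no locus {focal_gene_id!r}")
    lo, hi = focal.start - window_bp, focal.end + window_bp
    genes = []
    for loc in sorted(loci, key=lambda l: l.start):
        if loc.genome_id != focal.genome_id or loc.gene_id == focal_gene_id:
            continue
        if loc.end <= lo or loc.start >= hi:
            continue
        fam = families.get(loc.gene_id)
        if fam is None:
            continue
        genes.append((fam, loc.strand, loc.start - focal.start))
    return NeighborhoodProfile(focal=focal, window_bp=window_bp, genes=genes)


def neighborhood_synteny(profile_a: NeighborhoodProfile, profile_b: NeighborhoodProfile) -> float:
    """Synteny score in [0, 1] between two neighborhood profiles.

    ``score = J/2 + ADJ/2`` where J is the Jaccard index of family sets and
    ADJ the fraction of A's adjacent ordered family pairs (restricted to
    shared families) preserved as adjacent ordered pairs in B. With shared
    families but no adjacent pair to check, ADJ is vacuously 1.
    """
    if profile_a.window_bp != profile_b.window_bp:
        raise ValueError("profiles built with different windows")
    fam_a = [g[0] for g in profile_a.genes]
    fam_b = [g[0] for g in profile_b.genes]
    if not fam_a or not fam_b:
        raise ValueError("empty neighborhood profile: score undefined")
    set_a, set_b = set(fam_a), set(fam_b)
    shared = set_a & set_b
    jaccard = len(shared) / len(set_a | set_b)
    if not shared:
        return 0.0
    ra = [f for f in fam_a if f in shared]
    rb = [f for f in fam_b if f in shared]
    pairs_a = list(zip(ra, ra[1:]))
    pairs_b = set(zip(rb, rb[1:]))
    adj = (
        sum(p in pairs_b for p in pairs_a) / len(pairs_a) if pairs_a else 1.0
    )
    return 0.5 * jaccard + 0.5 * adj
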