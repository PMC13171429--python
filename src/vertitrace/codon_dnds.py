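"""Protein-guided codon alignments and pairwise Nei-Gojobori (NG86) dN/dS.

The selection screen asks whether the focal gene evolves under the same
purifying pressure as conserved single-copy core genes. Amino-acid alignments
are back-translated onto their coding sequences (gap columns become the gap
codon ``---``), and each unordered pair of rows yields NG86 estimates:

* synonymous/nonsynonymous *site* counts S and N from per-codon site
  fractions, averaged over the two sequences;
* *difference* counts Sd and Nd, averaging over all mutational pathways
  between codons differing at 2 or 3 positions with equal weight, pathways
  through stop codons excluded and weights renormalized;
* proportions pS = Sd/S, pN = Nd/N corrected to distances with the
  Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p), and omega = dN/dS.

Pairs where the ratio is undefined (pS = 0 with nonsynonymous change
present), where dN or dS is zero, or where a proportion saturates the JC
correction are excluded from the retained omega set; each exclusion is
reported with a distinct status.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from Bio.Data import CodonTable

from .seqio import SeqSet

GAP_CODON = "---"

_STATUS_OK = "ok"
_STATUS_UNDEF = "undefined_pS0"
_STATUS_FILTERED = "filtered_dN0_or_dS0"
_STATUS_SATURATED = "saturated"


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 1) -> dict[str, str]:
    """codon -> amino acid (stop as '*') for an NCBI translation table."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


@dataclass
class CodonAlignment:
    ids: list[str]
    rows: list[str]  # aligned nucleotide strings, length divisible by 3
    code: int = 1

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("rows of unequal length")
        width = widths.pop() if widths else 0
        if width % 3:
            raise ValueError("alignment width not divisible by 3")
        for rid, row in zip(self.ids, self.rows):
            for i in range(0, len(row), 3):
                codon = row[i : i + 3]
                if "-" in codon and codon != GAP_CODON:
                    raise ValueError(
                        f"partially gapped codon {codon!r} at column {i // 3 + 1} "
                        f"of {rid!r}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]


@dataclass
class PairwiseDnDs:
    id1: str
    id2: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float | None
    pN: float | None
    dS: float | None
    dN: float | None
    omega: float | None
    status: str


@dataclass
class DnDsMatrix:
    label: str
    pairs: list[PairwiseDnDs]

    @property
    def retained_omegas(self) -> list[float]:
        return [p.omega for p in self.pairs if p.status == _STATUS_OK]


def _translate(cds: str, code: dict[str, str]) -> str:
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon not in code:
            raise ValueError(f"untranslatable codon {codon!r} at position {i // 3 + 1}")
        aas.append(code[codon])
    return "".join(aas)


def backtranslate(protein_msa: SeqSet, cds_set: SeqSet, code: int = 1) -> CodonAlignment:
    """Thread coding sequences onto a protein alignment (PAL2NAL-style).

    Each amino-acid column maps to its codon; protein gaps map to ``---``.
    A terminal stop codon on the CDS is tolerated and stripped. The CDS must
    translate exactly to the ungapped protein row; the first mismatch is
    reported.
    """
    table = genetic_code(code)
    ids, rows = [], []
    for sid, prot in protein_msa.items():
        if sid not in cds_set:
            raise KeyError(f"no CDS for aligned protein {sid!r}")
        cds = cds_set[sid].replace("-", "")
        ungapped = prot.replace("-", "")
        if len(cds) % 3:
            raise ValueError(f"CDS length of {sid!r} not divisible by 3")
        if len(cds) == 3 * (len(ungapped) + 1) and table.get(cds[-3:]) == "*":
            cds = cds[:-3]
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"CDS length {len(cds)} of {sid!r} does not match protein "
                f"length {len(ungapped)} (x3, terminal stop tolerated)"
            )
        trans = _translate(cds, table)
        for pos, (a, b) in enumerate(zip(trans, ungapped), 1):
            if a != b:
                raise ValueError(
                    f"translation mismatch for {sid!r} at protein position "
                    f"{pos}: CDS gives {a!r}, alignment has {b!r}"
                )
        out = []
        it = iter(range(0, len(cds), 3))
        for aa in prot:
            out.append(GAP_CODON if aa == "-" else cds[(i := next(it)) : i + 3])
        ids.append(sid)
        rows.append("".join(out))
    return CodonAlignment(ids=ids, rows=rows, code=code)


def codon_site_counts(codon: str, code: int | dict = 1) -> tuple[float, float]:
    """Synonymous/nonsynonymous site fractions (s, n) of one sense codon.

    Each of the three positions contributes the fraction of its single-base
    changes that are synonymous, counting only changes to sense codons
    (changes to stops reduce that position's denominator); n = 3 - s.
    """
    table = code if isinstance(code, dict) else genetic_code(code)
    aa = table.get(codon)
    if aa is None:
        raise ValueError(f"ambiguous or invalid codon {codon!r}")
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no site counts")
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if table[alt] == "*":
                continue
            valid += 1
            if table[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def _pathway_differences(c1: str, c2: str, table: dict[str, str]) -> tuple[float, float] | None:
    """Pathway-averaged (syn, nonsyn) difference counts between two sense codons.

    Averages over all orderings of the differing positions with equal weight;
    orderings passing through a stop codon are dropped and the rest
    reweighted. Returns None when every pathway passes through a stop.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    syn_tot = nsyn_tot = 0.0
    n_valid = 0
    for order in itertools.permutations(diff):
        cur = c1
        syn = nsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if table[nxt] == "*":
                ok = False
                break
            if table[nxt] == table[cur]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nsyn_tot += nsyn
            n_valid += 1
    if n_valid == 0:
        return None
    return syn_tot / n_valid, nsyn_tot / n_valid


@lru_cache(maxsize=None)
def _site_counts_cached(codon: str, table_id: int) -> tuple[float, float]:
    return codon_site_counts(codon, genetic_code(table_id))


@lru_cache(maxsize=None)
def _pathway_cached(c1: str, c2: str, table_id: int):
    return _pathway_differences(c1, c2, genetic_code(table_id))


def _jc(p: float) -> float | None:
    """Jukes-Cantor distance; None when the proportion saturates (4/3 p >= 1)."""
    if p == 0:
        return 0.0
    if (4.0 / 3.0) * p >= 1.0:
        return None
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def ng86_pair(row1: str, row2: str, code: int = 1, id1: str = "seq1", id2: str = "seq2") -> PairwiseDnDs:
    """NG86 dN/dS for one pair of aligned codon rows.

    Only columns where both codons are ungapped sense codons over {A,C,G,T}
    are compared. Site counts are averaged over the two sequences; a column
    whose every mutational pathway crosses a stop codon is skipped entirely.
    """
    if len(row1) != len(row2):
        raise ValueError("codon rows of unequal length")
    table = genetic_code(code)
    S = N = Sd = Nd = 0.0
    compared = 0
    for i in range(0, len(row1), 3):
        c1, c2 = row1[i : i + 3], row2[i : i + 3]
        if c1 not in table or c2 not in table:
            continue
        if table[c1] == "*" or table[c2] == "*":
            continue
        diffs = _pathway_cached(c1, c2, code)
        if diffs is None:
            continue
        s1, n1 = _site_counts_cached(c1, code)
        s2, n2 = _site_counts_cached(c2, code)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        Sd += diffs[0]
        Nd += diffs[1]
        compared += 1
    if compared == 0:
        raise ValueError(f"no comparable codon columns between {id1!r} and {id2!r}")
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    dS = _jc(pS) if pS is not None else None
    dN = _jc(pN) if pN is not None else None
    omega = None
    # undefined ratio (pS = 0 with nonsynonymous change) reported before the
    # dN=0-or-dS=0 filter; both-zero pairs fall to the filter status
    if pS == 0 and (pN or 0) > 0:
        status = _STATUS_UNDEF
    elif dS is None or dN is None:
        status = _STATUS_SATURATED
    elif dS == 0 or dN == 0:
        status = _STATUS_FILTERED
    else:
        status = _STATUS_OK
        omega = dN / dS
    return PairwiseDnDs(
        id1=id1, id2=id2, S=S, N=N, Sd=Sd, Nd=Nd,
        pS=pS, pN=pN, dS=dS, dN=dN, omega=omega, status=status,
    )


def pairwise_matrix(aln: CodonAlignment, label: str = "") -> DnDsMatrix:
    """NG86 for every unordered pair of rows; omegas retained for status ok."""
    if len(aln.ids) < 2:
        raise ValueError("need at least 2 rows")
    pairs = []
    for i, j in itertools.combinations(range(len(aln.ids)), 2):
        pairs.append(
            ng86_pair(aln.rows[i], aln.rows[j], code=aln.code,
                      id1=aln.ids[i], id2=aln.ids[j])
        )
    return DnDsMatrix(label=label, pairs=pairs)


def matrix_to_rows(matrix: DnDsMatrix) -> list[dict]:
    """TSV-ready dict rows for a DnDsMatrix."""
    return [
        {
            "id1": p.id1, "id2": p.id2, "S": p.S, "N": p.N,
            "Sd": p.Sd, "Nd": p.Nd, "pS": p.pS, "pN": p.pN,
            "dS": p.dS, "dN": p.dN, "omega": p.omega, "status": p.status,
        }
        for p in matrix.pairs
    ]
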