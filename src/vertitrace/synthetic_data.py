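"""Synthetic-data generators with machine-readable ground truth.

Every stage of the pipeline can be exercised without downloads: genomes with
compositionally distinct inserted islands at known coordinates (emulating an
integrated prophage), codon pairs diverged under a chosen dN/dS ratio, Yule
species trees, binary traits evolved under gain/loss rates, gene trees with
one engineered tip transfer, and protein variant sets with controlled
within/between-subtype identity. Generators are pure functions of their
arguments including the seed, and each returns the truth needed to score the
corresponding inference stage.

The codon simulator is deliberately richer than the NG86 estimator (it has a
transition/transversion parameter kappa), so recovery tests probe estimator
robustness rather than a shared-model tautology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .codon_dnds import genetic_code
from .seqio import GenomeRecord

_BASES = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class IslandTruth:
    genome_id: str
    islands: tuple[tuple[int, int], ...]
    island_freqs: tuple[tuple[float, ...], ...]
    background_freqs: tuple[float, ...]


@dataclass(frozen=True)
class CodonSimParams:
    n_codons: int = 500
    t: float = 0.5  # expected substitutions per codon site along the pair path
    omega: float = 1.0
    kappa: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1 or self.t < 0 or self.omega < 0 or self.kappa <= 0:
            raise ValueError("invalid codon simulation parameters")


@dataclass
class TraitTruth:
    node_states: dict[str, int]
    events: list[tuple[str, str, str]]  # (parent id, child id, "gain"/"loss")
    q01: float
    q10: float

    @property
    def n_gains(self) -> int:
        return sum(e[2] == "gain" for e in self.events)

    @property
    def n_losses(self) -> int:
        return sum(e[2] == "loss" for e in self.events)


def sim_genome_with_islands(
    length: int,
    background_freqs=(0.14, 0.36, 0.36, 0.14),
    islands=(),
    seed: int = 0,
    genome_id: str = "synthetic",
) -> tuple[GenomeRecord, IslandTruth]:
    """Genome of i.i.d. bases with composition-shifted islands.

    ``islands`` is a list of ``(start, end, freqs)`` with disjoint, in-bounds
    0-based half-open intervals. The default background emulates a high-GC
    actinomycete chromosome (72% GC).
    """
    rng = np.random.default_rng(seed)
    intervals = sorted((s, e) for s, e, _ in islands)
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError("overlapping islands")
    for s, e, _ in islands:
        if not (0 <= s < e <= length):
            raise ValueError(f"island [{s}, {e}) out of bounds")
    bases = np.array(list(_BASES))
    seq = rng.choice(bases, size=length, p=np.asarray(background_freqs))
    for s, e, freqs in islands:
        seq[s:e] = rng.choice(bases, size=e - s, p=np.asarray(freqs))
    record = GenomeRecord(genome_id, "".join(seq))
    truth = IslandTruth(
        genome_id=genome_id,
        islands=tuple((s, e) for s, e, _ in islands),
        island_freqs=tuple(tuple(f) for _, _, f in islands),
        background_freqs=tuple(background_freqs),
    )
    return record, truth


def _codon_graph(omega: float, kappa: float):
    """Sense codons and their single-base-change rate structure."""
    table = genetic_code(1)
    sense = sorted(c for c, aa in table.items() if aa != "*")
    index = {c: i for i, c in enumerate(sense)}
    neighbors: list[list[tuple[int, float, bool]]] = []  # (target, rate, synonymous)
    for c in sense:
        row = []
        for pos in range(3):
            for b in _BASES:
                if b == c[pos]:
                    continue
                alt = c[:pos] + b + c[pos + 1 :]
                if table[alt] == "*":
                    continue
                syn = table[alt] == table[c]
                rate = (kappa if (c[pos], b) in _TRANSITIONS else 1.0) * (
                    1.0 if syn else omega
                )
                row.append((index[alt], rate, syn))
        neighbors.append(row)
    return sense, neighbors


def expected_syn_fraction(omega: float, kappa: float) -> float:
    """Expected synonymous fraction of substitutions from a uniform codon start.

    Rate-sum over the sense-codon graph; used as the oracle for the realized
    substitution classes of :func:`sim_codon_pair`.
    """
    _, neighbors = _codon_graph(omega, kappa)
    syn = tot = 0.0
    for row in neighbors:
        for _, rate, is_syn in row:
            tot += rate
            if is_syn:
                syn += rate
    return syn / tot


def sim_codon_pair(params: CodonSimParams):
    """Evolve two coding sequences from a common ancestor.

    The ancestor is drawn uniformly over sense codons; each lineage evolves
    for t/2 by an event-by-event continuous-time process on codons in which
    single-base changes have rate proportional to (kappa if transition) x
    (omega if nonsynonymous); multi-base instantaneous changes and stop
    codons are disallowed. Time is scaled so one unit is one expected
    substitution per codon at the uniform-ancestor average rate. Returns
    ``(cds1, cds2, truth)`` where truth records every substitution's class.
    """
    rng = np.random.default_rng(params.seed)
    sense, neighbors = _codon_graph(params.omega, params.kappa)
    total_rates = np.array([sum(r for _, r, _ in row) for row in neighbors])
    mean_rate = total_rates.mean()
    events = {"syn": 0, "nonsyn": 0}
    ancestor = rng.integers(0, len(sense), size=params.n_codons)

    def evolve(start_states):
        out = []
        for state in start_states:
            t_left = params.t / 2.0
            while True:
                rate = total_rates[state] / mean_rate
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if wait > t_left:
                    break
                t_left -= wait
                row = neighbors[state]
                weights = np.array([r for _, r, _ in row])
                k = rng.choice(len(row), p=weights / weights.sum())
                target, _, syn = row[k]
                events["syn" if syn else "nonsyn"] += 1
                state = target
            out.append(state)
        return out

    s1 = evolve(ancestor)
    s2 = evolve(ancestor)
    cds1 = "".join(sense[i] for i in s1)
    cds2 = "".join(sense[i] for i in s2)
    truth = {
        "n_syn_events": events["syn"],
        "n_nonsyn_events": events["nonsyn"],
        "params": params,
    }
    return cds1, cds2, truth


def sim_yule_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with n_tips; ultrametric, deterministic per seed.

    Starting from the root split (two lineages), while k lineages exist a
    waiting time Exp(k * birth_rate) elapses; a uniformly chosen lineage
    splits until n lineages exist, after which the final waiting period runs
    to the present. Root depth is therefore a sum of Exp(k*lambda) terms for
    k = 2..n.
    """
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    birth_time = {tree.seed_node: 0.0}
    active = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        birth_time[child] = 0.0
        active.append(child)
    now = 0.0
    k = 2
    while True:
        now += rng.exponential(1.0 / (k * birth_rate))
        if k == n_tips:
            break
        idx = int(rng.integers(0, len(active)))
        node = active.pop(idx)
        node.edge.length = now - birth_time[node]
        for _ in range(2):
            child = node.new_child()
            birth_time[child] = now
            active.append(child)
        k += 1
    for i, leaf in enumerate(active):
        leaf.edge.length = now - birth_time[leaf]
    # name tips in a stable left-to-right order
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"t{i + 1}")
    tree.seed_node.edge.length = None
    return tree


def sim_trait_on_tree(
    tree: dendropy.Tree,
    q01: float,
    q10: float,
    root_state: int = 0,
    seed: int = 0,
):
    """Evolve a binary trait edge-by-edge with exponential waiting times.

    Returns ``(traits, truth)``: tip states keyed by label, and a
    :class:`TraitTruth` listing every 0->1 (gain) and 1->0 (loss) flip with
    the edge it occurred on. Edges on which the state flips an even number of
    times back to its starting value contribute no event.
    """
    if q01 < 0 or q10 < 0:
        raise ValueError("rates must be >= 0")
    from .trait_evo import assign_node_ids

    rng = np.random.default_rng(seed)
    ids = assign_node_ids(tree)
    states: dict[dendropy.Node, int] = {tree.seed_node: int(root_state)}
    events: list[tuple[str, str, str]] = []
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            state = states[node]
            t_left = child.edge.length or 0.0
            while True:
                rate = q01 if state == 0 else q10
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if wait > t_left:
                    break
                t_left -= wait
                state = 1 - state
            states[child] = state
            if state != states[node]:
                events.append(
                    (ids[node], ids[child], "gain" if state == 1 else "loss")
                )
    traits = {
        lf.taxon.label: states[lf] for lf in tree.leaf_node_iter()
    }
    truth = TraitTruth(
        node_states={ids[n]: s for n, s in states.items()},
        events=events,
        q01=q01,
        q10=q10,
    )
    return traits, truth


def apply_transfer(tree: dendropy.Tree, donor_tip: str, recipient_tip: str) -> dendropy.Tree:
    """Regraft ``recipient_tip`` as sister to ``donor_tip``.

    Emulates a tip-level allele transfer: the recipient is pruned and
    re-attached at the midpoint of the donor's pendant edge; all other
    relationships are preserved. Returns a new tree.
    """
    if donor_tip == recipient_tip:
        raise ValueError("donor and recipient must differ")
    out = tree.clone(depth=1)
    labels = {lf.taxon.label for lf in out.leaf_node_iter()}
    if donor_tip not in labels or recipient_tip not in labels:
        raise ValueError("donor or recipient tip not in tree")
    out.prune_taxa_with_labels([recipient_tip], suppress_unifurcations=True)
    donor = next(
        lf for lf in out.leaf_node_iter() if lf.taxon.label == donor_tip
    )
    pend = donor.edge.length or 0.0
    parent = donor.parent_node
    joint = dendropy.Node()
    parent.remove_child(donor)
    parent.add_child(joint)
    joint.edge.length = pend / 2.0
    joint.add_child(donor)
    donor.edge.length = pend / 2.0
    recipient = dendropy.Node()
    recipient.taxon = out.taxon_namespace.get_taxon(recipient_tip) or out.taxon_namespace.new_taxon(label=recipient_tip)
    recipient.edge.length = pend / 2.0
    joint.add_child(recipient)
    return out


def _identity_to_mutation_fraction(target: float) -> float:
    """Mutation fraction x with expected pairwise identity (1-x)^2 + x^2/19."""
    if not (0.05 <= target <= 1.0):
        raise ValueError("identity target must be in [0.05, 1]")
    disc = 1.0 - (20.0 / 19.0) * (1.0 - target)
    return (1.0 - math.sqrt(disc)) * 19.0 / 20.0


def _mutate(seq: np.ndarray, fraction: float, rng) -> np.ndarray:
    out = seq.copy()
    k = int(round(fraction * len(seq)))
    if k == 0:
        return out
    pos = rng.choice(len(seq), size=k, replace=False)
    aa = np.array(list(_AA))
    for p in pos:
        choices = aa[aa != out[p]]
        out[p] = rng.choice(choices)
    return out


def sim_variant_proteins(
    base_length: int = 300,
    n_subtypes: int = 8,
    variants_per_subtype: int = 3,
    within_identity: float = 95.0,
    between_identity: float = 60.0,
    seed: int = 0,
):
    """Protein variant set with controlled within/between-subtype identity.

    Subtype ancestors are mutated from a common base protein so that
    ancestor pairs hit the between-subtype identity target; variants are
    mutated from their ancestor so that variant pairs within a subtype hit
    the within-subtype target. Returns ``(sequences, true_subtype)`` dicts
    keyed by variant id ``S<s>V<v>``.
    """
    if not (0 <= between_identity < within_identity <= 100):
        raise ValueError("need 0 <= between < within <= 100")
    rng = np.random.default_rng(seed)
    base = rng.choice(list(_AA), size=base_length)
    # identity targets are pairwise: two sequences each mutated at fraction x
    # from a common source match at (1-x)^2 + x^2/19 of positions
    f_between = _identity_to_mutation_fraction(between_identity / 100.0)
    f_within = _identity_to_mutation_fraction(within_identity / 100.0)
    seqs: dict[str, str] = {}
    truth: dict[str, int] = {}
    for s in range(1, n_subtypes + 1):
        ancestor = _mutate(base, f_between, rng)
        for v in range(1, variants_per_subtype + 1):
            variant = _mutate(ancestor, f_within, rng)
            vid = f"S{s}V{v}"
            seqs[vid] = "".join(variant)
            truth[vid] = s
    return seqs, truth
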