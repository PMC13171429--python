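"""Trait evolution on a species tree.

Covers four questions about a binary gene presence/absence character:

* **Ancestral-state reconstruction** — maximum likelihood under a 2-state
  Markov (Mk) model, either equal-rates (ER, one rate q) or all-rates-
  different (ARD, gain rate q01 and loss rate q10). The likelihood is
  computed by Felsenstein pruning with the closed-form 2-state transition
  probabilities; rates are optimized by bounded maximization; per-node
  marginal probabilities come from the standard up/down (re-rooting)
  construction.
* **Gain/loss counting** — edges whose max-marginal state labels change
  0 -> 1 (gain) or 1 -> 0 (loss); ties inherit the parent's label (root tie
  resolves to absent).
* **Origin-node inference** — the node closest to the root whose marginal
  presence probability reaches a threshold and that is ancestral to every
  present tip.
* **Relative-rate dating** — node depths as mean path length to descendant
  tips (substitutions/site), converted to ages by a substitution rate fitted
  through the origin against one or more calibration points by least
  squares; confidence intervals by refitting the rate at the calibration CI
  bounds. This is a deliberately simple relative-rate method, not a relaxed
  clock.
* **Transfer flagging** — tip-level gene-tree vs species-tree sister-set
  incongruence, with a refinement identifying transfer recipients as flagged
  tips whose removal restores full congruence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar

_RATE_LO, _RATE_HI = 1e-8, 1e4


@dataclass
class MkModel:
    """2-state Markov model: ER (q01 = q10) or ARD (independent gain/loss rates)."""

    kind: str = "ER"  # "ER" or "ARD"
    q01: float | None = None
    q10: float | None = None
    root_prior: str = "equal"  # "equal" or "stationary"

    def __post_init__(self) -> None:
        if self.kind not in ("ER", "ARD"):
            raise ValueError("model kind must be ER or ARD")
        if self.root_prior not in ("equal", "stationary"):
            raise ValueError("root prior must be equal or stationary")

    def prior(self) -> np.ndarray:
        if self.root_prior == "equal" or not (self.q01 and self.q10):
            return np.array([0.5, 0.5])
        r = self.q01 + self.q10
        return np.array([self.q10 / r, self.q01 / r])


def transition_matrix(q01: float, q10: float, t: float) -> np.ndarray:
    """Closed-form P(t) of the 2-state chain with gain rate q01, loss rate q10."""
    r = q01 + q10
    if r == 0 or t == 0:
        return np.eye(2)
    e = math.exp(-r * t)
    p0, p1 = q10 / r, q01 / r
    return np.array(
        [[p0 + p1 * e, p1 * (1 - e)], [p0 * (1 - e), p1 + p0 * e]]
    )


@dataclass
class ASRResult:
    marginals: dict[str, float]  # node id -> P(present)
    rates: dict[str, float]
    log_likelihood: float
    model: MkModel
    labels: dict[str, int]  # max-marginal state labeling
    gains: list[tuple[str, str]]  # (parent id, child id) edges 0 -> 1
    losses: list[tuple[str, str]]
    origin: str | None


@dataclass(frozen=True)
class CalibrationPoint:
    tips: tuple[str, ...]
    age: float  # Ma
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.ci is not None and not (self.ci[0] <= self.age <= self.ci[1]):
            raise ValueError("calibration age outside its CI")


@dataclass
class DatingResult:
    ages: dict[str, float]  # node id -> age in Ma
    rate: float  # substitutions/site/Ma
    age_ci: dict[str, tuple[float, float]] | None
    rate_ci: tuple[float, float] | None


@dataclass
class LgtFlag:
    tip: str
    gene_sisters: frozenset[str]
    species_sisters: frozenset[str]
    flagged: bool
    proposed_donor: frozenset[str]
    recipient_candidate: bool = False


def assign_node_ids(tree: dendropy.Tree) -> dict[dendropy.Node, str]:
    """Stable node ids: taxon label for tips, preorder ``nodeK`` for internals."""
    ids: dict[dendropy.Node, str] = {}
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            ids[node] = node.taxon.label
        else:
            ids[node] = node.label if node.label else f"node{k}"
        k += 1
    return ids


def _check_tree_traits(tree: dendropy.Tree, traits: dict[str, int]) -> None:
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = set(tips) - set(traits)
    if missing:
        raise ValueError(f"missing trait state for tips {sorted(missing)}")
    if len(tree.seed_node.child_nodes()) > 2:
        raise ValueError("tree must be rooted (basal polytomy found)")
    lengths = [e.length or 0.0 for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
    if lengths and max(lengths) == 0.0:
        raise ValueError("all branch lengths are zero; Mk likelihood degenerate")


def _postorder_partials(tree, traits, q01, q10):
    """Felsenstein pruning: conditional likelihoods of the data below each node."""
    down: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = traits[node.taxon.label]
            vec = np.zeros(2)
            vec[state] = 1.0
            down[node] = vec
        else:
            vec = np.ones(2)
            for child in node.child_nodes():
                P = transition_matrix(q01, q10, child.edge.length or 0.0)
                vec = vec * (P @ down[child])
            down[node] = vec
    return down


def mk_loglik(tree, traits, q01, q10, prior=None) -> float:
    down = _postorder_partials(tree, traits, q01, q10)
    if prior is None:
        prior = np.array([0.5, 0.5])
    like = float(prior @ down[tree.seed_node])
    if like <= 0:
        return -np.inf
    return math.log(like)


def _optimize_rates(tree, traits, model: MkModel) -> tuple[float, float, float]:
    """ML rates for the Mk model; returns (q01, q10, loglik)."""
    if model.kind == "ER":
        res = minimize_scalar(
            lambda lg: -mk_loglik(tree, traits, 10.0**lg, 10.0**lg),
            bounds=(math.log10(_RATE_LO), math.log10(_RATE_HI)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        q = 10.0 ** res.x
        return q, q, -res.fun

    def nll(lg):
        m = MkModel("ARD", 10.0 ** lg[0], 10.0 ** lg[1], model.root_prior)
        return -mk_loglik(tree, traits, m.q01, m.q10, m.prior())

    best = None
    for start in ([0.0, 0.0], [-1.0, 0.0], [0.0, -1.0]):
        res = minimize(
            nll, start, method="L-BFGS-B",
            bounds=[(math.log10(_RATE_LO), math.log10(_RATE_HI))] * 2,
        )
        if best is None or res.fun < best.fun:
            best = res
    return 10.0 ** best.x[0], 10.0 ** best.x[1], -best.fun


def _marginals(tree, traits, q01, q10, prior) -> dict[dendropy.Node, float]:
    """Marginal P(present) at every node via the up/down construction."""
    down = _postorder_partials(tree, traits, q01, q10)
    up: dict[dendropy.Node, np.ndarray] = {tree.seed_node: prior.copy()}
    out: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        joint = up[node] * down[node]
        tot = joint.sum()
        out[node] = float(joint[1] / tot) if tot > 0 else 0.5
        for child in node.child_nodes():
            # message to child: everything except child's own subtree
            msg = up[node].copy()
            for sib in node.child_nodes():
                if sib is child:
                    continue
                Ps = transition_matrix(q01, q10, sib.edge.length or 0.0)
                msg = msg * (Ps @ down[sib])
            Pc = transition_matrix(q01, q10, child.edge.length or 0.0)
            up[child] = msg @ Pc
    return out


def mk_asr(
    tree: dendropy.Tree,
    traits: dict[str, int],
    model: MkModel | None = None,
    origin_threshold: float = 0.5,
) -> ASRResult:
    """ML ancestral-state reconstruction of a binary trait on a rooted tree.

    Optimizes the model rate(s), computes per-node marginal presence
    probabilities, labels nodes by max marginal, counts gains and losses, and
    infers the origin node. Deterministic.
    """
    if model is None:
        model = MkModel("ER")
    _check_tree_traits(tree, traits)
    q01, q10, loglik = _optimize_rates(tree, traits, model)
    fitted = MkModel(model.kind, q01, q10, model.root_prior)
    node_marg = _marginals(tree, traits, q01, q10, fitted.prior())
    ids = assign_node_ids(tree)
    marginals = {ids[n]: p for n, p in node_marg.items()}
    result = ASRResult(
        marginals=marginals,
        rates={"q01": q01, "q10": q10} if model.kind == "ARD" else {"q": q01},
        log_likelihood=loglik,
        model=fitted,
        labels={},
        gains=[],
        losses=[],
        origin=None,
    )
    result.labels = _max_marginal_labels(tree, traits, marginals, ids)
    result.gains, result.losses = count_transitions(result, tree)
    result.origin = origin_node(result, tree, origin_threshold)
    return result


def _max_marginal_labels(tree, traits, marginals, ids) -> dict[str, int]:
    labels: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        nid = ids[node]
        if node.is_leaf():
            labels[nid] = traits[node.taxon.label]
            continue
        p = marginals[nid]
        if p > 0.5:
            labels[nid] = 1
        elif p < 0.5:
            labels[nid] = 0
        else:  # tie: inherit the parent's label; root tie -> absent
            parent = node.parent_node
            labels[nid] = labels[ids[parent]] if parent is not None else 0
    return labels


def count_transitions(asr: ASRResult, tree: dendropy.Tree) -> tuple[list, list]:
    """Gain (0->1) and loss (1->0) edges under the max-marginal labeling."""
    ids = assign_node_ids(tree)
    gains, losses = [], []
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            a, b = asr.labels[ids[node]], asr.labels[ids[child]]
            if (a, b) == (0, 1):
                gains.append((ids[node], ids[child]))
            elif (a, b) == (1, 0):
                losses.append((ids[node], ids[child]))
    return gains, losses


def origin_node(asr: ASRResult, tree: dendropy.Tree, threshold: float = 0.5) -> str:
    """Deepest node with P(present) above threshold ancestral to all present tips.

    The comparison is strict, so with the default threshold of 0.5 a
    maximally uncertain node (marginal exactly 1/2, as at the root of a
    symmetric half-present configuration) never claims the origin. Falls
    back (with a warning) to the MRCA of the present tips when no node
    qualifies.
    """
    ids = assign_node_ids(tree)
    present = {
        lf.taxon.label for lf in tree.leaf_node_iter() if asr.labels[lf.taxon.label] == 1
    }
    if not present:
        raise ValueError("no present tips")
    best = None
    for node in tree.preorder_node_iter():  # preorder: root first
        tips_below = {lf.taxon.label for lf in node.leaf_iter()}
        # 1e-9 guard: a marginal equal to the threshold up to optimizer noise
        # (e.g. exactly 1/2 at a symmetric root) must not qualify
        if present <= tips_below and asr.marginals[ids[node]] > threshold + 1e-9:
            best = ids[node]
            break
    if best is None:
        mrca = tree.mrca(taxon_labels=sorted(present))
        warnings.warn(
            "no node reaches the origin threshold; falling back to the MRCA "
            "of present tips",
            stacklevel=2,
        )
        best = ids[mrca]
    return best


# ---------------------------------------------------------------- dating


def _mean_path_depths(tree) -> dict[dendropy.Node, float]:
    """Mean path length (substitutions/site) from each node to its tips."""
    depth: dict[dendropy.Node, float] = {}
    ntips: dict[dendropy.Node, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            depth[node], ntips[node] = 0.0, 1
        else:
            tot = n = 0.0
            for child in node.child_nodes():
                n += ntips[child]
                tot += ntips[child] * ((child.edge.length or 0.0) + depth[child])
            depth[node], ntips[node] = tot / n, int(n)
    return depth


def date_nodes(tree: dendropy.Tree, calibrations: list[CalibrationPoint]) -> DatingResult:
    """Relative-rate dating from mean-path-length depths and calibrations.

    The substitution rate r (subs/site/Ma) is fitted by least squares through
    the origin over calibration nodes, ``r = sum(h_c a_c) / sum(a_c^2)``;
    node ages are depth/r. CIs refit r at the calibration CI bounds.
    """
    if not calibrations:
        raise ValueError("need at least one calibration")
    depths = _mean_path_depths(tree)
    ids = assign_node_ids(tree)
    cal_nodes = []
    for cal in calibrations:
        node = tree.mrca(taxon_labels=list(cal.tips))
        if node is None:
            raise ValueError(f"calibration tips {cal.tips} not found")
        if node.is_leaf():
            raise ValueError("calibration resolves to a tip")
        if depths[node] == 0:
            raise ValueError("zero-depth calibration node")
        cal_nodes.append((node, cal))

    def fit_rate(ages):
        num = sum(depths[n] * a for (n, _), a in zip(cal_nodes, ages))
        den = sum(a * a for a in ages)
        return num / den

    r = fit_rate([c.age for _, c in cal_nodes])
    ages = {ids[n]: depths[n] / r for n in depths}
    rate_ci = age_ci = None
    if all(c.ci is not None for _, c in cal_nodes):
        r_old = fit_rate([c.ci[1] for _, c in cal_nodes])  # older ages -> slower rate
        r_young = fit_rate([c.ci[0] for _, c in cal_nodes])
        rate_ci = (r_old, r_young)
        age_ci = {ids[n]: (depths[n] / r_young, depths[n] / r_old) for n in depths}
    return DatingResult(ages=ages, rate=r, age_ci=age_ci, rate_ci=rate_ci)


# ---------------------------------------------------------------- LGT flags


def _restrict(tree: dendropy.Tree, labels: set[str]) -> dendropy.Tree:
    return tree.extract_tree_with_taxa_labels(labels=sorted(labels))


def _sister_sets(tree: dendropy.Tree) -> dict[str, frozenset[str]]:
    """tip label -> tip labels of its sibling subtree(s)."""
    out: dict[str, frozenset[str]] = {}
    for leaf in tree.leaf_node_iter():
        parent = leaf.parent_node
        if parent is None:
            out[leaf.taxon.label] = frozenset()
            continue
        sibs: set[str] = set()
        for child in parent.child_nodes():
            if child is leaf:
                continue
            sibs.update(lf.taxon.label for lf in child.leaf_iter())
        out[leaf.taxon.label] = frozenset(sibs)
    return out


def lgt_flags(gene_tree: dendropy.Tree, species_tree: dendropy.Tree) -> list[LgtFlag]:
    """Tip-level incongruence flags between a gene tree and the species tree.

    The species tree is restricted to the shared tip set; a tip is flagged
    when its sister set (tips of its sibling subtree) differs between the two
    trees, with the gene-tree sister set proposed as the donor lineage. A
    flagged tip is additionally marked as a *recipient candidate* when
    pruning it from both trees removes all remaining incongruence — the
    signature of a single tip-level transfer.
    """
    gene_tips = {lf.taxon.label for lf in gene_tree.leaf_node_iter()}
    sp_tips = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    shared = gene_tips & sp_tips
    if not shared:
        raise ValueError("no shared tips between gene and species tree")
    g = _restrict(gene_tree, shared)
    s = _restrict(species_tree, shared)
    gsis = _sister_sets(g)
    ssis = _sister_sets(s)
    flags = []
    for tip in sorted(shared):
        is_flagged = gsis[tip] != ssis[tip]
        recipient = False
        if is_flagged and len(shared) > 3:
            rest = shared - {tip}
            g2, s2 = _restrict(g, rest), _restrict(s, rest)
            g2s, s2s = _sister_sets(g2), _sister_sets(s2)
            recipient = all(g2s[t] == s2s[t] for t in rest)
        flags.append(
            LgtFlag(
                tip=tip,
                gene_sisters=gsis[tip],
                species_sisters=ssis[tip],
                flagged=is_flagged,
                proposed_donor=gsis[tip] if is_flagged else frozenset(),
                recipient_candidate=recipient,
            )
        )
    return flags


def transfer_recipients(gene_tree: dendropy.Tree, species_tree: dendropy.Tree) -> list[str]:
    """Tips whose removal restores gene/species tree congruence."""
    return [f.tip for f in lgt_flags(gene_tree, species_tree) if f.recipient_candidate]
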