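"""Ancestral reconstruction of gene functionality on a rooted phylogeny.

Two reconstruction routes, mirroring the two standard approaches for
discrete characters:

* an equal-rates Markov model (Mk-ER) with k states: all transitions share
  one rate ``mu``, so the transition kernel has the closed form
  ``P_ii(t) = 1/k + (k-1)/k * exp(-k mu t)`` and
  ``P_ij(t) = 1/k * (1 - exp(-k mu t))``. Likelihoods use Felsenstein
  pruning; marginal (per-node posterior) reconstruction uses the standard
  inside/outside two-pass algorithm with a uniform root prior.

* Dollo parsimony for binary characters: the derived (non-functional)
  state arises exactly once, on the branch subtending the MRCA of all
  derived tips; reversions to the ancestral state are allowed and
  minimized. Each maximal all-ancestral subtree inside the origin clade
  receives one reversal on its stem.

The four-state degradation code can be collapsed to binary under three
schemes: "functional" (0 vs 1/2/3), "complete" (0/1 vs 2/3) and
"existing" (0/1/2 vs 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from ._model import CharacterMatrix
from .tree import Node, Tree

BINARIZATION_SCHEMES = {
    "functional": lambda s: 0 if s == 0 else 1,
    "complete": lambda s: 0 if s <= 1 else 1,
    "existing": lambda s: 0 if s <= 2 else 1,
}

MU_BOUNDS = (1e-8, 1e3)


def binarize(matrix: CharacterMatrix, scheme: str) -> CharacterMatrix:
    """Collapse the four-state matrix to binary under a named scheme."""
    try:
        fn = BINARIZATION_SCHEMES[scheme]
    except KeyError:
        raise ValueError(
            f"unknown scheme {scheme!r}; expected one of {sorted(BINARIZATION_SCHEMES)}"
        ) from None
    data = matrix.data.map(fn)
    return CharacterMatrix(data, alphabet=(0, 1))


# -- Mk equal-rates likelihood ----------------------------------------------


def er_transition_matrix(mu: float, t: float, k: int) -> np.ndarray:
    e = np.exp(-k * mu * t)
    p = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(p, 1.0 / k + (k - 1) / k * e)
    return p


def _tip_states(tree: Tree, character: Mapping[str, int] | Mapping[str, Sequence[int]], k: int):
    tips = tree.tip_labels()
    missing = set(tips) ^ set(character)
    if missing:
        raise ValueError(f"tip/taxa mismatch: {sorted(missing)}")
    states = {t: np.atleast_1d(np.asarray(character[t], dtype=int)) for t in tips}
    n_chars = {s.size for s in states.values()}
    if len(n_chars) != 1:
        raise ValueError("characters must have equal length for every taxon")
    for t, s in states.items():
        if ((s < 0) | (s >= k)).any():
            raise ValueError(f"state out of range [0, {k}) at tip {t}")
    return states, n_chars.pop()


def _warn_missing_lengths(tree: Tree) -> None:
    if tree.has_missing_lengths():
        warnings.warn("branches without lengths treated as 1.0", stacklevel=3)


def _inside_pass(tree: Tree, states, n_chars: int, mu: float, k: int):
    """Felsenstein pruning; returns per-node partials, log scalers, messages."""
    partial: dict[Node, np.ndarray] = {}
    logscale = np.zeros(n_chars)
    message: dict[Node, np.ndarray] = {}  # child -> message to its parent
    for node in tree.postorder():
        if node.is_leaf:
            lk = np.zeros((n_chars, k))
            lk[np.arange(n_chars), states[node.name]] = 1.0
        else:
            lk = np.ones((n_chars, k))
            for child in node.children:
                p = er_transition_matrix(mu, tree.branch_length(child), k)
                msg = partial[child] @ p  # ER kernel is symmetric
                message[child] = msg
                lk = lk * msg
            scale = lk.max(axis=1)
            scale[scale == 0.0] = 1.0
            lk = lk / scale[:, None]
            logscale += np.log(scale)
        partial[node] = lk
    return partial, logscale, message


def mk_er_loglik(
    tree: Tree, character: Mapping[str, int], mu: float, k: int = 2
) -> float:
    """Log-likelihood of one (or several pooled) characters under Mk-ER."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    _warn_missing_lengths(tree)
    states, n_chars = _tip_states(tree, character, k)
    partial, logscale, _ = _inside_pass(tree, states, n_chars, mu, k)
    root_lk = partial[tree.root].sum(axis=1) / k  # uniform root prior
    return float(np.sum(np.log(root_lk) + logscale))


@dataclass
class MkERFit:
    mu: float
    log_likelihood: float
    at_bound: bool


def fit_mk_er(tree: Tree, character, k: int = 2) -> MkERFit:
    """Maximum-likelihood rate by bounded scalar search on [1e-8, 1e3].

    ``character`` may map each taxon to one state or to a vector of states
    (all characters then share the fitted rate). An invariant character
    drives the rate to the lower bound, which is flagged.
    """
    _warn_missing_lengths(tree)
    states, n_chars = _tip_states(tree, character, k)

    def neg_loglik(mu: float) -> float:
        partial, logscale, _ = _inside_pass(tree, states, n_chars, mu, k)
        root_lk = partial[tree.root].sum(axis=1) / k
        val = float(np.sum(np.log(root_lk) + logscale))
        if not np.isfinite(val):
            raise ValueError(f"non-finite likelihood at mu={mu}")
        return -val

    # the likelihood flattens for large mu (independence plateau), which
    # defeats a naive golden-section over 11 decades: bracket the optimum
    # on a log-spaced grid first, then refine
    grid = np.geomspace(MU_BOUNDS[0], MU_BOUNDS[1], 45)
    values = [neg_loglik(m) for m in grid]
    i = int(np.argmin(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        neg_loglik, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    mu_hat = float(res.x)
    if values[i] < res.fun:
        mu_hat, res_fun = float(grid[i]), values[i]
    else:
        res_fun = float(res.fun)
    at_bound = mu_hat <= MU_BOUNDS[0] * 10 or mu_hat >= MU_BOUNDS[1] * 0.9
    if at_bound:
        warnings.warn("fitted rate at a search bound", stacklevel=2)
    return MkERFit(mu=mu_hat, log_likelihood=-res_fun, at_bound=at_bound)


@dataclass
class MarginalResult:
    """Per-node marginal state probabilities under Mk-ER."""

    tree: Tree
    probabilities: dict[Node, np.ndarray]
    log_likelihood: float
    mu: float
    k: int

    def at(self, tip_labels) -> np.ndarray:
        """Probability vector at the MRCA of the given tips."""
        return self.probabilities[self.tree.mrca(tip_labels)]


def marginal_ancestral(
    tree: Tree, character: Mapping[str, int], mu: float, k: int = 2
) -> MarginalResult:
    """Marginal ancestral state probabilities at every node (two-pass).

    Probabilities at each node are conditional on all tip data; tips
    recover their observed state with probability 1.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    _warn_missing_lengths(tree)
    states, n_chars = _tip_states(tree, character, k)
    if n_chars != 1:
        raise ValueError("marginal reconstruction runs one character at a time")
    partial, logscale, message = _inside_pass(tree, states, n_chars, mu, k)
    root_lk = partial[tree.root].sum(axis=1) / k
    loglik = float(np.sum(np.log(root_lk) + logscale))

    outside: dict[Node, np.ndarray] = {tree.root: np.full((1, k), 1.0 / k)}
    for node in tree.preorder():
        for child in node.children:
            pre = outside[node].copy()
            for sib in node.children:
                if sib is not child:
                    pre = pre * message[sib]
            p = er_transition_matrix(mu, tree.branch_length(child), k)
            g = pre @ p
            s = g.sum(axis=1, keepdims=True)
            outside[child] = g / np.where(s > 0, s, 1.0)

    probs: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        joint = outside[node] * partial[node]
        probs[node] = (joint / joint.sum(axis=1, keepdims=True))[0]
    return MarginalResult(tree=tree, probabilities=probs, log_likelihood=loglik, mu=mu, k=k)


# -- Dollo parsimony ---------------------------------------------------------


@dataclass
class DolloResult:
    """Single-origin reconstruction of a binary character.

    ``origin`` is the node whose stem branch carries the ancestral->derived
    change (None when no tip is derived; the root when the derived clade is
    the whole tree). ``reversals`` lists the nodes whose stems carry
    derived->ancestral changes.
    """

    tree: Tree
    node_states: dict[Node, int]
    origin: Node | None
    reversals: list[Node] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return (1 if self.origin is not None else 0) + len(self.reversals)

    def state_at(self, tip_labels) -> int:
        return self.node_states[self.tree.mrca(tip_labels)]

    def event_branches(self) -> list[tuple[str, frozenset]]:
        """(event type, tip set below the branch) pairs, reversals sorted."""
        out = []
        if self.origin is not None:
            out.append(("origin", _tipset(self.origin)))
        for r in sorted(self.reversals, key=lambda n: sorted(_tipset(n))):
            out.append(("reversal", _tipset(r)))
        return out


def _tipset(node: Node) -> frozenset:
    stack, tips = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            tips.append(n.name)
        stack.extend(n.children)
    return frozenset(tips)


def dollo_reconstruct(tree: Tree, binary_character: Mapping[str, int]) -> DolloResult:
    """Dollo reconstruction: one origin of the derived state, minimal reversals.

    The origin is placed on the branch subtending the MRCA of all derived
    tips; inside that clade every maximal subtree whose tips are all
    ancestral receives one reversal on its stem. This minimizes the number
    of reversals subject to the single-origin constraint.
    """
    tips = tree.tip_labels()
    missing = set(tips) ^ set(binary_character)
    if missing:
        raise ValueError(f"tip/taxa mismatch: {sorted(missing)}")
    values = set(binary_character.values())
    if not values <= {0, 1}:
        raise ValueError(f"character must be binary, got states {sorted(values)}")

    derived = [t for t in tips if binary_character[t] == 1]
    if not derived:
        return DolloResult(tree, {n: 0 for n in tree.postorder()}, origin=None)

    origin = tree.mrca(derived)
    in_clade: dict[Node, bool] = {}
    for node in tree.preorder():
        in_clade[node] = node is origin or (node.parent is not None and in_clade.get(node.parent, False))

    all_ancestral: dict[Node, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            all_ancestral[node] = binary_character[node.name] == 0
        else:
            all_ancestral[node] = all(all_ancestral[c] for c in node.children)

    reversals = [
        n
        for n in tree.postorder()
        if in_clade[n]
        and n is not origin
        and all_ancestral[n]
        and not all_ancestral[n.parent]
    ]

    under_reversal: dict[Node, bool] = {}
    for node in tree.preorder():
        under_reversal[node] = node in reversals or (
            node.parent is not None and under_reversal.get(node.parent, False)
        )
    node_states = {
        n: 1 if (in_clade[n] and not under_reversal[n]) else 0 for n in tree.postorder()
    }
    return DolloResult(tree, node_states, origin=origin, reversals=reversals)


def summarize_losses(
    dollo_results: Mapping[str, DolloResult], tree: Tree, node_selector: Sequence[str]
) -> int:
    """Number of genes reconstructed as derived (non-functional) at a node.

    The node is named by the tip set whose MRCA it is.
    """
    node = tree.mrca(node_selector)
    return sum(1 for res in dollo_results.values() if res.node_states[node] == 1)
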