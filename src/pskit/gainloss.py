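"""Ancestral gene-content reconstruction on a rooted tree.

The model is a two-state (absent/present) continuous-time Markov process
per gene family, with a global gain rate g (0 -> 1), loss rate l (1 -> 0)
and a Bernoulli root-presence prior.  Rates are fitted by maximum
likelihood with Felsenstein pruning, conditioning on families being
observable (present in at least one genome).  Per-branch gain/loss
posteriors come from the standard up-down (inside-outside) recursion and
are thresholded into "likely events".  A Wagner-parsimony reconstruction
(Sankoff dynamic programming with asymmetric gain cost) provides an
independent combinatorial oracle.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from skbio import TreeNode

from .orthopan import PanCategories, PanMatrix

logger = logging.getLogger(__name__)

RATE_BOUNDS = (1e-6, 60.0)
PRIOR_BOUNDS = (1e-4, 1.0 - 1e-4)


@dataclass
class EventModel:
    gain_rate: float
    loss_rate: float
    root_prior: float  # P(present at root)
    posterior_threshold: float = 0.5
    log_likelihood: float = float("nan")
    optimization_rounds: int = 100

    def validate(self) -> None:
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0 < self.posterior_threshold < 1:
            raise ValueError("posterior_threshold must lie in (0, 1)")


@dataclass
class EventProfile:
    """Per-branch inferred event counts (branches keyed by child node name)."""

    expected_gains: dict[str, float]
    expected_losses: dict[str, float]
    likely_gains: dict[str, int]
    likely_losses: dict[str, int]
    threshold: float
    by_category: pd.DataFrame | None = None

    @property
    def total_likely_gains(self) -> int:
        return sum(self.likely_gains.values())

    @property
    def total_likely_losses(self) -> int:
        return sum(self.likely_losses.values())

    @property
    def gain_loss_ratio(self) -> float:
        losses = self.total_likely_losses
        return self.total_likely_gains / losses if losses else float("inf")

    def to_frame(self) -> pd.DataFrame:
        branches = sorted(self.expected_gains)
        return pd.DataFrame(
            {
                "branch": branches,
                "expected_gains": [self.expected_gains[b] for b in branches],
                "expected_losses": [self.expected_losses[b] for b in branches],
                "likely_gains": [self.likely_gains[b] for b in branches],
                "likely_losses": [self.likely_losses[b] for b in branches],
            }
        )


# ---------------------------------------------------------------------------
# Transition machinery
# ---------------------------------------------------------------------------


def transition_matrix(t: float, gain: float, loss: float) -> np.ndarray:
    """Closed-form two-state CTMC transition matrix over branch length t."""
    r = gain + loss
    if r <= 0 or t <= 0:
        return np.eye(2)
    decay = np.exp(-r * t)
    p01 = (gain / r) * (1.0 - decay)
    p10 = (loss / r) * (1.0 - decay)
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


def _prepare(tree: TreeNode) -> tuple[list[TreeNode], dict[str, TreeNode]]:
    """Name anonymous internal nodes and return postorder + lookup."""
    counter = 0
    for node in tree.preorder():
        if not node.name:
            counter += 1
            node.name = f"gl{counter}"
    nodes = list(tree.postorder())
    return nodes, {n.name: n for n in nodes}


def _leaf_matrix(pan: PanMatrix, tree: TreeNode) -> tuple[np.ndarray, list[str]]:
    leaves = [t.name for t in tree.tips()]
    missing = set(leaves) - set(pan.genomes)
    if missing:
        raise ValueError(f"tree leaves absent from pan matrix: {sorted(missing)}")
    pres = pan.presence()
    data = np.stack([pres[leaf].to_numpy() for leaf in leaves], axis=0)
    return data.astype(int), leaves


def _pruning_partials(
    tree: TreeNode, leaf_states: dict[str, np.ndarray], gain: float, loss: float
) -> dict[str, np.ndarray]:
    """Downward (inside) partial likelihoods D[node][state, family]."""
    n_fam = next(iter(leaf_states.values())).shape[0]
    partials: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip():
            d = np.zeros((2, n_fam))
            d[leaf_states[node.name], np.arange(n_fam)] = 1.0
            partials[node.name] = d
        else:
            d = np.ones((2, n_fam))
            for child in node.children:
                p = transition_matrix(float(child.length or 0.0), gain, loss)
                d *= p @ partials[child.name]
            partials[node.name] = d
    return partials


def log_likelihood(
    pan: PanMatrix, tree: TreeNode, model: EventModel, condition_observable: bool = True
) -> float:
    """Pruning log-likelihood of the presence matrix, summed over families.

    With ``condition_observable`` the per-family likelihood is divided by
    the probability that a family is present in at least one genome,
    correcting for the fact that all-absent families cannot be observed.
    """
    model.validate()
    _prepare(tree)
    data, leaves = _leaf_matrix(pan, tree)
    leaf_states = {leaf: data[i] for i, leaf in enumerate(leaves)}
    partials = _pruning_partials(tree, leaf_states, model.gain_rate, model.loss_rate)
    pi = np.array([1.0 - model.root_prior, model.root_prior])
    fam_lik = pi @ partials[tree.name]
    ll = float(np.sum(np.log(np.clip(fam_lik, 1e-300, None))))
    if condition_observable:
        zero_states = {leaf: np.zeros(1, dtype=int) for leaf in leaves}
        zero_part = _pruning_partials(tree, zero_states, model.gain_rate, model.loss_rate)
        p_empty = float((pi @ zero_part[tree.name])[0])
        ll -= data.shape[1] * np.log(max(1.0 - p_empty, 1e-300))
    return ll


def fit_rates(
    pan: PanMatrix,
    tree: TreeNode,
    posterior_threshold: float = 0.5,
    rounds: int = 100,
    tol: float = 1e-6,
) -> EventModel:
    """Maximum-likelihood gain/loss rates and root prior.

    Coordinate-wise bounded scalar optimization (rates on a log scale),
    iterated up to `rounds` passes or until the log-likelihood stalls.
    A fit driven to the lower rate boundary is reported with a warning
    rather than treated as failure.
    """
    params = {"gain": 0.5, "loss": 0.5, "prior": 0.5}

    def objective_for(name: str, current: dict[str, float]):
        def f(x: float) -> float:
            trial = dict(current)
            trial[name] = 10 ** x if name != "prior" else x
            model = EventModel(trial["gain"], trial["loss"], trial["prior"],
                               posterior_threshold)
            return -log_likelihood(pan, tree, model)
        return f

    last = np.inf
    lo, hi = np.log10(RATE_BOUNDS[0]), np.log10(RATE_BOUNDS[1])
    for _ in range(rounds):
        for name in ("gain", "loss", "prior"):
            bounds = PRIOR_BOUNDS if name == "prior" else (lo, hi)
            res = minimize_scalar(
                objective_for(name, params), bounds=bounds, method="bounded",
                options={"xatol": 1e-4},
            )
            params[name] = res.x if name == "prior" else 10 ** res.x
        if abs(last - res.fun) < tol:
            last = res.fun
            break
        last = res.fun
    if params["loss"] <= RATE_BOUNDS[0] * 10 or params["gain"] <= RATE_BOUNDS[0] * 10:
        logger.warning("a rate was driven to the lower boundary (frozen content?)")
    model = EventModel(params["gain"], params["loss"], params["prior"],
                       posterior_threshold, log_likelihood=-last, optimization_rounds=rounds)
    return model


# ---------------------------------------------------------------------------
# Posterior event profiles
# ---------------------------------------------------------------------------


def branch_posteriors(
    pan: PanMatrix, tree: TreeNode, model: EventModel
) -> dict[str, pd.DataFrame]:
    """Per-family posterior gain/loss probabilities for every branch.

    For the branch above node c with parent v:
    gain posterior  = P(X_v = 0, X_c = 1 | data),
    loss posterior  = P(X_v = 1, X_c = 0 | data),
    computed by the up-down recursion.  Returns
    {"gain": DataFrame(branch x family), "loss": ...}.
    """
    model.validate()
    _prepare(tree)
    data, leaves = _leaf_matrix(pan, tree)
    leaf_states = {leaf: data[i] for i, leaf in enumerate(leaves)}
    g, l = model.gain_rate, model.loss_rate
    down = _pruning_partials(tree, leaf_states, g, l)
    pi = np.array([1.0 - model.root_prior, model.root_prior])
    fam_lik = pi @ down[tree.name]
    fam_lik = np.clip(fam_lik, 1e-300, None)

    # upward (outside) pass: up[node][state, family] = P(data outside
    # subtree(node), X_node = state)
    up: dict[str, np.ndarray] = {tree.name: np.tile(pi[:, None], (1, data.shape[1]))}
    for node in tree.preorder():
        if node.is_tip():
            continue
        for child in node.children:
            sib_prod = np.ones_like(down[node.name])
            for sib in node.children:
                if sib is child:
                    continue
                p_s = transition_matrix(float(sib.length or 0.0), g, l)
                sib_prod *= p_s @ down[sib.name]
            h_v = up[node.name] * sib_prod  # (2, F)
            p_c = transition_matrix(float(child.length or 0.0), g, l)
            up[child.name] = p_c.T @ h_v

    branches = [n.name for n in tree.preorder() if n is not tree]
    fams = pan.families
    gain_post = np.zeros((len(branches), len(fams)))
    loss_post = np.zeros((len(branches), len(fams)))
    by_name = {n.name: n for n in tree.traverse()}
    for bi, bname in enumerate(branches):
        child = by_name[bname]
        parent = child.parent
        p_c = transition_matrix(float(child.length or 0.0), g, l)
        sib_prod = np.ones_like(down[parent.name])
        for sib in parent.children:
            if sib is child:
                continue
            p_s = transition_matrix(float(sib.length or 0.0), g, l)
            sib_prod *= p_s @ down[sib.name]
        h_v = up[parent.name] * sib_prod  # (2, F): outside + siblings at parent
        # joint(parent=a, child=b) = h_v[a] * P[a,b] * down_child[b]
        gain_post[bi] = h_v[0] * p_c[0, 1] * down[bname][1] / fam_lik
        loss_post[bi] = h_v[1] * p_c[1, 0] * down[bname][0] / fam_lik
    return {
        "gain": pd.DataFrame(gain_post, index=branches, columns=fams),
        "loss": pd.DataFrame(loss_post, index=branches, columns=fams),
    }


def likely_events(
    posteriors: dict[str, pd.DataFrame],
    threshold: float = 0.5,
    categories: PanCategories | None = None,
) -> EventProfile:
    """Threshold posteriors into likely per-branch event counts.

    When `categories` is given, likely events are additionally attributed
    to pan-genome frequency categories (gains concentrate in shell/cloud
    on gain-dominated histories).
    """
    gain, loss = posteriors["gain"], posteriors["loss"]
    expected_g = gain.sum(axis=1).to_dict()
    expected_l = loss.sum(axis=1).to_dict()
    likely_g = (gain > threshold).sum(axis=1).astype(int).to_dict()
    likely_l = (loss > threshold).sum(axis=1).astype(int).to_dict()
    by_cat = None
    if categories is not None:
        rows = []
        cats = categories.labels
        for cat in sorted(cats.unique()):
            fams = [f for f in gain.columns if cats.get(f) == cat]
            rows.append(
                (
                    cat,
                    int((gain[fams] > threshold).to_numpy().sum()),
                    int((loss[fams] > threshold).to_numpy().sum()),
                )
            )
        by_cat = pd.DataFrame(rows, columns=["category", "likely_gains", "likely_losses"])
    return EventProfile(expected_g, expected_l, likely_g, likely_l, threshold, by_cat)


# ---------------------------------------------------------------------------
# Wagner parsimony oracle
# ---------------------------------------------------------------------------


def wagner_parsimony(
    pan: PanMatrix, tree: TreeNode, gain_penalty: float = 2.0
) -> dict[str, tuple[int, int]]:
    """Sankoff minimal-cost ancestral presence/absence reconstruction.

    cost(gain) = gain_penalty, cost(loss) = 1.  Ties prefer absence at the
    root and, below it, retaining the parent state.  Returns per-branch
    (gain_count, loss_count) keyed by child node name.
    """
    _prepare(tree)
    data, leaves = _leaf_matrix(pan, tree)
    leaf_idx = {leaf: i for i, leaf in enumerate(leaves)}
    n_fam = data.shape[1]
    trans_cost = np.array([[0.0, gain_penalty], [1.0, 0.0]])  # [from, to]

    cost: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip():
            c = np.full((2, n_fam), np.inf)
            states = data[leaf_idx[node.name]]
            c[states, np.arange(n_fam)] = 0.0
            cost[node.name] = c
        else:
            c = np.zeros((2, n_fam))
            for child in node.children:
                child_cost = cost[child.name]
                # min over child state of transition + subtree cost
                opts = trans_cost[:, :, None] + child_cost[None, :, :]
                c += opts.min(axis=1)
            cost[node.name] = c

    events: dict[str, tuple[int, int]] = {
        n.name: (0, 0) for n in tree.preorder() if n is not tree
    }
    root_cost = cost[tree.name]
    # tie-break: absence preferred at the root
    root_state = np.where(root_cost[0] <= root_cost[1], 0, 1)
    states: dict[str, np.ndarray] = {tree.name: root_state}
    for node in tree.preorder():
        if node is tree:
            continue
        parent_state = states[node.parent.name]
        child_cost = cost[node.name]
        opts = trans_cost[parent_state, :] + child_cost.T  # (F, 2)
        # tie-break: keep the parent state when costs are equal
        pick = np.where(
            np.isclose(opts[:, 0], opts[:, 1]),
            parent_state,
            opts.argmin(axis=1),
        )
        gains = int(np.sum((parent_state == 0) & (pick == 1)))
        losses = int(np.sum((parent_state == 1) & (pick == 0)))
        events[node.name] = (gains, losses)
        states[node.name] = pick
    return events


def enumerate_likelihood(
    pan: PanMatrix, tree: TreeNode, model: EventModel
) -> float:
    """Brute-force likelihood by summing over all internal-state
    combinations; exponential in internal node count (oracle for tests)."""
    _prepare(tree)
    data, leaves = _leaf_matrix(pan, tree)
    internal = [n for n in tree.postorder() if not n.is_tip()]
    pi = np.array([1.0 - model.root_prior, model.root_prior])
    total_ll = 0.0
    for fi in range(data.shape[1]):
        leaf_state = {leaf: int(data[i, fi]) for i, leaf in enumerate(leaves)}
        lik = 0.0
        for states in itertools.product((0, 1), repeat=len(internal)):
            assign = {n.name: s for n, s in zip(internal, states)}
            assign.update(leaf_state)
            p = pi[assign[tree.name]]
            for node in tree.preorder():
                if node is tree:
                    continue
                pm = transition_matrix(
                    float(node.length or 0.0), model.gain_rate, model.loss_rate
                )
                p *= pm[assign[node.parent.name], assign[node.name]]
            lik += p
        total_ll += np.log(max(lik, 1e-300))
    return float(total_ll)
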