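"""Synthetic trees, predictors and responses with the statistical structure
the comparative analysis assumes.

The generator emulates the shape of the real data: a rooted ultrametric tree,
one ordinal predictor (clutch size, coded 1/2) plus three binary predictors
on its tips, and a continuous response built as X beta plus Brownian-motion
noise whose covariance is the lambda-transformed tree covariance.  Everything
is seeded: one root seed fans out to independent substreams for the tree, the
predictors and the noise, so changing the predictor model never perturbs the
tree draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import CovMatrix, PhyloTree, TreeSample, _Node, vcv_matrix
from .pgls import lambda_transform

__all__ = [
    "SimulationConfig",
    "simulate_yule_tree",
    "simulate_bm_traits",
    "simulate_regression_dataset",
    "simulate_tree_sample",
]

PREDICTORS = ("clutch_size", "foraging", "activity", "nest")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated comparative dataset.

    ``predictor_model`` maps predictor name to a probability: for
    ``clutch_size`` the probability of a two-egg clutch (values coded 1/2),
    for the binary predictors the probability of a 1.  ``true_beta`` is
    (intercept, clutch_size, foraging, activity, nest) in response units.
    """

    n_tips: int = 100
    birth_rate: float = 1.0
    true_lambda: float = 1.0
    true_beta: tuple[float, ...] = (0.0, -8.0, 2.0, -3.5, -4.0)
    sigma2: float = 25.0
    predictor_model: dict[str, float] = field(
        default_factory=lambda: {
            "clutch_size": 0.5,
            "foraging": 0.5,
            "activity": 0.5,
            "nest": 0.5,
        }
    )
    seed: int = 0
    n_replicates: int = 1
    phylo_predictors: bool = False

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if not 0.0 <= self.true_lambda <= 1.0:
            raise ValueError("true_lambda must be in [0, 1]")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if len(self.true_beta) != 1 + len(PREDICTORS):
            raise ValueError(
                f"true_beta must have {1 + len(PREDICTORS)} entries "
                "(intercept + predictors)"
            )
        for name, p in self.predictor_model.items():
            if name not in PREDICTORS:
                raise ValueError(f"unknown predictor {name!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {name!r} outside [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int | np.random.Generator = 0
) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_tips`` leaves, labelled t1..tn.

    Starting from two lineages at the root, waiting times between speciation
    events are Exponential(k * birth_rate) while k lineages are extant and
    the splitting lineage is chosen uniformly; after the n-th lineage appears
    the tree is cut one further exponential waiting time later, so the
    expected depth is sum_{k=2..n} 1 / (k * birth_rate).  The result is
    rooted and exactly ultrametric.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    root = _Node()
    # active lineages as (node, birth_time of its subtending edge's origin)
    t = 0.0
    active: list[tuple[_Node, float]] = []
    for _ in range(2):
        c = _Node()
        root.children.append(c)
        active.append((c, 0.0))
    label_counter = 1

    while True:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        if k == n_tips:
            break
        i = rng.integers(k)
        node, born = active.pop(i)
        node.length = t - born
        for _ in range(2):
            c = _Node()
            node.children.append(c)
            active.append((c, t))
    for node, born in active:
        node.length = t - born
        node.label = f"t{label_counter}"
        label_counter += 1
    return PhyloTree(root)


def _covariance_factor(S: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Cholesky factor, falling back to a clipped eigen-factor when singular."""
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(S)
        if np.min(w) < -tol * max(np.max(w), 1.0):
            raise np.linalg.LinAlgError(
                f"covariance has negative eigenvalue {np.min(w):.3g}"
            ) from None
        return U * np.sqrt(np.clip(w, 0.0, None))


def simulate_bm_traits(
    tree: PhyloTree,
    lam: float = 1.0,
    sigma2: float = 1.0,
    seed: int | np.random.Generator = 0,
    n_draws: int = 1,
) -> pd.DataFrame:
    """Draws from N(0, sigma2 * V(lambda)) over the tips of ``tree``.

    Returns a DataFrame with one column per leaf label (canonical order) and
    one row per draw.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    V = lambda_transform(vcv_matrix(tree), lam)
    F = _covariance_factor(sigma2 * V.values)
    Z = rng.standard_normal((n_draws, len(V.labels)))
    return pd.DataFrame(Z @ F.T, columns=list(V.labels))


def simulate_regression_dataset(
    config: SimulationConfig,
) -> tuple[PhyloTree, pd.DataFrame, dict]:
    """One synthetic comparative dataset.

    Returns ``(tree, traits, truth)``: the Yule tree, a trait table in the
    pipeline's delimited layout (species, response, predictors), and the
    generating parameters for recovery scoring.  Predictors are redrawn (up
    to 100 times) if any comes out constant across tips, which would make the
    design rank deficient.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_tree, rng_pred, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    tree = simulate_yule_tree(config.n_tips, config.birth_rate, rng_tree)
    labels = list(tree.leaf_labels)
    n = len(labels)

    V = lambda_transform(vcv_matrix(tree), config.true_lambda)

    def draw_predictors() -> pd.DataFrame:
        cols = {}
        for name in PREDICTORS:
            p = config.predictor_model.get(name, 0.5)
            if config.phylo_predictors:
                # threshold a latent Brownian trait at its median ->
                # phylogenetically autocorrelated 0/1 with marginal ~0.5
                z = simulate_bm_traits(tree, 1.0, 1.0, rng_pred).iloc[0].values
                x = (z > np.median(z)).astype(int)
            else:
                x = (rng_pred.random(n) < p).astype(int)
            if name == "clutch_size":
                x = x + 1
            cols[name] = x
        return pd.DataFrame(cols, index=labels)

    for _attempt in range(100):
        P = draw_predictors()
        if all(P[c].nunique() > 1 for c in PREDICTORS):
            break
    else:
        raise RuntimeError(
            "could not draw non-degenerate predictors in 100 attempts"
        )

    X = np.column_stack(
        [np.ones(n)] + [P[c].to_numpy(float) for c in PREDICTORS]
    )
    beta = np.asarray(config.true_beta, float)
    F = _covariance_factor(config.sigma2 * V.values)
    noise = F @ rng_noise.standard_normal(n)
    y = X @ beta + noise

    traits = pd.DataFrame({"species": labels, "edp_residual": y})
    for c in PREDICTORS:
        traits[c] = P[c].to_numpy()
    truth = {
        "true_lambda": config.true_lambda,
        "true_beta": tuple(beta),
        "sigma2": config.sigma2,
        "seed": config.seed,
        "n_tips": config.n_tips,
        "birth_rate": config.birth_rate,
    }
    return tree, traits, truth


def write_truth_sidecar(truth: dict, path: str) -> None:
    """Write the generating parameters as a key = value sidecar file."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in truth.items():
            fh.write(f"{key} = {val}\n")


def simulate_tree_sample(
    base_tree: PhyloTree,
    n_trees: int,
    perturb_prob: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> TreeSample:
    """Copies of ``base_tree`` with random nearest-neighbour interchanges.

    Each internal edge (an edge both of whose endpoints are internal nodes)
    is independently perturbed with probability ``perturb_prob`` by swapping
    a random child of its lower node with a random sibling subtree.  Branch
    lengths travel with their subtrees, so perturbed trees are generally no
    longer ultrametric; the sample is meant for consensus-building tests.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if not 0.0 <= perturb_prob <= 1.0:
        raise ValueError("perturb_prob must be in [0, 1]")
    if perturb_prob > 0 and base_tree.n_leaves < 4:
        raise ValueError("NNI perturbation needs at least 4 leaves")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    trees = []
    for _ in range(n_trees):
        root = base_tree.root.clone()
        if perturb_prob > 0:
            _nni_pass(root, perturb_prob, rng)
        trees.append(PhyloTree(root))
    return TreeSample(trees)


def _nni_pass(root: _Node, p: float, rng: np.random.Generator) -> None:
    # collect internal edges as (parent, child) pairs, then perturb each
    # with probability p
    edges: list[tuple[_Node, _Node]] = []

    def collect(n: _Node) -> None:
        for c in n.children:
            if not c.is_leaf:
                edges.append((n, c))
                collect(c)

    collect(root)

    def iindex(nodes, target):
        return next(i for i, n in enumerate(nodes) if n is target)

    for parent, child in edges:
        if rng.random() >= p:
            continue
        # earlier swaps may have relocated this edge; skip stale entries
        if not any(c is child for c in parent.children):
            continue
        siblings = [c for c in parent.children if c is not child]
        if not siblings or not child.children:
            continue
        s = siblings[int(rng.integers(len(siblings)))]
        g = child.children[int(rng.integers(len(child.children)))]
        parent.children[iindex(parent.children, s)] = g
        child.children[iindex(child.children, g)] = s
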