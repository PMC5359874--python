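"""Likelihoods for discrete characters under Mk variants and GTR+Gamma.

The symmetric k-state Markov model (Mk) treats all state changes as
equally likely; its one-parameter binary special case ("Mk1") and the
asymmetric two-parameter binary model ("aMk2", independent gain and
loss rates) are the models used for ancestral-state reconstruction of
skeletal characters.  Branch lengths are in expected substitutions, so
the symmetric model's single rate ``q`` is the total leaving rate of a
state.  Among-character rate variation uses the standard discrete gamma
with equal-probability classes represented by their class means.

Because morphological matrices are assembled from variable (or strictly
parsimony-informative) characters only, likelihoods can be conditioned
on that ascertainment: the probability of the excluded patterns
(constant, or constant plus single-taxon autapomorphies) is computed by
pruning with indicator tips and divided out.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize
from scipy.special import gammainc, logsumexp

from glasstree.matrix_io import CharacterMatrix
from glasstree.parsimony_engine import _leaf_row_map

__all__ = [
    "AscertainmentMode",
    "FitResult",
    "GtrModel",
    "MkModel",
    "discrete_gamma_rates",
    "excluded_pattern_probability",
    "optimize_model",
    "per_character_loglik",
    "pruning_loglik",
    "transition_probabilities",
]

#: Valid ascertainment-correction modes.
AscertainmentMode = ("none", "variable-only", "informative-only")

_RATE_BOUNDS = (1e-6, 100.0)
_SHAPE_BOUNDS = (1e-2, 100.0)


@dataclass
class MkModel:
    """Symmetric k-state or asymmetric 2-state Markov model.

    ``q`` is the total rate of leaving a state (symmetric mode);
    ``q01``/``q10`` are the 0->1 and 1->0 rates (asymmetric mode, which
    requires ``k == 2``).  ``root_prior`` is ``"equilibrium"`` (default;
    the stationary distribution), ``"equal"``, or an explicit vector.
    """

    k: int = 2
    mode: str = "symmetric"  # symmetric | asymmetric
    q: float = 1.0
    q01: float = 1.0
    q10: float = 1.0
    gamma_shape: float | None = None
    n_categories: int = 4
    root_prior: object = "equilibrium"

    def __post_init__(self) -> None:
        if self.mode not in ("symmetric", "asymmetric"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "asymmetric" and self.k != 2:
            raise ValueError("asymmetric mode requires k = 2")
        if self.mode == "symmetric" and self.q <= 0:
            raise ValueError("rate q must be positive")
        if self.mode == "asymmetric" and (self.q01 <= 0 or self.q10 <= 0):
            raise ValueError("rates q01, q10 must be positive")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    def stationary(self) -> np.ndarray:
        if self.mode == "symmetric":
            return np.full(self.k, 1.0 / self.k)
        total = self.q01 + self.q10
        return np.array([self.q10 / total, self.q01 / total])

    def root_distribution(self) -> np.ndarray:
        if isinstance(self.root_prior, str):
            if self.root_prior == "equilibrium":
                return self.stationary()
            if self.root_prior == "equal":
                return np.full(self.k, 1.0 / self.k)
            raise ValueError(f"unknown root prior {self.root_prior!r}")
        prior = np.asarray(self.root_prior, dtype=float)
        if prior.shape != (self.k,) or not np.isclose(prior.sum(), 1.0):
            raise ValueError("root prior vector must have length k and sum to 1")
        return prior


@dataclass
class GtrModel:
    """General-time-reversible nucleotide model with discrete gamma.

    The rate matrix is normalized to one expected substitution per unit
    branch length at stationarity.
    """

    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6)
    )  # AC, AG, AT, CG, CT, GT
    base_freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    gamma_shape: float | None = None
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if (self.exchangeabilities <= 0).any():
            raise ValueError("exchangeabilities must be positive")
        if not np.isclose(self.base_freqs.sum(), 1.0):
            raise ValueError("base frequencies must sum to 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    @property
    def k(self) -> int:
        return 4

    def stationary(self) -> np.ndarray:
        return self.base_freqs

    def root_distribution(self) -> np.ndarray:
        return self.base_freqs

    def rate_matrix(self) -> np.ndarray:
        a, b, c, d, e, f = self.exchangeabilities
        pi = self.base_freqs
        rates = np.array(
            [
                [0, a, b, c],
                [a, 0, d, e],
                [b, d, 0, f],
                [c, e, f, 0],
            ]
        )
        q = rates * pi[None, :]
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        return q / scale


def discrete_gamma_rates(shape: float, n_categories: int = 4) -> np.ndarray:
    """Mean rates of equal-probability discrete gamma classes (mean 1)."""
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    edges = np.linspace(0, 1, n_categories + 1)
    from scipy.stats import gamma as gamma_dist

    cuts = gamma_dist.ppf(edges, a=shape, scale=1.0 / shape)
    upper = gammainc(shape + 1, cuts[1:] * shape)
    lower = gammainc(shape + 1, cuts[:-1] * shape)
    return n_categories * (upper - lower)


def _category_rates(model) -> np.ndarray:
    if model.gamma_shape is None:
        return np.array([1.0])
    return discrete_gamma_rates(model.gamma_shape, model.n_categories)


def transition_probabilities(model, t: float) -> np.ndarray:
    """k x k transition-probability matrix over a branch of length ``t``.

    Symmetric k-state: ``p_stay(t) = 1/k + (k-1)/k * exp(-k*mu*t)`` with
    per-pair rate ``mu = q/(k-1)`` so the total leaving rate is ``q``.
    Asymmetric 2-state: ``p_00(t) = pi_0 + pi_1 * exp(-(q01+q10) t)``
    with ``pi_0 = q10/(q01+q10)``.  GTR uses the spectral decomposition
    of the normalized rate matrix.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if isinstance(model, GtrModel):
        q = model.rate_matrix()
        pi = model.base_freqs
        sqrt_pi = np.sqrt(pi)
        sym = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        vals, vecs = eigh(sym)
        inner = (vecs * np.exp(vals * t)) @ vecs.T
        p = inner / sqrt_pi[:, None] * sqrt_pi[None, :]
        return np.clip(p, 0.0, None)
    k = model.k
    if model.mode == "symmetric":
        mu = model.q / (k - 1)
        decay = np.exp(-k * mu * t)
        p = np.full((k, k), (1.0 - decay) / k)
        np.fill_diagonal(p, 1.0 / k + (k - 1) / k * decay)
        return p
    total = model.q01 + model.q10
    pi0 = model.q10 / total
    pi1 = model.q01 / total
    decay = np.exp(-total * t)
    return np.array(
        [
            [pi0 + pi1 * decay, pi1 - pi1 * decay],
            [pi0 - pi0 * decay, pi1 + pi0 * decay],
        ]
    )


# ---------------------------------------------------------------------------
# pruning


def _edge_length(node: dendropy.Node, unit_branch_lengths: bool) -> float:
    if unit_branch_lengths:
        return 1.0
    length = node.edge.length
    if length is None:
        raise ValueError(
            "tree has branches without lengths; pass unit_branch_lengths=True "
            "to adopt the all-unit convention used for parsimony trees"
        )
    if length < 0:
        raise ValueError("negative branch length")
    return float(length)


def _prune_loglik(
    tree: dendropy.Tree,
    leaf_partials: dict,
    model,
    unit_branch_lengths: bool,
) -> np.ndarray:
    """Per-item log-likelihood via Felsenstein pruning with scaling.

    ``leaf_partials`` maps each leaf node to an ``(n_items, k)`` partial
    array (one-hot for observed states, all-ones for missing).  Gamma
    categories are averaged with equal weights in likelihood space.
    """
    rates = _category_rates(model)
    prior = model.root_distribution()
    n_items = next(iter(leaf_partials.values())).shape[0]
    per_category = np.empty((len(rates), n_items))
    order = list(tree.postorder_node_iter())
    for ci, rate in enumerate(rates):
        partials: dict = {}
        logscale = np.zeros(n_items)
        for node in order:
            if node.is_leaf():
                partials[node] = leaf_partials[node]
                continue
            product = np.ones((n_items, model.k))
            for child in node.child_nodes():
                t = _edge_length(child, unit_branch_lengths) * rate
                p = transition_probabilities(model, t)
                product = product * (partials.pop(child) @ p.T)
            peak = product.max(axis=1)
            safe = np.where(peak > 0, peak, 1.0)
            product = product / safe[:, None]
            logscale += np.where(peak > 0, np.log(safe), -np.inf)
            partials[node] = product
        site = partials[order[-1]] @ prior
        with np.errstate(divide="ignore"):
            per_category[ci] = np.log(site) + logscale
    return logsumexp(per_category, axis=0) - np.log(len(rates))


def _matrix_leaf_partials(tree, matrix: CharacterMatrix, k: int) -> dict:
    mapping = _leaf_row_map(tree, matrix)
    enc, symbols = matrix.encoded()
    if len(symbols) > k:
        raise ValueError(f"matrix has {len(symbols)} states but model has k={k}")
    partials = {}
    for leaf, row in mapping.items():
        states = enc[row]
        part = np.zeros((matrix.n_characters, k))
        part[states < 0, :] = 1.0
        observed = np.flatnonzero(states >= 0)
        part[observed, states[observed]] = 1.0
        partials[leaf] = part
    return partials


def per_character_loglik(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    model,
    unit_branch_lengths: bool = False,
) -> np.ndarray:
    """Uncorrected per-character log-likelihoods by pruning."""
    partials = _matrix_leaf_partials(tree, matrix, model.k)
    return _prune_loglik(tree, partials, model, unit_branch_lengths)


def excluded_pattern_probability(
    tree: dendropy.Tree,
    model,
    mode: str,
    unit_branch_lengths: bool = False,
) -> float:
    """Probability mass of the patterns an ascertained matrix excludes.

    ``variable-only`` sums the probabilities of the k constant leaf
    patterns; ``informative-only`` adds every singleton pattern (exactly
    one leaf differing from an otherwise constant background).  Each
    pattern probability is computed by pruning with indicator tips.
    """
    if mode not in AscertainmentMode:
        raise ValueError(f"unknown ascertainment mode {mode!r}")
    if mode == "none":
        raise ValueError("no correction requested; caller should skip")
    leaves = list(tree.leaf_node_iter())
    k = model.k
    patterns: list[dict] = []
    for s in range(k):
        patterns.append({leaf: s for leaf in leaves})
    if mode == "informative-only" and len(leaves) > 2:
        for leaf in leaves:
            for background in range(k):
                for deviant in range(k):
                    if deviant == background:
                        continue
                    pattern = {other: background for other in leaves}
                    pattern[leaf] = deviant
                    patterns.append(pattern)
    n_patterns = len(patterns)
    leaf_partials = {}
    for leaf in leaves:
        part = np.zeros((n_patterns, k))
        for i, pattern in enumerate(patterns):
            part[i, pattern[leaf]] = 1.0
        leaf_partials[leaf] = part
    logp = _prune_loglik(tree, leaf_partials, model, unit_branch_lengths)
    return float(np.exp(logsumexp(logp)))


def pruning_loglik(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    model,
    ascertainment: str = "none",
    unit_branch_lengths: bool = False,
) -> float:
    """Total log-likelihood, optionally ascertainment-corrected.

    Under correction the per-character likelihoods are conditioned on
    the character being observable:
    ``logL = sum_i log L_i - n * log(1 - P_excluded)``.
    """
    per_char = per_character_loglik(tree, matrix, model, unit_branch_lengths)
    total = float(per_char.sum())
    if ascertainment != "none":
        p_excluded = excluded_pattern_probability(tree, model, ascertainment, unit_branch_lengths)
        total -= matrix.n_characters * np.log1p(-p_excluded)
    return total


# ---------------------------------------------------------------------------
# optimization


@dataclass
class FitResult:
    """Outcome of a bounded multi-start likelihood optimization."""

    model: object
    loglik: float
    converged: bool
    n_evaluations: int
    free_parameters: tuple


def _get_param(model, name: str) -> float:
    return getattr(model, name)


def optimize_model(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    model,
    free_parameters: tuple = ("q",),
    ascertainment: str = "none",
    seed: int = 0,
    n_starts: int = 3,
    unit_branch_lengths: bool = False,
) -> FitResult:
    """Fit free rate/shape parameters by bounded maximum likelihood.

    Derivative-free (Nelder-Mead) optimization on the log-parameter
    scale with multiple seeded starts; rates are bounded to
    ``[1e-6, 100]`` and gamma shape to ``[1e-2, 100]``.  Deterministic
    given ``seed``.  Non-convergence is flagged, never silent.
    """
    if not free_parameters:
        raise ValueError("need at least one free parameter")
    rng = np.random.default_rng(seed)
    bounds = []
    for name in free_parameters:
        lo, hi = _SHAPE_BOUNDS if name == "gamma_shape" else _RATE_BOUNDS
        bounds.append((np.log(lo), np.log(hi)))
    bounds = np.array(bounds)

    evaluations = 0

    def negloglik(log_params: np.ndarray) -> float:
        nonlocal evaluations
        evaluations += 1
        updates = {}
        for name, value in zip(free_parameters, np.exp(log_params)):
            updates[name] = float(value) if name != "gamma_shape" else float(value)
        candidate = replace(model, **updates)
        try:
            return -pruning_loglik(tree, matrix, candidate, ascertainment, unit_branch_lengths)
        except (FloatingPointError, ValueError):
            return 1e12

    start0 = np.array(
        [np.log(np.clip(_get_param(model, n) or 1.0, *(_SHAPE_BOUNDS if n == "gamma_shape" else _RATE_BOUNDS))) for n in free_parameters]
    )
    starts = [start0]
    for _ in range(max(n_starts - 1, 0)):
        jitter = rng.normal(0.0, 1.0, size=len(free_parameters))
        starts.append(np.clip(start0 + jitter, bounds[:, 0], bounds[:, 1]))

    best = None
    converged = False
    for x0 in starts:
        result = minimize(
            negloglik,
            x0,
            method="Nelder-Mead",
            bounds=[tuple(b) for b in bounds],
            options={"xatol": 1e-8, "fatol": 1e-8, "maxfev": 2000},
        )
        if best is None or result.fun < best.fun:
            best = result
            converged = bool(result.success)
    fitted = replace(
        model, **{name: float(v) for name, v in zip(free_parameters, np.exp(best.x))}
    )
    return FitResult(fitted, -float(best.fun), converged, evaluations, tuple(free_parameters))
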