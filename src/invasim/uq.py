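"""Uncertainty propagation by arbitrary Polynomial Chaos on a Smolyak grid.

The per-class habitat-suitability scores entering the spread model are
uncertain.  Collecting the n_u uncertain scores in a random vector xi with
independent components, the model output is expanded as

    u(x, t | xi) = sum_{k=0..P} a_k(x, t) Psi_k(xi),

where each multivariate basis polynomial Psi_k is a product of univariate
polynomials orthonormal with respect to the marginal distribution of each
input — built directly from the input's statistical moments (arbitrary
PC), so any distribution with finite moments is admissible.  The number of
terms for total degree p is P + 1 = (n_u + p)! / (n_u! p!).

Coefficients are fitted by discrete projection on a sparse Smolyak
collocation grid assembled from nested univariate Gauss rules (1 node at
level 0, 3 at level 1), giving 2 n_u + 1 nodes at level 1 — 9 model
evaluations for the four uncertain land-cover classes with p = 2.  The
orthonormal-basis identities give the output mean field as a_0 and the
variance field as sum_{k>=1} a_k^2.

At level 1 the grid varies one input at a time, so mixed basis terms
(two or more nonzero indices) vanish at every node; their projection is
0/0 and the coefficient is set to zero.  The expansion consequently
captures additive effects exactly through degree 2 but no interactions —
the price of 2 n_u + 1 instead of 3^n_u model runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, factorial
from typing import Mapping, Sequence

import numpy as np

from .grids import Grid, LandUseMap, PresenceMap
from .hsi import project_scores
from .invasion import ModelParams, initial_density, simulate

__all__ = [
    "PCBasis",
    "SparseGrid",
    "PCExpansion",
    "gaussian_moments",
    "orthopoly_from_moments",
    "gauss_rule_from_moments",
    "index_matrix",
    "smolyak_grid",
    "fit_expansion",
    "propagate",
]


def gaussian_moments(mean: float, sd: float, order: int) -> np.ndarray:
    """Raw moments m_0..m_order of N(mean, sd^2)."""
    # central moments: 0 for odd k, sd^k (k-1)!! for even k
    central = np.zeros(order + 1)
    central[0] = 1.0
    for k in range(2, order + 1, 2):
        central[k] = sd**k * float(np.prod(np.arange(k - 1, 0, -2)))
    raw = np.zeros(order + 1)
    for n in range(order + 1):
        raw[n] = sum(comb(n, j) * central[j] * mean ** (n - j) for j in range(n + 1))
    return raw


def orthopoly_from_moments(moments: Sequence[float], p: int) -> np.ndarray:
    """Orthonormal polynomial table from raw moments m_0..m_{2p}.

    Returns a (p+1, p+1) array of coefficients in ascending powers; row k
    is the degree-k polynomial, orthonormal under the moment functional
    <x^i, x^j> = m_{i+j} and with positive leading coefficient.  Raises if
    the Hankel moment matrix is not positive definite (degenerate input
    distribution).
    """
    moments = np.asarray(moments, dtype=float)
    if moments.size < 2 * p + 1:
        raise ValueError(f"need moments up to order {2 * p}")
    G = np.empty((p + 1, p + 1))
    for i in range(p + 1):
        for j in range(p + 1):
            G[i, j] = moments[i + j]
    try:
        R = np.linalg.cholesky(G).T  # G = R^T R, R upper triangular
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "Hankel moment matrix is not positive definite: the input "
            "distribution is degenerate (zero spread?)"
        ) from exc
    C = np.linalg.inv(R).T  # rows: orthonormal polys, lower triangular
    # enforce positive leading coefficients (Cholesky already gives them)
    signs = np.sign(np.diag(C))
    return C * signs[:, None]


def gauss_rule_from_moments(moments: Sequence[float], n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """n-point Gauss quadrature of the distribution behind ``moments``.

    Uses the Golub-Welsch construction: recurrence coefficients from the
    Cholesky factor of the Hankel matrix, then the Jacobi matrix
    eigendecomposition.  Needs raw moments m_0..m_{2n}.
    """
    m = np.asarray(moments, dtype=float)
    if m.size < 2 * n_points + 1:
        raise ValueError(f"need moments up to order {2 * n_points}")
    n = n_points
    G = np.array([[m[i + j] for j in range(n + 1)] for i in range(n + 1)])
    try:
        R = np.linalg.cholesky(G).T
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate distribution: Hankel matrix not PD") from exc
    alpha = np.empty(n)
    beta = np.empty(n)  # beta[0] unused below
    for k in range(n):
        alpha[k] = R[k, k + 1] / R[k, k] - (R[k - 1, k] / R[k - 1, k - 1] if k > 0 else 0.0)
        beta[k] = (R[k, k] / R[k - 1, k - 1]) ** 2 if k > 0 else 0.0
    Jm = np.diag(alpha) + np.diag(np.sqrt(beta[1:]), 1) + np.diag(np.sqrt(beta[1:]), -1)
    nodes, vecs = np.linalg.eigh(Jm)
    weights = m[0] * vecs[0, :] ** 2
    return nodes, weights


@dataclass
class PCBasis:
    """Multivariate orthonormal basis: univariate tables plus index matrix."""

    tables: list[np.ndarray]  # one (p+1, p+1) coefficient table per input
    index: np.ndarray  # (P+1, n_u) multi-index matrix
    p: int

    def __post_init__(self) -> None:
        n_u = len(self.tables)
        expected = factorial(n_u + self.p) // (factorial(n_u) * factorial(self.p))
        if self.index.shape != (expected, n_u):
            raise ValueError("index matrix shape inconsistent with (n_u, p)")

    @property
    def n_inputs(self) -> int:
        return len(self.tables)

    @property
    def n_terms(self) -> int:
        return self.index.shape[0]

    def eval_univariate(self, dim: int, degree: int, x: np.ndarray) -> np.ndarray:
        coeffs = self.tables[dim][degree]
        return np.polyval(coeffs[::-1], np.asarray(x, dtype=float))

    def eval(self, points: np.ndarray) -> np.ndarray:
        """Evaluate all basis terms at points of shape (n, n_u) -> (n, P+1)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.ones((pts.shape[0], self.n_terms))
        for k, row in enumerate(self.index):
            for i, deg in enumerate(row):
                if deg:
                    out[:, k] *= self.eval_univariate(i, int(deg), pts[:, i])
        return out


@dataclass
class _CombinationTerm:
    """One tensor rule of the Smolyak combination.

    ``node_idx`` indexes the term's tensor nodes into the union node list;
    ``weights`` are the tensor-product quadrature weights; ``max_deg``
    bounds the univariate polynomial degree per dimension for which
    projection on this rule is exact.
    """

    coef: float
    node_idx: np.ndarray
    weights: np.ndarray
    max_deg: tuple[int, ...]


@dataclass
class SparseGrid:
    """Collocation nodes (n_nodes, n_u) and Smolyak combination weights."""

    nodes: np.ndarray
    weights: np.ndarray
    terms: list[_CombinationTerm] | None = None

    def __post_init__(self) -> None:
        if self.nodes.shape[0] != self.weights.size:
            raise ValueError("node/weight count mismatch")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("quadrature weights must sum to 1")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def integrate(self, values: np.ndarray) -> np.ndarray:
        """Weighted sum over nodes; ``values`` has node index first."""
        v = np.asarray(values, dtype=float)
        return np.tensordot(self.weights, v, axes=(0, 0))


@dataclass
class PCExpansion:
    """Fitted expansion: coefficient array with term index first."""

    coeffs: np.ndarray  # (P+1, ...) coefficient fields
    basis: PCBasis

    @property
    def mean(self) -> np.ndarray:
        return self.coeffs[0]

    @property
    def variance(self) -> np.ndarray:
        return np.sum(self.coeffs[1:] ** 2, axis=0)

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.variance)

    def __call__(self, xi: np.ndarray) -> np.ndarray:
        psi = self.basis.eval(np.atleast_2d(xi))
        return np.tensordot(psi, self.coeffs, axes=(1, 0))


def index_matrix(n_u: int, p: int) -> np.ndarray:
    """All multi-indices of total degree <= p, graded-lexicographic order."""
    if n_u < 1 or p < 0:
        raise ValueError("need n_u >= 1 and p >= 0")
    rows: list[tuple[int, ...]] = []
    for total in range(p + 1):
        level = [idx for idx in itertools.product(range(total + 1), repeat=n_u)
                 if sum(idx) == total]
        rows.extend(sorted(level, reverse=True))
    return np.array(rows, dtype=int)


def _nested_rules(moment_sets: Sequence[Sequence[float]], level: int) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Per-dimension nested 1-D rules: 1 node at level 0, 2l+1 Gauss at level l."""
    rules = []
    for m in moment_sets:
        m = np.asarray(m, dtype=float)
        mean = m[1] / m[0]
        dim_rules = [(np.array([mean]), np.array([1.0]))]
        for l in range(1, level + 1):
            nodes, weights = gauss_rule_from_moments(m, 2 * l + 1)
            dim_rules.append((nodes, weights / m[0]))
        rules.append(dim_rules)
    return rules


def smolyak_grid(moment_sets: Sequence[Sequence[float]], level: int = 1) -> SparseGrid:
    """Sparse collocation grid for independent inputs given their moments.

    ``moment_sets[i]`` holds the raw moments of input i (up to order
    2*(2*level+1)).  Level 1 combines the one-point rule (the mean) with
    each input's 3-point Gauss rule, giving the union of the centre and
    two off-centre nodes per dimension: 2 n_u + 1 distinct nodes.  The
    Gauss rules nest the mean node, which the combination requires.
    """
    d = len(moment_sets)
    if d < 1:
        raise ValueError("need at least one uncertain input")
    if level < 1:
        raise ValueError("level must be >= 1")
    rules = _nested_rules(moment_sets, level)
    for dim_rules in rules:
        center = dim_rules[0][0][0]
        for nodes, _ in dim_rules[1:]:
            if not np.any(np.isclose(nodes, center, atol=1e-9 * (1 + abs(center)))):
                raise ValueError("univariate rules are not nested at the mean")

    q = level + d
    acc: dict[tuple, float] = {}
    raw_terms: list[tuple[float, list[tuple], np.ndarray, tuple[int, ...]]] = []
    for sizes in itertools.product(range(1, level + 2), repeat=d):
        s = sum(sizes)
        if not (max(d, q - d + 1) <= s <= q):
            continue
        coef = float((-1) ** (q - s) * comb(d - 1, q - s))
        tensor_nodes = [rules[i][sizes[i] - 1][0] for i in range(d)]
        tensor_weights = [rules[i][sizes[i] - 1][1] for i in range(d)]
        keys, wgts = [], []
        for combo in itertools.product(*[range(len(n)) for n in tensor_nodes]):
            node = tuple(float(tensor_nodes[i][j]) for i, j in enumerate(combo))
            wgt = float(np.prod([tensor_weights[i][j] for i, j in enumerate(combo)]))
            key = tuple(np.round(node, 12))
            acc[key] = acc.get(key, 0.0) + coef * wgt
            keys.append(key)
            wgts.append(wgt)
        # an (2l+1)-point Gauss rule projects exactly onto degrees <= 2l
        max_deg = tuple(2 * (sz - 1) for sz in sizes)
        raw_terms.append((coef, keys, np.array(wgts), max_deg))
    items = sorted(acc.items())
    nodes = np.array([k for k, _ in items], dtype=float)
    weights = np.array([w for _, w in items], dtype=float)
    pos = {k: i for i, (k, _) in enumerate(items)}
    terms = [
        _CombinationTerm(coef=c, node_idx=np.array([pos[k] for k in ks], dtype=int),
                         weights=ws, max_deg=md)
        for c, ks, ws, md in raw_terms
    ]
    return SparseGrid(nodes=nodes, weights=weights, terms=terms)


def fit_expansion(model_outputs: Sequence[np.ndarray], grid: SparseGrid, basis: PCBasis) -> PCExpansion:
    """Discrete projection of per-node model outputs onto the basis.

    a_k = sum_i w_i u_i Psi_k(theta_i) / sum_i w_i Psi_k(theta_i)^2,
    computed cell-wise.  When the grid carries its Smolyak combination
    structure, the projection is applied per tensor term and each term
    contributes only the basis modes it integrates exactly (the sparse
    pseudo-spectral construction) — projecting directly on the union
    weights would alias cross-variance into univariate modes.  Modes no
    term supports (mixed terms at level 1) get a_k = 0.
    """
    if len(model_outputs) != grid.n_nodes:
        raise ValueError(
            f"{len(model_outputs)} model outputs for {grid.n_nodes} nodes"
        )
    outs = np.asarray([np.asarray(o, dtype=float) for o in model_outputs])

    if grid.terms is None:
        # plain discrete projection on the union weights
        psi = basis.eval(grid.nodes)  # (n_nodes, P+1)
        denom = np.einsum("i,ik->k", grid.weights, psi**2)
        numer = np.tensordot(grid.weights[:, None] * psi, outs, axes=(0, 0))
        coeffs = np.zeros_like(numer)
        visible = np.abs(denom) > 1e-12
        coeffs[visible] = numer[visible] / denom[visible].reshape(
            (-1,) + (1,) * (numer.ndim - 1))
        return PCExpansion(coeffs=coeffs, basis=basis)

    coeffs = np.zeros((basis.n_terms,) + outs.shape[1:])
    for term in grid.terms:
        supported = np.all(basis.index <= np.asarray(term.max_deg), axis=1)
        if not supported.any():
            continue
        psi = basis.eval(grid.nodes[term.node_idx])  # (n_t, P+1)
        denom = np.einsum("i,ik->k", term.weights, psi**2)
        numer = np.tensordot(term.weights[:, None] * psi, outs[term.node_idx], axes=(0, 0))
        sel = supported & (np.abs(denom) > 1e-12)
        contrib = numer[sel] / denom[sel].reshape((-1,) + (1,) * (numer.ndim - 1))
        coeffs[sel] += term.coef * contrib
    return PCExpansion(coeffs=coeffs, basis=basis)


def basis_for_gaussians(means: Sequence[float], sds: Sequence[float], p: int = 2) -> PCBasis:
    """Orthonormal basis for independent Gaussian inputs N(mean_i, sd_i^2)."""
    tables = [
        orthopoly_from_moments(gaussian_moments(m, s, max(2 * p, 6)), p)
        for m, s in zip(means, sds)
    ]
    return PCBasis(tables=tables, index=index_matrix(len(tables), p), p=p)


def propagate(
    lu: LandUseMap,
    presence: PresenceMap,
    scores: Mapping[int, float],
    uncertain_classes: Sequence[int],
    sds: Mapping[int, float] | Sequence[float],
    p_model: ModelParams,
    p: int = 2,
    t0: float = 0.0,
    t1: float = 10.0,
    dt: float = 0.05,
    out_times: Sequence[float] | None = None,
    scheme: str = "imex",
) -> tuple[dict[float, Grid], dict[float, Grid], PCExpansion | None]:
    """Propagate Gaussian HSI-score uncertainty through the uncontrolled model.

    Each uncertain class score is N(scores[c], sd_c); at every Smolyak
    node the per-class scores are set to the node coordinates (clipped to
    [0, 1]), projected to an HSI map, multiplied by the presence map to
    form the initial density, and the model is run with E = 0.  Returns
    ({time: mean Grid}, {time: sd Grid}, expansion-at-final-time).

    Classes with sd = 0 are treated as certain; with no uncertain class
    left a single deterministic run is returned with sd = 0.
    """
    scores = {int(c): float(s) for c, s in scores.items()}
    classes = [int(c) for c in uncertain_classes]
    missing = set(classes) - set(scores)
    if missing:
        raise ValueError(f"uncertain classes without a score: {sorted(missing)}")
    if isinstance(sds, Mapping):
        sd_map = {int(c): float(sds[c]) for c in classes}
    else:
        sd_map = {c: float(s) for c, s in zip(classes, sds)}
    active = [c for c in classes if sd_map[c] > 0]
    if out_times is None:
        out_times = [t0, t1]

    def run(score_map: Mapping[int, float]) -> dict[float, np.ndarray]:
        hsi = project_scores(lu, {c: float(np.clip(s, 0.0, 1.0)) for c, s in score_map.items()})
        state0 = initial_density(presence, hsi, t=t0)
        traj = simulate(state0, None, t0, t1, dt, hsi.with_values(np.asarray(hsi.values, dtype=float)),
                        p_model, scheme=scheme)
        times = np.array([s.t for s in traj])
        out = {}
        for t_req in out_times:
            i = int(np.argmin(np.abs(times - t_req)))
            out[float(t_req)] = np.asarray(traj[i].u.values, dtype=float)
        return out

    def as_grid(arr: np.ndarray) -> Grid:
        return Grid(values=arr, cellsize=lu.cellsize,
                    xllcorner=lu.xllcorner, yllcorner=lu.yllcorner)

    if not active:
        det = run(scores)
        means = {t: as_grid(v) for t, v in det.items()}
        sds_out = {t: as_grid(np.zeros_like(v)) for t, v in det.items()}
        return means, sds_out, None

    moment_sets = [gaussian_moments(scores[c], sd_map[c], 6) for c in active]
    grid = smolyak_grid(moment_sets, level=1)
    basis = basis_for_gaussians([scores[c] for c in active], [sd_map[c] for c in active], p=p)

    node_outputs: list[dict[float, np.ndarray]] = []
    for node in grid.nodes:
        score_map = dict(scores)
        for c, v in zip(active, node):
            score_map[c] = float(v)
        node_outputs.append(run(score_map))

    means, sds_out = {}, {}
    expansion = None
    for t_req in out_times:
        exp_t = fit_expansion([o[float(t_req)] for o in node_outputs], grid, basis)
        means[float(t_req)] = as_grid(exp_t.mean)
        sds_out[float(t_req)] = as_grid(exp_t.sd)
        expansion = exp_t
    return means, sds_out, expansion
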