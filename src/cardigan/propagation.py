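"""Label-propagation core.

Scores are obtained by the consistency method of Zhou et al.: balance
smoothness of labels over the (degree-normalized) network against
fidelity to the seed vector Y.  The quadratic cost

    C(F) = 1/2 ( sum_ij W_ij (F_i/sqrt(D_ii) - F_j/sqrt(D_jj))^2
                 + mu * sum_i (F_i - Y_i)^2 ),    mu > 0,

is traded off by mu; the scoring vector used throughout the package is

    F = beta (I - alpha S)^{-1} Y,   alpha = 1/(1+mu),  beta = mu/(1+mu),

with S = D^{-1/2} W D^{-1/2}.  Note a bookkeeping subtlety inherited
from the original formulation: with the cost written as above (the edge
sum running over both orientations), its exact minimizer is the closed
form evaluated at half the regularization weight, i.e. argmin_F C(F; mu)
= beta'(I - alpha' S)^{-1} Y with alpha' = 1/(1 + mu/2).  Since mu is a
free tunable and only the rank order of F is consumed, the package
standardizes on the closed form parametrized by alpha (default 0.9) and
treats the factor-of-two as a reparametrization; ``cost`` evaluates the
displayed formula literally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .interactome import Interactome
from .qws import QueryWeightSet

__all__ = [
    "DiffusionParams",
    "GeneRanking",
    "ConvergenceError",
    "cost",
    "propagate_closed_form",
    "propagate_iterative",
    "propagate",
    "rank_genes",
]

# above this size the direct sparse factorization is replaced by iteration
_DIRECT_SOLVE_MAX_N = 20_000


@dataclass(frozen=True)
class DiffusionParams:
    """Diffusion hyper-parameters.

    Exactly one of ``mu`` or ``alpha`` may be given; they are linked by
    alpha = 1/(1+mu), beta = mu/(1+mu) = 1 - alpha.  Default alpha = 0.9.
    """

    alpha: float = 0.9
    solver: str = "closed_form"  # or "iterative"
    tol: float = 1e-10
    max_iter: int = 100_000

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.solver not in ("closed_form", "iterative"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    @classmethod
    def from_mu(cls, mu: float, **kw) -> "DiffusionParams":
        if mu <= 0:
            raise ValueError(f"mu must be > 0, got {mu}")
        return cls(alpha=1.0 / (1.0 + mu), **kw)

    @property
    def mu(self) -> float:
        return (1.0 - self.alpha) / self.alpha

    @property
    def beta(self) -> float:
        return 1.0 - self.alpha


class ConvergenceError(RuntimeError):
    """Iteration cap reached; carries the last iterate and its residual."""

    def __init__(self, message: str, last: np.ndarray, residual: float):
        super().__init__(message)
        self.last = last
        self.residual = residual


def _as_vector(Y: QueryWeightSet | np.ndarray | Sequence[float], n: int) -> np.ndarray:
    v = Y.Y if isinstance(Y, QueryWeightSet) else np.asarray(Y, dtype=float)
    v = np.asarray(v, dtype=float).ravel()
    if v.shape[0] != n:
        raise ValueError(f"vector length {v.shape[0]} does not match network size {n}")
    return v


def cost(
    F: np.ndarray | Sequence[float],
    net: Interactome,
    Y: QueryWeightSet | np.ndarray | Sequence[float],
    mu: float,
) -> float:
    """Evaluate the consistency cost exactly as displayed above.

    The edge sum runs over both orientations of every undirected edge.
    Isolated nodes contribute only to the fidelity term.
    """
    n = net.n
    F = _as_vector(F, n)
    Yv = _as_vector(Y, n)
    D = net.D
    a = np.zeros(n)
    nz = D > 0
    a[nz] = F[nz] / np.sqrt(D[nz])
    W = net.W.tocoo()
    smooth = float(np.sum(W.data * (a[W.row] - a[W.col]) ** 2))
    fidelity = mu * float(np.sum((F - Yv) ** 2))
    return 0.5 * (smooth + fidelity)


def propagate_closed_form(
    net: Interactome,
    Y: QueryWeightSet | np.ndarray | Sequence[float],
    params: DiffusionParams | None = None,
) -> np.ndarray:
    """Solve (I - alpha S) F = beta Y directly.

    For alpha < 1 the system matrix is nonsingular (the spectrum of S
    lies in [-1, 1]) and its inverse has nonnegative entries, so F >= 0
    whenever Y >= 0.
    """
    params = params or DiffusionParams()
    Yv = _as_vector(Y, net.n)
    A = (sparse.identity(net.n, format="csr") - params.alpha * net.S).tocsc()
    if net.n <= _DIRECT_SOLVE_MAX_N:
        F = spsolve(A, params.beta * Yv)
        F = np.asarray(F, dtype=float).ravel()
        if not np.all(np.isfinite(F)):
            raise np.linalg.LinAlgError("singular diffusion system")
        return F
    return propagate_iterative(net, Yv, params)


def propagate_iterative(
    net: Interactome,
    Y: QueryWeightSet | np.ndarray | Sequence[float],
    params: DiffusionParams | None = None,
) -> np.ndarray:
    """Fixed-point iteration F <- alpha S F + beta Y.

    The map is an (alpha)-contraction in every norm dominated by the
    spectral norm, so convergence to the closed-form solution is
    guaranteed; iteration stops when the sup-norm update falls below
    ``tol * (1 + ||F||_inf)``.

    Raises :class:`ConvergenceError` (carrying the last iterate) if
    ``max_iter`` is reached first.
    """
    params = params or DiffusionParams()
    Yv = _as_vector(Y, net.n)
    S = net.S
    alpha, beta = params.alpha, params.beta
    F = beta * Yv.copy()
    for it in range(1, params.max_iter + 1):
        F_new = alpha * (S @ F) + beta * Yv
        delta = float(np.max(np.abs(F_new - F), initial=0.0))
        F = F_new
        if delta <= params.tol * (1.0 + float(np.max(np.abs(F), initial=0.0))):
            return F
    raise ConvergenceError(
        f"no convergence within {params.max_iter} iterations "
        f"(residual {delta:.3e}, tol {params.tol:.3e})",
        last=F,
        residual=delta,
    )


def propagate(
    net: Interactome,
    Y: QueryWeightSet | np.ndarray | Sequence[float],
    params: DiffusionParams | None = None,
) -> np.ndarray:
    """Dispatch on ``params.solver``; both routes satisfy the same contract."""
    params = params or DiffusionParams()
    if params.solver == "iterative":
        return propagate_iterative(net, Y, params)
    return propagate_closed_form(net, Y, params)


@dataclass
class GeneRanking:
    """Genes ordered by descending score, ties broken by gene id."""

    genes: list[str]
    scores: np.ndarray
    query: str | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def rank_of(self, gene: str) -> int:
        """1-based rank of ``gene``; raises KeyError if absent."""
        try:
            return self.genes.index(gene) + 1
        except ValueError:
            raise KeyError(f"gene {gene!r} not in ranking") from None

    def top(self, k: int) -> list[str]:
        return self.genes[:k]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tgene_id\tscore\n")
            for r, (g, s) in enumerate(zip(self.genes, self.scores), start=1):
                fh.write(f"{r}\t{g}\t{s:.17g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, query: str | None = None) -> "GeneRanking":
        genes, scores = [], []
        with open(path) as fh:
            header = fh.readline()
            for raw in fh:
                parts = raw.rstrip("\n").split("\t")
                genes.append(parts[1])
                scores.append(float(parts[2]))
        return cls(genes, np.asarray(scores), query=query)


def rank_genes(
    F: np.ndarray | Sequence[float],
    net: Interactome,
    exclude: Iterable[str] = (),
    query: str | None = None,
) -> GeneRanking:
    """Order genes by descending score, excluding a candidate blacklist.

    ``exclude`` typically holds the query's remaining known genes during
    leave-one-out evaluation.  Ties are broken lexicographically by gene
    id so output is deterministic.
    """
    F = _as_vector(F, net.n)
    if not np.all(np.isfinite(F)):
        raise ValueError("scores contain non-finite values")
    excl = set(exclude)
    unknown = excl - set(net.genes)
    if unknown:
        raise KeyError(f"exclude genes not in network: {sorted(unknown)[:5]}")
    order = sorted(
        (i for i, g in enumerate(net.genes) if g not in excl),
        key=lambda i: (-F[i], net.genes[i]),
    )
    return GeneRanking(
        genes=[net.genes[i] for i in order],
        scores=F[np.asarray(order, dtype=int)] if order else np.empty(0),
        query=query,
    )
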