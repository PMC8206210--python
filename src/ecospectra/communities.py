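"""Random ecological communities and their linearised (community/noise) matrices.

Two model families are provided:

* a generalised Lotka-Volterra community of ``N`` species in which each
  unordered pair interacts with probability ``c/N``, interaction rates are
  half-normal with raw second moment ``sigma2``, and the mix of interaction
  types (mutualism / competition / predation) is controlled by the symmetry
  parameter ``gamma`` = 1 - 2p, p the predator-prey proportion;
* a bipartite trophic community of ``Nx`` predators and ``Ny`` prey wired as a
  random biregular graph with uniform predation rate ``alpha``.

Both are returned with their community matrix ``A`` (the Jacobian at the
equilibrium), the demographic-noise correlator ``B`` evaluated at the
equilibrium, and the equilibrium itself, ready for spectral analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "LVParams",
    "LVCommunity",
    "TrophicParams",
    "TrophicCommunity",
    "sample_lv_community",
    "sample_trophic_community",
    "stability_edge",
    "tune_to_marginal_stability",
    "trophic_fixed_point",
    "save_community",
    "load_community",
]

_INTERACTION_TYPES = ("mutualism", "competition", "predation")


@dataclass(frozen=True)
class LVParams:
    """Parameters of the random Lotka-Volterra community.

    ``mu`` (the mean interaction rate) is not free: rates are half-normal, so
    ``mu = sigma * sqrt(2/pi)`` and is exposed as a property.
    """

    N: int
    c: float
    sigma2: float
    gamma: float
    b: float
    V: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be a positive integer")
        if not (0 <= self.c <= self.N):
            raise ValueError(f"mean degree c must lie in [0, N]; got c={self.c}")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")
        if not (-1.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [-1, 1]")
        if self.b <= 0:
            raise ValueError("birth rate b must be positive")
        if self.V <= 0:
            raise ValueError("system size V must be positive")

    @property
    def mu(self) -> float:
        """Mean interaction rate of the half-normal, sigma*sqrt(2/pi)."""
        return math.sqrt(2.0 * self.sigma2 / math.pi)


@dataclass
class LVCommunity:
    """A sampled Lotka-Volterra system: matrices, equilibrium and edge data."""

    params: LVParams
    A: np.ndarray
    B: np.ndarray
    x_star: np.ndarray
    # parallel edge arrays: pair (i, j) with i < j, rate R_ij >= 0, type code
    edge_i: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    edge_j: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    edge_rate: np.ndarray = field(default_factory=lambda: np.empty(0))
    edge_type: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))

    @property
    def edge_list(self) -> list[tuple[int, int, str]]:
        return [
            (int(i), int(j), _INTERACTION_TYPES[t])
            for i, j, t in zip(self.edge_i, self.edge_j, self.edge_type)
        ]

    @property
    def N(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class TrophicParams:
    """Parameters of the bipartite predator-prey community."""

    Nx: int
    Ny: int
    cx: int
    cy: int
    alpha: float
    b: float
    d: float
    V: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Nx < 1 or self.Ny < 1:
            raise ValueError("Nx and Ny must be positive")
        if self.Nx * self.cx != self.Ny * self.cy:
            raise ValueError("degree balance Nx*cx == Ny*cy violated")
        if self.cx > self.Ny or self.cy > self.Nx:
            raise ValueError("out-degrees exceed the opposite group size")
        if self.alpha <= 0 or self.b <= 0 or self.d <= 0:
            raise ValueError("alpha, b, d must be positive")
        if self.V <= 0:
            raise ValueError("system size V must be positive")


@dataclass
class TrophicCommunity:
    """A sampled bipartite trophic system.

    ``A`` and ``B`` are the (Nx+Ny) x (Nx+Ny) block community and noise
    matrices evaluated at the group equilibrium (x_star, y_star); rows/columns
    0..Nx-1 are predators, the rest prey. ``R`` is the Nx x Ny predation-rate
    incidence (entries alpha or 0).
    """

    params: TrophicParams
    R: np.ndarray
    x_star: float
    y_star: float
    A: np.ndarray
    B: np.ndarray

    @property
    def N(self) -> int:
        return self.A.shape[0]


def stability_edge(b: float, c_sigma2: float, gamma: float) -> float:
    """Predicted rightmost edge of the eigenvalue support (elliptic law).

    Returns ``sqrt(c*sigma^2) * (1 + gamma) - b``; the community is predicted
    linearly stable iff this is negative. At ``gamma = -1`` (pure predator-prey)
    the edge is ``-b`` regardless of interaction strength.
    """
    if c_sigma2 < 0:
        raise ValueError("c_sigma2 must be nonnegative")
    return math.sqrt(c_sigma2) * (1.0 + gamma) - b


def _rng_streams(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Named, independently seeded generator streams derived from one seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def sample_lv_community(params: LVParams) -> LVCommunity:
    """Sample a random Lotka-Volterra community.

    Each unordered pair (i, j) interacts independently with probability c/N.
    The rate is |Normal(0, sigma2)| (half-normal, so E[R^2] = sigma2 and
    E[R] = sigma*sqrt(2/pi)). The pair is predatory with probability
    p = (1 - gamma)/2 (random orientation), otherwise mutualistic or
    competitive with equal probability. The noise correlator B has diagonal
    2b + sum_{j~i} R_ij and off-diagonal -R_ij on predation pairs only.
    """
    N, b = params.N, params.b
    streams = _rng_streams(params.seed, "edges", "rates", "types", "orientation")

    iu, ju = np.triu_indices(N, k=1)
    present = streams["edges"].random(iu.size) < params.c / N
    ei, ej = iu[present], ju[present]
    n_edges = ei.size

    rates = np.abs(streams["rates"].normal(0.0, math.sqrt(params.sigma2), n_edges))
    p_pred = (1.0 - params.gamma) / 2.0
    u = streams["types"].random(n_edges)
    # codes: 0 mutualism, 1 competition, 2 predation; non-predatory mass is
    # split evenly between mutualism and competition
    types = np.zeros(n_edges, dtype=np.int8)
    types[u < p_pred] = 2
    types[u >= p_pred + (1.0 - p_pred) / 2.0] = 1

    flips = streams["orientation"].random(n_edges) < 0.5

    A = np.zeros((N, N))
    np.fill_diagonal(A, -b)
    B = np.zeros((N, N))

    sij = np.ones(n_edges)
    sji = np.ones(n_edges)
    comp = types == 1
    pred = types == 2
    sij[comp] = -1.0
    sji[comp] = -1.0
    sij[pred] = np.where(flips[pred], 1.0, -1.0)
    sji[pred] = -sij[pred]

    A[ei, ej] = sij * rates
    A[ej, ei] = sji * rates
    B[ei[pred], ej[pred]] = -rates[pred]
    B[ej[pred], ei[pred]] = -rates[pred]

    row_rate_sum = np.zeros(N)
    np.add.at(row_rate_sum, ei, rates)
    np.add.at(row_rate_sum, ej, rates)
    np.fill_diagonal(B, 2.0 * b + row_rate_sum)

    return LVCommunity(
        params=params,
        A=A,
        B=B,
        x_star=np.ones(N),
        edge_i=ei,
        edge_j=ej,
        edge_rate=rates,
        edge_type=types,
    )


def tune_to_marginal_stability(community: LVCommunity) -> LVCommunity:
    """Shift the birth rate so the rightmost eigenvalue of ``A`` sits at zero.

    Finite samples have a rightmost eigenvalue that deviates from the
    infinite-size edge prediction; to study marginally stable systems the
    self-regulation ``b`` is re-chosen as b' = b + max Re eig(A), which
    translates the whole spectrum so its rightmost point is exactly 0. The
    self-interaction part of the noise diagonal is updated accordingly
    (2b -> 2b').
    """
    lam = float(np.max(np.linalg.eigvals(community.A).real))
    b_old = community.params.b
    b_new = b_old + lam
    if b_new <= 0:
        raise ValueError(
            f"marginal tuning gives nonpositive birth rate b'={b_new:.3g}; "
            "the sampled spectrum lies entirely to the left of -b"
        )
    A = community.A.copy()
    A[np.diag_indices_from(A)] -= lam
    B = community.B.copy()
    B[np.diag_indices_from(B)] += 2.0 * lam
    params = replace(community.params, b=b_new)
    return LVCommunity(
        params=params,
        A=A,
        B=B,
        x_star=community.x_star.copy(),
        edge_i=community.edge_i.copy(),
        edge_j=community.edge_j.copy(),
        edge_rate=community.edge_rate.copy(),
        edge_type=community.edge_type.copy(),
    )


def trophic_fixed_point(params: TrophicParams) -> tuple[float, float]:
    """Coexistence equilibrium (x*, y*) of the averaged two-group system.

    x* = (cx*alpha*b - d) / (cx*cy*alpha^2 + 1),
    y* = (cy*alpha*d + b) / (cx*cy*alpha^2 + 1).
    Raises if predators cannot persist (x* <= 0).
    """
    denom = params.cx * params.cy * params.alpha**2 + 1.0
    x_star = (params.cx * params.alpha * params.b - params.d) / denom
    y_star = (params.cy * params.alpha * params.d + params.b) / denom
    if x_star <= 0:
        raise ValueError(
            "no coexistence equilibrium: cx*alpha*b <= d (predators starve)"
        )
    return x_star, y_star


def _biregular_incidence(
    Nx: int, Ny: int, cx: int, cy: int, rng: np.random.Generator, max_sweeps: int = 1000
) -> np.ndarray:
    """0/1 incidence with all row sums cx and column sums cy.

    Stub matching produces a multigraph with the right degrees; duplicate
    edges are then removed by degree-preserving double-edge swaps, which keeps
    the sample approximately uniform over simple biregular graphs.
    """
    rows = np.repeat(np.arange(Nx), cx)
    cols = np.repeat(np.arange(Ny), cy)
    rng.shuffle(cols)
    m = rows.size
    for _ in range(max_sweeps):
        counts: dict[tuple[int, int], int] = {}
        for e in range(m):
            key = (rows[e], cols[e])
            counts[key] = counts.get(key, 0) + 1
        dup_edges = [e for e in range(m) if counts[(rows[e], cols[e])] > 1]
        if not dup_edges:
            M = np.zeros((Nx, Ny))
            M[rows, cols] = 1.0
            return M
        for e in dup_edges:
            if counts[(rows[e], cols[e])] <= 1:
                continue
            for _try in range(50):
                f = int(rng.integers(m))
                # swap prey endpoints of edges e and f if no new duplicate arises
                a, bb = (rows[e], cols[e]), (rows[f], cols[f])
                if a == bb:
                    continue
                new1, new2 = (rows[e], cols[f]), (rows[f], cols[e])
                if counts.get(new1, 0) == 0 and counts.get(new2, 0) == 0:
                    counts[a] -= 1
                    counts[bb] -= 1
                    counts[new1] = counts.get(new1, 0) + 1
                    counts[new2] = counts.get(new2, 0) + 1
                    cols[e], cols[f] = cols[f], cols[e]
                    break
    raise RuntimeError("biregular wiring failed to become simple within the sweep bound")


def sample_trophic_community(params: TrophicParams) -> TrophicCommunity:
    """Sample a bipartite trophic community with biregular random wiring."""
    x_star, y_star = trophic_fixed_point(params)
    streams = _rng_streams(params.seed, "wiring")
    M = _biregular_incidence(params.Nx, params.Ny, params.cx, params.cy, streams["wiring"])
    R = params.alpha * M

    A = np.block(
        [
            [-x_star * np.eye(params.Nx), x_star * R],
            [-y_star * R.T, -y_star * np.eye(params.Ny)],
        ]
    )
    B = np.block(
        [
            [
                2.0 * x_star * (x_star + params.d) * np.eye(params.Nx),
                -x_star * y_star * R,
            ],
            [-x_star * y_star * R.T, 2.0 * y_star * params.b * np.eye(params.Ny)],
        ]
    )
    return TrophicCommunity(params=params, R=R, x_star=x_star, y_star=y_star, A=A, B=B)


# ---------------------------------------------------------------------------
# serialization: params.yaml + dense TSV matrices, round-trip exact at 17 s.f.


_FMT = "%.17g"


def _write_tsv(path: Path, arr: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(arr), fmt=_FMT, delimiter="\t")


def _read_tsv(path: Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def save_community(community: LVCommunity | TrophicCommunity, directory: str | Path) -> None:
    """Serialize a community to ``params.yaml`` plus plain-text matrices."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p = community.params
    if isinstance(community, LVCommunity):
        meta = {
            "kind": "lv",
            "N": p.N, "c": p.c, "sigma2": p.sigma2, "gamma": p.gamma,
            "b": p.b, "V": p.V, "seed": p.seed,
        }
        _write_tsv(directory / "A.tsv", community.A)
        _write_tsv(directory / "B.tsv", community.B)
        np.savetxt(
            directory / "edges.tsv",
            np.column_stack(
                [community.edge_i, community.edge_j, community.edge_type]
            ).astype(int)
            if community.edge_i.size
            else np.empty((0, 3), dtype=int),
            fmt="%d",
            delimiter="\t",
            header="i\tj\ttype",
            comments="",
        )
        np.savetxt(
            directory / "edge_rates.tsv",
            community.edge_rate.reshape(-1, 1),
            fmt=_FMT,
            delimiter="\t",
        )
    else:
        meta = {
            "kind": "trophic",
            "Nx": p.Nx, "Ny": p.Ny, "cx": p.cx, "cy": p.cy,
            "alpha": p.alpha, "b": p.b, "d": p.d, "V": p.V, "seed": p.seed,
        }
        _write_tsv(directory / "A.tsv", community.A)
        _write_tsv(directory / "B.tsv", community.B)
        _write_tsv(directory / "R.tsv", community.R)
    (directory / "params.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def load_community(directory: str | Path) -> LVCommunity | TrophicCommunity:
    directory = Path(directory)
    meta = yaml.safe_load((directory / "params.yaml").read_text())
    kind = meta.pop("kind")
    if kind == "lv":
        params = LVParams(**meta)
        A = _read_tsv(directory / "A.tsv")
        B = _read_tsv(directory / "B.tsv")
        edges = np.loadtxt(directory / "edges.tsv", delimiter="\t", skiprows=1, ndmin=2)
        if edges.size:
            ei = edges[:, 0].astype(np.intp)
            ej = edges[:, 1].astype(np.intp)
            et = edges[:, 2].astype(np.int8)
        else:
            ei = np.empty(0, dtype=np.intp)
            ej = np.empty(0, dtype=np.intp)
            et = np.empty(0, dtype=np.int8)
        rates = np.loadtxt(directory / "edge_rates.tsv", delimiter="\t", ndmin=1)
        return LVCommunity(
            params=params, A=A, B=B, x_star=np.ones(params.N),
            edge_i=ei, edge_j=ej, edge_rate=np.asarray(rates).ravel(), edge_type=et,
        )
    if kind == "trophic":
        params = TrophicParams(**meta)
        x_star, y_star = trophic_fixed_point(params)
        return TrophicCommunity(
            params=params,
            R=_read_tsv(directory / "R.tsv"),
            x_star=x_star,
            y_star=y_star,
            A=_read_tsv(directory / "A.tsv"),
            B=_read_tsv(directory / "B.tsv"),
        )
    raise ValueError(f"unknown community kind {kind!r}")
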