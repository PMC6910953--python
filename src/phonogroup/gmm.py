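"""Diagonal-covariance GMMs: EM training, MAP adaptation, log-densities.

The classifier is the classic universal-background-model scheme from
speaker verification: one diagonal GMM is trained by EM on a large
background corpus, then adapted towards each class (patient / control)
with Reynolds-style maximum-a-posteriori re-estimation, interpolating the
sufficient statistics of the adaptation data with the background model
under a relevance factor r (alpha_g = n_g / (n_g + r)).  By default only
the means are adapted, which is the standard, best-behaved choice for
small adaptation sets.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

_G_GRID = tuple(2**k for k in range(2, 9))  # 4 .. 256

_ADAPTABLE = ("means", "weights", "variances")


@dataclass
class MapConfig:
    """EM / MAP hyper-parameters.

    relevance is the MAP relevance factor r (frames needed before the data
    mean outweighs the prior mean); variance_floor_factor scales the global
    per-dimension variance into an absolute floor.
    """

    relevance: float = 16.0
    adapt: tuple[str, ...] = ("means",)
    n_em_iters: int = 25
    init_seed: int = 0
    variance_floor_factor: float = 1e-3
    em_tol: float = 1e-6
    init_subsample: int = 10000

    def __post_init__(self) -> None:
        if self.relevance <= 0:
            raise ValueError("relevance factor must be positive")
        for p in self.adapt:
            if p not in _ADAPTABLE:
                raise ValueError(f"unknown adaptable parameter {p!r}")


@dataclass
class DiagGMM:
    """Weights / means / variances of a diagonal-covariance mixture."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.asarray(self.means, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def component_log_densities(self, X: np.ndarray) -> np.ndarray:
        """(N, G) matrix of log w_g + log N(x_n; mu_g, diag sigma2_g)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.dim:
            raise ValueError(f"dimension mismatch: {X.shape[1]} != {self.dim}")
        const = -0.5 * (
            self.dim * np.log(2.0 * np.pi) + np.sum(np.log(self.variances), axis=1)
        )
        # (N,G): sum_d (x-mu)^2 / var, expanded to avoid an N*G*D temporary
        inv = 1.0 / self.variances
        quad = (
            (X**2) @ inv.T
            - 2.0 * X @ (self.means * inv).T
            + np.sum(self.means**2 * inv, axis=1)[None, :]
        )
        return np.log(self.weights)[None, :] + const[None, :] - 0.5 * quad

    def log_density(self, X: np.ndarray) -> np.ndarray:
        """log p(x) for each row of X via log-sum-exp (overflow safe)."""
        single = np.asarray(X).ndim == 1
        out = logsumexp(self.component_log_densities(X), axis=1)
        return float(out[0]) if single else out

    # -- serialization (plain JSON; bit-exact via float hex round-trip) ----
    def to_json(self) -> str:
        def enc(a: np.ndarray) -> list:
            return np.vectorize(float.hex)(a.astype(np.float64)).tolist()

        return json.dumps(
            {
                "weights": enc(self.weights),
                "means": enc(self.means),
                "variances": enc(self.variances),
                "metadata": self.metadata,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DiagGMM":
        d = json.loads(text)

        def dec(a) -> np.ndarray:
            return np.vectorize(float.fromhex)(np.asarray(a, dtype=object)).astype(
                np.float64
            )

        return cls(dec(d["weights"]), dec(d["means"]), dec(d["variances"]), d["metadata"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "DiagGMM":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def log_density(model: DiagGMM, x: np.ndarray):
    """Module-level convenience wrapper around :meth:`DiagGMM.log_density`."""
    return model.log_density(x)


# ---------------------------------------------------------------------------
# EM training
# ---------------------------------------------------------------------------

def _variance_floor(X: np.ndarray, factor: float) -> np.ndarray:
    gvar = X.var(axis=0)
    return np.maximum(factor * gvar, 1e-10)


def _init_means(X: np.ndarray, G: int, seed: int, subsample: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    if X.shape[0] > subsample:
        idx = rng.choice(X.shape[0], subsample, replace=False)
        Xs = X[idx]
    else:
        Xs = X
    if np.unique(Xs, axis=0).shape[0] < G:
        # k-means++ is ill-defined with fewer distinct points than clusters
        return Xs[rng.choice(Xs.shape[0], G, replace=True)]
    centers, _ = kmeans_plusplus(Xs, G, random_state=int(seed) % (2**32))
    return centers


def train_ubm(X: np.ndarray, G: int, config: MapConfig | None = None) -> DiagGMM:
    """Fit a diagonal GMM by EM; deterministic given ``config.init_seed``.

    Initialisation is seeded k-means++ on a subsample; variances start at
    the global per-dimension variance and are floored throughout.  The
    per-frame total log-likelihood history is stored in
    ``metadata['log_likelihood_history']`` (non-decreasing up to floor
    effects; asserted in the test suite).
    """
    config = config or MapConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty N x D matrix")
    n, d = X.shape
    if n < G:
        raise ValueError(f"{n} rows cannot support {G} components")
    if n < G * d:
        warnings.warn(
            f"only {n} rows for G={G}, D={d}; estimates may be poor", stacklevel=2
        )
    floor = _variance_floor(X, config.variance_floor_factor)
    gvar = np.maximum(X.var(axis=0), floor)
    model = DiagGMM(
        np.full(G, 1.0 / G),
        _init_means(X, G, config.init_seed, config.init_subsample),
        np.tile(gvar, (G, 1)),
    )
    history: list[float] = []
    for _ in range(config.n_em_iters):
        # E step
        joint = model.component_log_densities(X)
        norm = logsumexp(joint, axis=1)
        ll = float(np.sum(norm))
        resp = np.exp(joint - norm[:, None])
        # M step
        ng = resp.sum(axis=0)
        ng = np.maximum(ng, 1e-300)
        w = ng / n
        mu = (resp.T @ X) / ng[:, None]
        ex2 = (resp.T @ (X**2)) / ng[:, None]
        var = np.maximum(ex2 - mu**2, floor[None, :])
        model = DiagGMM(w / w.sum(), mu, var)
        if history and abs(ll - history[-1]) <= config.em_tol * abs(history[-1]):
            history.append(ll)
            break
        history.append(ll)
    model.metadata = {
        "log_likelihood_history": history,
        "n_frames": n,
        "G": G,
        "init_seed": config.init_seed,
    }
    return model


# ---------------------------------------------------------------------------
# MAP adaptation
# ---------------------------------------------------------------------------

def map_adapt(
    ubm: DiagGMM, X: np.ndarray, config: MapConfig | None = None
) -> DiagGMM:
    """Reynolds-style MAP adaptation of a UBM towards adaptation frames.

    With zero frames the UBM is returned unchanged.  Each adapted mean
    coordinate is a convex combination of the UBM mean and the
    posterior-weighted data mean, so it always lies between the two.
    """
    config = config or MapConfig()
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] == 0:
        return DiagGMM(
            ubm.weights.copy(), ubm.means.copy(), ubm.variances.copy(),
            dict(ubm.metadata),
        )
    if X.shape[1] != ubm.dim:
        raise ValueError(f"dimension mismatch: {X.shape[1]} != {ubm.dim}")
    joint = ubm.component_log_densities(X)
    resp = np.exp(joint - logsumexp(joint, axis=1)[:, None])
    ng = resp.sum(axis=0)
    safe_ng = np.maximum(ng, 1e-300)
    ex = (resp.T @ X) / safe_ng[:, None]
    alpha = ng / (ng + config.relevance)
    w, mu, var = ubm.weights.copy(), ubm.means.copy(), ubm.variances.copy()
    if "means" in config.adapt:
        mu = alpha[:, None] * ex + (1.0 - alpha[:, None]) * ubm.means
    if "weights" in config.adapt:
        w = alpha * (ng / X.shape[0]) + (1.0 - alpha) * ubm.weights
        w = w / w.sum()
    if "variances" in config.adapt:
        ex2 = (resp.T @ (X**2)) / safe_ng[:, None]
        var = (
            alpha[:, None] * ex2
            + (1.0 - alpha[:, None]) * (ubm.variances + ubm.means**2)
            - mu**2
        )
        var = np.maximum(var, 1e-10)
    meta = dict(ubm.metadata)
    meta.update({"adapted": list(config.adapt), "n_adapt_frames": int(X.shape[0])})
    return DiagGMM(w, mu, var, meta)
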