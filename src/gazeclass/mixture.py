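"""Gaussian-mixture modelling of fixation positions (ROI discovery).

A set of regions of interest on an image is modelled as a K-component
bivariate Gaussian mixture over fixation coordinates, fitted by
expectation-maximization.  The number of components is chosen by the
Bayesian information criterion.  Fixations are assigned to components
either by maximum responsibility (``map``) or by the responsibility-to-mass
ratio rule (``ratio``): argmax_k p_ik / p_k with p_k = sum_i p_ik.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2

__all__ = [
    "GaussianComponent",
    "MixtureModel",
    "ClusterAssignment",
    "FitError",
    "DegenerateClusterError",
    "InsufficientDataError",
    "NumericalError",
    "component_density",
    "e_step",
    "m_step",
    "fit_em",
    "bic",
    "select_k",
    "assign_clusters",
    "cluster_ellipses",
]

_LOG_2PI = np.log(2.0 * np.pi)


class FitError(RuntimeError):
    """Mixture fitting failed."""


class DegenerateClusterError(FitError):
    """A component collapsed (total responsibility below threshold)."""


class InsufficientDataError(FitError):
    """Fewer observations than requested components."""


class NumericalError(FitError):
    """Density underflow or singular covariance."""


@dataclass
class GaussianComponent:
    """One mixture component: weight pi_k, mean mu_k (px), covariance (px^2)."""

    weight: float
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(2)
        self.cov = np.asarray(self.cov, dtype=float).reshape(2, 2)
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance must be symmetric")


@dataclass
class MixtureModel:
    components: list[GaussianComponent]
    log_likelihood: float
    n_observations: int
    converged: bool = False
    n_iterations: int = 0
    #: per-iteration log-likelihood trace of the fit that produced this model
    ll_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("K >= 1 required")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {total}, expected 1")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.stack([c.mean for c in self.components])

    @property
    def covariances(self) -> np.ndarray:
        return np.stack([c.cov for c in self.components])

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_observations": self.n_observations,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        comps = [
            GaussianComponent(w, np.array(m), np.array(c))
            for w, m, c in zip(d["weights"], d["means"], d["covariances"])
        ]
        return cls(
            comps,
            log_likelihood=d["log_likelihood"],
            n_observations=d["n_observations"],
            converged=d.get("converged", False),
            n_iterations=d.get("n_iterations", 0),
        )


@dataclass
class ClusterAssignment:
    """Per-fixation cluster labels plus the full responsibility matrix.

    ``labels`` are 0-based component indices.  ``cluster_mass`` is the
    column sum of ``responsibilities`` (p_k).
    """

    labels: np.ndarray
    responsibilities: np.ndarray
    cluster_mass: np.ndarray

    @property
    def n_clusters(self) -> int:
        return self.responsibilities.shape[1]


def _log_density(points: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log bivariate-normal density of each row of ``points`` (closed-form 2x2)."""
    a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
    det = a * c - b * b
    if det <= 0 or a <= 0:
        raise NumericalError(f"singular covariance {cov.tolist()}")
    dx = points[:, 0] - mean[0]
    dy = points[:, 1] - mean[1]
    maha = (c * dx * dx - 2.0 * b * dx * dy + a * dy * dy) / det
    return -0.5 * (2 * _LOG_2PI + np.log(det) + maha)


def component_density(point: np.ndarray, comp: GaussianComponent) -> float:
    """Bivariate normal density f(x; mu_k, cov_k) at ``point`` (units 1/px^2)."""
    point = np.asarray(point, dtype=float).reshape(1, 2)
    return float(np.exp(_log_density(point, comp.mean, comp.cov)[0]))


def _log_joint(points: np.ndarray, model: MixtureModel) -> np.ndarray:
    """N x K matrix of log(pi_k) + log f(x_i; theta_k)."""
    cols = [
        np.log(c.weight) + _log_density(points, c.mean, c.cov)
        for c in model.components
    ]
    return np.stack(cols, axis=1)


def e_step(points: np.ndarray, model: MixtureModel) -> ClusterAssignment:
    """Posterior responsibilities p_ik, computed in log space.

    Each row sums to 1; a point for which every component density
    underflows raises :class:`NumericalError` naming the point index.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    lj = _log_joint(points, model)
    norm = logsumexp(lj, axis=1)
    bad = np.where(~np.isfinite(norm))[0]
    if bad.size:
        raise NumericalError(f"density underflow at point index {bad[0]}")
    resp = np.exp(lj - norm[:, None])
    return ClusterAssignment(
        labels=np.argmax(resp, axis=1),
        responsibilities=resp,
        cluster_mass=resp.sum(axis=0),
    )


def _regularization(points: np.ndarray) -> float:
    """Eigenvalue floor: 1e-6 x trace(global covariance) / 2."""
    gcov = np.cov(points.T) if len(points) > 1 else np.eye(2)
    eps = 1e-6 * float(np.trace(np.atleast_2d(gcov))) / 2.0
    return max(eps, 1e-12)


def _floor_cov(cov: np.ndarray, eps: float) -> np.ndarray:
    """Shift the diagonal so both eigenvalues are >= ``eps``.

    A no-op for healthy matrices, so EM monotonicity is untouched away from
    degeneracy.
    """
    vals = np.linalg.eigvalsh(cov)
    if vals[0] >= eps:
        return cov
    return cov + (eps - vals[0]) * np.eye(2)


def m_step(
    points: np.ndarray,
    resp: ClusterAssignment | np.ndarray,
    eps: float | None = None,
) -> MixtureModel:
    """Re-estimate mixture parameters from responsibilities.

    pi_k = mean responsibility; mu_k and cov_k are responsibility-weighted
    moments (biased, mass-normalized).  Covariance eigenvalues are floored
    at ``eps``.  The returned model carries the log-likelihood of the *new*
    parameters on ``points``.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    r = resp.responsibilities if isinstance(resp, ClusterAssignment) else np.asarray(resp)
    n, k = r.shape
    if eps is None:
        eps = _regularization(points)
    mass = r.sum(axis=0)
    if np.any(mass < 1e-12):
        raise DegenerateClusterError(
            f"component {int(np.argmin(mass))} has vanishing responsibility mass"
        )
    weights = mass / n
    means = (r.T @ points) / mass[:, None]
    comps = []
    for j in range(k):
        diff = points - means[j]
        cov = (r[:, j, None] * diff).T @ diff / mass[j]
        comps.append(GaussianComponent(weights[j], means[j], _floor_cov(cov, eps)))
    model = MixtureModel(comps, log_likelihood=np.nan, n_observations=n)
    model.log_likelihood = float(logsumexp(_log_joint(points, model), axis=1).sum())
    return model


def _kmeanspp_means(
    points: np.ndarray, k: int, rng: np.random.Generator, n_candidates: int = 4
) -> np.ndarray:
    """Greedy k-means++ seeding: sample several candidates per step and keep
    the one minimizing the resulting potential (as in sklearn's k-means)."""
    n = len(points)
    idx = [int(rng.integers(n))]
    d2 = np.sum((points - points[idx[0]]) ** 2, axis=1)
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx.append(int(rng.integers(n)))
            continue
        cand = rng.choice(n, size=n_candidates, p=d2 / total)
        best, best_d2, best_pot = None, None, np.inf
        for c in cand:
            nd2 = np.minimum(d2, np.sum((points - points[c]) ** 2, axis=1))
            pot = nd2.sum()
            if pot < best_pot:
                best, best_d2, best_pot = int(c), nd2, pot
        idx.append(best)
        d2 = best_d2
    return points[idx].copy()


def _lloyd_refine(
    points: np.ndarray, means: np.ndarray, max_iter: int = 15
) -> tuple[np.ndarray, np.ndarray]:
    """A few k-means iterations to polish the seeds; returns means and labels."""
    labels = None
    for _ in range(max_iter):
        d2 = ((points[:, None, :] - means[None, :, :]) ** 2).sum(-1)
        new_labels = d2.argmin(1)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(len(means)):
            sel = labels == j
            if sel.any():
                means[j] = points[sel].mean(0)
    return means, labels


def _log_joint_arrays(
    points: np.ndarray, weights: np.ndarray, means: np.ndarray, covs: np.ndarray
) -> np.ndarray:
    cols = [
        np.log(weights[j]) + _log_density(points, means[j], covs[j])
        for j in range(len(weights))
    ]
    return np.stack(cols, axis=1)


def _fit_once(
    points: np.ndarray,
    k: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    eps: float,
) -> MixtureModel:
    n = len(points)
    gcov = _floor_cov(np.atleast_2d(np.cov(points.T)) if n > 1 else np.eye(2), eps)
    means = _kmeanspp_means(points, k, rng)
    means, hard = _lloyd_refine(points, means)
    # per-seed empirical moments where the hard clusters are big enough;
    # fall back to a (1/k)-scaled global covariance otherwise
    weights = np.full(k, 1.0 / k)
    covs = np.repeat(gcov[None, :, :] / k, k, axis=0)
    if hard is not None:
        sizes = np.bincount(hard, minlength=k).astype(float)
        for j in range(k):
            if sizes[j] > 3:
                covs[j] = _floor_cov(np.atleast_2d(np.cov(points[hard == j].T)), eps)
        if np.all(sizes > 0):
            weights = sizes / sizes.sum()

    # vectorized EM over all K components; covariances tracked as the three
    # distinct entries a = cov_xx, b = cov_xy, c = cov_yy, each shape (K,).
    # The (N, K) work buffers are preallocated: this loop dominates runtime.
    x0, x1 = points[:, 0], points[:, 1]
    a, b, c = covs[:, 0, 0].copy(), covs[:, 0, 1].copy(), covs[:, 1, 1].copy()
    dx = np.empty((n, k))
    dy = np.empty((n, k))
    work = np.empty((n, k))
    tmp = np.empty((n, k))
    prev_ll = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        det = a * c - b * b
        if np.any(det <= 0):
            raise NumericalError("singular covariance during EM")
        np.subtract(x0[:, None], means[:, 0], out=dx)
        np.subtract(x1[:, None], means[:, 1], out=dy)
        # work <- log pi_k + log f(x_i; theta_k)
        np.multiply(dx, dx, out=work)
        work *= c
        np.multiply(dx, dy, out=tmp)
        tmp *= -2.0 * b
        work += tmp
        np.multiply(dy, dy, out=tmp)
        tmp *= a
        work += tmp
        work /= det
        work += 2 * _LOG_2PI + np.log(det)
        work *= -0.5
        work += np.log(weights)
        mx = work.max(axis=1)
        np.subtract(work, mx[:, None], out=work)
        np.exp(work, out=work)
        rowsum = work.sum(axis=1)
        norm = mx + np.log(rowsum)
        if not np.all(np.isfinite(norm)):
            raise NumericalError("density underflow during EM")
        ll = float(norm.sum())
        trace.append(ll)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
        work /= rowsum[:, None]  # work is now the responsibility matrix
        mass = work.sum(axis=0)
        if np.any(mass < 1e-12):
            raise DegenerateClusterError(
                f"component {int(np.argmin(mass))} has vanishing responsibility mass"
            )
        weights = mass / n
        means = (work.T @ points) / mass[:, None]
        np.subtract(x0[:, None], means[:, 0], out=dx)
        np.subtract(x1[:, None], means[:, 1], out=dy)
        np.multiply(dx, dx, out=tmp)
        tmp *= work
        a = tmp.sum(axis=0) / mass
        np.multiply(dx, dy, out=tmp)
        tmp *= work
        b = tmp.sum(axis=0) / mass
        np.multiply(dy, dy, out=tmp)
        tmp *= work
        c = tmp.sum(axis=0) / mass
        # eigenvalue floor via diagonal shift (no-op for healthy components)
        min_eig = 0.5 * ((a + c) - np.sqrt((a - c) ** 2 + 4.0 * b * b))
        delta = np.maximum(0.0, eps - min_eig)
        a = a + delta
        c = c + delta
    comps = [
        GaussianComponent(weights[j], means[j], np.array([[a[j], b[j]], [b[j], c[j]]]))
        for j in range(k)
    ]
    model = MixtureModel(
        comps,
        log_likelihood=trace[-1],
        n_observations=n,
        converged=converged,
        n_iterations=it,
        ll_trace=trace,
    )
    return model


def fit_em(
    points: np.ndarray,
    k: int,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 10,
    seed: int | None = None,
) -> MixtureModel:
    """Fit a K-component mixture by EM, best of ``n_restarts`` by log-likelihood.

    Initialization: k-means++ seeding of means, global covariance, uniform
    weights.  Restarts that collapse a component are discarded; if every
    restart degenerates a :class:`FitError` is raised.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(points)
    if k < 1:
        raise ValueError("K >= 1 required")
    if n < k:
        raise InsufficientDataError(f"{n} observations < {k} components")
    eps = _regularization(points)
    rng = np.random.default_rng(seed)
    best: MixtureModel | None = None
    for _ in range(max(1, n_restarts)):
        try:
            model = _fit_once(points, k, rng, tol, max_iter, eps)
        except (DegenerateClusterError, NumericalError):
            continue
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    if best is None:
        raise FitError(f"all {n_restarts} restarts degenerated for K={k}")
    return best


def bic(model: MixtureModel) -> float:
    """Bayesian information criterion -2 lnL + m ln N, m = 6K - 1; lower is better."""
    n = model.n_observations
    if n == 0:
        raise ValueError("BIC undefined for N = 0")
    m = 6 * model.n_components - 1
    return -2.0 * model.log_likelihood + m * np.log(n)


def select_k(
    points: np.ndarray,
    k_min: int = 2,
    k_max: int = 20,
    *,
    seed: int | None = None,
    **em_kwargs,
) -> tuple[MixtureModel, list[dict]]:
    """Fit every K in [k_min, k_max]; return the BIC-minimizing model and trace.

    The trace has one entry per attempted K: ``{"k", "bic", "log_likelihood"}``
    on success, ``{"k", "error"}`` for a failed fit.  All-K failure raises.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if not 1 <= k_min <= k_max <= len(points):
        raise ValueError(f"need 1 <= k_min <= k_max <= N, got [{k_min}, {k_max}]")
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=k_max - k_min + 1)
    best: MixtureModel | None = None
    best_bic = np.inf
    trace: list[dict] = []
    for k, s in zip(range(k_min, k_max + 1), seeds):
        try:
            model = fit_em(points, k, seed=int(s), **em_kwargs)
        except FitError as exc:
            trace.append({"k": k, "error": str(exc)})
            continue
        b = bic(model)
        trace.append({"k": k, "bic": b, "log_likelihood": model.log_likelihood})
        if b < best_bic:
            best, best_bic = model, b
    if best is None:
        raise FitError("every K in range failed to fit")
    return best, trace


def assign_clusters(
    points: np.ndarray, model: MixtureModel, rule: str = "paper_ratio"
) -> ClusterAssignment:
    """Assign each fixation to a cluster.

    ``paper_ratio``: argmax_k p_ik / p_k with p_k the responsibility column
    sums — the rule favours low-mass clusters.  ``map``: argmax_k p_ik.
    Ties break toward the lowest cluster index.
    """
    assignment = e_step(points, model)
    if rule == "map":
        score = assignment.responsibilities
    elif rule == "paper_ratio":
        score = assignment.responsibilities / assignment.cluster_mass[None, :]
    else:
        raise ValueError(f"unknown assignment rule {rule!r}")
    return ClusterAssignment(
        labels=np.argmax(score, axis=1),
        responsibilities=assignment.responsibilities,
        cluster_mass=assignment.cluster_mass,
    )


def cluster_ellipses(model: MixtureModel, coverage: float = 0.95) -> list[dict]:
    """Coverage ellipses per component.

    Semi-axes are sqrt(chi2_2(coverage) * eigenvalues); ``angle`` is the
    orientation of the principal axis in radians, measured from +x.
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    q = chi2.ppf(coverage, df=2)
    out = []
    for j, comp in enumerate(model.components):
        vals, vecs = np.linalg.eigh(comp.cov)  # ascending
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        out.append(
            {
                "cluster": j,
                "center": comp.mean.tolist(),
                "semi_axes": np.sqrt(q * vals).tolist(),
                "angle": float(np.arctan2(vecs[1, 0], vecs[0, 0])),
                "weight": comp.weight,
            }
        )
    return out
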