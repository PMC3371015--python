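"""Multi-label Gaussian-process classifier with label correlations.

The model places a zero-mean GP prior over one latent function per
(label, view) pair.  The likelihood depends on the per-view latents
only through their sum, so inference runs on the collapsed latents

    g_ik = sum_j f_k^j(x_i),   cov(g_ik, g_i'k') = C_kk' * K_ii',

i.e. a Kronecker prior ``C (x) K`` with ``K = sum_j a_j K_j`` the
weighted combination of per-view Gaussian Grams, ``C`` a unit-diagonal
PSD label-correlation matrix, and ``a >= 0`` the view weights.  The
per-sample Bernoulli likelihood is the logistic sigmoid of the latent,
exponentiated by a positive weight ``w_i`` that up-weights samples
carrying rare labels.

The non-Gaussian posterior over the latents is approximated by
Laplace's method (Newton mode finding with backtracking line search);
``C`` and ``a`` are learned by maximizing the Laplace approximation of
the log marginal likelihood.  Predictive label probabilities are
Monte-Carlo (or Gauss-Hermite) averages of the sigmoid over the
approximate posterior of the test latents.

Identifiability: scaling ``C`` and inversely scaling ``a`` leaves the
prior unchanged, so ``C`` is constrained to unit diagonal (a
correlation matrix) and all amplitude lives in ``a``.

Flattening convention: an (n, Q) latent matrix ``G`` is vectorized
label-major, ``g = G.T.ravel()``, so that ``cov(g) = kron(C, K)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.special import expit, roots_hermite

from .data import MultiViewDataset
from .kernels import KernelStack, combine, gaussian_gram

logger = logging.getLogger(__name__)


def log_sigmoid(x: np.ndarray) -> np.ndarray:
    """log(sigma(x)) without overflow for large |x|."""
    return -np.logaddexp(0.0, -x)


# ---------------------------------------------------------------------------
# parameters and weights
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """Hyperparameters of the collapsed model.

    C : (Q, Q) unit-diagonal PSD label-correlation matrix.
    a : (m,) nonnegative view weights.
    theta : (m,) positive per-view bandwidths.
    w : (n,) positive per-sample likelihood weights, mean 1.
    """

    C: np.ndarray
    a: np.ndarray
    theta: np.ndarray
    w: np.ndarray
    opt_trace: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if np.abs(self.C - self.C.T).max() > 1e-10:
            raise ValueError("C must be symmetric")
        if np.abs(np.diag(self.C) - 1.0).max() > 1e-8:
            raise ValueError("C must have unit diagonal")
        if np.linalg.eigvalsh(self.C).min() < -1e-8:
            raise ValueError("C must be PSD")
        if np.any(self.a < 0) or not np.any(self.a > 0):
            raise ValueError("view weights must be nonnegative, not all zero")
        if np.any(self.theta <= 0):
            raise ValueError("bandwidths must be positive")
        if abs(self.w.mean() - 1.0) > 1e-10:
            raise ValueError("sample weights must average to 1")


def sample_weights(Y: np.ndarray) -> np.ndarray:
    """Inverse-positive-frequency likelihood weights, normalized to mean 1.

    For sample i let ``r_i`` be the mean over its positive labels k of
    ``1 / n_k`` (``n_k`` = number of positives of label k); then
    ``w_i = r_i * n / sum(r)``.  Samples carrying only rare labels get
    large weights; on a balanced single-label dataset all weights are 1.
    Labels with zero positives never appear as anyone's positive label
    and so contribute nothing.
    """
    Y = np.asarray(Y)
    pos = Y > 0
    if not pos.any(axis=1).all():
        bad = int(np.flatnonzero(~pos.any(axis=1))[0])
        raise ValueError(f"sample {bad} has no positive label")
    n_k = pos.sum(axis=0).astype(float)
    inv = np.zeros_like(n_k)
    nz = n_k > 0
    inv[nz] = 1.0 / n_k[nz]
    r = (pos * inv).sum(axis=1) / pos.sum(axis=1)
    return r * (len(r) / r.sum())


# ---------------------------------------------------------------------------
# prior construction and the collapse diagnostic
# ---------------------------------------------------------------------------


def full_prior_cov(C: np.ndarray, K_combined: np.ndarray) -> np.ndarray:
    """Explicit (nQ, nQ) Kronecker prior covariance ``C (x) K``.

    Only for small instances (tests, diagnostics); inference never
    forms the inverse and solves via Cholesky of the damped system.
    """
    C = np.asarray(C, dtype=float)
    K = np.asarray(K_combined, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be square")
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    return np.kron(C, K)


def collapse_equivalence_check(
    stack: KernelStack, C: np.ndarray, a: np.ndarray, tol: float = 1e-8
) -> bool:
    """Verify the collapsed prior equals the marginalized per-view stack.

    The explicit model keeps one latent block per view, ``f^j`` with
    covariance ``a_j * (C (x) K_j)``, independent across views; the sum
    ``g = sum_j f^j`` then has covariance ``sum_j a_j (C (x) K_j)``.
    The collapsed representation uses ``C (x) sum_j a_j K_j`` directly.
    This diagnostic constructs both covariances explicitly (so it is
    only for tiny instances) and compares them in Frobenius norm.
    """
    n, Q, m = stack.n_samples, np.asarray(C).shape[0], stack.n_views
    if n * Q * m > 600:
        raise ValueError("collapse check is an explicit-matrix diagnostic; keep nQm small")
    a = np.asarray(a, dtype=float)
    # marginalize the stacked prior: S blockdiag_j(a_j C (x) K_j) S^T with S = [I ... I]
    nQ = n * Q
    stacked = np.zeros((nQ, nQ))
    for aj, Kj in zip(a, stack.grams):
        stacked += aj * np.kron(C, Kj)
    collapsed = full_prior_cov(C, combine(stack, a))
    return float(np.linalg.norm(stacked - collapsed)) < tol


# ---------------------------------------------------------------------------
# Laplace approximation
# ---------------------------------------------------------------------------


@dataclass
class PosteriorApprox:
    """Laplace approximation of the posterior over the collapsed latents.

    G_hat : (n, Q) posterior mode.
    alpha : (nQ,) = Sigma^{-1} g_hat, kept so no prior inverse is ever formed.
    W : (n, Q) likelihood curvature w_i * pi * (1 - pi) at the mode.
    L : Cholesky factor of B = I + sqrt(W) Sigma sqrt(W).
    dloglik : (n, Q) likelihood gradient at the mode (equals alpha there).
    log_marginal : Laplace approximation of log p(Y | C, a).
    """

    G_hat: np.ndarray
    alpha: np.ndarray
    W: np.ndarray
    L: np.ndarray
    dloglik: np.ndarray
    log_marginal: float
    grad_norm: float
    C: np.ndarray
    K: np.ndarray
    n_iter: int


def _kron_mv(C: np.ndarray, K: np.ndarray, v: np.ndarray) -> np.ndarray:
    """(C (x) K) v for label-major flattened v, without forming the Kron."""
    Q, n = C.shape[0], K.shape[0]
    return (C @ v.reshape(Q, n) @ K).ravel()


def laplace_fit(
    K_combined: np.ndarray,
    C: np.ndarray,
    Y: np.ndarray,
    w: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
    G0: np.ndarray | None = None,
) -> PosteriorApprox:
    """Find the Laplace approximation of the latent posterior.

    Newton iteration on the collapsed latents maximizes

        psi(g) = sum_ik w_i log sigma(y_ik g_ik) - 1/2 g^T Sigma^{-1} g

    with ``Sigma = C (x) K``.  Each step solves the damped system
    through ``B = I + W^{1/2} Sigma W^{1/2}`` (numerically safe: B's
    eigenvalues are >= 1) and backtracks on psi.  Iterates are kept in
    the form ``g = Sigma alpha`` so the prior inverse is never formed.

    Returns the mode, curvature, B-factor and the approximate log
    marginal  log p(Y|g_hat) - 1/2 alpha^T g_hat - 1/2 log|B|.
    """
    K = np.asarray(K_combined, dtype=float)
    C = np.asarray(C, dtype=float)
    Y = np.asarray(Y, dtype=float)
    w = np.asarray(w, dtype=float)
    n, Q = Y.shape
    if K.shape != (n, n) or C.shape != (Q, Q):
        raise ValueError("dimension mismatch between K, C and Y")
    if not (np.all(np.isfinite(K)) and np.all(np.isfinite(C))):
        raise ValueError("non-finite kernel or correlation entries")

    T = (Y + 1.0) / 2.0  # targets in {0, 1}
    Sigma = np.kron(C, K)
    nQ = n * Q

    def loglik(G: np.ndarray) -> float:
        return float(np.sum(w[:, None] * log_sigmoid(Y * G)))

    if G0 is not None and G0.shape == (n, Q):
        # project the warm start onto the representable manifold g = Sigma alpha
        g0 = G0.T.ravel()
        reg = Sigma + 1e-8 * np.trace(Sigma) / nQ * np.eye(nQ)
        alpha = np.linalg.solve(reg, g0)
        g = Sigma @ alpha
    else:
        alpha = np.zeros(nQ)
        g = np.zeros(nQ)

    G = g.reshape(Q, n).T
    psi = loglik(G) - 0.5 * float(alpha @ g)
    trace = []
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        Pi = expit(G)
        dll = w[:, None] * (T - Pi)                  # likelihood gradient
        Wc = w[:, None] * Pi * (1.0 - Pi)            # curvature, in (0, max(w)/4]
        grad = dll.T.ravel() - alpha                 # gradient of psi
        grad_norm = float(np.abs(grad).max())
        trace.append((it, psi, grad_norm))
        if grad_norm < tol:
            break

        sw = np.sqrt(Wc.T.ravel())
        B = np.eye(nQ) + sw[:, None] * Sigma * sw[None, :]
        L = cholesky(B, lower=True)
        b = Wc.T.ravel() * g + dll.T.ravel()
        Sb = Sigma @ b
        alpha_new = b - sw * cho_solve((L, True), sw * Sb)

        # backtracking line search in alpha-space (g = Sigma alpha stays exact)
        step = 1.0
        improved = False
        for _ in range(30):
            a_try = alpha + step * (alpha_new - alpha)
            g_try = Sigma @ a_try
            G_try = g_try.reshape(Q, n).T
            psi_try = loglik(G_try) - 0.5 * float(a_try @ g_try)
            if psi_try > psi - 1e-12:
                improved = psi_try > psi
                alpha, g, G = a_try, g_try, G_try
                dpsi = psi_try - psi
                psi = psi_try
                break
            step *= 0.5
        else:
            raise RuntimeError(
                f"Laplace mode finding: line search failed at iter {it}; "
                f"trace={trace[-5:]}"
            )
        if improved and dpsi < 1e-10:
            # objective flat: recompute gradient once more and stop
            Pi = expit(G)
            grad_norm = float(np.abs((w[:, None] * (T - Pi)).T.ravel() - alpha).max())
            break
    else:
        raise RuntimeError(
            f"Laplace mode finding did not converge in {max_iter} iterations "
            f"(last grad norm {grad_norm:.3e}); trace={trace[-5:]}"
        )

    Pi = expit(G)
    dll = w[:, None] * (T - Pi)
    Wc = w[:, None] * Pi * (1.0 - Pi)
    sw = np.sqrt(Wc.T.ravel())
    B = np.eye(nQ) + sw[:, None] * Sigma * sw[None, :]
    L = cholesky(B, lower=True)
    log_marginal = (
        loglik(G) - 0.5 * float(alpha @ g) - float(np.log(np.diag(L)).sum())
    )
    return PosteriorApprox(
        G_hat=G,
        alpha=alpha,
        W=Wc,
        L=L,
        dloglik=dll,
        log_marginal=log_marginal,
        grad_norm=grad_norm,
        C=C,
        K=K,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# hyperparameter learning (Laplace evidence maximization)
# ---------------------------------------------------------------------------


def _corr_from_params(z: np.ndarray, Q: int) -> np.ndarray:
    """Unit-diagonal PSD matrix from Q(Q-1)/2 unconstrained parameters.

    Row k of a lower-triangular factor is (z_k1..z_kk, 1) normalized to
    unit length; C = L L^T.  z = 0 gives the identity.
    """
    L = np.zeros((Q, Q))
    L[0, 0] = 1.0
    pos = 0
    for k in range(1, Q):
        row = np.concatenate([z[pos:pos + k], [1.0]])
        L[k, :k + 1] = row / np.linalg.norm(row)
        pos += k
    return L @ L.T


def optimize_hyperparams(
    stack: KernelStack,
    Y: np.ndarray,
    w: np.ndarray,
    learn_C: bool = True,
    learn_a: bool = True,
    max_evals: int = 300,
    maxiter: int = 40,
    newton_tol: float = 1e-6,
    a_fixed: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Learn C (unit-diagonal PSD) and a (>= 0) by maximizing the
    Laplace log marginal.

    C is parameterized through a Cholesky-of-correlation factor and
    ``a`` through its logarithm, so both constraints hold by
    construction.  The evidence is recomputed per evaluation with the
    Newton mode warm-started from the previous one; gradients are
    finite-difference (quasi-Newton L-BFGS).  Accepted steps never
    decrease the evidence (descent method on the negated objective).

    Returns (C, a, trace) where trace records the accepted objective
    values.
    """
    Y = np.asarray(Y)
    n, Q = Y.shape
    m = stack.n_views
    default_a = (
        np.asarray(a_fixed, dtype=float) if a_fixed is not None
        else np.full(m, 1.0 / m)
    )
    nC = Q * (Q - 1) // 2 if learn_C else 0
    x0 = np.concatenate(
        [np.zeros(nC), np.log(default_a) if learn_a else []]
    )
    if not learn_a and nC == 0:
        return np.eye(Q), default_a, []

    warm: dict = {"G": None}
    trace: list = []

    def unpack(x: np.ndarray):
        C = _corr_from_params(x[:nC], Q) if learn_C else np.eye(Q)
        a = np.exp(x[nC:]) if learn_a else default_a
        return C, a

    def neg_evidence(x: np.ndarray) -> float:
        C, a = unpack(x)
        K = combine(stack, a)
        try:
            post = laplace_fit(K, C, Y, w, tol=newton_tol, G0=warm["G"])
        except RuntimeError:
            # cold restart once before declaring the point infeasible
            post = laplace_fit(K, C, Y, w, tol=newton_tol)
        warm["G"] = post.G_hat
        if not np.isfinite(post.log_marginal):
            raise FloatingPointError(f"evidence NaN at parameters {x}")
        return -post.log_marginal

    def cb(xk: np.ndarray) -> None:
        trace.append(-neg_evidence(xk))

    res = minimize(
        neg_evidence,
        x0,
        method="L-BFGS-B",
        callback=cb,
        options={"maxiter": maxiter, "maxfun": max_evals, "eps": 1e-4},
    )
    C, a = unpack(res.x)
    logger.info(
        "evidence optimization: %d evals, final log marginal %.4f",
        res.nfev, -res.fun,
    )
    return C, a, trace


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict_latent(
    post: PosteriorApprox,
    kstar: np.ndarray,
    kss: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian of the collapsed test latents for one test point.

    kstar : (n,) combined cross-kernel sum_j a_j k_j(x*, x_i).
    kss : prior variance of the combined kernel at the test point
        (sum_j a_j for unit-diagonal Gaussian kernels).

    Returns (mu, Sigma_star): mean ``C (A kstar)`` with A the
    reshaped ``Sigma^{-1} g_hat`` (equal to the likelihood gradient at
    the mode), and covariance ``kss C - V^T V`` from the B-factor.
    A far-away test point (kstar -> 0) reverts to the prior N(0, kss C).
    """
    C, n, Q = post.C, post.K.shape[0], post.C.shape[0]
    kstar = np.asarray(kstar, dtype=float)
    if kstar.shape != (n,):
        raise ValueError(f"cross-kernel must have shape ({n},), got {kstar.shape}")
    A = post.alpha.reshape(Q, n)
    mu = C @ (A @ kstar)
    Sfs = np.kron(C, kstar[:, None])               # (nQ, Q) cross-covariance
    sw = np.sqrt(post.W.T.ravel())
    V = solve_triangular(post.L, sw[:, None] * Sfs, lower=True)
    Sigma_star = kss * C - V.T @ V
    Sigma_star = (Sigma_star + Sigma_star.T) / 2.0
    lo = float(np.linalg.eigvalsh(Sigma_star).min())
    if lo < -1e-8 * max(1.0, kss):
        raise np.linalg.LinAlgError(
            f"predictive covariance not PSD (min eigenvalue {lo:.3e})"
        )
    if lo < 0:
        Sigma_star += (1e-12 - lo) * np.eye(Q)
    return mu, Sigma_star


def predict_proba(
    mu: np.ndarray,
    Sigma: np.ndarray,
    n_samples: int = 5000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Monte-Carlo predictive probabilities p_k = E[sigma(g_k)],
    g ~ N(mu, Sigma).  Reproducible given the seed."""
    mu = np.asarray(mu, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    Q = mu.shape[0]
    if n_samples < 1:
        raise ValueError("need at least one Monte-Carlo sample")
    lo = float(np.linalg.eigvalsh(Sigma).min())
    if lo < -1e-6 * max(1.0, float(np.trace(Sigma)) / Q):
        raise np.linalg.LinAlgError(f"Sigma not PSD (min eigenvalue {lo:.3e})")
    jitter = max(0.0, -lo) + 1e-12
    root = np.linalg.cholesky(Sigma + jitter * np.eye(Q))
    if rng is None:
        rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_samples, Q))
    return expit(mu[None, :] + Z @ root.T).mean(axis=0)


def predict_proba_ghq(mu: np.ndarray, Sigma: np.ndarray, n_nodes: int = 64) -> np.ndarray:
    """Deterministic Gauss-Hermite predictive probabilities.

    p_k depends only on the marginal N(mu_k, Sigma_kk), so a 1-D
    quadrature per label is exact up to quadrature error regardless of
    the label correlations.
    """
    mu = np.asarray(mu, dtype=float)
    var = np.clip(np.diag(np.asarray(Sigma, dtype=float)), 0.0, None)
    x, wq = roots_hermite(n_nodes)
    nodes = mu[:, None] + np.sqrt(2.0 * var)[:, None] * x[None, :]
    return (expit(nodes) @ wq) / np.sqrt(np.pi)


def decide(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Decided label set {k : p_k > threshold}; if empty, the top-1
    label (every protein has at least one site).  Ties at the maximum
    go to the lowest label index."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    mask = p > threshold
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(p))] = True
    return mask


@dataclass
class PredictionResult:
    """Per-sample prediction: probabilities, induced ranking, decided set."""

    probabilities: np.ndarray
    ranking: np.ndarray        # label indices, best first
    decided: np.ndarray        # boolean mask, at least one True

    def __post_init__(self) -> None:
        if not self.decided.any():
            raise ValueError("decided set must be nonempty")


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------


class MultiLabelGP:
    """High-level estimator wiring kernels, weights, Laplace inference,
    evidence optimization and prediction together.

    Parameters
    ----------
    learn_C
        Learn the label-correlation matrix; ``False`` fixes C to the
        identity (independent locations — the ablation baseline).
    learn_a
        Learn the view-combination weights by evidence maximization.
    use_weights
        Apply the inverse-frequency likelihood weights; ``False`` uses
        uniform weights (imbalance ablation).
    threshold, mc_samples, max_evals, newton_tol
        Decision threshold, Monte-Carlo sample count, evidence
        evaluation budget and Newton gradient tolerance.
    proba_method
        "mc" (Monte-Carlo, the default) or "ghq" (deterministic
        Gauss-Hermite on the marginals).
    """

    def __init__(
        self,
        learn_C: bool = True,
        learn_a: bool = True,
        use_weights: bool = True,
        threshold: float = 0.5,
        mc_samples: int = 5000,
        max_evals: int = 300,
        maxiter: int = 40,
        newton_tol: float = 1e-6,
        proba_method: str = "mc",
        bandwidths: list[float] | str = "median",
        a_fixed: np.ndarray | None = None,
        seed: int | None = None,
    ) -> None:
        self.learn_C = learn_C
        self.learn_a = learn_a
        self.use_weights = use_weights
        self.threshold = threshold
        self.mc_samples = mc_samples
        self.max_evals = max_evals
        self.maxiter = maxiter
        self.newton_tol = newton_tol
        if proba_method not in ("mc", "ghq"):
            raise ValueError("proba_method must be 'mc' or 'ghq'")
        self.proba_method = proba_method
        self.bandwidths = bandwidths
        self.a_fixed = a_fixed
        self.seed = seed

    def fit(self, dataset: MultiViewDataset) -> "MultiLabelGP":
        if dataset.Y is None:
            raise ValueError("training dataset has no labels")
        Y = dataset.Y
        # drop labels with zero training positives: nothing to learn,
        # they are always predicted absent
        pos_counts = (Y > 0).sum(axis=0)
        self.active_labels_ = np.flatnonzero(pos_counts > 0)
        if len(self.active_labels_) < Y.shape[1]:
            dropped = np.flatnonzero(pos_counts == 0)
            names = dataset.label_names
            logger.warning(
                "dropping %d label(s) with zero training positives: %s",
                len(dropped),
                [names[k] if names else int(k) for k in dropped],
            )
        self.n_labels_total_ = Y.shape[1]
        Y = Y[:, self.active_labels_]

        self.train_views_ = [v.matrix for v in dataset.views]
        self.view_names_ = [v.name for v in dataset.views]
        bw = None if self.bandwidths == "median" else list(self.bandwidths)
        self.stack_ = KernelStack.from_views(dataset.views, bandwidths=bw)
        self.theta_ = np.array(self.stack_.bandwidths)

        self.w_ = sample_weights(Y) if self.use_weights else np.ones(len(Y))
        self.C_, self.a_, self.opt_trace_ = optimize_hyperparams(
            self.stack_, Y, self.w_,
            learn_C=self.learn_C, learn_a=self.learn_a,
            max_evals=self.max_evals, maxiter=self.maxiter,
            newton_tol=self.newton_tol, a_fixed=self.a_fixed,
        )
        K = combine(self.stack_, self.a_)
        self.posterior_ = laplace_fit(K, self.C_, Y, self.w_, tol=self.newton_tol)
        self.Y_ = Y
        self.params_ = ModelParams(
            C=self.C_, a=self.a_, theta=self.theta_, w=self.w_,
            opt_trace=self.opt_trace_,
        )
        return self

    def _cross_kernel(self, test_views: list[np.ndarray]) -> np.ndarray:
        if len(test_views) != len(self.train_views_):
            raise ValueError(
                f"expected {len(self.train_views_)} views, got {len(test_views)}"
            )
        n = self.train_views_[0].shape[0]
        t = test_views[0].shape[0]
        Kx = np.zeros((n, t))
        for Xtr, Xte, th, aj, name in zip(
            self.train_views_, test_views, self.theta_, self.a_, self.view_names_
        ):
            if Xte.shape[1] != Xtr.shape[1]:
                raise ValueError(
                    f"view {name!r}: test dimension {Xte.shape[1]} != "
                    f"training dimension {Xtr.shape[1]}"
                )
            Kx += aj * gaussian_gram(Xtr, th, Xte)
        return Kx

    def predict(
        self, test_views: list[np.ndarray], seed: int | None = None
    ) -> list[PredictionResult]:
        """Per-sample probabilities, ranking and decided set.

        Labels dropped at training time reappear with probability 0 and
        are never decided.
        """
        if not hasattr(self, "posterior_"):
            raise ValueError("model is not fitted")
        Kx = self._cross_kernel([np.atleast_2d(v) for v in test_views])
        kss = float(self.a_.sum())
        rng = np.random.default_rng(self.seed if seed is None else seed)
        out = []
        for col in Kx.T:
            mu, Sig = predict_latent(self.posterior_, col, kss)
            if self.proba_method == "ghq":
                p_act = predict_proba_ghq(mu, Sig)
            else:
                p_act = predict_proba(mu, Sig, self.mc_samples, rng=rng)
            p = np.zeros(self.n_labels_total_)
            p[self.active_labels_] = p_act
            mask = np.zeros(self.n_labels_total_, dtype=bool)
            mask[self.active_labels_] = decide(p_act, self.threshold)
            ranking = np.lexsort((np.arange(p.size), -p))
            out.append(PredictionResult(probabilities=p, ranking=ranking, decided=mask))
        return out

    def predict_proba_matrix(
        self, test_views: list[np.ndarray], seed: int | None = None
    ) -> np.ndarray:
        return np.vstack([r.probabilities for r in self.predict(test_views, seed=seed)])
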