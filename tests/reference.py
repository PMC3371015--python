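"""Independent reference implementations used as test oracles.

Everything here is deliberately written from scratch (dense algebra,
direct loops) and never calls into the package's inference code, so it
can serve as an independent cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, roots_hermite


# ---------------------------------------------------------------------------
# single-label binary Laplace GP (standard textbook algorithm, per label)
# ---------------------------------------------------------------------------


class BinaryLaplaceGP:
    """Textbook binary GP classifier with logistic likelihood and
    Laplace inference (Newton iteration on f, B = I + W^1/2 K W^1/2)."""

    def __init__(self, K: np.ndarray, y: np.ndarray):
        self.K = np.asarray(K, dtype=float)
        self.y = np.asarray(y, dtype=float)  # in {-1, +1}
        n = len(self.y)
        f = np.zeros(n)
        t = (self.y + 1) / 2
        for _ in range(200):
            pi = expit(f)
            W = pi * (1 - pi)
            sw = np.sqrt(W)
            B = np.eye(n) + sw[:, None] * self.K * sw[None, :]
            L = np.linalg.cholesky(B)
            b = W * f + (t - pi)
            v = np.linalg.solve(L, sw * (self.K @ b))
            a = b - sw * np.linalg.solve(L.T, v)
            f_new = self.K @ a
            if np.max(np.abs(f_new - f)) < 1e-12:
                f = f_new
                break
            f = f_new
        self.f_hat = f
        pi = expit(f)
        self.grad = t - pi
        self.W = pi * (1 - pi)
        sw = np.sqrt(self.W)
        self.L = np.linalg.cholesky(
            np.eye(n) + sw[:, None] * self.K * sw[None, :]
        )
        self.sw = sw

    def predict_latent(self, kstar: np.ndarray, kss: float) -> tuple[float, float]:
        mu = float(kstar @ self.grad)
        v = np.linalg.solve(self.L, self.sw * kstar)
        var = float(kss - v @ v)
        return mu, max(var, 0.0)

    def predict_proba(self, kstar: np.ndarray, kss: float, n_nodes: int = 64) -> float:
        mu, var = self.predict_latent(kstar, kss)
        x, w = roots_hermite(n_nodes)
        return float(expit(mu + np.sqrt(2 * var) * x) @ w / np.sqrt(np.pi))


# ---------------------------------------------------------------------------
# brute-force multi-label metrics (O(Q^2) pair loops)
# ---------------------------------------------------------------------------


def _rank_of(scores, k):
    """1-based rank of label k: labels with strictly higher score, or
    equal score and lower index, rank above it."""
    r = 1
    for j in range(len(scores)):
        if j == k:
            continue
        if scores[j] > scores[k] or (scores[j] == scores[k] and j < k):
            r += 1
    return r


def bf_average_precision(Y, S):
    vals = []
    for yi, si in zip(Y, S):
        true = [k for k in range(len(si)) if yi[k] > 0]
        acc = 0.0
        for k in true:
            rk = _rank_of(si, k)
            above = sum(1 for k2 in true if _rank_of(si, k2) <= rk)
            acc += above / rk
        vals.append(acc / len(true))
    return float(np.mean(vals))


def bf_coverage(Y, S):
    vals = []
    for yi, si in zip(Y, S):
        vals.append(max(_rank_of(si, k) for k in range(len(si)) if yi[k] > 0) - 1)
    return float(np.mean(vals))


def bf_ranking_loss(Y, S):
    vals = []
    for yi, si in zip(Y, S):
        pos = [k for k in range(len(si)) if yi[k] > 0]
        neg = [k for k in range(len(si)) if yi[k] <= 0]
        if not neg:
            continue
        bad = sum(1 for p in pos for q in neg if si[p] <= si[q])
        vals.append(bad / (len(pos) * len(neg)))
    return float(np.mean(vals))


def bf_set_metrics(Y, Yhat):
    rec, prec, exact = [], [], []
    for yi, pi in zip(Y, Yhat):
        t = {k for k in range(len(yi)) if yi[k] > 0}
        p = {k for k in range(len(pi)) if pi[k] > 0}
        rec.append(len(t & p) / len(t))
        prec.append(len(t & p) / len(p))
        exact.append(1.0 if t == p else 0.0)
    R, P = float(np.mean(rec)), float(np.mean(prec))
    f1 = 0.0 if P + R == 0 else 2 * P * R / (P + R)
    return R, P, f1, float(np.mean(exact))


# ---------------------------------------------------------------------------
# classic pseudo amino-acid composition by direct double loop
# ---------------------------------------------------------------------------


def bf_pseudo_aac(sequence, lam, weight, prop_tables, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    """Direct evaluation: standardize each property over the alphabet,
    average squared differences over properties for each residue pair,
    tier-average, then normalize the (20 + lam)-vector."""
    stand = []
    for tbl in prop_tables:
        vals = np.array([tbl[a] for a in alphabet], dtype=float)
        stand.append({a: (tbl[a] - vals.mean()) / vals.std() for a in alphabet})
    L = len(sequence)
    comp = np.array([sequence.count(a) for a in alphabet], dtype=float) / L
    taus = []
    for t in range(1, lam + 1):
        total = 0.0
        for i in range(L - t):
            a, b = sequence[i], sequence[i + t]
            theta = np.mean([(s[b] - s[a]) ** 2 for s in stand])
            total += theta
        taus.append(total / (L - t))
    taus = np.array(taus)
    denom = comp.sum() + weight * taus.sum()
    return np.concatenate([comp, weight * taus]) / denom
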