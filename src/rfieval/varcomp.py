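"""REML variance components for animal models.

Implements average-information (AI) REML with likelihood-guarded steps and an
EM/gradient fallback, for

* the univariate animal model  y = X b + u + e,  u ~ N(0, A σa²),
  e ~ N(0, I σe²), one record per animal, and
* the bivariate animal model with additive covariance A ⊗ K and residual
  covariance R ⊗ I (K, R 2x2), allowing animals missing one trait.

With one record per animal the relationship matrix can be eigendecomposed
once (A = U D U'); in the rotated basis every REML quantity is a sum of
per-animal scalar (univariate) or 2x2 (bivariate, complete-case) terms, so
each AI iteration costs O(n).  Bivariate data with missing-trait animals use
a dense P-matrix path instead.

The asymptotic covariance of the estimates is the inverse AI matrix at
convergence; standard errors of derived parameters (h², r_g) are obtained by
sampling component vectors from the asymptotic Gaussian and taking the SD of
the derived parameter across draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UnivariateAnimalModel",
    "BivariateAnimalModel",
    "UnivariateResults",
    "BivariateResults",
    "reml_univariate",
    "reml_bivariate",
    "sample_derived_se",
]

_BASIS2 = [
    np.array([[1.0, 0.0], [0.0, 0.0]]),
    np.array([[0.0, 1.0], [1.0, 0.0]]),
    np.array([[0.0, 0.0], [0.0, 1.0]]),
]


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the iteration trajectory."""

    def __init__(self, message, trajectory):
        super().__init__(message)
        self.trajectory = trajectory


def sample_derived_se(
    estimates,
    acov,
    func,
    n_draws: int = 100_000,
    seed=None,
    validity=None,
):
    """SE of a derived parameter by sampling the asymptotic distribution.

    Draws ``n_draws`` component vectors from N(estimates, acov), applies
    ``func`` to each draw, and returns ``(sd, n_rejected)``.  Draws for which
    ``validity`` (if given) is False are rejected; more than 50% rejections
    means the asymptotics are unreliable and raises.
    """
    est = np.asarray(estimates, dtype=float)
    acov = np.asarray(acov, dtype=float)
    if np.allclose(acov, 0):
        return 0.0, 0
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(est, acov, size=n_draws, method="eigh")
    if validity is not None:
        ok = np.array([validity(d) for d in draws])
    else:
        ok = np.ones(n_draws, dtype=bool)
    n_rej = int((~ok).sum())
    if n_rej > 0.5 * n_draws:
        raise RuntimeError(
            f"{n_rej}/{n_draws} draws produced invalid components; "
            "asymptotic covariance is unreliable"
        )
    vals = np.array([func(d) for d in draws[ok]])
    return float(np.std(vals)), n_rej


# ---------------------------------------------------------------------------
# univariate


@dataclass
class UnivariateResults:
    """Estimated additive and residual variance with REML diagnostics."""

    sigma_a2: float
    sigma_e2: float
    acov: np.ndarray  # 2x2 inverse-AI, order (sigma_a2, sigma_e2)
    loglike: float
    converged: bool
    boundary: bool
    n_iter: int
    trajectory: list = field(repr=False, default_factory=list)
    n_obs: int = 0

    @property
    def params(self) -> np.ndarray:
        return np.array([self.sigma_a2, self.sigma_e2])

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.acov), 0, None))

    @property
    def h2(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)

    def h2_se(self, method: str = "sample", n_draws: int = 100_000, seed=0) -> float:
        if method == "delta":
            sa, se = self.sigma_a2, self.sigma_e2
            tot = sa + se
            grad = np.array([se / tot**2, -sa / tot**2])
            return float(np.sqrt(grad @ self.acov @ grad))
        se_, _ = sample_derived_se(
            self.params,
            self.acov,
            lambda th: th[0] / (th[0] + th[1]),
            n_draws=n_draws,
            seed=seed,
            validity=lambda th: th[0] >= 0 and th[1] > 0,
        )
        return se_

    def summary(self) -> str:
        lines = [
            "Univariate animal model (AI-REML)",
            "=" * 48,
            f"{'n records':<26}{self.n_obs:>12d}",
            f"{'REML log-likelihood':<26}{self.loglike:>12.4f}",
            f"{'converged':<26}{str(self.converged):>12}"
            + ("  (boundary)" if self.boundary else ""),
            f"{'iterations':<26}{self.n_iter:>12d}",
            "-" * 48,
            f"{'component':<16}{'estimate':>12}{'SE':>12}",
            f"{'additive  (sa2)':<16}{self.sigma_a2:>12.4f}{self.bse[0]:>12.4f}",
            f"{'residual  (se2)':<16}{self.sigma_e2:>12.4f}{self.bse[1]:>12.4f}",
            f"{'heritability h2':<16}{self.h2:>12.4f}{self.h2_se('delta'):>12.4f}",
            "=" * 48,
        ]
        return "\n".join(lines)


class UnivariateAnimalModel:
    """Univariate animal model fitted by AI-REML.

    Parameters
    ----------
    y : array (n,)
        One phenotypic record per animal.
    relationship : array (n, n) or RelationshipMatrix
        Additive relationship matrix (pedigree A or genomic G) aligned to y.
    X : array (n, p), optional
        Fixed-effect design; defaults to an intercept.  REML estimates are
        invariant to the (full-rank) coding chosen.
    """

    def __init__(self, y, relationship, X=None, ids=None):
        self.y = np.asarray(y, dtype=float).ravel()
        n = len(self.y)
        vals = getattr(relationship, "values", relationship)
        self.A = np.asarray(vals, dtype=float)
        if self.A.shape != (n, n):
            raise ValueError("relationship matrix must be n x n, aligned with y")
        self.X = (
            np.ones((n, 1)) if X is None else np.asarray(X, dtype=float).reshape(n, -1)
        )
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")
        self.ids = ids
        self._decomposed = False

    def _decompose(self):
        if not self._decomposed:
            d, U = np.linalg.eigh(self.A)
            self.d = np.clip(d, 0.0, None)
            self.ty = U.T @ self.y
            self.tX = U.T @ self.X
            self._decomposed = True

    def _quantities(self, sa2, se2):
        d, ty, tX = self.d, self.ty, self.tX
        v = sa2 * d + se2
        vi = 1.0 / v
        W = tX.T @ (tX * vi[:, None])
        Wc = np.linalg.cholesky(W)
        beta = np.linalg.solve(W, tX.T @ (ty * vi))
        r = ty - tX @ beta
        Py = r * vi
        logdetW = 2.0 * np.sum(np.log(np.diag(Wc)))
        ll = -0.5 * (np.sum(np.log(v)) + logdetW + r @ Py)
        return v, vi, W, Py, ll

    def _P_apply(self, f, vi, W):
        tX = self.tX
        return f * vi - (self.tX @ np.linalg.solve(W, tX.T @ (f * vi))) * vi

    def loglike(self, sa2, se2) -> float:
        self._decompose()
        return self._quantities(sa2, se2)[-1]

    def _score_ai(self, sa2, se2):
        d, tX = self.d, self.tX
        v, vi, W, Py, ll = self._quantities(sa2, se2)
        Winv = np.linalg.inv(W)
        # diag of P in the rotated basis
        q = np.einsum("ij,jk,ik->i", tX, Winv, tX)
        Pdiag = vi - q * vi**2
        derivs = [d, np.ones_like(d)]
        score = np.empty(2)
        F = np.empty((len(d), 2))
        for k, w in enumerate(derivs):
            trPV = np.sum(w * Pdiag)
            f = w * Py
            F[:, k] = f
            score[k] = -0.5 * (trPV - Py @ f)
        PF = np.column_stack([self._P_apply(F[:, k], vi, W) for k in range(2)])
        AI = 0.5 * (F.T @ PF)
        return score, AI, ll, Py, Pdiag, derivs

    def fit(
        self,
        start=None,
        tol: float = 1e-8,
        gtol: float = 1e-6,
        maxiter: int = 200,
    ) -> UnivariateResults:
        """Maximize the restricted likelihood by AI-REML.

        AI steps are kept inside the parameter space and are required not to
        decrease the restricted log-likelihood (step-halving); when a step
        fails entirely, an EM-REML update (which cannot decrease the
        likelihood) is taken instead.  Convergence requires a relative
        parameter change below ``tol`` or a scaled gradient below ``gtol``.
        A vanishing additive variance is flagged as a boundary estimate,
        not an error.
        """
        self._decompose()
        vy = np.var(self.y)
        if vy == 0:
            raise ValueError("response has zero variance")
        floor = 1e-10 * vy
        theta = (
            np.array([0.5 * vy, 0.5 * vy]) if start is None else np.asarray(start, float)
        )
        theta = np.maximum(theta, floor)
        trajectory = []
        converged = False
        n = len(self.y)
        for it in range(maxiter):
            score, AI, ll, Py, Pdiag, derivs = self._score_ai(*theta)
            trajectory.append(
                {"iter": it, "sigma_a2": theta[0], "sigma_e2": theta[1], "loglike": ll}
            )
            rel_grad = np.linalg.norm(score * theta) / n
            try:
                delta = np.linalg.solve(AI, score)
            except np.linalg.LinAlgError:
                delta = score * theta**2 / n
            step = 1.0
            new = None
            for _ in range(30):
                cand = theta + step * delta
                if (cand > floor).all():
                    ll_new = self.loglike(*cand)
                    if ll_new >= ll - 1e-10:
                        new = cand
                        break
                step *= 0.5
            if new is None:
                # EM-REML fallback: guaranteed non-decreasing likelihood
                em = theta.copy()
                for k, w in enumerate(derivs):
                    trPV = np.sum(w * Pdiag)
                    em[k] = theta[k] + (theta[k] ** 2 / n) * (Py @ (w * Py) - trPV)
                new = np.maximum(em, floor)
            rel_change = np.max(np.abs(new - theta) / np.maximum(theta, floor))
            theta = new
            if rel_change < tol or rel_grad < gtol / n:
                converged = True
                break
        if not converged and maxiter > 2:
            raise ConvergenceError(
                f"AI-REML did not converge in {maxiter} iterations", trajectory
            )
        score, AI, ll, *_ = self._score_ai(*theta)
        try:
            acov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            acov = np.full((2, 2), np.nan)
        boundary = theta[0] <= 10 * floor
        return UnivariateResults(
            sigma_a2=float(theta[0]),
            sigma_e2=float(theta[1]),
            acov=acov,
            loglike=float(ll),
            converged=converged,
            boundary=bool(boundary),
            n_iter=len(trajectory),
            trajectory=trajectory,
            n_obs=n,
        )


# ---------------------------------------------------------------------------
# bivariate


@dataclass
class BivariateResults:
    """Genetic (K) and residual (R) 2x2 (co)variance estimates."""

    K: np.ndarray
    R: np.ndarray
    acov: np.ndarray  # 6x6, order (K11, K12, K22, R11, R12, R22)
    loglike: float
    converged: bool
    k_projected: bool
    n_iter: int
    trajectory: list = field(repr=False, default_factory=list)
    n_obs: tuple = (0, 0)

    param_names = ("K11", "K12", "K22", "R11", "R12", "R22")

    @property
    def params(self) -> np.ndarray:
        return np.array(
            [
                self.K[0, 0],
                self.K[0, 1],
                self.K[1, 1],
                self.R[0, 0],
                self.R[0, 1],
                self.R[1, 1],
            ]
        )

    @property
    def rg(self) -> float:
        return float(self.K[0, 1] / np.sqrt(self.K[0, 0] * self.K[1, 1]))

    @property
    def h2(self) -> np.ndarray:
        return np.array(
            [
                self.K[0, 0] / (self.K[0, 0] + self.R[0, 0]),
                self.K[1, 1] / (self.K[1, 1] + self.R[1, 1]),
            ]
        )

    def rg_se(self, n_draws: int = 100_000, seed=0) -> float:
        se_, _ = sample_derived_se(
            self.params,
            self.acov,
            lambda th: th[1] / np.sqrt(th[0] * th[2]),
            n_draws=n_draws,
            seed=seed,
            validity=lambda th: th[0] > 0 and th[2] > 0,
        )
        return se_

    def summary(self) -> str:
        bse = np.sqrt(np.clip(np.diag(self.acov), 0, None))
        lines = [
            "Bivariate animal model (AI-REML)",
            "=" * 48,
            f"{'n records (trait 1, 2)':<26}{str(self.n_obs):>16}",
            f"{'REML log-likelihood':<26}{self.loglike:>14.4f}",
            f"{'converged':<26}{str(self.converged):>14}"
            + ("  (K projected to PSD)" if self.k_projected else ""),
            "-" * 48,
            f"{'parameter':<12}{'estimate':>12}{'SE':>12}",
        ]
        for name, est, se_ in zip(self.param_names, self.params, bse):
            lines.append(f"{name:<12}{est:>12.4f}{se_:>12.4f}")
        lines += [
            f"{'r_g':<12}{self.rg:>12.4f}",
            f"{'h2 (t1,t2)':<12}{self.h2[0]:>12.4f}{self.h2[1]:>12.4f}",
            "=" * 48,
        ]
        return "\n".join(lines)


def _is_admissible(theta, floor):
    K = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
    R = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
    if theta[0] <= floor or theta[2] <= floor or theta[3] <= floor or theta[5] <= floor:
        return False
    # K may touch the PSD boundary; R must stay PD so every V_i is invertible
    if np.linalg.det(K) < -1e-12:
        return False
    if np.linalg.det(R) <= 0:
        return False
    return True


class BivariateAnimalModel:
    """Two-trait animal model fitted by AI-REML.

    Parameters
    ----------
    y1, y2 : arrays (n,)
        One record per animal and trait; NaN marks a missing trait record
        (each animal needs at least one trait).
    relationship : array (n, n) or RelationshipMatrix
        Additive relationship matrix covering all n animals.
    X1, X2 : optional per-trait fixed-effect designs; default an intercept
        (trait mean) each.
    """

    def __init__(self, y1, y2, relationship, X1=None, X2=None):
        self.y1 = np.asarray(y1, dtype=float).ravel()
        self.y2 = np.asarray(y2, dtype=float).ravel()
        n = len(self.y1)
        if len(self.y2) != n:
            raise ValueError("y1 and y2 must cover the same animals (use NaN)")
        vals = getattr(relationship, "values", relationship)
        self.A = np.asarray(vals, dtype=float)
        if self.A.shape != (n, n):
            raise ValueError("relationship matrix must be n x n")
        self.X1 = np.ones((n, 1)) if X1 is None else np.asarray(X1, float).reshape(n, -1)
        self.X2 = np.ones((n, 1)) if X2 is None else np.asarray(X2, float).reshape(n, -1)
        self.m1 = ~np.isnan(self.y1)
        self.m2 = ~np.isnan(self.y2)
        if not (self.m1 | self.m2).all():
            raise ValueError("every animal needs a record for at least one trait")
        self.complete = bool(self.m1.all() and self.m2.all())
        self._prepared = False

    # -- eigen path (complete records) --------------------------------------

    def _prepare_eigen(self):
        d, U = np.linalg.eigh(self.A)
        self.d = np.clip(d, 0.0, None)
        n = len(self.y1)
        self.tz = np.column_stack([U.T @ self.y1, U.T @ self.y2])  # (n, 2)
        p1, p2 = self.X1.shape[1], self.X2.shape[1]
        self.p = p1 + p2
        Xa = np.zeros((n, 2, self.p))
        Xa[:, 0, :p1] = U.T @ self.X1
        Xa[:, 1, p1:] = U.T @ self.X2
        self.Xa = Xa

    def _eigen_quantities(self, K, R):
        d, z, Xa = self.d, self.tz, self.Xa
        V = d[:, None, None] * K + R  # (n, 2, 2)
        det = V[:, 0, 0] * V[:, 1, 1] - V[:, 0, 1] ** 2
        Vinv = np.empty_like(V)
        Vinv[:, 0, 0] = V[:, 1, 1] / det
        Vinv[:, 1, 1] = V[:, 0, 0] / det
        Vinv[:, 0, 1] = Vinv[:, 1, 0] = -V[:, 0, 1] / det
        W = np.einsum("nia,nij,njb->ab", Xa, Vinv, Xa)
        rhs = np.einsum("nia,nij,nj->a", Xa, Vinv, z)
        Wc = np.linalg.cholesky(W)
        beta = np.linalg.solve(W, rhs)
        r = z - np.einsum("nia,a->ni", Xa, beta)
        Py = np.einsum("nij,nj->ni", Vinv, r)
        ll = -0.5 * (
            np.sum(np.log(det)) + 2 * np.sum(np.log(np.diag(Wc))) + np.einsum("ni,ni->", r, Py)
        )
        return V, Vinv, W, Py, ll

    def _eigen_P_apply(self, f, Vinv, W):
        Xa = self.Xa
        Vf = np.einsum("nij,nj->ni", Vinv, f)
        proj = np.linalg.solve(W, np.einsum("nia,ni->a", Xa, Vf))
        return Vf - np.einsum("nij,nja,a->ni", Vinv, Xa, proj)

    def _eigen_score_ai(self, K, R):
        d, Xa = self.d, self.Xa
        V, Vinv, W, Py, ll = self._eigen_quantities(K, R)
        Winv = np.linalg.inv(W)
        # S_i = Vinv_i X_i Winv X_i' Vinv_i  (2x2 per animal)
        XV = np.einsum("nij,nja->nia", Vinv, Xa)
        S = np.einsum("nia,ab,njb->nij", XV, Winv, XV)
        Pd = Vinv - S  # "block diagonal of P"
        score = np.empty(6)
        F = np.empty((len(d), 2, 6))
        for k in range(6):
            E = _BASIS2[k % 3]
            c = d if k < 3 else np.ones_like(d)
            trPV = np.einsum("n,nij,ji->", c, Pd, E)
            f = c[:, None] * np.einsum("ij,nj->ni", E, Py)
            F[:, :, k] = f
            score[k] = -0.5 * (trPV - np.einsum("ni,ni->", Py, f))
        AI = np.empty((6, 6))
        PF = np.stack(
            [self._eigen_P_apply(F[:, :, l], Vinv, W) for l in range(6)], axis=-1
        )
        for k in range(6):
            for l in range(k, 6):
                AI[k, l] = AI[l, k] = 0.5 * np.einsum("ni,ni->", F[:, :, k], PF[:, :, l])
        return score, AI, ll

    # -- dense path (missing-trait animals) ---------------------------------

    def _prepare_dense(self):
        i1 = np.where(self.m1)[0]
        i2 = np.where(self.m2)[0]
        self.i1, self.i2 = i1, i2
        self.n1, self.n2 = len(i1), len(i2)
        self.A11 = self.A[np.ix_(i1, i1)]
        self.A12 = self.A[np.ix_(i1, i2)]
        self.A22 = self.A[np.ix_(i2, i2)]
        # residual covariance only links the two records of the same animal
        self.C12 = (i1[:, None] == i2[None, :]).astype(float)
        self.yv = np.concatenate([self.y1[i1], self.y2[i2]])
        p1, p2 = self.X1.shape[1], self.X2.shape[1]
        Xd = np.zeros((self.n1 + self.n2, p1 + p2))
        Xd[: self.n1, :p1] = self.X1[i1]
        Xd[self.n1 :, p1:] = self.X2[i2]
        self.Xd = Xd

    def _dense_V(self, K, R):
        n1, n2 = self.n1, self.n2
        V = np.empty((n1 + n2, n1 + n2))
        V[:n1, :n1] = K[0, 0] * self.A11 + R[0, 0] * np.eye(n1)
        V[n1:, n1:] = K[1, 1] * self.A22 + R[1, 1] * np.eye(n2)
        V[:n1, n1:] = K[0, 1] * self.A12 + R[0, 1] * self.C12
        V[n1:, :n1] = V[:n1, n1:].T
        return V

    def _dense_quantities(self, K, R):
        from scipy.linalg import cho_factor, cho_solve

        V = self._dense_V(K, R)
        c, low = cho_factor(V, lower=True)
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        Vinv = cho_solve((c, low), np.eye(V.shape[0]))
        X = self.Xd
        VX = Vinv @ X
        W = X.T @ VX
        Wc = np.linalg.cholesky(W)
        P = Vinv - VX @ np.linalg.solve(W, VX.T)
        Py = P @ self.yv
        ll = -0.5 * (logdetV + 2 * np.sum(np.log(np.diag(Wc))) + self.yv @ Py)
        return P, Py, ll

    def _dense_apply_deriv(self, k, vec):
        """V̇_k @ vec for parameter k in (K11,K12,K22,R11,R12,R22)."""
        n1 = self.n1
        v1, v2 = vec[:n1], vec[n1:]
        out = np.zeros_like(vec)
        if k == 0:
            out[:n1] = self.A11 @ v1
        elif k == 1:
            out[:n1] = self.A12 @ v2
            out[n1:] = self.A12.T @ v1
        elif k == 2:
            out[n1:] = self.A22 @ v2
        elif k == 3:
            out[:n1] = v1
        elif k == 4:
            out[:n1] = self.C12 @ v2
            out[n1:] = self.C12.T @ v1
        else:
            out[n1:] = v2
        return out

    def _dense_score_ai(self, K, R):
        n1 = self.n1
        P, Py, ll = self._dense_quantities(K, R)
        P11, P12, P22 = P[:n1, :n1], P[:n1, n1:], P[n1:, n1:]
        traces = [
            np.sum(P11 * self.A11),
            2.0 * np.sum(P12 * self.A12),
            np.sum(P22 * self.A22),
            np.trace(P11),
            2.0 * np.sum(P12 * self.C12),
            np.trace(P22),
        ]
        F = np.column_stack([self._dense_apply_deriv(k, Py) for k in range(6)])
        score = np.array(
            [-0.5 * (traces[k] - Py @ F[:, k]) for k in range(6)]
        )
        AI = 0.5 * (F.T @ (P @ F))
        AI = 0.5 * (AI + AI.T)
        return score, AI, ll

    # -- shared fitting loop -------------------------------------------------

    def _score_ai(self, theta):
        K = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
        R = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
        if self.complete:
            return self._eigen_score_ai(K, R)
        return self._dense_score_ai(K, R)

    def loglike(self, theta) -> float:
        K = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
        R = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
        if self.complete:
            return self._eigen_quantities(K, R)[-1]
        return self._dense_quantities(K, R)[-1]

    def fit(
        self,
        start=None,
        tol: float = 1e-8,
        gtol: float = 1e-6,
        maxiter: int = 200,
    ) -> BivariateResults:
        """AI-REML for (K11, K12, K22, R11, R12, R22).

        Steps are guarded exactly as in the univariate model; the fallback is
        a likelihood-ascending scaled-gradient step.  If the converged K is
        indefinite it is projected to the nearest PSD matrix and flagged.
        """
        if self.complete:
            self._prepare_eigen()
        else:
            self._prepare_dense()
        v1 = np.nanvar(self.y1)
        v2 = np.nanvar(self.y2)
        floor = 1e-10 * max(v1, v2)
        if start is None:
            theta = np.array([0.5 * v1, 0.0, 0.5 * v2, 0.5 * v1, 0.0, 0.5 * v2])
        else:
            theta = np.asarray(start, dtype=float).copy()
        trajectory = []
        converged = False
        n = int(self.m1.sum() + self.m2.sum())
        for it in range(maxiter):
            score, AI, ll = self._score_ai(theta)
            trajectory.append({"iter": it, "theta": theta.copy(), "loglike": ll})
            rel_grad = np.linalg.norm(score * np.abs(theta)) / n
            try:
                delta = np.linalg.solve(AI + 1e-12 * np.eye(6), score)
            except np.linalg.LinAlgError:
                delta = score * np.abs(theta) / n
            new = None
            step = 1.0
            for _ in range(30):
                cand = theta + step * delta
                if _is_admissible(cand, floor):
                    ll_new = self.loglike(cand)
                    if ll_new >= ll - 1e-10:
                        new = cand
                        break
                step *= 0.5
            if new is None:
                # gradient-ascent fallback with likelihood guard
                g = score * np.maximum(np.abs(theta), floor) ** 2 / n
                step = 1.0
                for _ in range(30):
                    cand = theta + step * g
                    if _is_admissible(cand, floor) and self.loglike(cand) >= ll - 1e-10:
                        new = cand
                        break
                    step *= 0.5
                if new is None:
                    new = theta  # stuck at a boundary stationary point
            rel_change = np.max(
                np.abs(new - theta) / np.maximum(np.abs(theta), 1e-8)
            )
            theta = new
            if rel_change < tol or rel_grad < gtol / n:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"bivariate AI-REML did not converge in {maxiter} iterations",
                trajectory,
            )
        score, AI, ll = self._score_ai(theta)
        try:
            acov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            acov = np.full((6, 6), np.nan)
        K = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
        R = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
        k_projected = False
        w, Q = np.linalg.eigh(K)
        if w.min() < 0:
            K = (Q * np.clip(w, 0, None)) @ Q.T
            k_projected = True
        return BivariateResults(
            K=K,
            R=R,
            acov=acov,
            loglike=float(ll),
            converged=converged,
            k_projected=k_projected,
            n_iter=len(trajectory),
            trajectory=trajectory,
            n_obs=(int(self.m1.sum()), int(self.m2.sum())),
        )


def reml_univariate(y, relationship, X=None, **fit_kws) -> UnivariateResults:
    """Functional wrapper: fit the univariate animal model by AI-REML."""
    return UnivariateAnimalModel(y, relationship, X=X).fit(**fit_kws)


def reml_bivariate(y1, y2, relationship, X1=None, X2=None, **fit_kws) -> BivariateResults:
    """Functional wrapper: fit the bivariate animal model by AI-REML."""
    return BivariateAnimalModel(y1, y2, relationship, X1=X1, X2=X2).fit(**fit_kws)
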