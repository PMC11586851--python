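"""Two-step GBLUP: training mixed-model equations, indirect prediction of
non-phenotyped animals, and approximate reliabilities.

The variance components are estimated beforehand (pedigree-based REML) and
held fixed here.  Training GEBVs solve the standard mixed model equations
with λ = σe²/σa² on G_TT⁻¹; prediction animals get

    û_P = G_PT G_TT⁻¹ û_T,

and their prediction (co)variance is the quadratic form

    G_PT G_TT⁻¹ (G_TT σa² − C22 σe²) G_TT⁻¹ G_TP,

where C22 is the animal block of the inverse MME coefficient matrix.  Divided
by g_ii σa² (the additive variance of animal i) this becomes a reliability in
[0, 1] — the standard Var(û)/Var(u) definition.  Training reliabilities use
the prediction-error variance: rel_i = 1 − C22_ii σe² / (g_ii σa²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GBLUP",
    "GBLUPResults",
    "solve_training_mme",
    "indirect_predict",
    "reliability",
]


def solve_training_mme(y, X, G_TT, sigma_a2, sigma_e2):
    """Solve the training mixed model equations with fixed components.

    Returns ``(u_hat, C22, b_hat)``: training GEBVs, the animal block of the
    inverse coefficient matrix (unscaled; PEV = C22_ii σe²), and fixed-effect
    solutions.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    X = np.ones((n, 1)) if X is None else np.asarray(X, dtype=float).reshape(n, -1)
    G = np.asarray(getattr(G_TT, "values", G_TT), dtype=float)
    if sigma_a2 <= 0 or sigma_e2 <= 0:
        raise ValueError("variance components must be positive")
    lam = sigma_e2 / sigma_a2
    p = X.shape[1]
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "G_TT is singular; stabilize it first (diagonal epsilon or A-blend)"
        ) from err
    C = np.empty((p + n, p + n))
    C[:p, :p] = X.T @ X
    C[:p, p:] = X.T
    C[p:, :p] = X
    C[p:, p:] = np.eye(n) + lam * Ginv
    rhs = np.concatenate([X.T @ y, y])
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "MME coefficient matrix is singular (rank-deficient fixed effects?)"
        ) from err
    sol = Cinv @ rhs
    b_hat, u_hat = sol[:p], sol[p:]
    C22 = Cinv[p:, p:]
    return u_hat, C22, b_hat


def indirect_predict(G_PT, G_TT, u_hat_T):
    """û_P = G_PT G_TT⁻¹ û_T for non-phenotyped (prediction) animals."""
    G_PT = np.atleast_2d(np.asarray(G_PT, dtype=float))
    G = np.asarray(getattr(G_TT, "values", G_TT), dtype=float)
    u = np.asarray(u_hat_T, dtype=float).ravel()
    if G_PT.shape[1] != G.shape[0] or G.shape[0] != len(u):
        raise ValueError(
            f"dimension mismatch: G_PT {G_PT.shape}, G_TT {G.shape}, u_T {u.shape}"
        )
    return G_PT @ np.linalg.solve(G, u)


def reliability(G_PT, G_TT, C22, sigma_a2, sigma_e2, diag_GPP, tol: float = 1e-6):
    """Reliability of indirectly predicted GEBVs.

    Computes the prediction (co)variance quadratic form and normalizes each
    animal by its additive variance g_ii σa² so the result lies in [0, 1].
    Values outside [0, 1] beyond ``tol`` signal an inconsistent C22/G pairing
    and raise.
    """
    if sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be positive")
    G_PT = np.atleast_2d(np.asarray(G_PT, dtype=float))
    G = np.asarray(getattr(G_TT, "values", G_TT), dtype=float)
    B = np.linalg.solve(G, G_PT.T).T  # G_PT G_TT^{-1}
    M = G * sigma_a2 - np.asarray(C22) * sigma_e2
    quad = np.einsum("ij,jk,ik->i", B, M, B)
    rel = quad / (np.asarray(diag_GPP, dtype=float) * sigma_a2)
    if (rel < -tol).any() or (rel > 1 + tol).any():
        raise ValueError(
            f"reliabilities outside [0,1] (min {rel.min():.3g}, max {rel.max():.3g}); "
            "C22 does not match this G/variance-component pairing"
        )
    return np.clip(rel, 0.0, 1.0)


class GBLUP:
    """Two-step GBLUP model with fixed variance components.

    Parameters
    ----------
    y : array (n_T,)
        Phenotypes (e.g. RFI) of the training animals.
    G_TT : array or RelationshipMatrix
        Genomic relationships among training animals (invertible; run
        :func:`rfieval.relationships.stabilize` first if needed).
    sigma_a2, sigma_e2 : float
        Variance components from the pedigree-based REML fit, held fixed.
    X : optional fixed-effect design (default intercept).
    """

    def __init__(self, y, G_TT, sigma_a2, sigma_e2, X=None, ids=None):
        self.y = np.asarray(y, dtype=float).ravel()
        self.G_TT = np.asarray(getattr(G_TT, "values", G_TT), dtype=float)
        self.sigma_a2 = float(sigma_a2)
        self.sigma_e2 = float(sigma_e2)
        self.X = X
        self.ids = np.asarray(ids) if ids is not None else np.arange(len(self.y))

    def fit(self) -> "GBLUPResults":
        u_hat, C22, b_hat = solve_training_mme(
            self.y, self.X, self.G_TT, self.sigma_a2, self.sigma_e2
        )
        return GBLUPResults(
            gebv_training=u_hat,
            C22=C22,
            fixed_effects=b_hat,
            G_TT=self.G_TT,
            sigma_a2=self.sigma_a2,
            sigma_e2=self.sigma_e2,
            training_ids=self.ids,
        )


@dataclass
class GBLUPResults:
    """Training GEBVs plus everything needed for indirect prediction."""

    gebv_training: np.ndarray
    C22: np.ndarray
    fixed_effects: np.ndarray
    G_TT: np.ndarray
    sigma_a2: float
    sigma_e2: float
    training_ids: np.ndarray = field(default=None)

    def reliability_training(self) -> np.ndarray:
        """rel_i = 1 − C22_ii σe² / (g_ii σa²) for training animals."""
        pev = np.diag(self.C22) * self.sigma_e2
        rel = 1.0 - pev / (np.diag(self.G_TT) * self.sigma_a2)
        return np.clip(rel, 0.0, 1.0)

    def predict(self, G_PT) -> np.ndarray:
        return indirect_predict(G_PT, self.G_TT, self.gebv_training)

    def reliability(self, G_PT, diag_GPP) -> np.ndarray:
        return reliability(
            G_PT, self.G_TT, self.C22, self.sigma_a2, self.sigma_e2, diag_GPP
        )

    def gebv_table(
        self, G_PT=None, diag_GPP=None, prediction_ids=None, group=None
    ) -> pd.DataFrame:
        """Tidy GEBV table: animal_id, gebv, reliability, population tag."""
        rows = pd.DataFrame(
            {
                "animal_id": self.training_ids,
                "gebv": self.gebv_training,
                "reliability": self.reliability_training(),
                "population": "training",
            }
        )
        if G_PT is not None:
            up = self.predict(G_PT)
            rel = self.reliability(G_PT, diag_GPP)
            pids = (
                prediction_ids
                if prediction_ids is not None
                else np.arange(len(up))
            )
            rows = pd.concat(
                [
                    rows,
                    pd.DataFrame(
                        {
                            "animal_id": pids,
                            "gebv": up,
                            "reliability": rel,
                            "population": group if group is not None else "prediction",
                        }
                    ),
                ],
                ignore_index=True,
            )
        return rows

    def summary(self) -> str:
        rel = self.reliability_training()
        lines = [
            "Two-step GBLUP (fixed variance components)",
            "=" * 50,
            f"{'n training animals':<28}{len(self.gebv_training):>10d}",
            f"{'sigma_a2 / sigma_e2':<28}{self.sigma_a2:>10.4f} /{self.sigma_e2:>8.4f}",
            f"{'GEBV SD (training)':<28}{np.std(self.gebv_training):>10.4f}",
            f"{'mean reliability (training)':<28}{rel.mean():>10.4f}",
            "=" * 50,
        ]
        return "\n".join(lines)
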