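"""Genomic evaluation: GRM construction, GBLUP and REML variance components.

The bivariate model treats performance measured in the breeding environment
(B) and in the commercial environment (C) as two correlated traits:

    [y_B]   [X_B  0 ] [b_B]   [Z_B  0 ] [g_B]   [e_B]
    [y_C] = [0  X_C ] [b_C] + [0  Z_C ] [g_C] + [e_C]

with Var([g_B; g_C]) = Sigma_g (x) G for a marker-based genomic relationship
matrix G (VanRaden method 1, founder allele frequencies), and independent
residuals with per-environment variances.  Fixed effects are year classes
within environment.  The univariate model is the single-trait special case
used when no records are measured in C.

GEBV are the solutions of the mixed-model equations.  Variance components
are estimated by average-information REML with EM-REML fallback steps;
every trace needed for the scores and the EM updates is taken from the
inverse of the coefficient matrix, so the estimates maximize the restricted
likelihood of the exact model above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "VarianceComponents",
    "EvaluationData",
    "GBLUPResult",
    "REMLResult",
    "compute_grm",
    "invert_grm",
    "solve_gblup",
    "solve_bivariate_gblup",
    "solve_univariate_gblup",
    "estimate_varcomp_reml",
    "expected_bias",
]

ENV_B, ENV_C = 0, 1


@dataclass
class VarianceComponents:
    """Genetic (co)variances and residual variances of the two-trait model."""

    sigma2_gB: float
    sigma2_gC: float
    sigma_gBgC: float
    sigma2_eB: float
    sigma2_eC: float

    @classmethod
    def from_true(cls, r_g: float, h2: float) -> "VarianceComponents":
        """Simulation truth: unit genetic variances, covariance r_g,
        residual (1-h2)/h2 in both environments."""
        se2 = (1.0 - h2) / h2
        return cls(1.0, 1.0, float(r_g), se2, se2)

    @property
    def genetic_matrix(self) -> np.ndarray:
        return np.array(
            [[self.sigma2_gB, self.sigma_gBgC], [self.sigma_gBgC, self.sigma2_gC]]
        )

    @property
    def residual_variances(self) -> np.ndarray:
        return np.array([self.sigma2_eB, self.sigma2_eC])

    @property
    def h2_B(self) -> float:
        return self.sigma2_gB / (self.sigma2_gB + self.sigma2_eB)

    @property
    def h2_C(self) -> float:
        return self.sigma2_gC / (self.sigma2_gC + self.sigma2_eC)

    @property
    def genetic_correlation(self) -> float:
        return self.sigma_gBgC / np.sqrt(self.sigma2_gB * self.sigma2_gC)

    def validate(self) -> None:
        if self.sigma2_eB <= 0 or self.sigma2_eC <= 0:
            raise ValueError("residual variances must be positive")
        if np.linalg.eigvalsh(self.genetic_matrix).min() < -1e-10:
            raise ValueError("genetic covariance matrix must be positive semi-definite")


@dataclass
class EvaluationData:
    """Phenotypic records of genotyped fish mapped to animals and year classes.

    Each record belongs to exactly one animal (index into the rows of the
    GRM), one environment (0 = B, 1 = C) and one year.  Only genotyped fish
    contribute records: pedigrees and phenotypes of non-genotyped fish are
    not registered in the field design this mirrors.
    """

    y: np.ndarray
    animal: np.ndarray
    env: np.ndarray
    year: np.ndarray
    n_animals: int

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (len(self.animal) == len(self.env) == len(self.year) == n):
            raise ValueError("record vectors must have equal length")
        if n and (self.animal.min() < 0 or self.animal.max() >= self.n_animals):
            raise ValueError("animal indices out of range")

    @property
    def n_records(self) -> int:
        return int(len(self.y))

    @property
    def traits_present(self) -> np.ndarray:
        return np.unique(self.env)

    def fixed_effect_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """(class index per record, (env, year) label per class)."""
        labels, idx = np.unique(np.stack([self.env, self.year]), axis=1, return_inverse=True)
        return idx.ravel(), labels.T


def compute_grm(marker_genotypes: np.ndarray, allele_freqs: np.ndarray) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    ``marker_genotypes`` is the (n, m) dosage matrix (0/1/2); ``allele_freqs``
    are the reference (founder-generation) frequencies.  Loci whose reference
    frequency is not strictly inside (0, 1) are dropped.
    """
    Z = np.asarray(marker_genotypes, dtype=np.float64)
    p = np.asarray(allele_freqs, dtype=np.float64)
    if Z.ndim != 2 or p.shape != (Z.shape[1],):
        raise ValueError("genotypes must be (n, m) with one frequency per locus")
    keep = (p > 0.0) & (p < 1.0)
    if not keep.any():
        raise ValueError("no usable loci: all reference frequencies fixed")
    Z = Z[:, keep]
    p = p[keep]
    W = Z - 2.0 * p
    scale = 2.0 * np.sum(p * (1.0 - p))
    return (W @ W.T) / scale


def invert_grm(G: np.ndarray, max_ridge: float = 1e-2) -> tuple[np.ndarray, float]:
    """Inverse of the GRM, ridge-stabilizing the diagonal only if singular.

    Returns ``(G_inv, applied_ridge)`` where the ridge is the multiple of
    ``mean(diag(G))`` added to the diagonal (0.0 in the regular case).
    """
    base = float(np.mean(np.diag(G))) or 1.0
    for ridge in (0.0, 1e-8, 1e-6, 1e-4, max_ridge):
        try:
            cf = cho_factor(G + ridge * base * np.eye(G.shape[0]), lower=True, check_finite=False)
            return cho_solve(cf, np.eye(G.shape[0]), check_finite=False), ridge
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("GRM is singular even after ridge stabilization")


# ---------------------------------------------------------------------------
# mixed-model equations


class _MME:
    """Dense mixed-model equations for 1- or 2-trait GBLUP on a GRM.

    Solution order: fixed year-within-environment classes first, then animal
    effects trait-major (all animals trait 1, then all animals trait 2).
    """

    def __init__(self, data: EvaluationData, G_inv: np.ndarray, vc: VarianceComponents):
        self.data = data
        self.n = data.n_animals
        self.traits = [int(t) for t in data.traits_present]
        self.nt = len(self.traits)
        if self.nt == 0:
            raise ValueError("no records")
        self.trait_of = {t: k for k, t in enumerate(self.traits)}
        self.G_inv = G_inv

        Sg_full = vc.genetic_matrix
        self.Sg = Sg_full[np.ix_(self.traits, self.traits)]
        re_full = vc.residual_variances
        self.re = re_full[self.traits]
        if np.linalg.eigvalsh(self.Sg).min() <= 0:
            raise np.linalg.LinAlgError("genetic covariance matrix not positive definite")
        self.Sg_inv = np.linalg.inv(self.Sg)

        self.class_of, self.class_labels = data.fixed_effect_classes()
        self.p = self.class_labels.shape[0]
        k_env = np.array([self.trait_of[int(e)] for e in data.env])
        self.w = 1.0 / self.re[k_env]  # record weights
        self.ucol = self.p + k_env * self.n + data.animal  # column of each record's animal effect
        self.dim = self.p + self.nt * self.n
        self._build()

    def _build(self) -> None:
        d = self.data
        C = np.zeros((self.dim, self.dim))
        np.add.at(C, (self.class_of, self.class_of), self.w)
        np.add.at(C, (self.class_of, self.ucol), self.w)
        np.add.at(C, (self.ucol, self.class_of), self.w)
        np.add.at(C, (self.ucol, self.ucol), self.w)
        for a in range(self.nt):
            for b in range(self.nt):
                C[
                    self.p + a * self.n : self.p + (a + 1) * self.n,
                    self.p + b * self.n : self.p + (b + 1) * self.n,
                ] += self.Sg_inv[a, b] * self.G_inv
        rhs = np.zeros(self.dim)
        np.add.at(rhs, self.class_of, self.w * d.y)
        np.add.at(rhs, self.ucol, self.w * d.y)
        self.C = C
        self.rhs = rhs
        self.cf = cho_factor(C, lower=True, check_finite=False)
        self.sol = cho_solve(self.cf, rhs, check_finite=False)

    # -- helpers used by GBLUP and REML -----------------------------------
    @property
    def b_hat(self) -> np.ndarray:
        return self.sol[: self.p]

    def u_hat(self) -> np.ndarray:
        """(n, nt) animal solutions in local trait order."""
        return self.sol[self.p :].reshape(self.nt, self.n).T

    def residuals(self) -> np.ndarray:
        d = self.data
        return d.y - self.sol[self.class_of] - self.sol[self.ucol]

    def logdet_C(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self.cf[0]))))

    def inverse(self) -> np.ndarray:
        """Full inverse of the coefficient matrix from its Cholesky factor."""
        from scipy.linalg.lapack import dpotri

        inv, info = dpotri(self.cf[0], lower=True)
        if info != 0:
            return cho_solve(self.cf, np.eye(self.dim), check_finite=False)
        inv = np.tril(inv) + np.tril(inv, -1).T
        return inv

    def project(self, f: np.ndarray) -> np.ndarray:
        """P f for a record-space vector f (P = V^-1 - V^-1 X (X'V^-1 X)^- X'V^-1)."""
        wf = self.w * f
        t = np.zeros(self.dim)
        np.add.at(t, self.class_of, wf)
        np.add.at(t, self.ucol, wf)
        s = cho_solve(self.cf, t, check_finite=False)
        return wf - self.w * (s[self.class_of] + s[self.ucol])


def _solve_record_space(data: EvaluationData, G: np.ndarray, vc: VarianceComponents) -> "GBLUPResult":
    """GLS/BLUP through the phenotypic covariance matrix.

    With at most one record per animal the phenotypic covariance is simply
    ``V_rs = Sg[env_r, env_s] G[a_r, a_s] + delta_rs sigma2_e(env_r)``; this
    is algebraically identical to solving the mixed-model equations but
    factorizes an N x N instead of a (p + 2n) x (p + 2n) system and needs no
    inverse of G.
    """
    Sg = vc.genetic_matrix
    re = vc.residual_variances
    a = data.animal
    env = data.env
    Gaa = G if a.size == G.shape[0] and np.array_equal(a, np.arange(G.shape[0])) else G[np.ix_(a, a)]
    V = Sg[np.ix_(env, env)] * Gaa + np.diag(re[env])
    cf = cho_factor(V, lower=True, check_finite=False)
    class_of, labels = data.fixed_effect_classes()
    p = labels.shape[0]
    X = np.zeros((data.n_records, p))
    X[np.arange(data.n_records), class_of] = 1.0
    ViX = cho_solve(cf, X, check_finite=False)
    Viy = cho_solve(cf, data.y, check_finite=False)
    beta = np.linalg.solve(X.T @ ViX, X.T @ Viy)
    alpha = cho_solve(cf, data.y - X @ beta, check_finite=False)
    gebv = np.full((data.n_animals, 2), np.nan)
    for t in data.traits_present:
        w = Sg[t, env] * alpha
        gebv[:, int(t)] = G[:, a] @ w
    return GBLUPResult(gebv=gebv, fixed_effects=beta, fixed_labels=labels, applied_ridge=0.0)


def solve_gblup(
    data: EvaluationData,
    G: np.ndarray,
    vc: VarianceComponents,
    G_inv: np.ndarray | None = None,
) -> "GBLUPResult":
    """Solve the mixed-model equations for the traits present in ``data``.

    Animals without a record in one environment still receive a GEBV for
    that trait through the genomic relationships and the genetic covariance.
    When every record belongs to a distinct animal (the simulator's case)
    the equivalent record-space form is used, which avoids inverting G.
    """
    vc.validate()
    if G_inv is None and np.unique(data.animal).size == data.n_records:
        return _solve_record_space(data, G, vc)
    applied_ridge = 0.0
    if G_inv is None:
        G_inv, applied_ridge = invert_grm(G)
    mme = _MME(data, G_inv, vc)
    gebv = np.full((data.n_animals, 2), np.nan)
    u = mme.u_hat()
    for k, t in enumerate(mme.traits):
        gebv[:, t] = u[:, k]
    if mme.nt == 1:
        # single-trait model: no information flows to the unobserved trait
        other = 1 - mme.traits[0]
        gebv[:, other] = np.nan
    return GBLUPResult(
        gebv=gebv,
        fixed_effects=mme.b_hat,
        fixed_labels=mme.class_labels,
        applied_ridge=applied_ridge,
    )


@dataclass
class GBLUPResult:
    gebv: np.ndarray  # (n_animals, 2); NaN column if the trait was not in the model
    fixed_effects: np.ndarray
    fixed_labels: np.ndarray
    applied_ridge: float


def solve_bivariate_gblup(
    data: EvaluationData, G: np.ndarray, vc: VarianceComponents, G_inv: np.ndarray | None = None
) -> GBLUPResult:
    if len(data.traits_present) != 2:
        raise ValueError("bivariate model needs records in both environments")
    return solve_gblup(data, G, vc, G_inv)


def solve_univariate_gblup(
    data: EvaluationData, G: np.ndarray, vc: VarianceComponents, G_inv: np.ndarray | None = None
) -> GBLUPResult:
    if len(data.traits_present) != 1:
        raise ValueError("univariate model needs records from a single environment")
    return solve_gblup(data, G, vc, G_inv)


# ---------------------------------------------------------------------------
# REML


@dataclass
class REMLResult:
    varcomp: VarianceComponents
    converged: bool
    n_iterations: int
    minus2_loglik: float
    applied_ridge: float
    history: list = field(default_factory=list)


def _pack(Sg: np.ndarray, re: np.ndarray, nt: int) -> np.ndarray:
    gen = [Sg[i, j] for i in range(nt) for j in range(i, nt)]
    return np.array(gen + list(re))


def _unpack(theta: np.ndarray, nt: int) -> tuple[np.ndarray, np.ndarray]:
    Sg = np.zeros((nt, nt))
    k = 0
    for i in range(nt):
        for j in range(i, nt):
            Sg[i, j] = Sg[j, i] = theta[k]
            k += 1
    return Sg, theta[k:]


def _bend_psd(Sg: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the nearest one with eigenvalues >= floor."""
    vals, vecs = np.linalg.eigh(Sg)
    return (vecs * np.maximum(vals, floor)) @ vecs.T


def _vc_from(Sg: np.ndarray, re: np.ndarray, traits: list[int]) -> VarianceComponents:
    full_g = np.full((2, 2), np.nan)
    full_e = np.full(2, np.nan)
    for a, ta in enumerate(traits):
        full_e[ta] = re[a]
        for b, tb in enumerate(traits):
            full_g[ta, tb] = Sg[a, b]
    return VarianceComponents(
        sigma2_gB=full_g[0, 0],
        sigma2_gC=full_g[1, 1],
        sigma_gBgC=full_g[0, 1] if len(traits) == 2 else np.nan,
        sigma2_eB=full_e[0],
        sigma2_eC=full_e[1],
    )


def _initial_theta(data: EvaluationData, traits: list[int], nt: int) -> np.ndarray:
    """Moderate split of the within-class phenotypic variance."""
    vp = np.empty(nt)
    cls, _ = data.fixed_effect_classes()
    resid = data.y - np.bincount(cls, weights=data.y)[cls] / np.bincount(cls)[cls]
    for k, t in enumerate(traits):
        vp[k] = max(np.var(resid[data.env == t]), 1e-4)
    Sg = 0.4 * np.diag(vp) + 0.1 * np.sqrt(np.outer(vp, vp)) * (1 - np.eye(nt))
    re = 0.6 * vp
    return _pack(Sg, re, nt)


def _reml_record_space(
    data: EvaluationData,
    G: np.ndarray,
    init: VarianceComponents | None,
    tol: float,
    max_iter: int,
) -> REMLResult:
    """AI-REML in record space (one record per animal).

    Works on the explicit projection matrix
    ``P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1`` of the N x N phenotypic
    covariance, so every score, trace and average-information entry costs
    O(N^2).  Proposals outside the parameter space are bent back onto the
    PSD cone and rejected steps raise a Levenberg-style damping of the AI
    matrix, keeping the restricted likelihood non-decreasing.
    """
    traits = [int(t) for t in data.traits_present]
    nt = len(traits)
    N = data.n_records
    env = data.env
    k_env = np.searchsorted(np.array(traits), env)
    a = data.animal
    Gaa = G if a.size == G.shape[0] and np.array_equal(a, np.arange(G.shape[0])) else G[np.ix_(a, a)]
    class_of, labels = data.fixed_effect_classes()
    p = labels.shape[0]
    X = np.zeros((N, p))
    X[np.arange(N), class_of] = 1.0
    gen_pairs = [(i, j) for i in range(nt) for j in range(i, nt)]
    npar = len(gen_pairs) + nt

    if init is None:
        theta = _initial_theta(data, traits, nt)
    else:
        theta = _pack(
            init.genetic_matrix[np.ix_(traits, traits)], init.residual_variances[traits], nt
        )

    from scipy.linalg.lapack import dpotri

    def evaluate(theta_v):
        Sg, re = _unpack(theta_v, nt)
        if np.linalg.eigvalsh(Sg).min() <= 0 or np.any(re <= 0):
            return None
        V = Sg[np.ix_(k_env, k_env)] * Gaa + np.diag(re[k_env])
        try:
            cf = cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        logdet_V = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        Vi, info = dpotri(cf[0], lower=True)
        Vi = np.tril(Vi) + np.tril(Vi, -1).T
        ViX = Vi @ X
        XtViX = X.T @ ViX
        cfx = cho_factor(XtViX, lower=True, check_finite=False)
        logdet_X = 2.0 * float(np.sum(np.log(np.diag(cfx[0]))))
        P = Vi - ViX @ cho_solve(cfx, ViX.T, check_finite=False)
        Py = P @ data.y
        m2ll = logdet_V + logdet_X + float(data.y @ Py)
        return (Sg, re, P, Py, m2ll)

    state = evaluate(theta)
    if state is None:
        raise ValueError("initial variance components are outside the parameter space")
    history: list[dict] = []
    converged = False
    n_stalled = 0
    lam = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        Sg, re, P, Py, m2ll = state
        history.append({"iteration": it, "theta": theta.copy(), "minus2_loglik": m2ll})

        Qs = []
        for (i, j) in gen_pairs:
            E = np.zeros((nt, nt))
            E[i, j] = E[j, i] = 1.0
            Qs.append(E[np.ix_(k_env, k_env)] * Gaa)
        scores = np.empty(npar)
        F = np.empty((N, npar))
        for k, Q in enumerate(Qs):
            tr_PQ = float(np.sum(P * Q))
            f = Q @ Py
            F[:, k] = f
            scores[k] = -0.5 * (tr_PQ - float(Py @ f))
        for m in range(nt):
            k = len(gen_pairs) + m
            mask = k_env == m
            tr_PQ = float(np.sum(np.diag(P)[mask]))
            f = np.where(mask, Py, 0.0)
            F[:, k] = f
            scores[k] = -0.5 * (tr_PQ - float(Py @ f))
        PF = P @ F
        AI = 0.5 * (F.T @ PF)
        AI = 0.5 * (AI + AI.T)

        theta_new, state_new = None, None
        scale = float(np.trace(AI)) / npar + 1e-12
        for _ in range(4):
            try:
                delta = np.linalg.solve(AI + lam * scale * np.eye(npar), scores)
            except np.linalg.LinAlgError:
                lam = max(1e-6, 10.0 * lam)
                continue
            cand = theta + delta
            Sg_c, re_c = _unpack(cand, nt)
            floor = 1e-8 * max(float(np.max(np.abs(np.diag(Sg_c)))), 1.0)
            cand = _pack(_bend_psd(Sg_c, floor), np.maximum(re_c, 1e-10), nt)
            st = evaluate(cand)
            if st is not None and st[4] <= m2ll + 1e-8:
                theta_new, state_new = cand, st
                lam = lam / 10.0 if lam > 1e-8 else 0.0
                break
            lam = max(1e-4, 10.0 * lam)
        if theta_new is None:
            # EM-REML step through the gradient identity
            # Sg_em = Sg + (2/n) Sg D Sg with D the symmetric score matrix;
            # handles boundary approach monotonically where AI cannot
            D = np.zeros((nt, nt))
            for k, (i, j) in enumerate(gen_pairs):
                D[i, j] = D[j, i] = scores[k] if i == j else scores[k] / 2.0
            n_eff = data.n_animals
            Sg_em = Sg + (2.0 / n_eff) * (Sg @ D @ Sg)
            n_env = np.array([int(np.sum(k_env == m)) for m in range(nt)])
            re_em = re + (2.0 * re**2 / n_env) * scores[len(gen_pairs) :]
            base = _pack(Sg_em, re_em, nt) - theta
            for alpha in (4.0, 1.0):
                cand = theta + alpha * base
                Sg_c, re_c = _unpack(cand, nt)
                floor = 1e-8 * max(float(np.max(np.abs(np.diag(Sg_c)))), 1.0)
                cand = _pack(_bend_psd(Sg_c, floor), np.maximum(re_c, 1e-10), nt)
                st = evaluate(cand)
                if st is not None and st[4] <= m2ll + 1e-8:
                    theta_new, state_new = cand, st
                    break
        if theta_new is None:
            break  # no acceptable step under damping or EM

        rel = np.max(np.abs(theta_new - theta) / (np.abs(theta) + 1e-8))
        dll = abs(state_new[4] - m2ll)
        theta, state = theta_new, state_new
        # record-space iterations are cheap, so stall detection is patient
        n_stalled = n_stalled + 1 if dll < 1e-9 * (1.0 + abs(m2ll)) else 0
        if rel < tol or n_stalled >= 5:
            converged = True
            break

    Sg, re = _unpack(theta, nt)
    return REMLResult(
        varcomp=_vc_from(Sg, re, traits),
        converged=converged,
        n_iterations=it,
        minus2_loglik=state[4],
        applied_ridge=0.0,
        history=history,
    )


def estimate_varcomp_reml(
    data: EvaluationData,
    G: np.ndarray,
    init: VarianceComponents | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    method: str = "auto",
) -> REMLResult:
    """Average-information REML for the (bi)variate GBLUP model.

    With at most one record per animal (``method="auto"`` or ``"record"``)
    the iteration runs in record space on the explicit projection matrix;
    otherwise it works on the mixed-model equations.  In the MME form, AI
    steps are tried first (with step halving); whenever an AI step leaves
    the parameter space or decreases the restricted likelihood, an EM-REML
    step is taken instead, so every iteration increases the likelihood.
    Convergence is declared when the largest relative parameter change drops
    below ``tol`` or the likelihood stalls.
    """
    if method not in ("auto", "record", "mme"):
        raise ValueError("method must be 'auto', 'record' or 'mme'")
    if method in ("auto", "record") and np.unique(data.animal).size == data.n_records:
        return _reml_record_space(data, G, init, tol, max_iter)
    if method == "record":
        raise ValueError("record-space REML needs one record per animal")
    traits = [int(t) for t in data.traits_present]
    nt = len(traits)
    n = data.n_animals
    G_inv, applied_ridge = invert_grm(G)
    sign, logdet_G = np.linalg.slogdet(G + applied_ridge * float(np.mean(np.diag(G))) * np.eye(n))
    if sign <= 0:
        raise np.linalg.LinAlgError("GRM has non-positive determinant")

    # start values: a moderate split of the within-class phenotypic variance
    if init is None:
        vp = np.empty(nt)
        cls, _ = data.fixed_effect_classes()
        resid = data.y - np.bincount(cls, weights=data.y)[cls] / np.bincount(cls)[cls]
        for k, t in enumerate(traits):
            vp[k] = max(np.var(resid[data.env == t]), 1e-4)
        Sg = 0.4 * np.diag(vp) + 0.1 * np.sqrt(np.outer(vp, vp)) * (1 - np.eye(nt))
        re = 0.6 * vp
    else:
        Sg = init.genetic_matrix[np.ix_(traits, traits)].copy()
        re = init.residual_variances[traits].copy()

    n_env = np.array([int(np.sum(data.env == t)) for t in traits])
    theta = _pack(Sg, re, nt)
    npar = theta.size
    gen_pairs = [(i, j) for i in range(nt) for j in range(i, nt)]
    history: list[dict] = []
    prev_m2ll = np.inf
    converged = False
    n_stalled = 0
    it = 0

    def evaluate(theta_v: np.ndarray):
        Sg_, re_ = _unpack(theta_v, nt)
        if np.linalg.eigvalsh(Sg_).min() <= 0 or np.any(re_ <= 0):
            return None
        vc = _vc_from(Sg_, re_, traits)
        try:
            mme = _MME(data, G_inv, _expand(vc, traits))
        except np.linalg.LinAlgError:
            return None
        ehat = mme.residuals()
        Py = mme.w * ehat
        yPy = float(data.y @ Py)
        m2ll = (
            float(np.sum(n_env * np.log(re_)))
            + n * float(np.linalg.slogdet(Sg_)[1])
            + nt * logdet_G
            + mme.logdet_C()
            + yPy
        )
        return mme, Py, m2ll

    state = evaluate(theta)
    if state is None:
        raise ValueError("initial variance components are outside the parameter space")

    for it in range(1, max_iter + 1):
        mme, Py, m2ll = state
        u = mme.u_hat()  # (n, nt)
        A = mme.Sg_inv
        Cinv = mme.inverse()
        p = mme.p

        # traces of G^-1 against the animal blocks of C^-1
        T = np.empty((nt, nt))
        Giu = [G_inv @ u[:, k] for k in range(nt)]
        for a in range(nt):
            for b in range(nt):
                blk = Cinv[p + a * n : p + (a + 1) * n, p + b * n : p + (b + 1) * n]
                T[a, b] = float(np.sum(G_inv * blk.T))

        # per-record quadratic form w_r' C^-1 w_r
        diag_cls = Cinv[mme.class_of, mme.class_of]
        diag_u = Cinv[mme.ucol, mme.ucol]
        cross = Cinv[mme.class_of, mme.ucol]
        wCw = diag_cls + 2.0 * cross + diag_u

        # scores and AI working vectors
        scores = np.empty(npar)
        F = np.empty((data.n_records, npar))
        k_env = np.array([mme.trait_of[int(e)] for e in data.env])
        for k, (i, j) in enumerate(gen_pairs):
            E = np.zeros((nt, nt))
            E[i, j] = E[j, i] = 1.0
            EA = E @ A
            AEA = A @ EA
            tr_PQ = n * np.trace(EA) - float(np.sum(AEA * T))
            f = np.einsum("rt,rt->r", EA[k_env, :], u[data.animal, :])
            F[:, k] = f
            scores[k] = -0.5 * (tr_PQ - float(f @ Py))
        for a in range(nt):
            k = len(gen_pairs) + a
            mask = k_env == a
            tr_PD = float(np.sum(mask)) / mme.re[a] - float(np.sum(wCw[mask])) / mme.re[a] ** 2
            f = np.where(mask, Py, 0.0)
            F[:, k] = f
            scores[k] = -0.5 * (tr_PD - float(f @ Py))

        PF = np.column_stack([mme.project(F[:, k]) for k in range(npar)])
        AI = 0.5 * (F.T @ PF)
        AI = 0.5 * (AI + AI.T)

        history.append({"iteration": it, "theta": theta.copy(), "minus2_loglik": m2ll})

        # EM update, always available as a monotone fallback
        Sg_em = np.empty((nt, nt))
        for a in range(nt):
            for b in range(nt):
                Sg_em[a, b] = (float(u[:, a] @ Giu[b]) + T[a, b]) / n
        Sg_em = 0.5 * (Sg_em + Sg_em.T)
        re_em = np.empty(nt)
        ehat = mme.residuals()
        for a in range(nt):
            mask = k_env == a
            re_em[a] = (float(ehat[mask] @ ehat[mask]) + float(np.sum(wCw[mask]))) / n_env[a]
        theta_em = _pack(_bend_psd(Sg_em), np.maximum(re_em, 1e-10), nt)

        # AI step with halving, falling back to EM; proposals outside the
        # parameter space are projected back (PSD bending) so the search can
        # move along the r_g = +-1 boundary instead of stalling
        theta_new, state_new = None, None
        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(npar), scores)
        except np.linalg.LinAlgError:
            delta = None
        if delta is not None:
            step = 1.0
            for _ in range(3):
                cand = theta + step * delta
                Sg_c, re_c = _unpack(cand, nt)
                floor = 1e-8 * max(float(np.max(np.abs(np.diag(Sg_c)))), 1.0)
                cand = _pack(_bend_psd(Sg_c, floor), np.maximum(re_c, 1e-10), nt)
                st = evaluate(cand)
                if st is not None and st[2] <= m2ll + 1e-8:
                    theta_new, state_new = cand, st
                    break
                step *= 0.5
        if theta_new is None:
            # lengthened EM steps escape slow geometric crawls toward a
            # variance boundary; alpha = 1 is the plain (monotone) EM step
            base = theta_em - theta
            for alpha in (4.0, 1.0):
                cand = theta + alpha * base
                Sg_c, re_c = _unpack(cand, nt)
                floor = 1e-8 * max(float(np.max(np.abs(np.diag(Sg_c)))), 1.0)
                cand = _pack(_bend_psd(Sg_c, floor), np.maximum(re_c, 1e-10), nt)
                st = evaluate(cand)
                if st is not None and st[2] <= m2ll + 1e-8:
                    theta_new, state_new = cand, st
                    break
            if theta_new is None:
                # EM landed on the PSD boundary; bend harder and stop
                theta_new = _pack(
                    _bend_psd(_unpack(theta_em, nt)[0], 1e-4), _unpack(theta_em, nt)[1], nt
                )
                state_new = evaluate(theta_new)
                if state_new is None:
                    break

        rel = np.max(np.abs(theta_new - theta) / (np.abs(theta) + 1e-8))
        dll = abs(state_new[2] - m2ll)
        theta, state = theta_new, state_new
        prev_m2ll = m2ll
        n_stalled = n_stalled + 1 if dll < 1e-7 * (1.0 + abs(m2ll)) else 0
        if rel < tol or n_stalled >= 3:
            converged = True
            break

    Sg, re = _unpack(theta, nt)
    return REMLResult(
        varcomp=_vc_from(Sg, re, traits),
        converged=converged,
        n_iterations=it,
        minus2_loglik=state[2] if state is not None else prev_m2ll,
        applied_ridge=applied_ridge,
        history=history,
    )


def _expand(vc: VarianceComponents, traits: list[int]) -> VarianceComponents:
    """Fill NaN slots of a partial VarianceComponents so _MME can subset it."""
    g = vc.genetic_matrix
    e = vc.residual_variances
    g = np.where(np.isnan(g), np.eye(2), g)
    e = np.where(np.isnan(e), 1.0, e)
    return VarianceComponents(g[0, 0], g[1, 1], g[0, 1], e[0], e[1])


def expected_bias(r_g: float, vc: VarianceComponents, has_C_records: bool) -> float:
    """Expected regression slope of C-trait TBV on the selection-criterion GEBV.

    With C records in the model the slope has expectation 1.  Without them,
    selection is on the B-trait GEBV and the large-sample slope is
    r_g * sqrt(sigma2_gC / sigma2_gB), which equals r_g when the two genetic
    variances are equal.
    """
    if has_C_records:
        return 1.0
    return float(r_g) * float(np.sqrt(vc.sigma2_gC / vc.sigma2_gB))
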