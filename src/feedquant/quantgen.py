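"""Pedigree-based quantitative genetics: A matrix, animal-model REML,
heritabilities, genetic/phenotypic correlations, and correlated-response
selection efficiency.

The animal model is y = Xb + Za + e with b the fixed effects (sex and pen by
default), a ~ N(0, A * sigma_a^2) the additive genetic effect with A the
pedigree numerator relationship matrix, and e ~ N(0, I * sigma_e^2).  With one
record per phenotyped bird, Z selects the phenotyped rows of a, and the
phenotypic covariance V = sigma_a^2 * A_sub + sigma_e^2 * I is diagonalised by
a single symmetric eigendecomposition of A_sub.  All REML quantities (restricted
log-likelihood, scores, average-information matrix, EM updates) are then O(n)
per iteration in the rotated basis; the two-trait model block-diagonalises into
2x2 blocks per eigenvalue the same way.

Estimation is average-information REML with an EM-REML fallback whenever the
AI step fails or would decrease the restricted likelihood.  Variances are
floored at 1e-8 (on a per-trait standardised scale), non-positive-definite
covariance updates are bent to the nearest PD matrix, and convergence is a
restricted log-likelihood change below 1e-6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MixedModelSpec",
    "VarianceComponents",
    "SelectionEfficiencyResult",
    "PedigreeError",
    "REMLError",
    "sort_pedigree",
    "build_relationship_matrix",
    "reml_single_trait",
    "reml_two_trait",
    "selection_efficiency",
    "efficiency_table",
]

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-8
BEND_FLOOR = 1e-8


class PedigreeError(ValueError):
    pass


class REMLError(RuntimeError):
    """REML failure (unidentifiable model or non-convergence)."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class MixedModelSpec:
    """Animal-model specification: response structure and fitting controls."""

    fixed_effects: tuple[str, ...] = ("sex", "pen")
    max_iter: int = 200
    tol: float = 1e-6
    algorithm: str = "ai"  # "ai" (AI with EM fallback) or "em" (pure EM-REML)


@dataclass
class VarianceComponents:
    """REML estimates for one or two traits."""

    traits: list[str]
    G: pd.DataFrame  # additive genetic (co)variance
    R: pd.DataFrame  # residual (co)variance
    h2: pd.Series
    h2_se: pd.Series
    loglik: float
    n_iter: int
    converged: bool
    n_birds: int
    trace: list = field(default_factory=list, repr=False)
    r_g: float | None = None
    r_g_se: float | None = None
    r_p: float | None = None
    r_p_se: float | None = None
    bending_events: int = 0


@dataclass(frozen=True)
class SelectionEfficiencyResult:
    """Relative efficiency of indirect selection, (h1/h2) * r_A1A2."""

    primary_trait: str
    secondary_trait: str
    h1: float
    h2: float
    r_g: float
    efficiency: float


# ---------------------------------------------------------------------------
# pedigree and relationship matrix
# ---------------------------------------------------------------------------

def sort_pedigree(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Topologically sort a pedigree so parents precede offspring.

    Raises :class:`PedigreeError` naming the individuals on a cycle if any
    bird is (transitively) its own ancestor, and for parents that never
    appear as individuals.
    """
    ids = pedigree["id"].to_numpy()
    idset = set(ids)
    if len(idset) != len(ids):
        raise PedigreeError("duplicate individual ids in pedigree")
    for col in ("sire", "dam"):
        unknown = set(pedigree[col]) - idset - {0}
        if unknown:
            raise PedigreeError(
                f"{col}s {sorted(unknown)} never appear as individuals; "
                "add founder rows (sire=dam=0) for them"
            )

    children: dict = {i: [] for i in ids}
    indeg = {i: 0 for i in ids}
    for i, s, d in pedigree[["id", "sire", "dam"]].itertuples(index=False):
        for p in {s, d} - {0}:
            children[p].append(i)
            indeg[i] += 1

    order, queue = [], sorted(i for i in ids if indeg[i] == 0)
    while queue:
        node = queue.pop(0)
        order.append(node)
        ready = []
        for c in children[node]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
        queue.extend(sorted(ready))
    if len(order) != len(ids):
        cyclic = sorted(i for i in ids if indeg[i] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving ids {cyclic}")
    return pedigree.set_index("id").loc[order].reset_index()


def build_relationship_matrix(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Additive numerator relationship matrix A by the tabular method.

    a_ii = 1 + a(sire,dam)/2 and a_ij = (a(j,sire) + a(j,dam))/2 for j earlier
    in the (parents-first) ordering; unknown parents contribute zero.  Returns
    A as a DataFrame indexed by individual id.
    """
    ped = sort_pedigree(pedigree[["id", "sire", "dam"]].copy())
    ids = ped["id"].to_numpy()
    pos = {i: k for k, i in enumerate(ids)}
    sire_ix = np.array([pos.get(s, -1) for s in ped["sire"]])
    dam_ix = np.array([pos.get(d, -1) for d in ped["dam"]])

    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire_ix[i], dam_ix[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
    return pd.DataFrame(A, index=pd.Index(ids, name="id"), columns=ids)


# ---------------------------------------------------------------------------
# fixed-effect design
# ---------------------------------------------------------------------------

def _fixed_design(pheno: pd.DataFrame, factors: Sequence[str]):
    """Intercept + reference-coded dummies, reduced to full column rank.

    Pens nested within sex make a sex dummy linearly dependent on the pen
    dummies; dependent columns are dropped greedily (order-preserving) and
    logged.  Returns (X, kept column names).
    """
    cols = [np.ones(len(pheno))]
    names = ["intercept"]
    for factor in factors:
        if factor not in pheno.columns:
            raise ValueError(f"fixed effect {factor!r} not in phenotype table")
        levels = sorted(pheno[factor].astype(str).unique())
        for lev in levels[1:]:
            cols.append((pheno[factor].astype(str) == lev).to_numpy(float))
            names.append(f"{factor}[{lev}]")
    X = np.column_stack(cols)

    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        logger.info("dropped aliased fixed-effect columns: %s", dropped)
    return X[:, keep], [names[j] for j in keep]


def _eigen_rotation(A: pd.DataFrame, ids: Sequence):
    """Eigendecomposition of the phenotyped submatrix of A."""
    sub = A.loc[ids, ids].to_numpy()
    d, U = np.linalg.eigh(sub)
    d = np.clip(d, 0.0, None)
    if np.ptp(d) < 1e-9:
        raise REMLError(
            "additive and residual variances are not separately identifiable: "
            "the relationship matrix restricted to phenotyped birds is a "
            "multiple of the identity (all birds unrelated, single records)"
        )
    return d, U


# ---------------------------------------------------------------------------
# single-trait AI-REML
# ---------------------------------------------------------------------------

def _st_loglik(theta, d, Xr, yr):
    """Restricted log-likelihood and GLS pieces in the rotated basis."""
    va, ve = theta
    v = va * d + ve
    if np.any(v <= 0):
        return None
    vinv = 1.0 / v
    XtVX = Xr.T @ (Xr * vinv[:, None])
    sign, logdet_c = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return None
    beta = np.linalg.solve(XtVX, Xr.T @ (vinv * yr))
    resid = yr - Xr @ beta
    py = vinv * resid
    ll = -0.5 * (np.log(v).sum() + logdet_c + resid @ py)
    return {"ll": ll, "vinv": vinv, "py": py, "XtVX": XtVX, "beta": beta}


def _st_score_ai(state, d, Xr):
    vinv, py = state["vinv"], state["py"]
    Cinv = np.linalg.inv(state["XtVX"])
    deltas = (d, np.ones_like(d))
    score = np.empty(2)
    w = [delta * py for delta in deltas]
    # P w = V^-1 w - V^-1 X Cinv X' V^-1 w
    pw = []
    for wk in w:
        vw = vinv * wk
        pw.append(vw - vinv * (Xr @ (Cinv @ (Xr.T @ vw))))
    ai = np.empty((2, 2))
    for k, delta in enumerate(deltas):
        tr_vinv = np.sum(delta * vinv)
        M = Xr.T @ (Xr * (delta * vinv**2)[:, None])
        tr_pd = tr_vinv - np.trace(Cinv @ M)
        quad = np.sum(delta * py**2)
        score[k] = -0.5 * (tr_pd - quad)
        for l in range(2):
            ai[k, l] = 0.5 * (w[k] @ pw[l])
    return score, ai, {"tr_pd": None}


def _st_em_step(theta, state, d, Xr, n):
    vinv, py = state["vinv"], state["py"]
    Cinv = np.linalg.inv(state["XtVX"])
    new = np.empty(2)
    for k, delta in enumerate((d, np.ones_like(d))):
        tr_vinv = np.sum(delta * vinv)
        M = Xr.T @ (Xr * (delta * vinv**2)[:, None])
        tr_pd = tr_vinv - np.trace(Cinv @ M)
        quad = np.sum(delta * py**2)
        new[k] = theta[k] + theta[k] ** 2 * (quad - tr_pd) / n
    return np.maximum(new, VARIANCE_FLOOR)


def reml_single_trait(
    phenotypes: pd.DataFrame,
    trait: str,
    spec: MixedModelSpec,
    A: pd.DataFrame,
) -> VarianceComponents:
    """Single-trait animal-model REML for one column of the phenotype table.

    Phenotyped birds are the non-missing rows of ``trait`` that appear in A.
    Returns a :class:`VarianceComponents` with h2 and its delta-method SE from
    the inverse average-information matrix.
    """
    pheno = phenotypes.dropna(subset=[trait])
    ids = [i for i in pheno.index if i in A.index]
    if len(ids) < 10:
        raise ValueError(f"too few phenotyped birds in pedigree: {len(ids)}")
    pheno = pheno.loc[ids]
    y = pheno[trait].to_numpy(float)
    X, _ = _fixed_design(pheno, spec.fixed_effects)

    scale = y.std(ddof=1)
    if scale == 0:
        raise ValueError(f"trait {trait} has zero variance")
    ys = y / scale

    d, U = _eigen_rotation(A, ids)
    yr = U.T @ ys
    Xr = U.T @ X
    n = len(yr)

    theta = np.array([0.5, 0.5])
    state = _st_loglik(theta, d, Xr, yr)
    trace = [{"iter": 0, "loglik": state["ll"], "step": "init",
              "theta": theta.copy()}]
    converged = False
    for it in range(1, spec.max_iter + 1):
        if spec.algorithm == "em":
            theta_new, step = _st_em_step(theta, state, d, Xr, n), "EM"
            state_new = _st_loglik(theta_new, d, Xr, yr)
        else:
            score, ai, _ = _st_score_ai(state, d, Xr)
            theta_new, step, state_new = None, None, None
            try:
                cand = np.maximum(theta + np.linalg.solve(ai, score), VARIANCE_FLOOR)
                cand_state = _st_loglik(cand, d, Xr, yr)
                if cand_state is not None and cand_state["ll"] >= state["ll"] - 1e-10:
                    theta_new, step, state_new = cand, "AI", cand_state
            except np.linalg.LinAlgError:
                pass
            if theta_new is None:
                theta_new = _st_em_step(theta, state, d, Xr, n)
                step = "EM"
                state_new = _st_loglik(theta_new, d, Xr, yr)
        delta_ll = state_new["ll"] - state["ll"]
        theta, state = theta_new, state_new
        trace.append({"iter": it, "loglik": state["ll"], "step": step,
                      "theta": theta.copy()})
        if abs(delta_ll) < spec.tol:
            converged = True
            break
    if not converged:
        raise REMLError(
            f"REML did not converge in {spec.max_iter} iterations for trait "
            f"{trait} (last delta logL {delta_ll:.3e})",
            trace=trace,
        )

    _, ai, _ = _st_score_ai(state, d, Xr)
    try:
        cov_theta = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov_theta = np.linalg.pinv(ai)
    va, ve = theta * scale**2
    cov_theta = cov_theta * scale**4
    s = va + ve
    h2 = va / s
    grad = np.array([ve, -va]) / s**2
    h2_se = float(np.sqrt(max(grad @ cov_theta @ grad, 0.0)))

    return VarianceComponents(
        traits=[trait],
        G=pd.DataFrame([[va]], index=[trait], columns=[trait]),
        R=pd.DataFrame([[ve]], index=[trait], columns=[trait]),
        h2=pd.Series({trait: h2}),
        h2_se=pd.Series({trait: h2_se}),
        loglik=float(state["ll"]),
        n_iter=trace[-1]["iter"],
        converged=converged,
        n_birds=n,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# two-trait AI-REML
# ---------------------------------------------------------------------------

_E_BASIS = (
    np.array([[1.0, 0.0], [0.0, 0.0]]),
    np.array([[0.0, 1.0], [1.0, 0.0]]),
    np.array([[0.0, 0.0], [0.0, 1.0]]),
)


def _theta_to_mats(theta):
    G = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
    R = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
    return G, R


def _mats_to_theta(G, R):
    return np.array([G[0, 0], G[0, 1], G[1, 1], R[0, 0], R[0, 1], R[1, 1]])


def _bend_pd(M, floor=BEND_FLOOR):
    """Clip eigenvalues at a small positive floor (nearest-PD bending)."""
    w, v = np.linalg.eigh(M)
    if w.min() >= floor:
        return M, False
    w = np.clip(w, floor, None)
    return (v * w) @ v.T, True


def _inv2(M):
    """Inverse and log-determinant of a stack of 2x2 matrices."""
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    if np.any(det <= 0) or np.any(M[:, 0, 0] <= 0):
        return None, None
    inv = np.empty_like(M)
    inv[:, 0, 0] = M[:, 1, 1]
    inv[:, 1, 1] = M[:, 0, 0]
    inv[:, 0, 1] = -M[:, 0, 1]
    inv[:, 1, 0] = -M[:, 1, 0]
    inv /= det[:, None, None]
    return inv, np.log(det).sum()


def _bt_loglik(theta, d, Xr, Yr):
    G, R = _theta_to_mats(theta)
    M = d[:, None, None] * G[None] + R[None]
    Minv, logdet_v = _inv2(M)
    if Minv is None:
        return None
    n, p = Xr.shape
    # C = sum_i Minv_i (x) (x_i x_i'), assembled block-wise (2p x 2p)
    C = np.empty((2 * p, 2 * p))
    for a in range(2):
        for b in range(2):
            C[a * p:(a + 1) * p, b * p:(b + 1) * p] = Xr.T @ (
                Xr * Minv[:, a, b, None]
            )
    sign, logdet_c = np.linalg.slogdet(C)
    if sign <= 0:
        return None
    w = np.einsum("nab,nb->na", Minv, Yr)
    rhs = np.concatenate([Xr.T @ w[:, 0], Xr.T @ w[:, 1]])
    beta = np.linalg.solve(C, rhs)
    fitted = np.column_stack([Xr @ beta[:p], Xr @ beta[p:]])
    resid = Yr - fitted
    py = np.einsum("nab,nb->na", Minv, resid)
    ll = -0.5 * (logdet_v + logdet_c + np.sum(resid * py))
    return {"ll": ll, "Minv": Minv, "py": py, "C": C, "beta": beta}


def _bt_derivative_coeffs(d):
    """(coefficient vector, E) for each of the 6 parameters (G then R)."""
    ones = np.ones_like(d)
    return [(d, E) for E in _E_BASIS] + [(ones, E) for E in _E_BASIS]


def _bt_apply_p(vec, Minv, Xr, Cinv):
    """P applied to a stacked (n,2) vector in the rotated basis."""
    n, p = Xr.shape
    v = np.einsum("nab,nb->na", Minv, vec)
    t = np.concatenate([Xr.T @ v[:, 0], Xr.T @ v[:, 1]])
    gamma = Cinv @ t
    correction = np.column_stack([Xr @ gamma[:p], Xr @ gamma[p:]])
    return v - np.einsum("nab,nb->na", Minv, correction)


def _bt_score_ai(state, d, Xr):
    Minv, py = state["Minv"], state["py"]
    Cinv = np.linalg.inv(state["C"])
    n, p = Xr.shape
    coeffs = _bt_derivative_coeffs(d)

    score = np.empty(6)
    ws = []
    for k, (c, E) in enumerate(coeffs):
        # tr(P dV) = sum_i c_i tr(Minv_i E) - tr(Cinv S), S from Minv E Minv
        T = np.einsum("nab,bc,ncd->nad", Minv, E, Minv) * c[:, None, None]
        S = np.empty((2 * p, 2 * p))
        for a in range(2):
            for b in range(2):
                S[a * p:(a + 1) * p, b * p:(b + 1) * p] = Xr.T @ (
                    Xr * T[:, a, b, None]
                )
        tr_pd = np.sum(c * np.einsum("nab,ba->n", Minv, E)) - np.sum(Cinv * S.T)
        wk = c[:, None] * np.einsum("ab,nb->na", E, py)
        quad = np.sum(py * wk)
        score[k] = -0.5 * (tr_pd - quad)
        ws.append(wk)

    ai = np.empty((6, 6))
    pws = [_bt_apply_p(wk, Minv, Xr, Cinv) for wk in ws]
    for k in range(6):
        for l in range(k, 6):
            ai[k, l] = ai[l, k] = 0.5 * np.sum(ws[k] * pws[l])
    return score, ai


def _bt_em_step(theta, state, d, Xr, n):
    """EM-REML update: G += G S_G G / n, R += R S_R R / n (then bending)."""
    Minv, py = state["Minv"], state["py"]
    Cinv = np.linalg.inv(state["C"])
    p = Xr.shape[1]
    # H_i[b,e] = x_i' Cinv[b,e] x_i for the 4 blocks of Cinv
    H = np.empty((n, 2, 2))
    for b in range(2):
        for e in range(2):
            block = Cinv[b * p:(b + 1) * p, e * p:(e + 1) * p]
            H[:, b, e] = np.einsum("ni,ij,nj->n", Xr, block, Xr)
    BCB = np.einsum("nab,nbe,nce->nac", Minv, H, Minv)
    P_ii = Minv - BCB
    outer = np.einsum("na,nc->nac", py, py)
    S_G = np.einsum("n,nac->ac", d, outer - P_ii)
    S_R = np.sum(outer - P_ii, axis=0)
    G, R = _theta_to_mats(theta)
    G_new = G + (G @ S_G @ G) / n
    R_new = R + (R @ S_R @ R) / n
    G_new, bent_g = _bend_pd(G_new)
    R_new, bent_r = _bend_pd(R_new)
    return _mats_to_theta(G_new, R_new), (bent_g or bent_r)


def reml_two_trait(
    phenotypes: pd.DataFrame,
    traits: tuple[str, str],
    spec: MixedModelSpec,
    A: pd.DataFrame,
) -> VarianceComponents:
    """Bivariate animal-model REML on birds with both traits observed.

    Estimates the 2x2 genetic and residual covariance matrices, the genetic
    correlation r_g = G12/sqrt(G11 G22) and the phenotypic correlation
    r_p = (G12+R12)/sqrt((G11+R11)(G22+R22)), with delta-method SEs from the
    inverse average-information matrix.  Non-PD updates are bent to the
    nearest PD matrix and counted in ``bending_events``.
    """
    t1, t2 = traits
    pheno = phenotypes.dropna(subset=[t1, t2])
    ids = [i for i in pheno.index if i in A.index]
    if len(ids) < 10:
        raise ValueError(f"too few phenotyped birds in pedigree: {len(ids)}")
    pheno = pheno.loc[ids]
    Y = pheno[[t1, t2]].to_numpy(float)
    X, _ = _fixed_design(pheno, spec.fixed_effects)

    scales = Y.std(axis=0, ddof=1)
    if np.any(scales == 0):
        raise ValueError(f"trait with zero variance among {traits}")
    Ys = Y / scales

    d, U = _eigen_rotation(A, ids)
    Yr = U.T @ Ys
    Xr = U.T @ X
    n = len(d)

    corr0 = float(np.clip(np.corrcoef(Ys.T)[0, 1], -0.9, 0.9))
    G0 = 0.5 * np.array([[1.0, corr0], [corr0, 1.0]])
    theta = _mats_to_theta(G0, G0.copy())
    state = _bt_loglik(theta, d, Xr, Yr)
    trace = [{"iter": 0, "loglik": state["ll"], "step": "init"}]
    bending_events = 0
    converged = False
    for it in range(1, spec.max_iter + 1):
        if spec.algorithm == "em":
            theta_new, bent = _bt_em_step(theta, state, d, Xr, n)
            step, state_new = "EM", _bt_loglik(theta_new, d, Xr, Yr)
        else:
            score, ai = _bt_score_ai(state, d, Xr)
            theta_new, step, state_new, bent = None, None, None, False
            try:
                cand = theta + np.linalg.solve(ai, score)
                Gc, Rc = _theta_to_mats(cand)
                Gc, bg = _bend_pd(Gc)
                Rc, br = _bend_pd(Rc)
                cand = _mats_to_theta(Gc, Rc)
                cand_state = _bt_loglik(cand, d, Xr, Yr)
                if cand_state is not None and cand_state["ll"] >= state["ll"] - 1e-10:
                    theta_new, step, state_new = cand, "AI", cand_state
                    bent = bg or br
            except np.linalg.LinAlgError:
                pass
            if theta_new is None:
                theta_new, bent = _bt_em_step(theta, state, d, Xr, n)
                step = "EM"
                state_new = _bt_loglik(theta_new, d, Xr, Yr)
        if state_new is None:
            raise REMLError(
                f"invalid covariance update at iteration {it} for traits {traits}",
                trace=trace,
            )
        bending_events += int(bent)
        delta_ll = state_new["ll"] - state["ll"]
        theta, state = theta_new, state_new
        trace.append({"iter": it, "loglik": state["ll"], "step": step})
        if abs(delta_ll) < spec.tol:
            converged = True
            break
    if not converged:
        raise REMLError(
            f"bivariate REML did not converge in {spec.max_iter} iterations for "
            f"traits {traits} (last delta logL {delta_ll:.3e})",
            trace=trace,
        )

    _, ai = _bt_score_ai(state, d, Xr)
    try:
        cov_theta = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov_theta = np.linalg.pinv(ai)

    # back to original trait scales
    s1, s2 = scales
    scale_vec = np.array([s1 * s1, s1 * s2, s2 * s2] * 2)
    theta_o = theta * scale_vec
    cov_o = cov_theta * np.outer(scale_vec, scale_vec)

    def h2_1(t):
        return t[0] / (t[0] + t[3])

    def h2_2(t):
        return t[2] / (t[2] + t[5])

    def rg(t):
        return t[1] / np.sqrt(t[0] * t[2])

    def rp(t):
        return (t[1] + t[4]) / np.sqrt((t[0] + t[3]) * (t[2] + t[5]))

    def delta_se(fn):
        grad = np.empty(6)
        for k in range(6):
            h = 1e-6 * max(abs(theta_o[k]), 1e-3)
            tp, tm = theta_o.copy(), theta_o.copy()
            tp[k] += h
            tm[k] -= h
            grad[k] = (fn(tp) - fn(tm)) / (2 * h)
        return float(np.sqrt(max(grad @ cov_o @ grad, 0.0)))

    G, R = _theta_to_mats(theta_o)
    return VarianceComponents(
        traits=[t1, t2],
        G=pd.DataFrame(G, index=[t1, t2], columns=[t1, t2]),
        R=pd.DataFrame(R, index=[t1, t2], columns=[t1, t2]),
        h2=pd.Series({t1: h2_1(theta_o), t2: h2_2(theta_o)}),
        h2_se=pd.Series({t1: delta_se(h2_1), t2: delta_se(h2_2)}),
        loglik=float(state["ll"]),
        n_iter=trace[-1]["iter"],
        converged=converged,
        n_birds=n,
        trace=trace,
        r_g=float(rg(theta_o)),
        r_g_se=delta_se(rg),
        r_p=float(rp(theta_o)),
        r_p_se=delta_se(rp),
        bending_events=bending_events,
    )


# ---------------------------------------------------------------------------
# correlated response to selection
# ---------------------------------------------------------------------------

def selection_efficiency(
    h1: float, h2: float, r_g: float,
    primary_trait: str = "primary", secondary_trait: str = "secondary",
) -> SelectionEfficiencyResult:
    """Relative efficiency of indirect selection: (h1/h2) * r_g.

    h1 and h2 are the tabulated heritability values of the primary and
    secondary traits, used directly (not through square roots); see the
    methods note for how this convention relates to the classical
    correlated-response formula.
    """
    if h2 == 0:
        raise ValueError("secondary-trait heritability h2 must be nonzero")
    return SelectionEfficiencyResult(
        primary_trait=primary_trait,
        secondary_trait=secondary_trait,
        h1=h1,
        h2=h2,
        r_g=r_g,
        efficiency=(h1 / h2) * r_g,
    )


def efficiency_table(
    h2: Mapping[str, float],
    r_g: Mapping[tuple[str, str], float],
    primary_traits: Sequence[str],
    secondary_traits: Sequence[str],
) -> pd.DataFrame:
    """Cross table of relative selection efficiencies.

    ``r_g`` is keyed by trait pairs (either order); cells with a missing
    heritability or correlation are NaN.
    """
    lookup = {}
    for (a, b), r in r_g.items():
        lookup[(a, b)] = r
        lookup[(b, a)] = r
    table = pd.DataFrame(
        index=pd.Index(secondary_traits, name="secondary"),
        columns=pd.Index(primary_traits, name="primary"),
        dtype=float,
    )
    for p in primary_traits:
        for s in secondary_traits:
            if p in h2 and s in h2 and h2[s] != 0 and (p, s) in lookup:
                table.loc[s, p] = selection_efficiency(
                    h2[p], h2[s], lookup[(p, s)], p, s
                ).efficiency
    return table
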