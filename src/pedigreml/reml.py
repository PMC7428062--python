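"""Restricted maximum likelihood engine for animal models.

The model is a Gaussian linear mixed model over phenotype records::

    y = X b + sum_t Z_t u_t + e

where each random term ``t`` attaches a latent vector of dimension K to
every individual (random-regression intercepts and slopes, possibly for
several traits at once).  A *genetic* term has covariance ``A (x) Sigma``
across individuals, with A the pedigree additive relationship matrix; a
non-genetic (permanent-environment / among-individual) term has
``I (x) Sigma``.  Residuals are independent with a per-trait variance,
optionally fixed to zero for traits observed once per individual.

The REML criterion maximised over the variance parameters is

    l = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ]

with ``P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1`` and the additive constant
dropped (it is fixed across compared models).

Three evaluation paths keep this fast at study scale: individuals are
independent when no genetic term is present, so V is block diagonal; with
a genetic term and a *balanced* record template (every individual measured
on the same trait/session layout) an eigen-rotation of A decouples the
individuals; otherwise the dense marginal covariance is assembled
directly (suitable for small problems).

Covariance matrices are parameterised by Cholesky factors (optionally in
block-diagonal structure), so positive semi-definiteness is maintained
without explicit constraints.  Standard errors come from the observed
information (finite-difference Hessian) in the natural covariance
parameters; boundary parameters get no standard error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import eigh as sp_eigh, solve_triangular

logger = logging.getLogger(__name__)

_BIG = 1e12


class RemlError(RuntimeError):
    pass


@dataclass
class RandomTerm:
    """One individual-level random term.

    ``dims`` label the latent components, conventionally
    ``"<trait>:int"`` / ``"<trait>:slope"``.  ``Z`` is the (N, K) matrix
    of record loadings (1 for the intercept of the record's trait, the
    scaled session ``s`` for its slope, 0 elsewhere).  ``blocks``
    partitions the dims into unstructured covariance blocks; covariances
    across blocks are fixed at zero.
    """

    name: str
    dims: list[str]
    Z: np.ndarray
    genetic: bool = False
    blocks: list[list[int]] | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.blocks is None:
            self.blocks = [list(range(len(self.dims)))]
        covered = sorted(i for b in self.blocks for i in b)
        if covered != list(range(len(self.dims))):
            raise ValueError(f"blocks of term {self.name} do not partition dims")


@dataclass
class MixedModelData:
    """Design for one REML fit.

    ``trait_codes`` index into ``trait_names``; ``residual_free`` says,
    per trait, whether the residual variance is a free parameter (False
    means structurally fixed to zero: single observation per individual
    with an individual-level intercept present).
    """

    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    individuals: np.ndarray          # (N,) individual id per record
    trait_codes: np.ndarray          # (N,) int
    trait_names: list[str]
    residual_free: list[bool]
    terms: list[RandomTerm]
    A: np.ndarray | None = None      # over unique_individuals order
    unique_individuals: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = self.y.shape[0]
        if self.X.shape[0] != n or len(self.individuals) != n:
            raise ValueError("inconsistent record counts in model data")
        if any(t.genetic for t in self.terms):
            if self.A is None or self.unique_individuals is None:
                raise ValueError("genetic term requires A and its id order")
        _check_rank(self.X, self.x_names)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        keep = piv[: r]
        dropped = [names[i] for i in range(X.shape[1]) if i not in keep]
        raise RemlError(
            "fixed-effect design is rank deficient; aliased terms: "
            + ", ".join(dropped)
        )


# ---------------------------------------------------------------------------
# parameter packing


def _tril_count(b: int) -> int:
    return b * (b + 1) // 2


@dataclass
class _ParamMap:
    term_blocks: list[tuple[int, list[int]]]   # (term index, dim indices)
    resid_idx: list[int]                       # free residual trait codes
    n_params: int

    @classmethod
    def build(cls, data: MixedModelData) -> "_ParamMap":
        tb = []
        n = 0
        for ti, term in enumerate(data.terms):
            for block in term.blocks:
                tb.append((ti, block))
                n += _tril_count(len(block))
        resid_idx = [i for i, f in enumerate(data.residual_free) if f]
        n += len(resid_idx)
        return cls(tb, resid_idx, n)

    def unpack(self, theta: np.ndarray, data: MixedModelData):
        """theta -> (list of Sigma per term, residual variances per trait)."""
        sigmas = [np.zeros((len(t.dims), len(t.dims))) for t in data.terms]
        k = 0
        for ti, block in self.term_blocks:
            b = len(block)
            m = _tril_count(b)
            L = np.zeros((b, b))
            L[np.tril_indices(b)] = theta[k:k + m]
            k += m
            sigmas[ti][np.ix_(block, block)] = L @ L.T
        resid = np.zeros(len(data.trait_names))
        for i in self.resid_idx:
            resid[i] = theta[k] ** 2
            k += 1
        return sigmas, resid

    def pack(self, sigmas, resid, data: MixedModelData) -> np.ndarray:
        theta = np.zeros(self.n_params)
        k = 0
        for ti, block in self.term_blocks:
            b = len(block)
            S = np.asarray(sigmas[ti])[np.ix_(block, block)]
            w, V = np.linalg.eigh(S)
            S = (V * np.clip(w, 0.0, None)) @ V.T
            L = np.linalg.cholesky(S + 1e-12 * np.eye(b) * max(np.trace(S) / b, 1.0))
            m = _tril_count(b)
            theta[k:k + m] = L[np.tril_indices(b)]
            k += m
        for i in self.resid_idx:
            theta[k] = np.sqrt(max(resid[i], 0.0))
            k += 1
        return theta


# ---------------------------------------------------------------------------
# likelihood evaluation


@dataclass
class _Group:
    """Individuals sharing one record template (same traits/sessions)."""

    Y: np.ndarray                    # (g, m)
    Xs: np.ndarray                   # (g, m, p)
    Zt: list[np.ndarray]             # per term, (m, K) template
    tcodes: np.ndarray               # (m,)
    d: np.ndarray | None = None      # eigenvalues of A for rotated groups
    B: np.ndarray | None = None      # cached [Xs | Y] design stack
    B2: np.ndarray | None = None     # (m, g*(p+1)) layout for one-shot solves

    def design(self) -> np.ndarray:
        if self.B is None:
            self.B = np.concatenate([self.Xs, self.Y[:, :, None]], axis=2)
        return self.B

    def design2d(self) -> np.ndarray:
        if self.B2 is None:
            B = self.design()
            g, m, q = B.shape
            self.B2 = np.ascontiguousarray(
                B.transpose(1, 0, 2).reshape(m, g * q))
        return self.B2


def _prepare(data: MixedModelData):
    """Group records by individual template; rotate by eig(A) if needed."""
    N = len(data.y)
    order = np.lexsort((np.arange(N), data.trait_codes, data.individuals))
    # stable per-individual record ordering by (trait, original order)
    by_ind: dict[str, list[int]] = {}
    for r in order:
        by_ind.setdefault(data.individuals[r], []).append(r)

    genetic = any(t.genetic for t in data.terms)

    def signature(rows):
        parts = [data.trait_codes[rows].tobytes()]
        for t in data.terms:
            parts.append(np.ascontiguousarray(t.Z[rows]).tobytes())
        return b"|".join(parts)

    sig_groups: dict[bytes, list[str]] = {}
    for iid, rows in by_ind.items():
        sig_groups.setdefault(signature(np.array(rows)), []).append(iid)

    if genetic and len(sig_groups) > 1:
        return None  # fall back to dense path

    groups = []
    p = data.X.shape[1]
    for sig, iids in sig_groups.items():
        rows0 = np.array(by_ind[iids[0]])
        m = len(rows0)
        g = len(iids)
        Y = np.empty((g, m))
        Xs = np.empty((g, m, p))
        for k, iid in enumerate(iids):
            rr = np.array(by_ind[iid])
            Y[k] = data.y[rr]
            Xs[k] = data.X[rr]
        Zt = [t.Z[rows0] for t in data.terms]
        tcodes = data.trait_codes[rows0]
        d = None
        if genetic:
            A = _a_submatrix(data, iids)
            w, U = np.linalg.eigh(A)
            w = np.clip(w, 0.0, None)
            Y = U.T @ Y
            Xs = np.einsum("ji,jmp->imp", U, Xs)
            d = w
        groups.append(_Group(Y, Xs, Zt, tcodes, d))
    return groups


def _a_submatrix(data: MixedModelData, iids) -> np.ndarray:
    pos = {iid: i for i, iid in enumerate(data.unique_individuals)}
    try:
        idx = np.array([pos[i] for i in iids])
    except KeyError as e:
        raise RemlError(f"individual {e.args[0]} missing from relationship matrix")
    return data.A[np.ix_(idx, idx)]


def _group_loglik_parts(groups, data, sigmas, resid):
    """Sum log|V|, X'V^-1X, X'V^-1y, y'V^-1y over independent blocks."""
    p = data.X.shape[1]
    logdet = 0.0
    cross = np.zeros((p + 1, p + 1))
    for grp in groups:
        m = len(grp.tcodes)
        Cg = np.zeros((m, m))
        Cu = np.zeros((m, m))
        for t, Zt, S in zip(data.terms, grp.Zt, sigmas):
            contrib = Zt @ S @ Zt.T
            if t.genetic:
                Cg += contrib
            else:
                Cu += contrib
        R = np.diag(resid[grp.tcodes])
        if grp.d is not None:
            # V_k = C0 + d_k Cg with shared C0 = Cu + R: one generalized
            # eigen-basis Q (Q'C0Q = I, Q'CgQ = diag(lam)) diagonalises
            # every individual's covariance simultaneously
            C0 = Cu + R
            g = grp.Y.shape[0]
            q = grp.design().shape[2]
            try:
                L0 = np.linalg.cholesky(C0)
                lam, Q = sp_eigh(Cg, C0, check_finite=False)
            except (np.linalg.LinAlgError, ValueError):
                return None
            M = 1.0 + np.outer(grp.d, lam)          # (g, m)
            if np.any(M <= 1e-12):
                return None
            logdet += 2.0 * g * np.sum(np.log(np.diag(L0))) + np.sum(np.log(M))
            T = (Q.T @ grp.design2d()).reshape(m, g, q)
            cross += np.einsum("mgi,gm,mgj->ij", T, 1.0 / M, T,
                               optimize=True)
        else:
            # identical covariance for every individual in the group:
            # one triangular solve against the (m, g*(p+1)) design layout
            try:
                L0 = np.linalg.cholesky(Cu + R)
            except np.linalg.LinAlgError:
                return None
            g = grp.Y.shape[0]
            logdet += 2.0 * g * np.sum(np.log(np.diag(L0)))
            W2 = solve_triangular(L0, grp.design2d(), lower=True,
                                  check_finite=False)
            q = grp.design().shape[2]
            Wf = W2.reshape(m, g, q).transpose(1, 0, 2).reshape(-1, q)
            cross += Wf.T @ Wf
    return logdet, cross


def _dense_loglik_parts(data, sigmas, resid):
    V = marginal_covariance(data, sigmas, resid)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return None
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    B = np.concatenate([data.X, data.y[:, None]], axis=1)
    W = np.linalg.solve(L, B)
    return logdet, W.T @ W


def marginal_covariance(data: MixedModelData, sigmas, resid) -> np.ndarray:
    """Dense covariance of the record vector for given variance values.

    Entry for records (i at basis phi, j at phi'):
    ``A_ij phi' Sigma_g phi + 1[i=j] phi' Sigma_u phi + 1[same record] V_R``.
    """
    N = len(data.y)
    if isinstance(sigmas, dict):
        sigmas = [sigmas[t.name] for t in data.terms]
    if isinstance(resid, dict):
        resid = np.array([resid.get(t, 0.0) for t in data.trait_names])
    resid = np.asarray(resid, dtype=float)
    for S in sigmas:
        if np.min(np.linalg.eigvalsh(np.asarray(S, float))) < -1e-8:
            raise RemlError("covariance structure is not positive semi-definite")
    V = np.diag(resid[data.trait_codes])
    if any(t.genetic for t in data.terms):
        pos = {iid: i for i, iid in enumerate(data.unique_individuals)}
        arec = np.array([pos[i] for i in data.individuals])
    same = (data.individuals[:, None] == data.individuals[None, :])
    for t, S in zip(data.terms, sigmas):
        ZS = t.Z @ np.asarray(S, float) @ t.Z.T
        if t.genetic:
            V += data.A[np.ix_(arec, arec)] * ZS
        else:
            V += same * ZS
    return V


def reml_loglik(data: MixedModelData, sigmas, resid, *, dense: bool = False) -> float:
    """REML log-likelihood (constant dropped) at given variance values."""
    if isinstance(sigmas, dict):
        sigmas = [np.asarray(sigmas[t.name], float) for t in data.terms]
    else:
        sigmas = [np.asarray(S, float) for S in sigmas]
    for S, t in zip(sigmas, data.terms):
        if S.shape != (len(t.dims), len(t.dims)):
            raise RemlError(f"sigma shape mismatch for term {t.name}")
    if isinstance(resid, dict):
        resid = np.array([resid.get(t, 0.0) for t in data.trait_names])
    resid = np.asarray(resid, dtype=float)
    groups = None if dense else _prepare(data)
    parts = (_group_loglik_parts(groups, data, sigmas, resid)
             if groups is not None else _dense_loglik_parts(data, sigmas, resid))
    if parts is None:
        raise RemlError("marginal covariance is singular at these parameter values")
    return _assemble_loglik(parts, data)


def _assemble_loglik(parts, data) -> float:
    logdet, cross = parts
    p = data.X.shape[1]
    XtViX = cross[:p, :p]
    XtViy = cross[:p, p]
    ytViy = cross[p, p]
    sign, ld2 = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise RemlError("X'V^-1X singular; fixed-effect design rank deficient")
    beta = np.linalg.solve(XtViX, XtViy)
    ypy = ytViy - XtViy @ beta
    return -0.5 * (logdet + ld2 + ypy)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """REML estimates for one model specification."""

    data: MixedModelData
    sigmas: dict[str, np.ndarray]
    sigma_dims: dict[str, list[str]]
    resid: dict[str, float]
    beta: np.ndarray
    beta_cov: np.ndarray
    x_names: list[str]
    loglik: float
    n_var_params: int
    converged: bool
    boundary_flags: dict[str, bool] = field(default_factory=dict)
    param_labels: list[str] = field(default_factory=list)
    param_values: np.ndarray | None = None
    param_cov: np.ndarray | None = None
    n_records: int = 0
    message: str = ""

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_var_params

    def std_error(self, label: str) -> float | None:
        """SE of one natural parameter; None if at a boundary/unavailable."""
        if self.param_cov is None or label not in self.param_labels:
            return None
        if self.boundary_flags.get(label, False):
            return None
        i = self.param_labels.index(label)
        v = self.param_cov[i, i]
        return float(np.sqrt(v)) if v > 0 else None

    def delta_se(self, fn) -> float | None:
        """Delta-method SE of ``fn(theta_natural)``; None when unavailable."""
        if self.param_cov is None:
            return None
        th = self.param_values
        g = np.zeros_like(th)
        for i in range(len(th)):
            h = max(1e-6, 1e-5 * abs(th[i]))
            tp, tm = th.copy(), th.copy()
            tp[i] += h
            tm[i] -= h
            g[i] = (fn(tp) - fn(tm)) / (2 * h)
        v = g @ self.param_cov @ g
        return float(np.sqrt(v)) if v > 0 else None

    def natural(self, label: str) -> float:
        """Value of one natural parameter by label."""
        return float(self.param_values[self.param_labels.index(label)])

    def summary(self) -> dict:
        return {
            "loglik": self.loglik,
            "aic": self.aic,
            "n_var_params": self.n_var_params,
            "converged": self.converged,
            "sigmas": {k: v.tolist() for k, v in self.sigmas.items()},
            "residual": self.resid,
            "fixed_effects": dict(zip(self.x_names, self.beta.tolist())),
            "boundary": {k: bool(v) for k, v in self.boundary_flags.items()},
        }


def _natural_labels(data: MixedModelData):
    """Natural parameters: free covariance elements + free residuals."""
    labels, getters = [], []
    for ti, term in enumerate(data.terms):
        for block in term.blocks:
            for a, i in enumerate(block):
                for j in block[: a + 1]:
                    labels.append(f"{term.name}[{term.dims[i]},{term.dims[j]}]"
                                  if i != j else f"{term.name}[{term.dims[i]}]")
                    getters.append(("sigma", ti, i, j))
    for i, free in enumerate(data.residual_free):
        if free:
            labels.append(f"residual[{data.trait_names[i]}]")
            getters.append(("resid", i, None, None))
    return labels, getters


def _natural_vector(getters, sigmas, resid):
    out = np.empty(len(getters))
    for k, (kind, a, i, j) in enumerate(getters):
        out[k] = sigmas[a][i, j] if kind == "sigma" else resid[a]
    return out


def _natural_to_structs(theta, getters, data):
    sigmas = [np.zeros((len(t.dims), len(t.dims))) for t in data.terms]
    resid = np.zeros(len(data.trait_names))
    for k, (kind, a, i, j) in enumerate(getters):
        if kind == "sigma":
            sigmas[a][i, j] = theta[k]
            sigmas[a][j, i] = theta[k]
        else:
            resid[a] = theta[k]
    return sigmas, resid


def _trait_scales(data: MixedModelData) -> np.ndarray:
    """Residual variance of y on X per trait — sets starting values."""
    beta, *_ = np.linalg.lstsq(data.X, data.y, rcond=None)
    r = data.y - data.X @ beta
    scales = np.empty(len(data.trait_names))
    for t in range(len(data.trait_names)):
        rt = r[data.trait_codes == t]
        scales[t] = np.var(rt) if len(rt) > 1 else 1.0
        if scales[t] <= 0:
            scales[t] = 1.0
    return scales


def default_start(data: MixedModelData):
    """Equal split of phenotypic variance over the free variance terms.

    Slope variances start at 10% of the corresponding intercept share;
    covariances start at zero.
    """
    scales = _trait_scales(data)
    n_contrib = {t: (1 if f else 0) for t, f in
                 zip(data.trait_names, data.residual_free)}
    for term in data.terms:
        for d in term.dims:
            trait, kind = d.rsplit(":", 1)
            if kind == "int":
                n_contrib[trait] = n_contrib.get(trait, 0) + 1
    sigmas = []
    for term in data.terms:
        S = np.zeros((len(term.dims), len(term.dims)))
        for i, d in enumerate(term.dims):
            trait, kind = d.rsplit(":", 1)
            share = scales[data.trait_names.index(trait)] / max(n_contrib[trait], 1)
            S[i, i] = share if kind == "int" else 0.1 * share
        sigmas.append(S)
    resid = np.array([
        (scales[i] / max(n_contrib[t], 1)) if f else 0.0
        for i, (t, f) in enumerate(zip(data.trait_names, data.residual_free))
    ])
    return sigmas, resid


def fit_reml(
    data: MixedModelData,
    *,
    start: np.ndarray | None = None,
    max_iter: int = 400,
    gtol: float = 1e-6,
    compute_se: bool = True,
    dense: bool = False,
) -> FitResult:
    """Maximise the REML log-likelihood over the variance parameters.

    Deterministic given the data and starting values.  Non-convergence
    is reported via ``converged=False``, never silently.
    """
    pm = _ParamMap.build(data)
    groups = None if dense else _prepare(data)

    def negll(theta: np.ndarray) -> float:
        sigmas, resid = pm.unpack(theta, data)
        parts = (_group_loglik_parts(groups, data, sigmas, resid)
                 if groups is not None
                 else _dense_loglik_parts(data, sigmas, resid))
        if parts is None:
            return _BIG
        try:
            return -_assemble_loglik(parts, data)
        except RemlError:
            return _BIG

    if start is None:
        s0, r0 = default_start(data)
        theta0 = pm.pack(s0, r0, data)
    else:
        theta0 = np.asarray(start, dtype=float)

    if pm.n_params == 0:
        # nothing to optimise (no random terms can't happen: residual always
        # free for at least one trait in a valid spec) — defensive
        raise RemlError("model has no free variance parameters")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            negll, theta0, method="L-BFGS-B",
            options={"maxiter": max_iter, "maxfun": 40 * max_iter,
                     "gtol": gtol, "ftol": 1e-12},
        )
        # polish with Nelder-Mead if L-BFGS stalled away from an optimum
        if not res.success:
            res2 = optimize.minimize(
                negll, res.x, method="Nelder-Mead",
                options={"maxiter": min(2500, 150 * pm.n_params),
                         "fatol": 1e-9, "xatol": 1e-7},
            )
            if res2.fun <= res.fun:
                res = res2

    if res.fun >= _BIG / 2:
        raise RemlError("REML likelihood could not be evaluated at the optimum")

    sigmas, resid = pm.unpack(res.x, data)
    loglik = -res.fun
    converged = bool(res.success)
    if not converged:
        logger.warning("REML did not meet convergence criteria: %s", res.message)

    # beta and its covariance at the optimum
    parts = (_group_loglik_parts(groups, data, sigmas, resid)
             if groups is not None else _dense_loglik_parts(data, sigmas, resid))
    logdet, cross = parts
    p = data.X.shape[1]
    XtViX = cross[:p, :p]
    beta = np.linalg.solve(XtViX, cross[:p, p])
    beta_cov = np.linalg.inv(XtViX)

    labels, getters = _natural_labels(data)
    theta_nat = _natural_vector(getters, sigmas, resid)
    scales = _trait_scales(data)

    boundary = _boundary_flags(labels, getters, sigmas, resid, data, scales)

    param_cov = None
    if compute_se:
        param_cov = _observed_information_cov(
            theta_nat, getters, data, groups, scales)

    sig_d = {t.name: sigmas[i] for i, t in enumerate(data.terms)}
    dims_d = {t.name: list(t.dims) for t in data.terms}
    resid_d = {nm: float(resid[i]) for i, nm in enumerate(data.trait_names)}
    return FitResult(
        data=data, sigmas=sig_d, sigma_dims=dims_d, resid=resid_d,
        beta=beta, beta_cov=beta_cov, x_names=list(data.x_names),
        loglik=float(loglik), n_var_params=pm.n_params,
        converged=converged, boundary_flags=boundary,
        param_labels=labels, param_values=theta_nat, param_cov=param_cov,
        n_records=len(data.y), message=str(res.message),
    )


def _boundary_flags(labels, getters, sigmas, resid, data, scales):
    """Flag variances near zero and correlations near +-1."""
    flags = {}
    for lab, (kind, a, i, j) in zip(labels, getters):
        if kind == "resid":
            flags[lab] = resid[a] < 1e-6 * scales[a]
            continue
        S = sigmas[a]
        if i == j:
            trait = data.terms[a].dims[i].rsplit(":", 1)[0]
            sc = scales[data.trait_names.index(trait)]
            flags[lab] = S[i, i] < 1e-6 * sc
        else:
            denom = np.sqrt(S[i, i] * S[j, j])
            r = S[i, j] / denom if denom > 0 else 0.0
            flags[lab] = abs(r) >= 0.9999 or S[i, i] <= 0 or S[j, j] <= 0
    return flags


def _observed_information_cov(theta, getters, data, groups, scales):
    """Covariance of the natural parameters from a central-difference
    Hessian of the restricted log-likelihood; pseudo-inverse if singular."""

    def ll(th):
        sigmas, resid = _natural_to_structs(th, getters, data)
        parts = (_group_loglik_parts(groups, data, sigmas, resid)
                 if groups is not None
                 else _dense_loglik_parts(data, sigmas, resid))
        if parts is None:
            return -_BIG
        try:
            return _assemble_loglik(parts, data)
        except RemlError:
            return -_BIG

    n = len(theta)
    scale0 = float(np.mean(scales))
    h = np.maximum(1e-5 * np.abs(theta), 1e-5 * scale0)
    H = np.zeros((n, n))
    f0 = ll(theta)
    if f0 <= -_BIG / 2:
        return None
    for i in range(n):
        for j in range(i + 1):
            tp, tm = theta.copy(), theta.copy()
            if i == j:
                tp[i] += h[i]
                tm[i] -= h[i]
                fp, fm = ll(tp), ll(tm)
                H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
            else:
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[[i, j]] += h[[i, j]]
                tmm[[i, j]] -= h[[i, j]]
                tpm[i] += h[i]
                tpm[j] -= h[j]
                tmp[i] -= h[i]
                tmp[j] += h[j]
                H[i, j] = H[j, i] = (
                    ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)
                ) / (4 * h[i] * h[j])
    info = -H
    try:
        cov = np.linalg.inv(info)
        if np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return cov
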