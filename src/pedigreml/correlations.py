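"""Among-individual (ID) and genetic (G) correlation structure.

The among-individual correlation matrix comes from a single four-trait
mixed model: an individual intercept on every trait (full cross-trait
covariance), random slopes on session for the two traits with enough
repeated sessions, residual variances fixed to zero for the two traits
entering with one observation per individual, and no cross-trait
residual covariance (traits are never co-observed at the same
observation).  Spatial discrimination enters as the per-individual mean
across its sessions.

A four-trait genetic model is not supported: G is estimated piecewise —
one trivariate animal model (inhibitory control, visual discrimination,
spatial ability) plus three bivariate models pairing spatial
discrimination with each other trait — and the six pairwise genetic
correlations are assembled into a patchwork matrix whose PSD status is
reported, not enforced.

Eigen-decomposing either correlation matrix is a principal component
analysis of the corresponding level of variation; a dominant first axis
with same-sign loadings on every trait is the signature a general-
intelligence (g) model predicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .model import TRAIT_DESIGNS, LRTResult, lrt, scale_sessions
from .pedigree import RelationshipMatrix
from .reml import FitResult, MixedModelData, RandomTerm, fit_reml

#: |r| at or beyond this is treated as a boundary solution (kept in the
#: allowable space, no SE estimable).
BOUNDARY_R = 0.9999

ID_TRAITS = ["inhibitory_control", "visual_discrimination",
             "spatial_discrimination", "spatial_ability"]
#: traits whose random slope on session is retained in multivariate models
SLOPE_TRAITS = {"visual_discrimination", "spatial_ability"}


class Level(Enum):
    AMONG_INDIVIDUAL = "among_individual"
    GENETIC = "genetic"


@dataclass
class CorrelationMatrix:
    """Labeled among-trait correlation matrix with SEs and boundary flags."""

    labels: list[str]
    values: np.ndarray
    std_errors: np.ndarray          # NaN where unavailable
    boundary_flags: np.ndarray      # bool
    level: Level

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    def is_psd(self, tol: float = 1e-8) -> bool:
        return bool(np.min(np.linalg.eigvalsh(self.values)) >= -tol)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "values": self.values.tolist(),
            "std_errors": [[None if not np.isfinite(v) else v for v in row]
                           for row in self.std_errors],
            "boundary": self.boundary_flags.tolist(),
            "level": self.level.value,
            "psd": self.is_psd(),
        }


@dataclass
class EigenSummary:
    """Eigenvalues, variance shares and loadings of a correlation matrix."""

    eigenvalues: np.ndarray          # descending
    proportions: np.ndarray          # eigenvalue / n_traits
    loadings: np.ndarray             # unit-norm columns, sign-conventioned
    labels: list[str]
    same_sign_pc1: bool

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "eigenvalues": self.eigenvalues.tolist(),
            "proportions": self.proportions.tolist(),
            "loadings": self.loadings.tolist(),
            "same_sign_pc1": bool(self.same_sign_pc1),
        }


@dataclass
class PairwiseCorrelation:
    trait_a: str
    trait_b: str
    value: float
    std_error: float | None
    boundary: bool
    source: str = ""


# ---------------------------------------------------------------------------
# data preparation


def mean_spatial_disc(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse spatial-discrimination sessions to one mean per individual.

    Individuals with no session are omitted; the output row carries the
    individual's covariates with session set to 1.
    """
    trait = "spatial_discrimination"
    sub = records[records["trait"] == trait]
    rest = records[records["trait"] != trait]
    if sub.empty:
        return records.copy()
    agg = sub.groupby("id", sort=False).agg(
        value=("value", "mean"),
        sex=("sex", "first"),
        rearing_group=("rearing_group", "first"),
        test_order=("test_order", "first"),
        cohort=("cohort", "first"),
    ).reset_index()
    agg["trait"] = trait
    agg["session"] = 1
    out = pd.concat([rest, agg[rest.columns.intersection(agg.columns)]],
                    ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# multivariate design assembly


def _basis_dims(traits: list[str], slopes: set[str]) -> list[str]:
    dims = []
    for t in traits:
        dims.append(f"{t}:int")
        if t in slopes:
            dims.append(f"{t}:slope")
    return dims


def _blocks(dims: list[str], scheme: str) -> list[list[int]]:
    if scheme == "full":
        return [list(range(len(dims)))]
    by_trait: dict[str, list[int]] = {}
    for i, d in enumerate(dims):
        by_trait.setdefault(d.rsplit(":", 1)[0], []).append(i)
    return list(by_trait.values())


def _term_Z(df: pd.DataFrame, dims: list[str]) -> np.ndarray:
    Z = np.zeros((len(df), len(dims)))
    trait = df["trait"].to_numpy(str)
    s = df["s"].to_numpy(float)
    for j, d in enumerate(dims):
        t, kind = d.rsplit(":", 1)
        mask = trait == t
        Z[mask, j] = 1.0 if kind == "int" else s[mask]
    return Z


def _stacked_design(df: pd.DataFrame, traits: list[str]):
    """Per-trait fixed-effect blocks: each trait gets its own intercept,
    sex, rearing-group, test-order and (where repeated) session columns."""
    cols, names = [], []
    trait_arr = df["trait"].to_numpy(str)
    for t in traits:
        mask = (trait_arr == t).astype(float)
        cols.append(mask)
        names.append(f"{t}:intercept")
        for term in ("sex", "rearing_group"):
            levels = sorted(df.loc[df["trait"] == t, term].astype(str).unique())
            for lev in levels[1:]:
                cols.append(mask * (df[term].astype(str) == lev).to_numpy(float))
                names.append(f"{t}:{term}[{lev}]")
        cols.append(mask * df["test_order"].to_numpy(float))
        names.append(f"{t}:test_order")
        sub = df.loc[df["trait"] == t, "s"]
        if sub.nunique() > 1:
            cols.append(mask * df["s"].to_numpy(float))
            names.append(f"{t}:s")
    X = np.column_stack(cols)
    return X, names


def _multitrait_data(
    records: pd.DataFrame,
    traits: list[str],
    *,
    id_slopes: set[str] | None,
    gen_traits: list[str] | None,
    id_scheme: str = "full",
    gen_scheme: str = "full",
    A: RelationshipMatrix | None = None,
) -> MixedModelData:
    df = records[records["trait"].isin(traits)].reset_index(drop=True)
    for t in traits:
        df = scale_sessions(df, t)
    X, names = _stacked_design(df, traits)
    y = df["value"].to_numpy(float)
    ids = df["id"].to_numpy(str)
    tcode = np.array([traits.index(t) for t in df["trait"]])

    terms = []
    uniq, Asub = None, None
    if gen_traits:
        gdims = _basis_dims(gen_traits, SLOPE_TRAITS & set(gen_traits))
        terms.append(RandomTerm("genetic", gdims, _term_Z(df, gdims),
                                genetic=True, blocks=_blocks(gdims, gen_scheme)))
        uniq = list(dict.fromkeys(ids))
        Asub = A.submatrix(uniq)
    id_traits_term: list[str] = []
    if id_slopes is not None:
        # individual-level term: every trait if no genetic term (the ID
        # model); otherwise only repeated traits (a permanent-environment
        # effect is unidentifiable from a single observation)
        if gen_traits:
            id_traits_term = [t for t in traits
                              if TRAIT_DESIGNS[t]["sessions"] > 1
                              and _n_sessions(df, t) > 1]
        else:
            id_traits_term = list(traits)
        if id_traits_term:
            udims = _basis_dims(id_traits_term, id_slopes & set(id_traits_term))
            terms.append(RandomTerm("individual", udims, _term_Z(df, udims),
                                    blocks=_blocks(udims, id_scheme)))

    residual_free = []
    for t in traits:
        single = _n_sessions(df, t) == 1
        has_id_int = t in id_traits_term
        residual_free.append(not (single and has_id_int))

    return MixedModelData(
        y=y, X=X, x_names=names, individuals=ids, trait_codes=tcode,
        trait_names=list(traits), residual_free=residual_free,
        terms=terms, A=Asub, unique_individuals=uniq,
    )


def _n_sessions(df: pd.DataFrame, trait: str) -> int:
    sub = df.loc[df["trait"] == trait, "session"]
    return int(sub.nunique()) if len(sub) else 0


def _corr_from_term(fit: FitResult, term: str, ta: str, tb: str):
    """Intercept-level correlation of two traits from a fitted term,
    with delta-method SE and boundary flag."""
    dims = fit.sigma_dims[term]
    S = fit.sigmas[term]
    i, j = dims.index(f"{ta}:int"), dims.index(f"{tb}:int")
    va, vb, c = S[i, i], S[j, j], S[i, j]
    denom = np.sqrt(va * vb)
    r = c / denom if denom > 0 else 0.0
    boundary = abs(r) >= BOUNDARY_R or va <= 0 or vb <= 0
    r = float(np.clip(r, -1.0, 1.0))
    se = None
    if not boundary:
        labels = fit.param_labels

        def idx_of(da, db):
            for cand in (f"{term}[{da},{db}]", f"{term}[{db},{da}]"):
                if cand in labels:
                    return labels.index(cand)
            return None

        ii = labels.index(f"{term}[{ta}:int]")
        jj = labels.index(f"{term}[{tb}:int]")
        ij = idx_of(f"{ta}:int", f"{tb}:int")

        def fn(theta):
            vva, vvb = theta[ii], theta[jj]
            cc = theta[ij] if ij is not None else 0.0
            d = np.sqrt(max(vva, 1e-30) * max(vvb, 1e-30))
            return cc / d

        se = fit.delta_se(fn) if ij is not None else None
    return r, se, boundary


# ---------------------------------------------------------------------------
# the ID model


@dataclass
class IDModelResult:
    fit: FitResult
    null_fit: FitResult
    matrix: CorrelationMatrix
    global_test: LRTResult
    eigen: EigenSummary


def fit_id_model(records: pd.DataFrame, **fit_kw) -> IDModelResult:
    """Four-trait among-individual model: r_P conditional on fixed effects.

    Spatial discrimination must be (or is) pre-averaged; sessions are
    scaled internally.  The global test compares the full cross-trait
    covariance structure against a per-trait-block null; its df is the
    number of freed covariance parameters.
    """
    records = mean_spatial_disc(records)
    traits = [t for t in ID_TRAITS if t in set(records["trait"])]
    if len(traits) < 2:
        raise ValueError("ID model needs at least two traits")
    alt = fit_reml(_multitrait_data(records, traits, id_slopes=SLOPE_TRAITS,
                                    gen_traits=None, id_scheme="full"),
                   **fit_kw)
    null = fit_reml(_multitrait_data(records, traits, id_slopes=SLOPE_TRAITS,
                                     gen_traits=None, id_scheme="by_trait"),
                    **fit_kw)
    df_free = alt.n_var_params - null.n_var_params
    test = lrt(null, alt, ("chisq", df_free), comparison="ID structure")
    pairs = []
    for a in range(len(traits)):
        for b in range(a + 1, len(traits)):
            r, se, bd = _corr_from_term(alt, "individual", traits[a], traits[b])
            pairs.append(PairwiseCorrelation(traits[a], traits[b], r, se, bd,
                                             source="four-trait ID model"))
    m = assemble_matrix(pairs, traits, level=Level.AMONG_INDIVIDUAL)
    return IDModelResult(alt, null, m, test, eigen_summary(m))


# ---------------------------------------------------------------------------
# partial G models


@dataclass
class GPartialResult:
    pairwise: list[PairwiseCorrelation]
    tests: list[LRTResult]
    fits: dict[str, FitResult]
    matrix: CorrelationMatrix
    eigen: EigenSummary


TRIVARIATE = ["inhibitory_control", "visual_discrimination", "spatial_ability"]


def fit_g_partial(records: pd.DataFrame, A: RelationshipMatrix,
                  **fit_kw) -> GPartialResult:
    """Estimate G piecewise: one trivariate animal model plus three
    bivariate models pairing spatial discrimination with each other trait.

    Each model frees all cross-trait genetic covariances and is compared
    against a reduced model with them fixed at zero.  Boundary estimates
    (|r_G| at 1) are returned flagged, never raised as errors.
    """
    records = mean_spatial_disc(records)
    present = set(records["trait"])
    pairwise: list[PairwiseCorrelation] = []
    tests: list[LRTResult] = []
    fits: dict[str, FitResult] = {}

    tri = [t for t in TRIVARIATE if t in present]
    if len(tri) >= 2:
        alt, null, test = _fit_genetic_pair_or_set(records, tri, A, "trivariate",
                                                   **fit_kw)
        fits["trivariate"] = alt
        tests.append(test)
        for a in range(len(tri)):
            for b in range(a + 1, len(tri)):
                r, se, bd = _corr_from_term(alt, "genetic", tri[a], tri[b])
                pairwise.append(PairwiseCorrelation(
                    tri[a], tri[b], r, se, bd, source="trivariate"))

    sdisc = "spatial_discrimination"
    if sdisc in present:
        for other in TRIVARIATE:
            if other not in present:
                continue
            pair = [t for t in ID_TRAITS if t in (sdisc, other)]
            name = f"bivariate:{other}"
            alt, null, test = _fit_genetic_pair_or_set(records, pair, A, name,
                                                       **fit_kw)
            fits[name] = alt
            tests.append(test)
            r, se, bd = _corr_from_term(alt, "genetic", pair[0], pair[1])
            pairwise.append(PairwiseCorrelation(pair[0], pair[1], r, se, bd,
                                                source=name))

    labels = [t for t in ID_TRAITS if t in present]
    m = assemble_matrix(pairwise, labels, level=Level.GENETIC)
    return GPartialResult(pairwise, tests, fits, m, eigen_summary(m))


def _fit_genetic_pair_or_set(records, traits, A, name, **fit_kw):
    alt = fit_reml(_multitrait_data(records, traits, id_slopes=SLOPE_TRAITS,
                                    gen_traits=traits, id_scheme="full",
                                    gen_scheme="full", A=A), **fit_kw)
    null = fit_reml(_multitrait_data(records, traits, id_slopes=SLOPE_TRAITS,
                                     gen_traits=traits, id_scheme="full",
                                     gen_scheme="by_trait", A=A), **fit_kw)
    df_free = alt.n_var_params - null.n_var_params
    test = lrt(null, alt, ("chisq", df_free), comparison=f"G structure ({name})")
    return alt, null, test


# ---------------------------------------------------------------------------
# assembly and eigen decomposition


def assemble_matrix(pairwise: list[PairwiseCorrelation], labels: list[str],
                    level: Level = Level.GENETIC) -> CorrelationMatrix:
    """Patch pairwise estimates into a labeled correlation matrix.

    Every unordered pair must appear exactly once.  Estimates outside
    [-1, 1] are clamped with a boundary flag; boundary entries carry no
    SE.  The result need not be PSD — its PSD status is reported by the
    matrix object, not enforced here.
    """
    k = len(labels)
    vals = np.eye(k)
    ses = np.full((k, k), np.nan)
    flags = np.zeros((k, k), dtype=bool)
    seen: set[tuple[str, str]] = set()
    for p in pairwise:
        key = tuple(sorted((p.trait_a, p.trait_b)))
        if p.trait_a not in labels or p.trait_b not in labels:
            raise ValueError(f"pair {key} not in labels")
        if key in seen:
            raise ValueError(f"duplicate pairwise estimate for {key}")
        seen.add(key)
        i, j = labels.index(p.trait_a), labels.index(p.trait_b)
        v = float(np.clip(p.value, -1.0, 1.0))
        bd = p.boundary or abs(p.value) >= BOUNDARY_R
        vals[i, j] = vals[j, i] = v
        flags[i, j] = flags[j, i] = bd
        if p.std_error is not None and not bd:
            ses[i, j] = ses[j, i] = p.std_error
    expected = {tuple(sorted(p)) for p in
                ((labels[i], labels[j]) for i in range(k) for j in range(i + 1, k))}
    missing = expected - seen
    if missing:
        raise ValueError(f"missing pairwise estimates: {sorted(missing)}")
    return CorrelationMatrix(labels, vals, ses, flags, level)


def eigen_summary(m: CorrelationMatrix | np.ndarray,
                  labels: list[str] | None = None) -> EigenSummary:
    """PCA of a correlation matrix: eigenvalues (descending), shares
    ``lambda / k`` and sign-conventioned unit loadings.

    Sign convention per component: flip so the count of positive
    loadings is maximal, ties broken by making the first trait's loading
    positive.
    """
    if isinstance(m, CorrelationMatrix):
        values, labels = m.values, m.labels
    else:
        values = np.asarray(m, dtype=float)
        if labels is None:
            labels = [f"trait{i+1}" for i in range(values.shape[0])]
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("eigen_summary requires a symmetric matrix")
    k = values.shape[0]
    w, V = np.linalg.eigh(values)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    for c in range(k):
        pos = int(np.sum(V[:, c] > 0))
        neg = int(np.sum(V[:, c] < 0))
        if neg > pos or (neg == pos and V[0, c] < 0):
            V[:, c] = -V[:, c]
    pc1 = V[:, 0]
    same_sign = bool(np.all(pc1 >= 0) or np.all(pc1 <= 0))
    return EigenSummary(w, w / k, V, list(labels), same_sign)


def nearest_psd(values: np.ndarray) -> np.ndarray:
    """Explicitly invoked repair: clip negative eigenvalues to zero and
    rescale back to unit diagonal.  Never applied automatically."""
    values = np.asarray(values, dtype=float)
    w, V = np.linalg.eigh((values + values.T) / 2)
    rep = (V * np.clip(w, 0, None)) @ V.T
    d = np.sqrt(np.clip(np.diag(rep), 1e-12, None))
    return rep / np.outer(d, d)
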