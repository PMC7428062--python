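"""Trait handling, transforms, design building and the model ladder.

Phenotypes live in a long-format table (one row per individual x trait x
session) with the covariates the fixed part of every model uses: sex,
rearing group (house/year combination), mean test order and — for traits
with repeated measures — session number.  Random-regression terms use the
basis ``phi(s) = (1, s)`` with the session covariate rescaled so the
*final* session is zero; intercept-indexed variances then pertain to
performance in the final session.

The univariate model ladder compares, with identical fixed effects:

====== ==========================================================
Model  Random structure
====== ==========================================================
0      fixed effects only (residual variance)
1      + among-individual intercept
2      + among-individual slope on session (2x2 unstructured)
3      + additive genetic intercept (animal model)
4      + additive genetic slope (random-regression animal model)
====== ==========================================================

For a trait observed once per individual only Models 0-1 apply, with
Model 1 the plain animal model (genetic intercept; no permanent-
environment term is identifiable from a single observation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .pedigree import RelationshipMatrix
from .reml import FitResult, MixedModelData, RandomTerm, fit_reml

#: Study trait designs: sessions, per-session score range, whether the raw
#: score counts errors (reverse-scored so positive = good performance).
TRAIT_DESIGNS: dict[str, dict] = {
    "inhibitory_control": {"sessions": 1, "max_score": None, "reverse": True,
                           "sqrt": True},
    "visual_discrimination": {"sessions": 5, "max_score": 10, "reverse": False,
                              "sqrt": False},
    "spatial_discrimination": {"sessions": 3, "max_score": 10, "reverse": False,
                               "sqrt": False},
    "spatial_ability": {"sessions": 8, "max_score": 18, "reverse": True,
                        "sqrt": False},
}

TRAITS = list(TRAIT_DESIGNS)

PHENOTYPE_COLUMNS = ["id", "trait", "session", "value", "sex",
                     "rearing_group", "test_order", "cohort"]


def read_phenotypes(path) -> pd.DataFrame:
    """Read the long-format phenotype CSV."""
    df = pd.read_csv(path, dtype={"id": str, "trait": str, "sex": str,
                                  "rearing_group": str})
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file missing columns: {sorted(missing)}")
    bad = set(df["trait"]) - set(TRAITS)
    if bad:
        raise ValueError(f"unknown traits in phenotype file: {sorted(bad)}")
    if not np.isfinite(df["value"]).all():
        raise ValueError("non-finite phenotype values")
    if (df["session"] < 1).any():
        raise ValueError("session numbers must be >= 1")
    return df


# ---------------------------------------------------------------------------
# transforms


def scale_sessions(records: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Add the centred session covariate ``s = session - max(session)``.

    ``s`` is <= 0 with the final observed session at zero, so intercept
    variances refer to end-of-testing performance.  Rows of other traits
    pass through unchanged.
    """
    out = records.copy()
    if "s" not in out.columns:
        out["s"] = 0.0
    mask = out["trait"] == trait
    if not mask.any():
        return out
    smax = out.loc[mask, "session"].max()
    out.loc[mask, "s"] = out.loc[mask, "session"] - smax
    return out


def sqrt_transform(value):
    """Square-root transform for non-negative counts (peck counts)."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("sqrt_transform requires non-negative values")
    out = np.sqrt(arr)
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


def reverse_score(errors_made, max_errors: int):
    """``max_errors - errors_made`` so positive values mean good performance."""
    arr = np.asarray(errors_made, dtype=float)
    if np.any(arr < 0) or np.any(arr > max_errors):
        raise ValueError(
            f"errors_made must lie in [0, {max_errors}]"
        )
    out = max_errors - arr
    return float(out) if arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# design


def build_design(records: pd.DataFrame, *, fixed_terms: list[str] | None = None,
                 trait: str | None = None):
    """Treatment-coded fixed-effect matrix for a set of records.

    Default terms: intercept, sex, rearing_group, test_order and — for
    repeated-measures traits — session (the centred ``s``).  Returns
    ``(X, names, y)`` aligned with the record order.
    """
    df = records
    if trait is not None:
        df = df[df["trait"] == trait]
    if fixed_terms is None:
        fixed_terms = ["sex", "rearing_group", "test_order"]
        reps = (trait is None or TRAIT_DESIGNS[trait]["sessions"] > 1)
        if reps and df["s"].nunique() > 1:
            fixed_terms.append("s")
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for term in fixed_terms:
        if df[term].dtype == object or str(df[term].dtype) == "category":
            levels = sorted(df[term].astype(str).unique())
            for lev in levels[1:]:  # treatment coding: first level reference
                cols.append((df[term].astype(str) == lev).to_numpy(float))
                names.append(f"{term}[{lev}]")
        else:
            cols.append(df[term].to_numpy(float))
            names.append(term)
    X = np.column_stack(cols)
    return X, names, df["value"].to_numpy(float)


# ---------------------------------------------------------------------------
# univariate model specification


@dataclass
class LadderModel:
    """One rung of the univariate ladder."""

    number: int
    label: str
    id_dims: int          # 0, 1 (intercept) or 2 (intercept+slope)
    gen_dims: int         # 0, 1 or 2
    pe_present: bool = True


def _univariate_data(records: pd.DataFrame, trait: str,
                     id_dims: int, gen_dims: int,
                     A: RelationshipMatrix | None) -> MixedModelData:
    df = records[records["trait"] == trait].reset_index(drop=True)
    if "s" not in df.columns:
        df = scale_sessions(df, trait)
    X, names, y = build_design(df, trait=trait)
    s = df["s"].to_numpy(float)
    terms = []
    single_obs = TRAIT_DESIGNS[trait]["sessions"] == 1
    if gen_dims:
        dims = [f"{trait}:int"] + ([f"{trait}:slope"] if gen_dims == 2 else [])
        Z = np.column_stack([np.ones(len(df))] + ([s] if gen_dims == 2 else []))
        terms.append(RandomTerm("genetic", dims, Z, genetic=True))
    if id_dims:
        dims = [f"{trait}:int"] + ([f"{trait}:slope"] if id_dims == 2 else [])
        Z = np.column_stack([np.ones(len(df))] + ([s] if id_dims == 2 else []))
        terms.append(RandomTerm("individual", dims, Z, genetic=False))
    # residual: free unless the trait is observed once and an
    # individual-level intercept absorbs all among-individual variance
    residual_free = not (single_obs and id_dims > 0)
    ids = df["id"].to_numpy(str)
    uniq = None
    Asub = None
    if gen_dims:
        uniq = list(dict.fromkeys(ids))
        Asub = A.submatrix(uniq)
    return MixedModelData(
        y=y, X=X, x_names=names, individuals=ids,
        trait_codes=np.zeros(len(df), dtype=int), trait_names=[trait],
        residual_free=[residual_free], terms=terms, A=Asub,
        unique_individuals=uniq,
    )


def fit_univariate(records: pd.DataFrame, trait: str,
                   A: RelationshipMatrix | None = None,
                   *, id_dims: int = 0, gen_dims: int = 0,
                   **kw) -> FitResult:
    """Fit one univariate (random-regression) animal model by REML."""
    data = _univariate_data(records, trait, id_dims, gen_dims, A)
    return fit_reml(data, **kw)


# ---------------------------------------------------------------------------
# likelihood-ratio tests and AIC


@dataclass
class LRTResult:
    """Likelihood-ratio test of nested REML fits.

    ``null_spec`` is either ``("mixture_0_1",)`` — a single variance
    tested on its zero boundary, p = 1/2 P(chi2_1 >= T) — or
    ``("chisq", df)`` for a block of df parameters.
    """

    statistic: float
    null_spec: tuple
    p_value: float
    comparison: str = ""

    def __post_init__(self) -> None:
        assert self.statistic >= 0


def lrt_pvalue(statistic: float, null_spec) -> float:
    """Tail probability of the LRT statistic under the stated null."""
    if isinstance(null_spec, str):
        null_spec = (null_spec,)
    T = float(statistic)
    if null_spec[0] == "mixture_0_1":
        # 50:50 mixture of a point mass at zero and chi2_1; by the >=
        # convention P(T >= 0) = 1
        return 1.0 if T <= 0 else 0.5 * float(chi2.sf(T, 1))
    if null_spec[0] == "chisq":
        return float(chi2.sf(T, null_spec[1]))
    raise ValueError(f"unknown null spec {null_spec!r}")


def lrt(null_fit: FitResult, alt_fit: FitResult, null_spec,
        comparison: str = "") -> LRTResult:
    """LRT of nested fits with identical fixed effects on the same data."""
    if null_fit.x_names != alt_fit.x_names:
        raise ValueError("LRT requires identical fixed effects")
    if null_fit.n_records != alt_fit.n_records:
        raise ValueError("LRT requires the same data in both fits")
    delta = 2.0 * (alt_fit.loglik - null_fit.loglik)
    if delta < -1e-6:
        import warnings

        warnings.warn(
            f"alternative log-likelihood below null by {-delta/2:.3g}; "
            "statistic clipped to 0", stacklevel=2)
    T = max(0.0, delta)
    if isinstance(null_spec, str):
        null_spec = (null_spec,)
    return LRTResult(T, tuple(null_spec), lrt_pvalue(T, null_spec), comparison)


def aic(fit: FitResult) -> float:
    """REML AIC: ``-2 loglik + 2 * (number of variance parameters)``.

    Comparable only across fits with identical fixed effects.
    """
    return fit.aic


# ---------------------------------------------------------------------------
# model ladder


@dataclass
class LadderResult:
    trait: str
    fits: list[FitResult]
    labels: list[str]
    tests: list[LRTResult]
    extra_tests: list[LRTResult] = field(default_factory=list)

    def aic_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": self.labels,
            "loglik": [f.loglik for f in self.fits],
            "k": [f.n_var_params for f in self.fits],
            "aic": [f.aic for f in self.fits],
            "converged": [f.converged for f in self.fits],
        })

    def best_by_aic(self) -> int:
        return int(np.argmin([f.aic for f in self.fits]))


# (id_dims, gen_dims) per rung; null spec for each sequential comparison
_REPEATED_LADDER = [(0, 0), (1, 0), (2, 0), (2, 1), (2, 2)]
_SEQ_NULLS = ["mixture_0_1", ("chisq", 2), "mixture_0_1", ("chisq", 2)]


def model_ladder(records: pd.DataFrame, trait: str,
                 A: RelationshipMatrix, **kw) -> LadderResult:
    """Fit Models 0-4 for a repeated trait (0-1 for a single-measure one)
    and report sequential LRTs plus the Model 4 vs Model 2 comparison.
    """
    single = TRAIT_DESIGNS[trait]["sessions"] == 1
    if single:
        plan = [(0, 0), (0, 1)]
        labels = ["M0: fixed only", "M1: animal model"]
        nulls = ["mixture_0_1"]
    else:
        plan = _REPEATED_LADDER
        labels = ["M0: fixed only", "M1: +ID intercept", "M2: +ID slope",
                  "M3: +genetic intercept", "M4: +genetic slope"]
        nulls = _SEQ_NULLS
    fits = [fit_univariate(records, trait, A, id_dims=i, gen_dims=g, **kw)
            for i, g in plan]
    tests = [
        lrt(fits[k], fits[k + 1], nulls[k],
            comparison=f"M{k + 1} vs M{k}")
        for k in range(len(fits) - 1)
    ]
    extra = []
    if not single:
        # the genetic block as a whole: Model 4 vs Model 2 adds the
        # genetic intercept variance, slope variance and their covariance
        extra.append(lrt(fits[2], fits[4], ("chisq", 3), comparison="M4 vs M2"))
    return LadderResult(trait, fits, labels, tests, extra)
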