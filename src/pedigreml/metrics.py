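"""Variance-component summaries: heritability, repeatability, evolvability.

All ratios use the random-*intercept* variances only, with the session
covariate scaled so the final session sits at zero — the reported h² and
R therefore pertain to performance in the final observed session.
Standard errors for the ratios come from the delta method applied to the
fit's observed-information covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .reml import FitResult


@dataclass
class VarianceComponents:
    """Additive genetic, permanent-environment and residual variances.

    ``V_PE`` is zero for traits measured once (no among-individual
    variance beyond genetics is identifiable).  ``at_session`` records
    the (scaled, <= 0) session the intercept variances refer to.
    """

    V_A: float
    V_PE: float
    V_R: float
    at_session: int = 0

    def __post_init__(self) -> None:
        for name in ("V_A", "V_PE", "V_R"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def V_P(self) -> float:
        return self.V_A + self.V_PE + self.V_R

    @property
    def V_I(self) -> float:
        return self.V_A + self.V_PE


class Scale(Enum):
    """Which scale the mean used for CV_A is measured on."""

    TRANSFORMED = "transformed"
    OBSERVED = "observed"


@dataclass
class MeanScaledEvolvability:
    CV_A: float
    mean_used: float
    scale_note: Scale


def variance_at_session(c: np.ndarray, s: int) -> float:
    """Variance implied by a 2x2 intercept/slope covariance at session s.

    ``v00 + 2 s v01 + s^2 v11`` — a quadratic form in phi(s) = (1, s),
    hence non-negative for PSD input; at s = 0 it is the intercept
    variance v00.
    """
    c = np.asarray(c, dtype=float)
    phi = np.array([1.0, float(s)])
    return float(phi @ c @ phi)


def heritability(v: VarianceComponents) -> float:
    """h² = V_A / V_P, the additive genetic share of phenotypic variance."""
    if v.V_P <= 0:
        raise ValueError("phenotypic variance must be positive")
    return v.V_A / v.V_P


def repeatability(v: VarianceComponents, *, repeated: bool = True) -> float:
    """R = (V_A + V_PE) / V_P, the among-individual share.

    Undefined for single-measure traits (among- and within-individual
    variance cannot be partitioned from one observation).
    """
    if not repeated:
        raise ValueError("repeatability is undefined for single-measure traits")
    if v.V_P <= 0:
        raise ValueError("phenotypic variance must be positive")
    return v.V_I / v.V_P


def cva(V_A: float, mean: float,
        scale_note: Scale = Scale.OBSERVED) -> MeanScaledEvolvability:
    """CV_A = sqrt(V_A) / mu — mean-standardised additive genetic variation.

    Only meaningful on a ratio scale with an objective zero; the mean's
    scale is recorded so transformed- and observed-scale values are not
    confused.
    """
    if mean <= 0:
        raise ValueError("CV_A undefined for non-positive mean")
    if V_A < 0:
        raise ValueError("V_A must be non-negative")
    return MeanScaledEvolvability(float(np.sqrt(V_A) / mean), mean, scale_note)


# ---------------------------------------------------------------------------
# extraction from fits


def components_from_fit(fit: FitResult, trait: str) -> VarianceComponents:
    """Intercept-level variance components for one trait of a fit."""
    V_A = _intercept_var(fit, "genetic", trait)
    V_PE = _intercept_var(fit, "individual", trait)
    V_R = fit.resid.get(trait, 0.0)
    return VarianceComponents(max(V_A, 0.0), max(V_PE, 0.0), max(V_R, 0.0))


def _intercept_var(fit: FitResult, term: str, trait: str) -> float:
    if term not in fit.sigmas:
        return 0.0
    dims = fit.sigma_dims[term]
    key = f"{trait}:int"
    if key not in dims:
        return 0.0
    i = dims.index(key)
    return float(fit.sigmas[term][i, i])


def _ratio_fn(fit: FitResult, trait: str, kind: str):
    """Build theta -> h² (or R) on the natural parameter vector."""
    labels = fit.param_labels
    va_lab = f"genetic[{trait}:int]"
    vpe_lab = f"individual[{trait}:int]"
    vr_lab = f"residual[{trait}]"

    def fn(theta: np.ndarray) -> float:
        def get(lab):
            return theta[labels.index(lab)] if lab in labels else 0.0

        va, vpe, vr = get(va_lab), get(vpe_lab), get(vr_lab)
        if vr_lab not in labels:
            vr = fit.resid.get(trait, 0.0)
        vp = va + vpe + vr
        num = va if kind == "h2" else va + vpe
        return num / vp if vp > 0 else np.nan

    return fn


def heritability_se(fit: FitResult, trait: str) -> float | None:
    """Delta-method SE of h² from the fit's observed information."""
    return fit.delta_se(_ratio_fn(fit, trait, "h2"))


def repeatability_se(fit: FitResult, trait: str) -> float | None:
    return fit.delta_se(_ratio_fn(fit, trait, "R"))


def metrics_table(fits: dict[str, FitResult], means: dict[str, float],
                  repeated: dict[str, bool]):
    """Assemble the per-trait metrics table (CSV-ready dict rows)."""
    rows = []
    for trait, fit in fits.items():
        v = components_from_fit(fit, trait)
        row = {
            "trait": trait,
            "V_A": v.V_A, "V_PE": v.V_PE, "V_R": v.V_R, "V_P": v.V_P,
            "h2": heritability(v),
            "h2_se": heritability_se(fit, trait),
        }
        if repeated.get(trait, True):
            row["R"] = repeatability(v)
            row["R_se"] = repeatability_se(fit, trait)
        else:
            row["R"] = None
            row["R_se"] = None
        mean = means.get(trait)
        row["CVA"] = cva(v.V_A, mean).CV_A if mean and mean > 0 else None
        rows.append(row)
    return rows
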