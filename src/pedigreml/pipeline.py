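"""End-to-end analysis: ladders, metrics, ID and G structure, PCA.

This is the programmatic form of the full analysis a user would run on a
pedigree + phenotype pair: univariate model ladders per trait, variance
ratios under the final models, the four-trait among-individual model,
the partial genetic-correlation plan, and eigen decompositions of both
correlation matrices.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import correlations, metrics, model
from .model import TRAIT_DESIGNS, scale_sessions, sqrt_transform, reverse_score
from .pedigree import Pedigree, additive_relationship

logger = logging.getLogger(__name__)


def prepare_scores(records: pd.DataFrame):
    """Convert raw task scores to the analysis scale.

    Inhibitory control (peck counts) is square-root transformed, then
    reversed about the observed maximum on the transformed scale so that
    positive values represent good performance.  Spatial ability error
    counts are reversed about the task maximum (18 per session).
    Discrimination scores (number correct) pass through unchanged.
    Returns ``(records, meta)`` where meta holds the means needed for
    observed- and transformed-scale CV_A.
    """
    df = records.copy()
    meta: dict[str, float] = {}
    m = df["trait"] == "inhibitory_control"
    if m.any():
        raw = df.loc[m, "value"].to_numpy(float)
        meta["inhibitory_observed_mean"] = float(np.mean(raw))
        sq = sqrt_transform(raw)
        meta["inhibitory_sqrt_mean"] = float(np.mean(sq))
        meta["inhibitory_reversal_constant"] = float(np.max(sq))
        df.loc[m, "value"] = np.max(sq) - sq
    m = df["trait"] == "spatial_ability"
    if m.any():
        df.loc[m, "value"] = reverse_score(df.loc[m, "value"].to_numpy(float), 18)
    return df, meta


def final_session_means(records: pd.DataFrame) -> dict[str, float]:
    """Observed mean performance in each trait's final session."""
    out = {}
    for t, sub in records.groupby("trait"):
        smax = sub["session"].max()
        out[str(t)] = float(sub.loc[sub["session"] == smax, "value"].mean())
    return out


def analyze(pedigree: Pedigree, records: pd.DataFrame, *,
            raw_scores: bool = False,
            traits: list[str] | None = None,
            do_ladder: bool = True,
            do_multivariate: bool = True,
            fit_kw: dict | None = None) -> dict:
    """Run the full pipeline; returns a JSON-serialisable report."""
    fit_kw = fit_kw or {}
    meta: dict = {}
    if raw_scores:
        records, meta = prepare_scores(records)
    traits = traits or [t for t in model.TRAITS if t in set(records["trait"])]
    for t in traits:
        records = scale_sessions(records, t)
    A = additive_relationship(pedigree)

    report: dict = {"score_meta": meta, "traits": traits}
    final_fits: dict[str, object] = {}
    if do_ladder:
        ladders = {}
        for t in traits:
            lad = model.model_ladder(records, t, A, **fit_kw)
            ladders[t] = lad
            single = TRAIT_DESIGNS[t]["sessions"] == 1
            final_fits[t] = lad.fits[-1]
            for f, lab in zip(lad.fits, lad.labels):
                if not f.converged:
                    logger.warning("%s %s: not converged at tolerance", t, lab)
        report["ladders"] = {
            t: {
                "aic_table": lad.aic_table().to_dict(orient="records"),
                "tests": [
                    {"comparison": x.comparison, "statistic": x.statistic,
                     "null": list(x.null_spec), "p": x.p_value}
                    for x in lad.tests + lad.extra_tests
                ],
                "best_by_aic": lad.labels[lad.best_by_aic()],
            }
            for t, lad in ladders.items()
        }
        means = final_session_means(records)
        if raw_scores and "inhibitory_sqrt_mean" in meta:
            means["inhibitory_control"] = meta["inhibitory_sqrt_mean"]
        repeated = {t: TRAIT_DESIGNS[t]["sessions"] > 1 for t in traits}
        report["metrics"] = metrics.metrics_table(final_fits, means, repeated)

    if do_multivariate and len(traits) >= 2:
        idres = correlations.fit_id_model(records, **fit_kw)
        report["id_model"] = {
            "matrix": idres.matrix.to_dict(),
            "global_test": {"statistic": idres.global_test.statistic,
                            "null": list(idres.global_test.null_spec),
                            "p": idres.global_test.p_value},
            "eigen": idres.eigen.to_dict(),
            "converged": idres.fit.converged,
        }
        gres = correlations.fit_g_partial(records, A, **fit_kw)
        report["g_partial"] = {
            "matrix": gres.matrix.to_dict(),
            "tests": [
                {"comparison": x.comparison, "statistic": x.statistic,
                 "null": list(x.null_spec), "p": x.p_value}
                for x in gres.tests
            ],
            "eigen": gres.eigen.to_dict(),
            "pairwise": [
                {"pair": [p.trait_a, p.trait_b], "r": p.value,
                 "se": p.std_error, "boundary": p.boundary, "source": p.source}
                for p in gres.pairwise
            ],
        }
    return report


def render_report(report: dict) -> str:
    """Human-readable text rendering of an analyze() report."""
    lines = []
    for t, lad in report.get("ladders", {}).items():
        lines.append(f"== {t} ==")
        for row in lad["aic_table"]:
            lines.append(
                f"  {row['model']:<24s} logL={row['loglik']:10.3f} "
                f"k={row['k']} AIC={row['aic']:10.3f}"
                + ("" if row["converged"] else "  [not converged]"))
        for x in lad["tests"]:
            lines.append(
                f"  LRT {x['comparison']}: T={x['statistic']:.3f} "
                f"p={x['p']:.3f}")
        lines.append(f"  preferred by AIC: {lad['best_by_aic']}")
    for row in report.get("metrics", []):
        h2se = row["h2_se"]
        lines.append(
            f"{row['trait']}: V_A={row['V_A']:.3f} V_PE={row['V_PE']:.3f} "
            f"V_R={row['V_R']:.3f} h2={row['h2']:.3f}"
            + (f" ({h2se:.3f})" if h2se else "")
            + (f" R={row['R']:.3f}" if row["R"] is not None else "")
            + (f" CVA={row['CVA']:.3f}" if row["CVA"] else ""))
    for key, label in (("id_model", "Among-individual"), ("g_partial", "Genetic")):
        if key in report:
            lines.append(f"== {label} correlation structure ==")
            mat = report[key]["matrix"]
            lines.append("  traits: " + ", ".join(mat["labels"]))
            for row in mat["values"]:
                lines.append("   " + "  ".join(f"{v:+.3f}" for v in row))
            eig = report[key]["eigen"]
            lines.append("  PC shares: "
                         + ", ".join(f"{p:.1%}" for p in eig["proportions"]))
            lines.append(f"  PC1 same-sign loadings: {eig['same_sign_pc1']}")
    return "\n".join(lines)
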