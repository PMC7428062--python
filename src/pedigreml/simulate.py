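"""Synthetic pedigrees and phenotypes with known genetic architecture.

The generator mirrors the study design the analysis modules assume:
annual cohorts reared in captivity, heavy overwinter mortality before
breeding, harem mating (one male with two to four females), and partial
parent identification.  Phenotypes follow the generative counterpart of
the fitted model::

    y(ind, trait, session) = mu + sex + rearing_group + b_order * order
                             + b_s * s + a0 + a1 s + pe0 + pe1 s + e

with ``s`` the session rescaled to zero at the final session, additive
genetic effects transmitted down the pedigree (unknown parents are
phantom base-population founders, so the masked pedigree's relationship
matrix is exactly the generative covariance), independent permanent-
environment effects, and Gaussian residuals.  Cross-trait structure is
specified at the intercept level through genetic and among-individual
correlation matrices; slope effects are independent across traits.

Values are generated on the analysis scale (positive = good
performance; inhibitory control on the square-root-transformed scale).
Optional discretisation rounds and clips to each task's legal count
range and can also emit study-style raw scores (peck counts, error
counts) for exercising the transform pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model import TRAIT_DESIGNS
from .pedigree import (UNKNOWN, Pedigree, PedigreeEntry, inbreeding,
                       topological_sort, write_pedigree)


@dataclass
class TraitSim:
    """Generating parameters for one trait (analysis scale)."""

    sessions: int
    mu: float
    G0: np.ndarray               # 1x1 or 2x2 genetic (intercept, slope)
    P0: np.ndarray | None        # permanent environment; None if single obs
    V_R: float
    sex_effect: float = 0.3      # male minus female difference
    group_sd: float = 0.3        # SD of rearing-group effects
    order_slope: float = -0.1    # per-SD of test order
    session_slope: float = 0.2   # mean improvement per session
    count_range: tuple[int, int] | None = None
    completion: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.G0 = np.atleast_2d(np.asarray(self.G0, dtype=float))
        if self.P0 is not None:
            self.P0 = np.atleast_2d(np.asarray(self.P0, dtype=float))
        for M in (self.G0, self.P0):
            if M is not None and np.min(np.linalg.eigvalsh(M)) < -1e-10:
                raise ValueError("trait covariance must be PSD")
        if self.V_R < 0:
            raise ValueError("V_R must be non-negative")
        if abs(sum(self.completion) - 1.0) > 1e-9:
            raise ValueError("completion distribution must sum to 1")


def _default_traits() -> dict[str, TraitSim]:
    """Study-shaped defaults: session counts and count ranges follow the
    four tasks; variance magnitudes give heritabilities between roughly
    0.1 and 0.25 and repeatabilities between roughly 0.17 and 0.33."""
    return {
        "inhibitory_control": TraitSim(
            sessions=1, mu=5.5, G0=[[0.2]], P0=None, V_R=0.8,
            session_slope=0.0, count_range=None),
        "visual_discrimination": TraitSim(
            sessions=5, mu=7.0,
            G0=[[0.5, 0.02], [0.02, 0.05]],
            P0=[[0.25, 0.01], [0.01, 0.03]],
            V_R=1.75, count_range=(0, 10)),
        "spatial_discrimination": TraitSim(
            sessions=3, mu=6.5,
            G0=[[0.55, 0.02], [0.02, 0.04]],
            P0=[[0.25, 0.01], [0.01, 0.03]],
            V_R=1.6, count_range=(0, 10)),
        "spatial_ability": TraitSim(
            sessions=8, mu=12.0,
            G0=[[0.55, 0.02], [0.02, 0.06]],
            P0=[[0.5, 0.02], [0.02, 0.1]],
            V_R=5.0, count_range=(0, 18)),
    }


def _uniform_corr(r: float, k: int) -> np.ndarray:
    return np.full((k, k), r) + (1 - r) * np.eye(k)


@dataclass
class SimulationConfig:
    """Study-design parameters; defaults emulate the source population."""

    seed: int = 0
    n_per_cohort: int = 200
    n_cohorts: int = 4
    survival_rate: float = 0.2
    harem_sizes: tuple[int, ...] = (2, 3, 4)
    prop_dam_known: float = 0.5
    prop_sire_known: float = 0.61
    traits: dict[str, TraitSim] = field(default_factory=_default_traits)
    #: cross-trait genetic correlations at the intercept level (in trait
    #: order); default is a shared general factor of moderate strength
    r_G: np.ndarray | None = None
    #: cross-trait among-individual (PE) intercept correlations
    r_PE: np.ndarray | None = None
    discretize: bool = False

    def __post_init__(self) -> None:
        k = len(self.traits)
        if self.r_G is None:
            self.r_G = _uniform_corr(0.6, k)
        if self.r_PE is None:
            self.r_PE = _uniform_corr(0.1, k)
        self.r_G = np.asarray(self.r_G, dtype=float)
        self.r_PE = np.asarray(self.r_PE, dtype=float)
        for name, M in (("r_G", self.r_G), ("r_PE", self.r_PE)):
            if M.shape != (k, k) or np.min(np.linalg.eigvalsh(M)) < -1e-10:
                raise ValueError(f"{name} must be a PSD {k}x{k} matrix")
        for p in (self.survival_rate, self.prop_dam_known, self.prop_sire_known):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    def trait_names(self) -> list[str]:
        return list(self.traits)


@dataclass
class SimulatedDataset:
    pedigree: Pedigree
    records: pd.DataFrame
    truth: dict


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(cfg: SimulationConfig, rng: np.random.Generator) -> Pedigree:
    """Cohort-structured pedigree with harem breeding and masked parents.

    Cohort 1 is all founders.  For each later cohort, survivors of the
    previous cohort (at ``survival_rate``) form harems of one male and
    2-4 females; each offspring draws a harem and a dam within it.
    Sire/dam identities are then masked to UNKNOWN independently with
    probability ``1 - prop_known``.  Acyclic by construction.
    """
    entries: list[PedigreeEntry] = []
    sex_of: dict[str, str] = {}
    prev_cohort: list[str] = []
    counter = 0
    for cohort in range(1, cfg.n_cohorts + 1):
        if cohort == 1:
            parents_m, parents_f = [], []
        else:
            survived = [i for i in prev_cohort
                        if rng.random() < cfg.survival_rate]
            parents_m = [i for i in survived if sex_of[i] == "M"]
            parents_f = [i for i in survived if sex_of[i] == "F"]
            if not parents_m or not parents_f:
                raise SimulationError(
                    f"no surviving {'males' if not parents_m else 'females'} "
                    f"for cohort {cohort}; increase n_per_cohort or "
                    "survival_rate")
        harems = _form_harems(parents_m, parents_f, cfg, rng)
        cohort_ids = []
        for _ in range(cfg.n_per_cohort):
            counter += 1
            iid = f"I{counter:05d}"
            if cohort == 1 or not harems:
                sire = dam = UNKNOWN
            else:
                sire, females = harems[rng.integers(len(harems))]
                dam = females[rng.integers(len(females))]
                if rng.random() >= cfg.prop_sire_known:
                    sire = UNKNOWN
                if rng.random() >= cfg.prop_dam_known:
                    dam = UNKNOWN
            entries.append(PedigreeEntry(iid, sire, dam, cohort))
            sex_of[iid] = "M" if rng.random() < 0.5 else "F"
            cohort_ids.append(iid)
        prev_cohort = cohort_ids
    ped = topological_sort(Pedigree(entries))
    ped.sexes = sex_of  # carried for phenotype simulation
    return ped


def _form_harems(males, females, cfg, rng):
    if not males or not females:
        return []
    males = list(rng.permutation(males))
    females = list(rng.permutation(females))
    harems = []
    i = 0
    for m in males:
        if i >= len(females):
            break
        size = int(rng.choice(cfg.harem_sizes))
        group = females[i:i + size]
        if group:
            harems.append((m, group))
        i += size
    return harems


# ---------------------------------------------------------------------------
# genetic effects


def joint_covariance(cfg: SimulationConfig, which: str):
    """Joint (trait x basis) covariance: per-trait blocks from G0/P0,
    cross-trait intercept covariances from r_G/r_PE, slopes independent
    across traits.  Returns (dim labels, matrix)."""
    names = cfg.trait_names()
    dims, int_pos, diag = [], {}, []
    for t in names:
        sim = cfg.traits[t]
        M = sim.G0 if which == "genetic" else sim.P0
        if M is None:
            continue
        int_pos[t] = len(dims)
        dims.append(f"{t}:int")
        diag.append((t, M))
        if M.shape[0] == 2:
            dims.append(f"{t}:slope")
    k = len(dims)
    J = np.zeros((k, k))
    pos = 0
    for t, M in diag:
        b = M.shape[0]
        J[pos:pos + b, pos:pos + b] = M
        pos += b
    R = cfg.r_G if which == "genetic" else cfg.r_PE
    for a, ta in enumerate(names):
        for b_, tb in enumerate(names):
            if a >= b_ or ta not in int_pos or tb not in int_pos:
                continue
            i, j = int_pos[ta], int_pos[tb]
            c = R[a, b_] * np.sqrt(J[i, i] * J[j, j])
            J[i, j] = J[j, i] = c
    w = np.min(np.linalg.eigvalsh(J)) if k else 0.0
    if w < -1e-10:
        raise ValueError("joint covariance is not PSD; weaken correlations")
    return dims, J


def simulate_breeding_values(ped: Pedigree, G_joint: np.ndarray,
                             rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw additive genetic effect vectors down the pedigree.

    Founders are N(0, G); an offspring is the parental mean plus a
    Mendelian deviation with covariance ``1/2 (1 - (F_s + F_d)/2) G``.
    An UNKNOWN parent contributes a fresh phantom founder draw.
    """
    G_joint = np.atleast_2d(np.asarray(G_joint, dtype=float))
    k = G_joint.shape[0]
    w = np.linalg.eigvalsh(G_joint)
    if np.min(w) < -1e-10:
        raise ValueError("G_joint must be PSD")
    if np.allclose(G_joint, 0):
        return {e.individual: np.zeros(k) for e in ped.entries}
    ped = topological_sort(ped)
    F = inbreeding(ped)
    Lg = np.linalg.cholesky(G_joint + 1e-12 * np.trace(G_joint) / k * np.eye(k))
    effects: dict[str, np.ndarray] = {}

    def founder_draw():
        return Lg @ rng.standard_normal(k)

    for e in ped.entries:
        if e.is_founder:
            effects[e.individual] = founder_draw()
            continue
        gs = effects[e.sire] if e.sire != UNKNOWN else founder_draw()
        gd = effects[e.dam] if e.dam != UNKNOWN else founder_draw()
        Fs = F.get(e.sire, 0.0) if e.sire != UNKNOWN else 0.0
        Fd = F.get(e.dam, 0.0) if e.dam != UNKNOWN else 0.0
        scale = np.sqrt(0.5 * (1.0 - 0.5 * (Fs + Fd)))
        effects[e.individual] = 0.5 * (gs + gd) + scale * Lg @ rng.standard_normal(k)
    return effects


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(ped: Pedigree, effects: dict[str, np.ndarray],
                        cfg: SimulationConfig,
                        rng: np.random.Generator) -> SimulatedDataset:
    """Assemble the long-format phenotype table from genetic effects,
    fresh permanent-environment effects, fixed effects and residuals."""
    gdims, _ = joint_covariance(cfg, "genetic")
    pdims, P_joint = joint_covariance(cfg, "pe")
    ids = ped.ids
    n = len(ids)
    sexes = getattr(ped, "sexes", None) or {
        i: ("M" if rng.random() < 0.5 else "F") for i in ids}
    cohorts = {e.individual: (e.cohort or 1) for e in ped.entries}
    houses = {i: int(rng.integers(1, 5)) for i in ids}
    test_order = {i: float(rng.standard_normal()) for i in ids}

    if len(pdims):
        Lp = np.linalg.cholesky(
            P_joint + 1e-12 * max(np.trace(P_joint), 1.0) / len(pdims)
            * np.eye(len(pdims)))
        pe = {i: Lp @ rng.standard_normal(len(pdims)) for i in ids}
    else:
        pe = {i: np.zeros(0) for i in ids}

    group_levels = sorted({(houses[i], cohorts[i]) for i in ids})
    group_eff: dict[str, dict] = {}
    for t, sim in cfg.traits.items():
        group_eff[t] = {g: sim.group_sd * rng.standard_normal()
                        for g in group_levels}

    gidx = {d: j for j, d in enumerate(gdims)}
    pidx = {d: j for j, d in enumerate(pdims)}
    rows = []
    for t, sim in cfg.traits.items():
        S = sim.sessions
        for i in ids:
            a = effects.get(i, np.zeros(len(gdims)))
            a0 = a[gidx[f"{t}:int"]] if f"{t}:int" in gidx else 0.0
            a1 = a[gidx[f"{t}:slope"]] if f"{t}:slope" in gidx else 0.0
            p0 = pe[i][pidx[f"{t}:int"]] if f"{t}:int" in pidx else 0.0
            p1 = pe[i][pidx[f"{t}:slope"]] if f"{t}:slope" in pidx else 0.0
            base = (sim.mu
                    + (0.5 if sexes[i] == "M" else -0.5) * sim.sex_effect
                    + group_eff[t][(houses[i], cohorts[i])]
                    + sim.order_slope * test_order[i])
            for session in range(1, S + 1):
                s = session - S
                e_res = np.sqrt(sim.V_R) * rng.standard_normal()
                y = base + sim.session_slope * s + a0 + a1 * s + p0 + p1 * s + e_res
                latent = y
                if cfg.discretize and sim.count_range is not None:
                    lo, hi = sim.count_range
                    y = float(np.clip(np.round(y), lo, hi))
                rows.append({
                    "id": i, "trait": t, "session": session, "value": y,
                    "sex": sexes[i],
                    "rearing_group": f"H{houses[i]}Y{cohorts[i]}",
                    "test_order": test_order[i], "cohort": cohorts[i],
                    "latent": latent,
                })
    records = pd.DataFrame(rows)
    truth = {
        "seed": cfg.seed,
        "trait_params": {
            t: {"sessions": sim.sessions, "mu": sim.mu,
                "G0": sim.G0.tolist(),
                "P0": None if sim.P0 is None else sim.P0.tolist(),
                "V_R": sim.V_R}
            for t, sim in cfg.traits.items()
        },
        "r_G": cfg.r_G.tolist(),
        "r_PE": cfg.r_PE.tolist(),
        "discretize": cfg.discretize,
        "n_individuals": n,
    }
    return SimulatedDataset(ped, records, truth)


def _sessions_kept(S: int, cls: int, rng) -> int:
    """Integer session count inside the completion class's band.

    Class 1 keeps 70-99% of sessions, class 2 keeps 50-70%; always at
    least half the sessions and never all of them."""
    lo_f, hi_f = (0.70, 0.99) if cls == 1 else (0.50, 0.6999)
    lo = max(int(np.ceil(lo_f * S)), int(np.ceil(0.5 * S)))
    hi = min(int(np.floor(hi_f * S)), S - 1)
    if lo > hi:
        return max(hi, int(np.ceil(0.5 * S)))
    return int(rng.integers(lo, hi + 1))


def apply_missingness(ds: SimulatedDataset, cfg: SimulationConfig,
                      rng: np.random.Generator) -> SimulatedDataset:
    """Drop sessions from the end per the trait's completion-class mix.

    Classes: complete, 70-99% complete, 50-70% complete.  No retained
    individual keeps fewer than half of the trait's sessions; the
    analysis kept only such completers.
    """
    keep = np.ones(len(ds.records), dtype=bool)
    df = ds.records
    for t, sim in cfg.traits.items():
        S = sim.sessions
        if S == 1 or sim.completion[0] >= 1.0 - 1e-12:
            continue
        for iid, idx in df[df["trait"] == t].groupby("id").groups.items():
            cls = rng.choice(3, p=sim.completion)
            if cls == 0:
                continue
            n_keep = _sessions_kept(S, int(cls), rng)
            idx = np.asarray(idx)
            sess = df.loc[idx, "session"].to_numpy()
            keep[idx[sess > n_keep]] = False
    out = SimulatedDataset(ds.pedigree, df[keep].reset_index(drop=True),
                           dict(ds.truth))
    return out


def simulate_dataset(cfg: SimulationConfig,
                     rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Full pipeline: pedigree, breeding values, phenotypes, missingness."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    gdims, G_joint = joint_covariance(cfg, "genetic")
    effects = (simulate_breeding_values(ped, G_joint, rng)
               if len(gdims) else {i: np.zeros(0) for i in ped.ids})
    ds = simulate_phenotypes(ped, effects, cfg, rng)
    ds = apply_missingness(ds, cfg, rng)
    return ds


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write pedigree.csv, phenotypes.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "truth": outdir / "truth.json",
    }
    write_pedigree(ds.pedigree, paths["pedigree"])
    ds.records.to_csv(paths["phenotypes"], index=False, float_format="%.10g")
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=1)
    return paths
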