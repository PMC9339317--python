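"""Replicate studies: bias/SD/MSE summaries and likelihood-surface grids.

Three study designs are orchestrated here:

* Study 1 (marker LD): genotypes for unrelated individuals under
  autocorrelated (1A), block (1B), or exact-repeat (1C) LD, across a grid of
  (n, m) combinations and LD levels, with every estimator applied to each
  replicate data set.
* Study 2 (likelihood surfaces): the MVN log-likelihood of the variance
  components evaluated on a dense (sigma_g^2, sigma_e^2) grid, averaged over
  replicates after subtracting each replicate's own maximum.
* Study 3 (relatedness): cousinship samples (10 groups of 40 first, second,
  or third cousins, or unrelateds) generated by pedigree gene drop, with the
  marker count swept from 400 to 4,000.

All randomness flows from a single master seed through spawned
``numpy.random.SeedSequence`` streams: the allele-frequency draw is fixed
once per condition and every replicate gets an independent child stream, so
reruns with the same master seed are byte-identical.  Estimator failures are
recorded per replicate with their reason and never dropped silently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import estimators as est
from . import simdata

__all__ = [
    "DEFAULT_ESTIMATORS",
    "STUDY1_GRID",
    "STUDY1_LEVELS",
    "STUDY3_MARKERS",
    "StudyCondition",
    "LikelihoodSurface",
    "run_condition",
    "summarize",
    "likelihood_surface",
    "run_study",
    "study_conditions",
]

logger = logging.getLogger(__name__)

DEFAULT_ESTIMATORS = ("HE", "Dicker1", "Dicker2", "ML", "gold")

#: (n, m) combinations per study; half causal for 1A/1B, all causal for 1C
STUDY1_GRID = {
    "1A": [(1000, 100), (200, 500), (200, 1500), (2000, 500)],
    "1B": [(1000, 100), (200, 500), (200, 1500), (2000, 500)],
    "1C": [(1000, 200), (200, 1000), (200, 3000), (2000, 1000)],
}
STUDY1_LEVELS = {
    "1A": [0.0, 0.2, 0.4, 0.6, 0.8],
    "1B": [0.0, 0.2, 0.4, 0.6, 0.8],
    "1C": [0, 2, 4, 6, 8],
}
STUDY3_MARKERS = list(range(400, 4001, 400))

#: default replicate counts at scale 1; a full-size run uses 500 for 1*/3
DEFAULT_REPLICATES = {"1A": 200, "1B": 200, "1C": 200, "2": 100, "3": 100}


@dataclass(frozen=True)
class StudyCondition:
    """One cell of a simulation study.

    Either ``ld_spec`` (unrelated individuals under an LD structure) or
    ``degree`` plus ``n_markers`` (cousinship gene drop) must be given.
    """

    label: str
    n: int
    h2: float = 0.8
    ld_spec: Optional[simdata.LDStructureSpec] = None
    degree: Optional[str] = None
    n_markers: Optional[int] = None
    k: int = 40
    n_groups: int = 10
    map_length_cM: float = 3000.0
    n_replicates: int = 200
    estimator_names: Sequence[str] = DEFAULT_ESTIMATORS
    backend: str = "binomial_threshold"
    master_seed: int = 0

    def __post_init__(self):
        if (self.ld_spec is None) == (self.degree is None):
            raise ValueError("give exactly one of ld_spec or degree")
        if self.degree is not None and self.n_markers is None:
            raise ValueError("pedigree conditions need n_markers")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class LikelihoodSurface:
    """Replicate-averaged relative log-likelihood over a variance grid.

    ``values[i, j]`` is the mean over replicates of
    loglik(sigma_g2_grid[i], sigma_e2_grid[j]) minus that replicate's grid
    maximum, so every stored cell is <= 0 and each replicate attains 0 at
    its own maximum before averaging.  ``truncation_quantile`` is a
    rendering hint only; stored values are untruncated.  Non-positive-
    definite cells are NaN.
    """

    sigma_g2_grid: np.ndarray
    sigma_e2_grid: np.ndarray
    values: np.ndarray
    argmax: tuple[float, float]
    n_replicates: int
    truncation_quantile: float = 0.6


def _apply_estimator(name: str, ctx: dict) -> est.VarianceEstimate:
    if name == "HE":
        return est.he_regression(ctx["y"], ctx["grm"])
    if name == "HE_matrix":
        return est.he_matrix_form(ctx["y"], ctx["grm"])
    if name == "Dicker1":
        return est.dicker1(ctx["y"], ctx["std"])
    if name == "Dicker1_sigma":
        return est.dicker1_sigma(ctx["y"], ctx["std"])
    if name == "Dicker2":
        return est.dicker2(ctx["y"], ctx["std"])
    if name == "ML":
        return est.fit_variance_components(ctx["y"], ctx["grm"], method="ML")
    if name == "REML":
        return est.fit_variance_components(ctx["y"], ctx["grm"], method="REML")
    if name == "gold":
        return est.gold_standard_from_trait(ctx["trait"])
    raise ValueError(f"unknown estimator {name!r}")


def _condition_freqs(cond: StudyCondition, ss: np.random.SeedSequence):
    rng = np.random.default_rng(ss)
    if cond.ld_spec is not None:
        return simdata.draw_allele_freqs(cond.ld_spec.n_base, rng)
    return simdata.draw_allele_freqs(cond.n_markers, rng)


def simulate_replicate(cond: StudyCondition, freqs, ped, rep_ss):
    """Fresh genotypes and phenotype for one replicate of a condition."""
    geno_ss, pheno_ss = rep_ss.spawn(2)
    if cond.ld_spec is not None:
        data = simdata.sim_genotypes(
            cond.n, cond.ld_spec, freqs, backend=cond.backend,
            seed=np.random.default_rng(geno_ss),
        )
    else:
        data = simdata.gene_drop(
            ped, cond.n_markers, freqs, cond.map_length_cM,
            seed=np.random.default_rng(geno_ss),
        )
    trait = simdata.sim_phenotype(data, cond.h2, seed=np.random.default_rng(pheno_ss))
    return data, trait


def run_condition(cond: StudyCondition) -> pd.DataFrame:
    """Run all replicates of one condition and return the raw estimate table.

    Each row is one (replicate, estimator) pair with the raw sigma_g^2 and
    h^2 estimates; failures carry the error message in the ``error`` column.
    """
    root = np.random.SeedSequence(cond.master_seed)
    freq_ss, rep_root = root.spawn(2)
    freqs = _condition_freqs(cond, freq_ss)
    ped = None
    if cond.degree is not None:
        ped = simdata.build_pedigree(cond.degree, cond.k, cond.n_groups)
        if len(ped.sampled_ids) != cond.n:
            raise ValueError(
                f"pedigree yields {len(ped.sampled_ids)} sampled individuals, "
                f"condition says n={cond.n}"
            )
    rows = []
    for rep, rep_ss in enumerate(rep_root.spawn(cond.n_replicates)):
        data, trait = simulate_replicate(cond, freqs, ped, rep_ss)
        std = est.standardize_data(data)
        ctx = {"y": trait.y, "std": std, "trait": trait, "grm": None}
        if any(name in ("HE", "HE_matrix", "ML", "REML") for name in cond.estimator_names):
            ctx["grm"] = est.compute_grm(std)
        for name in cond.estimator_names:
            row = {
                "label": cond.label,
                "replicate": rep,
                "estimator": name,
                "sigma_g2_hat": np.nan,
                "h2_hat": np.nan,
                "error": None,
                "seed": str(rep_ss.spawn_key),
            }
            try:
                fit = _apply_estimator(name, ctx)
                row["sigma_g2_hat"] = fit.sigma_g2_hat
                row["h2_hat"] = fit.h2_hat
            except (ValueError, np.linalg.LinAlgError) as exc:
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame, h2: float) -> pd.DataFrame:
    """Per (label, estimator) bias/SD/MSE summary on the h^2 scale.

    ``mse`` is the mean squared deviation from the generating ``h2``
    (denominator n), so it decomposes exactly as bias^2 + variance with the
    same denominator.  ``mc_se`` is the Monte-Carlo standard error of the
    mean estimate; failed replicates are counted, not imputed.
    """
    recs = []
    for (label, name), grp in table.groupby(["label", "estimator"], sort=False):
        ok = grp[grp["error"].isna()]
        n_ok = len(ok)
        n_fail = len(grp) - n_ok
        if n_ok < 2:
            raise ValueError(f"cell ({label}, {name}) has fewer than 2 successful replicates")
        vals = ok["h2_hat"].to_numpy()
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        recs.append(
            {
                "label": label,
                "estimator": name,
                "mean": mean,
                "bias": mean - h2,
                "sd": sd,
                "mse": float(np.mean((vals - h2) ** 2)),
                "mc_se": sd / math.sqrt(n_ok),
                "n_ok": n_ok,
                "n_fail": n_fail,
            }
        )
    return pd.DataFrame(recs)


def likelihood_surface(
    cond: StudyCondition,
    grid_min: float = 0.05,
    grid_max: float = 1.5,
    grid_spacing: float = 0.05,
    n_replicates: Optional[int] = None,
) -> LikelihoodSurface:
    """Replicate-averaged relative log-likelihood surface for a condition."""
    n_rep = cond.n_replicates if n_replicates is None else n_replicates
    grid = np.arange(grid_min, grid_max + grid_spacing / 2, grid_spacing)
    root = np.random.SeedSequence(cond.master_seed)
    freq_ss, rep_root = root.spawn(2)
    freqs = _condition_freqs(cond, freq_ss)
    ped = None
    if cond.degree is not None:
        ped = simdata.build_pedigree(cond.degree, cond.k, cond.n_groups)
    acc = np.zeros((grid.size, grid.size))
    for rep_ss in rep_root.spawn(n_rep):
        data, trait = simulate_replicate(cond, freqs, ped, rep_ss)
        std = est.standardize_data(data)
        grm = est.compute_grm(std)
        model = est.GaussianVarianceModel(trait.y, grm)
        ll = model.loglik_grid(grid, grid)
        acc += ll - np.nanmax(ll)
    values = acc / n_rep
    i, j = np.unravel_index(np.nanargmax(values), values.shape)
    return LikelihoodSurface(
        sigma_g2_grid=grid,
        sigma_e2_grid=grid,
        values=values,
        argmax=(float(grid[i]), float(grid[j])),
        n_replicates=n_rep,
    )


def ridge_slope(surface: LikelihoodSurface) -> float:
    """Slope of the conditional maxima sigma_e2*(sigma_g2).

    For each sigma_g^2 column, the maximizing sigma_e^2 is found; a least-
    squares line through those points has slope near -1 when the surface
    ridge follows the constant-total-variance diagonal (n >> m) and near 0
    when the ridge is horizontal (m >> n).
    """
    sg = surface.sigma_g2_grid
    se_star = surface.sigma_e2_grid[np.nanargmax(surface.values, axis=1)]
    return float(np.polyfit(sg, se_star, 1)[0])


# ---------------------------------------------------------------------------
# full study orchestration
# ---------------------------------------------------------------------------


def _scaled_reps(study_id: str, scale_factor: float, full: bool) -> int:
    base = 500 if (full and study_id in ("1A", "1B", "1C", "3")) else DEFAULT_REPLICATES[study_id]
    return max(2, int(round(base * scale_factor)))


def study_conditions(
    study_id: str,
    scale_factor: float = 1.0,
    master_seed: int = 0,
    backend: str = "binomial_threshold",
    full: bool = False,
) -> list[StudyCondition]:
    """The grid of conditions making up one study."""
    if study_id not in ("1A", "1B", "1C", "2", "3"):
        raise ValueError(f"unknown study {study_id!r}")
    if not (0.0 < scale_factor <= 1.0):
        raise ValueError("scale_factor must lie in (0, 1]")
    n_rep = _scaled_reps(study_id if study_id != "2" else "2", scale_factor, full)
    conds = []
    seed_counter = master_seed
    if study_id in ("1A", "1B"):
        kind = "autocorrelation" if study_id == "1A" else "block"
        for idx, (n, m) in enumerate(STUDY1_GRID[study_id], start=1):
            for rho in STUDY1_LEVELS[study_id]:
                conds.append(
                    StudyCondition(
                        label=f"{study_id}-{idx}-rho{rho:g}",
                        n=n,
                        ld_spec=simdata.LDStructureSpec(kind=kind, m=m, rho=rho),
                        n_replicates=n_rep,
                        backend=backend,
                        master_seed=seed_counter,
                    )
                )
                seed_counter += 1
    elif study_id == "1C":
        for idx, (n, m) in enumerate(STUDY1_GRID["1C"], start=1):
            for r in STUDY1_LEVELS["1C"]:
                conds.append(
                    StudyCondition(
                        label=f"1C-{idx}-r{r}",
                        n=n,
                        ld_spec=simdata.LDStructureSpec(
                            kind="repeat", m=m, repeat_count=r, repeat_fraction=0.1
                        ),
                        n_replicates=n_rep,
                        backend=backend,
                        master_seed=seed_counter,
                    )
                )
                seed_counter += 1
    elif study_id == "2":
        for idx, (n, m) in enumerate(STUDY1_GRID["1C"], start=1):
            for r in (0, 8):
                conds.append(
                    StudyCondition(
                        label=f"2-{idx}-r{r}",
                        n=n,
                        ld_spec=simdata.LDStructureSpec(
                            kind="repeat", m=m, repeat_count=r, repeat_fraction=0.1
                        ),
                        n_replicates=n_rep,
                        backend=backend,
                        master_seed=seed_counter,
                    )
                )
                seed_counter += 1
    else:  # study 3
        for degree in simdata.COUSIN_DEGREES:
            for M in STUDY3_MARKERS:
                conds.append(
                    StudyCondition(
                        label=f"3-{degree}-M{M}",
                        n=400,
                        degree=degree,
                        n_markers=M,
                        n_replicates=n_rep,
                        estimator_names=("HE", "Dicker2", "ML", "gold"),
                        master_seed=seed_counter,
                    )
                )
                seed_counter += 1
    return conds


def run_study(
    study_id: str,
    scale_factor: float = 1.0,
    master_seed: int = 0,
    outdir: Optional[str] = None,
    backend: str = "binomial_threshold",
    full: bool = False,
    conditions: Optional[Sequence[StudyCondition]] = None,
):
    """Execute a full study grid and optionally write its artifacts.

    Returns ``(replicates, summary)`` DataFrames for studies 1A/1B/1C/3 and
    a list of :class:`LikelihoodSurface` for study 2.  With ``outdir`` set,
    a tidy ``replicates.csv``, ``summary.csv``, per-condition figures, and a
    config echo are written there.
    """
    conds = (
        list(conditions)
        if conditions is not None
        else study_conditions(study_id, scale_factor, master_seed, backend, full)
    )
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        _write_config_echo(out / "config.yaml", study_id, conds)

    if study_id == "2":
        surfaces = []
        for cond in conds:
            logger.info("surface %s", cond.label)
            surf = likelihood_surface(cond)
            surfaces.append((cond, surf))
            if out:
                _render_surface(surf, cond, out / f"surface_{cond.label}.png")
        return surfaces

    tables = []
    for cond in conds:
        logger.info("condition %s (%d replicates)", cond.label, cond.n_replicates)
        tables.append(run_condition(cond))
    replicates = pd.concat(tables, ignore_index=True)
    summary = summarize(replicates, conds[0].h2)
    if out:
        replicates.to_csv(out / "replicates.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        _render_summary(summary, out / f"study_{study_id}_summary.png")
    return replicates, summary


def _write_config_echo(path: Path, study_id: str, conds) -> None:
    import yaml

    payload = {
        "study": study_id,
        "conditions": [
            {
                "label": c.label,
                "n": c.n,
                "h2": c.h2,
                "n_replicates": c.n_replicates,
                "backend": c.backend,
                "master_seed": c.master_seed,
                "estimators": list(c.estimator_names),
                **(
                    {
                        "kind": c.ld_spec.kind,
                        "m": c.ld_spec.m,
                        "rho": c.ld_spec.rho,
                        "repeat_count": c.ld_spec.repeat_count,
                        "repeat_fraction": c.ld_spec.repeat_fraction,
                    }
                    if c.ld_spec is not None
                    else {"degree": c.degree, "n_markers": c.n_markers}
                ),
            }
            for c in conds
        ],
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=False))


def _render_summary(summary: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4))
    for name, grp in summary.groupby("estimator"):
        ax1.errorbar(range(len(grp)), grp["mean"], yerr=grp["mc_se"], label=name, marker="o", ms=3)
        ax2.plot(range(len(grp)), grp["mse"], label=name, marker="o", ms=3)
    ax1.axhline(0.8, color="gray", lw=0.8)
    ax1.set_ylabel("mean $\\hat h^2$")
    ax2.set_ylabel("MSE")
    for ax in (ax1, ax2):
        ax.set_xlabel("condition index")
    ax1.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _render_surface(surface: LikelihoodSurface, cond, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = surface.values.copy()
    finite = vals[np.isfinite(vals)]
    # truncation applied for rendering only, never to stored values
    cut = np.quantile(finite, 1.0 - surface.truncation_quantile)
    shown = np.maximum(vals, cut)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.pcolormesh(surface.sigma_g2_grid, surface.sigma_e2_grid, shown.T, shading="nearest")
    ax.plot(*surface.argmax, "o", color="red", ms=5)
    ax.set_xlabel("$\\sigma_g^2$")
    ax.set_ylabel("$\\sigma_e^2$")
    ax.set_title(cond.label)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
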