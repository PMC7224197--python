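"""Simulated genotypes and clonal field trials with known ground truth.

The trial generator mirrors an augmented clonal evaluation design: clones
planted in plots arranged along ranges (optionally nested in locations),
with the number of harvested plants (NOHAV) and a 1-5 mosaic-disease
severity score (CMD) as plot covariates.  Every variance component, fixed
effect and residual is stored so downstream mixed-model estimates can be
checked against truth.

The genetic architecture is additive: a handful of QTL with explicit
effects plus a polygenic term spread over many small-effect markers, scaled
so that the plot-basis heritability sigma2_c / (sigma2_c + sigma2_e) hits a
target.  One designated "confound" QTL drives the latent liability behind
the CMD score, reproducing the situation where a disease-resistance locus
masquerades as a size/shape QTL unless phenotypes are CMD-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "GenotypeMatrix",
    "TrialParams",
    "DesignSpec",
    "SimulatedTrial",
    "simulate_genotypes",
    "simulate_trial",
]


@dataclass
class GenotypeMatrix:
    """Clone x marker dosage matrix with marker map.

    ``dosages`` holds 0/1/2 counts of the alternate allele (NaN = missing,
    allowed only pre-QC).  ``markers`` has one row per marker with columns
    ``marker_id, chrom, pos``.
    """

    dosages: np.ndarray  # (n_clones, n_markers) float
    clone_ids: np.ndarray  # (n_clones,) str
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.clone_ids) != n or len(self.markers) != m:
            raise ValueError("dosage matrix inconsistent with clone/marker labels")

    @property
    def n_clones(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[:, keep],
            clone_ids=self.clone_ids,
            markers=self.markers.iloc[np.asarray(keep)].reset_index(drop=True),
        )


def simulate_genotypes(
    n_clones: int,
    n_markers: int,
    n_chromosomes: int = 18,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Independent biallelic markers: dosage ~ Binomial(2, p_m), p_m ~ U(maf_range).

    Markers are assigned to ``n_chromosomes`` chromosomes in near-equal
    contiguous blocks with integer positions.  ``missing_rate`` > 0 blanks a
    random fraction of calls (for QC testing).
    """
    lo, hi = maf_range
    if hi < lo:
        raise ValueError(f"degenerate maf_range: upper {hi} < lower {lo}")
    if not (0 < lo <= 0.5 and 0 < hi <= 0.5):
        raise ValueError("maf_range must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_markers)
    dos = rng.binomial(2, p, size=(n_clones, n_markers)).astype(float)
    if missing_rate > 0:
        dos[rng.random(dos.shape) < missing_rate] = np.nan

    chrom_of = np.array_split(np.arange(n_markers), n_chromosomes)
    chrom = np.empty(n_markers, dtype=int)
    pos = np.empty(n_markers, dtype=int)
    for c, idx in enumerate(chrom_of, start=1):
        chrom[idx] = c
        pos[idx] = np.arange(1, len(idx) + 1) * 1000
    markers = pd.DataFrame(
        {
            "marker_id": [f"S{c}_{p}" for c, p in zip(chrom, pos)],
            "chrom": chrom,
            "pos": pos,
        }
    )
    clone_ids = np.array([f"clone{i:04d}" for i in range(n_clones)])
    return GenotypeMatrix(dosages=dos, clone_ids=clone_ids, markers=markers)


@dataclass
class TrialParams:
    """Generative parameters for one simulated trait.

    ``h2_plot`` is the plot-basis heritability sigma2_c/(sigma2_c+sigma2_e)
    that the clone genetic values are scaled to (given ``sigma2_e``).
    ``cmd_confound_r`` is the target correlation between the CMD severity
    score and the dosage at ``confound_qtl`` (which has no direct effect on
    the trait unless it also appears in ``qtl_effects``).
    """

    trait: str = "area"
    mu: float = 100.0
    h2_plot: float = 0.3
    sigma2_range: float = 0.5
    sigma2_e: float = 1.0
    beta_nohav: float = -0.2
    beta_cmd: float = 0.0
    n_qtl: int = 5
    qtl_var_frac: float = 0.3  # fraction of genetic variance from explicit QTL
    qtl_effects: dict[int, float] | None = None  # marker index -> raw effect
    confound_qtl: int | None = None
    cmd_confound_r: float = 0.0


@dataclass
class DesignSpec:
    """Field layout: an augmented design with checks in every range.

    Each clone gets ``plots_per_clone`` plots; on top of those, the first
    ``n_checks`` clones act as checks and ``checks_per_range`` check plots
    are added to every range.  The replicated checks connect ranges and keep
    the clone variance identifiable even at one plot per entry.
    """

    locations: tuple[str, ...] = ("LOC1",)
    plots_per_clone: int = 1
    plots_per_range: int = 20
    n_checks: int = 5
    checks_per_range: int = 2
    nohav_choices: tuple[int, ...] = (2, 3, 4)


@dataclass
class SimulatedTrial:
    """A simulated trial with full generative ground truth."""

    genotypes: GenotypeMatrix
    design: pd.DataFrame  # plot_id, clone_id, location, range, NOHAV, CMD
    phenotypes: pd.DataFrame  # design columns + one column per trait
    true_genetic_values: dict[str, pd.Series]  # trait -> clone-indexed values
    qtl_effects: dict[str, dict[int, float]]
    range_effects: pd.Series
    residuals: pd.DataFrame  # per plot, per trait
    params: list[TrialParams]
    components: pd.DataFrame  # per plot, per trait: additive decomposition
    seed: int = 0


def _scaled_genetic_values(
    geno: GenotypeMatrix, p: TrialParams, rng: np.random.Generator
) -> tuple[np.ndarray, dict[int, float]]:
    """Additive genetic values with Var = h2/(1-h2) * sigma2_e."""
    target_var = p.h2_plot / (1.0 - p.h2_plot) * p.sigma2_e
    n, m = geno.dosages.shape
    if target_var == 0.0:
        return np.zeros(n), {}

    if p.qtl_effects is not None:
        qtl = dict(p.qtl_effects)
    else:
        idx = rng.choice(m, size=min(p.n_qtl, m), replace=False)
        qtl = {int(j): float(rng.normal(0, 1)) for j in idx}
    g_qtl = np.zeros(n)
    for j, b in qtl.items():
        g_qtl += b * geno.dosages[:, j]

    poly_idx = np.setdiff1d(np.arange(m), np.fromiter(qtl, dtype=int))
    b_poly = rng.normal(0, 1.0 / max(1, np.sqrt(len(poly_idx))), size=len(poly_idx))
    g_poly = geno.dosages[:, poly_idx] @ b_poly

    v_qtl, v_poly = np.var(g_qtl), np.var(g_poly)
    w_qtl = np.sqrt(p.qtl_var_frac * target_var / v_qtl) if v_qtl > 0 else 0.0
    frac_poly = 1.0 - (p.qtl_var_frac if v_qtl > 0 else 0.0)
    w_poly = np.sqrt(frac_poly * target_var / v_poly) if v_poly > 0 else 0.0
    g = w_qtl * g_qtl + w_poly * g_poly
    g = g - g.mean()
    # renormalise the combined value to hit the target variance exactly
    sd = g.std()
    if sd > 0:
        g *= np.sqrt(target_var) / sd
        w_qtl *= np.sqrt(target_var) / sd
    qtl_scaled = {j: w_qtl * b for j, b in qtl.items()}
    return g, qtl_scaled


def _cmd_scores(
    geno: GenotypeMatrix, confound_qtl: int | None, r: float, n_plots: int,
    clone_idx: np.ndarray, rng: np.random.Generator,
) -> np.ndarray:
    """Severity scores 1-5 from a latent Gaussian tied to the confound QTL."""
    if not -1.0 < r < 1.0:
        raise ValueError("cmd_confound_r must be in (-1, 1)")
    if confound_qtl is not None and r != 0.0:
        dose = geno.dosages[clone_idx, confound_qtl]
        sd = dose.std()
        z = (dose - dose.mean()) / sd if sd > 0 else np.zeros(n_plots)
    else:
        z = np.zeros(n_plots)
        r = 0.0
    latent = r * z + np.sqrt(1.0 - r**2) * rng.standard_normal(n_plots)
    cuts = norm.ppf([0.2, 0.4, 0.6, 0.8])
    return (np.digitize(latent, cuts) + 1).astype(int)


def simulate_trial(
    genotypes: GenotypeMatrix,
    params: TrialParams | list[TrialParams],
    design_spec: DesignSpec | None = None,
    seed: int = 0,
) -> SimulatedTrial:
    """Simulate plot phenotypes over an augmented clonal-trial layout.

    Each plot phenotype decomposes exactly as::

        y = mu + g_clone + range_effect + beta_nohav*NOHAV + beta_cmd*CMD + resid

    and every term is returned, so recovery tests can compare REML estimates
    with the generating values.
    """
    if isinstance(params, TrialParams):
        params = [params]
    design_spec = design_spec or DesignSpec()
    for p in params:
        if not 0.0 <= p.h2_plot < 1.0:
            raise ValueError(f"target h2_plot must be in [0, 1): got {p.h2_plot}")
    rng = np.random.default_rng(seed)

    n = genotypes.n_clones
    # entry plots: each clone plots_per_clone times, spread over locations
    reps = design_spec.plots_per_clone
    base = np.repeat(np.arange(n), reps)
    rng.shuffle(base)
    locs = list(design_spec.locations)
    per_loc = np.array_split(base, len(locs))
    checks = np.arange(min(design_spec.n_checks, n))
    clone_idx_list: list[int] = []
    loc_list: list[str] = []
    range_list: list[str] = []
    check_cursor = 0
    for loc, entries in zip(locs, per_loc):
        n_ranges = max(1, int(np.ceil(len(entries) / design_spec.plots_per_range)))
        for k in range(n_ranges):
            chunk = entries[
                k * design_spec.plots_per_range : (k + 1) * design_spec.plots_per_range
            ]
            members = list(chunk)
            # augmented design: every range carries replicated check plots
            for _ in range(design_spec.checks_per_range if len(checks) else 0):
                members.append(int(checks[check_cursor % len(checks)]))
                check_cursor += 1
            for ci in members:
                clone_idx_list.append(int(ci))
                loc_list.append(loc)
                range_list.append(f"{loc}:r{k + 1}")
    clone_idx = np.array(clone_idx_list)
    n_plots = len(clone_idx)

    design = pd.DataFrame(
        {
            "plot_id": [f"plot{i:05d}" for i in range(n_plots)],
            "clone_id": genotypes.clone_ids[clone_idx],
            "location": loc_list,
            "range": range_list,
        }
    )
    design["NOHAV"] = rng.choice(design_spec.nohav_choices, size=n_plots)

    uniq_ranges = pd.unique(design["range"])
    # range effects shared across traits up to each trait's scale
    range_z = pd.Series(rng.standard_normal(len(uniq_ranges)), index=uniq_ranges)

    pheno = design.copy()
    true_g: dict[str, pd.Series] = {}
    qtl_all: dict[str, dict[int, float]] = {}
    resid = pd.DataFrame(index=design.index)
    comps = design[["plot_id", "clone_id"]].copy()

    # one CMD score per plot, driven by the first trait with a confound
    confound = next((p for p in params if p.confound_qtl is not None), None)
    design["CMD"] = _cmd_scores(
        genotypes,
        confound.confound_qtl if confound else None,
        confound.cmd_confound_r if confound else 0.0,
        n_plots,
        clone_idx,
        rng,
    )
    pheno["CMD"] = design["CMD"]

    for p in params:
        g, qtl = _scaled_genetic_values(genotypes, p, rng)
        true_g[p.trait] = pd.Series(g, index=genotypes.clone_ids)
        qtl_all[p.trait] = qtl
        r_eff = range_z * np.sqrt(p.sigma2_range)
        eps = rng.normal(0, np.sqrt(p.sigma2_e), size=n_plots)
        y = (
            p.mu
            + g[clone_idx]
            + r_eff[design["range"]].to_numpy()
            + p.beta_nohav * design["NOHAV"].to_numpy()
            + p.beta_cmd * design["CMD"].to_numpy()
            + eps
        )
        pheno[p.trait] = y
        resid[p.trait] = eps
        comps[f"{p.trait}_genetic"] = g[clone_idx]
        comps[f"{p.trait}_range"] = r_eff[design["range"]].to_numpy()
        comps[f"{p.trait}_nohav"] = p.beta_nohav * design["NOHAV"].to_numpy()
        comps[f"{p.trait}_cmd"] = p.beta_cmd * design["CMD"].to_numpy()

    range_effects = pd.concat(
        {p.trait: range_z * np.sqrt(p.sigma2_range) for p in params}
    ) if params else pd.Series(dtype=float)

    return SimulatedTrial(
        genotypes=genotypes,
        design=design,
        phenotypes=pheno,
        true_genetic_values=true_g,
        qtl_effects=qtl_all,
        range_effects=range_effects,
        residuals=resid,
        params=params,
        components=comps,
        seed=seed,
    )
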