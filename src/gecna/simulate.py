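"""Synthetic tumor cohort generator with a planted truth set.

Emulates the statistical structure the GE-CNA screen assumes: per-patient
latent CNA burden composed of independent amplification and deletion
counts (negative-binomial components whose sum has the configured total
mean and dispersion), realized as a gene x patient GISTIC-style call
matrix; per-gene expression z-scores, optionally coupled to burden for
planted facilitator/suppressor genes; gene-level missingness including
genes missing in more than a third of patients; clinical covariates with
sub-staged tumor stage strings; Cox-structured overall survival with
independent exponential censoring; and per-gene mutation flags plus
high-level CNA calls feeding altered/unaltered status.

A planted gene's coupling strength ``delta`` is expressed in units of the
burden SD: it is the expected burden separation between the gene's top-k
and bottom-k expression groups (k as configured, 10 by default), realized
by correlating the gene's expression with standardized burden.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .burden import burden_table
from .io import (
    Cohort,
    align_cohort,
    read_clinical,
    read_matrix,
    read_mutations,
    write_clinical,
    write_matrix,
    write_mutations,
    CnaCallMatrix,
    ExpressionMatrix,
)

_STAGES = np.array([1, 2, 3, 4])
_STAGE_PROBS = np.array([0.18, 0.38, 0.28, 0.16])
_STAGE_ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV"}
_RACES = np.array(["White", "Black or African American", "Asian", "Other"])
_RACE_PROBS = np.array([0.74, 0.13, 0.09, 0.04])


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class PlantedGene:
    """A gene whose expression is coupled to CNA burden.

    delta > 0 plants a facilitator (high expression, high burden), delta < 0
    a suppressor; mode selects which burden component the gene couples to.
    """

    delta: float
    mode: str = "total"
    name: str | None = None


@dataclass
class SimulationConfig:
    n_patients: int = 600
    n_genes: int = 2000
    # latent total burden: negative binomial with mean mu_burden and
    # dispersion theta_burden; amp and del are independent NB components
    # of that total, p_amp setting the expected amplification fraction
    mu_burden: float = 400.0
    theta_burden: float = 6.0
    p_amp: float = 0.5
    frac_high_level: float = 0.1  # fraction of nonzero calls that are +/-2
    facilitators: list[PlantedGene] = field(default_factory=list)
    suppressors: list[PlantedGene] = field(default_factory=list)
    missing_gene_fraction: float = 0.0  # genes missing in >1/3 of patients
    extreme_k: int = 10  # group size the delta coupling is calibrated for
    # survival model
    baseline_hazard: float = 0.01  # events per month at the reference profile
    beta_age: float = 0.03  # log-hazard per year of age
    beta_stage: float = 0.35  # log-hazard per stage step
    gene_betas: dict[str, float] = field(default_factory=dict)
    censoring_fraction: float = 0.3
    stage_missing_frac: float = 0.0
    mutation_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_genes <= 0:
            raise ConfigError("n_patients and n_genes must be positive")
        if not 0 <= self.p_amp <= 1:
            raise ConfigError("p_amp must lie in [0, 1]")
        if not 0 <= self.censoring_fraction < 1:
            raise ConfigError("censoring_fraction must lie in [0, 1)")
        planted = self.facilitators + self.suppressors
        if len(planted) > self.n_genes:
            raise ConfigError("more planted genes than n_genes")
        for pg in planted:
            if not np.isfinite(pg.delta):
                raise ConfigError("coupling strengths must be finite")
            if pg.mode not in ("total", "amp", "del"):
                raise ConfigError(f"unknown planted mode {pg.mode!r}")
        for f in self.facilitators:
            if f.delta <= 0:
                raise ConfigError("facilitator delta must be positive")
        for s in self.suppressors:
            if s.delta >= 0:
                raise ConfigError("suppressor delta must be negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("facilitators", "suppressors"):
            d[key] = [
                pg if isinstance(pg, PlantedGene) else PlantedGene(**pg)
                for pg in d.get(key, [])
            ]
        return cls(**d)


@dataclass
class TruthSet:
    """Ground truth for a generated cohort: per-gene labels and couplings,
    per-gene survival coefficients, per-patient latent burdens."""

    genes: pd.DataFrame  # index gene; columns label, mode, delta, beta
    burdens: pd.DataFrame  # index patient; columns total, amp, del

    @property
    def planted(self) -> pd.DataFrame:
        return self.genes[self.genes["label"] != "null"]


def expected_tail_mean(k: int, n: int) -> float:
    """Expected mean of a standard-normal upper k/n tail (the extreme-group
    shift a unit-correlation coupling would produce)."""
    frac = k / n
    z = stats.norm.ppf(1 - frac)
    return float(stats.norm.pdf(z) / frac)


def coupling_alpha(delta: float, k: int, n: int) -> float:
    """Correlation between expression and standardized burden that yields an
    expected top-vs-bottom group burden separation of |delta| burden SDs."""
    alpha = abs(delta) / (2.0 * expected_tail_mean(k, n))
    return float(np.copysign(min(alpha, 0.995), delta))


def _solve_censoring_rate(event_rates: np.ndarray, target: float) -> float:
    """Rate of an independent exponential censor achieving an expected
    censoring fraction ``target`` against per-patient event rates."""
    if target <= 0:
        return 0.0

    def frac(c: float) -> float:
        return float(np.mean(c / (c + event_rates)))

    lo, hi = 1e-12, float(event_rates.max())
    while frac(hi) < target:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: SimulationConfig) -> tuple[Cohort, TruthSet]:
    """Generate a cohort and its truth set. Deterministic given config.seed."""
    n, g = config.n_patients, config.n_genes
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_burden, rng_expr, rng_clin, rng_surv, rng_mut, rng_miss = (
        np.random.default_rng(s) for s in streams
    )

    patients = pd.Index([f"P{i:05d}" for i in range(n)], name="patient_id")
    gene_names = [f"G{i:05d}" for i in range(g)]

    # --- latent burden: independent amp and del components --------------
    # Each component is negative binomial with the same success probability
    # and size theta * p_amp (resp. theta * (1 - p_amp)), so their sum is
    # exactly NB(mu_burden, theta_burden) while amp and del stay
    # independent (a gene coupled to one CNA type must not light up the
    # other type's screen through burden correlation alone).
    p_nb = config.theta_burden / (config.theta_burden + config.mu_burden)
    amp = (
        rng_burden.negative_binomial(config.theta_burden * config.p_amp, p_nb, size=n)
        if config.p_amp > 0
        else np.zeros(n, dtype=np.int64)
    )
    dele = (
        rng_burden.negative_binomial(
            config.theta_burden * (1 - config.p_amp), p_nb, size=n
        )
        if config.p_amp < 1
        else np.zeros(n, dtype=np.int64)
    )
    total = amp + dele
    # a patient cannot alter more genes than exist
    overflow = np.maximum(total - g, 0)
    if overflow.any():
        import logging

        logging.getLogger(__name__).warning(
            "burden clipped to n_genes for %d patients; increase n_genes or "
            "lower mu_burden to avoid distorting the burden distribution",
            int((overflow > 0).sum()),
        )
    take_del = np.minimum(dele, overflow)
    dele = dele - take_del
    amp = amp - (overflow - take_del)
    total = amp + dele

    # --- realize the call matrix ---------------------------------------
    calls = np.zeros((g, n), dtype=np.int8)
    for j in range(n):
        pos = rng_burden.choice(g, size=total[j], replace=False)
        high = rng_burden.random(total[j]) < config.frac_high_level
        mag = np.where(high, 2, 1).astype(np.int8)
        calls[pos[: amp[j]], j] = mag[: amp[j]]
        calls[pos[amp[j]:], j] = -mag[amp[j]:]

    # --- planted genes --------------------------------------------------
    planted = list(config.facilitators) + list(config.suppressors)
    planted_idx = rng_expr.choice(g, size=len(planted), replace=False)
    for pg, idx in zip(planted, planted_idx):
        if pg.name is not None:
            gene_names[idx] = pg.name

    mode_counts = {"total": total, "amp": amp, "del": dele}

    def standardized(x: np.ndarray) -> np.ndarray:
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)

    # --- expression -----------------------------------------------------
    expr = rng_expr.standard_normal((g, n))
    for pg, idx in zip(planted, planted_idx):
        alpha = coupling_alpha(pg.delta, config.extreme_k, n)
        z = standardized(mode_counts[pg.mode].astype(float))
        expr[idx] = alpha * z + np.sqrt(1 - alpha**2) * rng_expr.standard_normal(n)
    # per-gene z-scores, as distributed by expression portals
    expr = (expr - expr.mean(axis=1, keepdims=True)) / expr.std(axis=1, keepdims=True)

    # --- missingness (planted genes stay complete) ----------------------
    n_bad = int(round(config.missing_gene_fraction * g))
    candidates = np.setdiff1d(np.arange(g), planted_idx)
    bad_idx = rng_miss.choice(candidates, size=min(n_bad, len(candidates)), replace=False)
    for idx in bad_idx:
        frac = rng_miss.uniform(0.4, 0.8)  # always beyond the 1/3 cutoff
        miss = rng_miss.choice(n, size=int(np.ceil(frac * n)), replace=False)
        expr[idx, miss] = np.nan

    expr_df = pd.DataFrame(expr, index=pd.Index(gene_names, name="gene"), columns=patients)
    cna_df = pd.DataFrame(calls, index=pd.Index(gene_names, name="gene"), columns=patients)

    # --- clinical -------------------------------------------------------
    age = np.clip(np.round(rng_clin.normal(66, 11, size=n)), 30, 90)
    sex = rng_clin.choice(["Male", "Female"], size=n)
    race = rng_clin.choice(_RACES, size=n, p=_RACE_PROBS)
    stage = rng_clin.choice(_STAGES, size=n, p=_STAGE_PROBS)
    sub = rng_clin.choice(["A", "B", "C", ""], size=n, p=[0.4, 0.4, 0.1, 0.1])
    stage_raw = np.array(
        [f"Stage {_STAGE_ROMAN[s]}{letter}" for s, letter in zip(stage, sub)],
        dtype=object,
    )
    if config.stage_missing_frac > 0:
        drop = rng_clin.random(n) < config.stage_missing_frac
        stage_raw[drop] = np.nan

    # --- survival -------------------------------------------------------
    lp = config.beta_age * (age - 66.0) + config.beta_stage * (stage - 2.0)
    for gene, beta in config.gene_betas.items():
        if gene not in expr_df.index:
            raise ConfigError(f"gene_betas references unknown gene {gene!r}")
        x = np.nan_to_num(expr_df.loc[gene].to_numpy())
        lp = lp + beta * x
    rates = config.baseline_hazard * np.exp(lp)
    event_time = rng_surv.exponential(1.0 / rates)
    c_rate = _solve_censoring_rate(rates, config.censoring_fraction)
    if c_rate > 0:
        censor_time = rng_surv.exponential(1.0 / c_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    clinical = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "race": race,
            "stage_raw": stage_raw,
            "os_time": os_time,
            "os_event": os_event,
        },
        index=patients,
    )

    # --- mutations ------------------------------------------------------
    mut = rng_mut.random((g, n)) < config.mutation_rate
    mut_df = pd.DataFrame(mut, index=pd.Index(gene_names, name="gene"), columns=patients)

    cohort = align_cohort(
        ExpressionMatrix(expr_df), CnaCallMatrix(cna_df), clinical, mut_df
    )

    truth_genes = pd.DataFrame(
        {"label": "null", "mode": "", "delta": 0.0, "beta": 0.0},
        index=pd.Index(gene_names, name="gene"),
    )
    for pg, idx in zip(planted, planted_idx):
        name = gene_names[idx]
        truth_genes.loc[name, ["label", "mode", "delta"]] = (
            "facilitator" if pg.delta > 0 else "suppressor",
            pg.mode,
            pg.delta,
        )
    for gene, beta in config.gene_betas.items():
        truth_genes.loc[gene, "beta"] = beta
    truth_burdens = pd.DataFrame(
        {"total": total, "amp": amp, "del": dele}, index=patients
    )
    return cohort, TruthSet(genes=truth_genes, burdens=truth_burdens)


def simulate_binary_survival(
    n: int,
    hr: float,
    censoring_fraction: float = 0.3,
    baseline_hazard: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-arm exponential survival with a known hazard ratio.

    Returns a DataFrame (group in {0,1}, time, event) where group 1 carries
    hazard ``hr`` times the baseline; censoring is independent exponential
    calibrated to the requested fraction. Used for Cox parameter-recovery
    checks.
    """
    rng = np.random.default_rng(seed)
    group = rng.integers(0, 2, size=n)
    rates = baseline_hazard * hr**group
    event_time = rng.exponential(1.0 / rates)
    c_rate = _solve_censoring_rate(rates, censoring_fraction)
    censor_time = (
        rng.exponential(1.0 / c_rate, size=n) if c_rate > 0 else np.full(n, np.inf)
    )
    return pd.DataFrame(
        {
            "group": group,
            "time": np.minimum(event_time, censor_time),
            "event": (event_time <= censor_time).astype(int),
        }
    )


# --- on-disk round trip ---------------------------------------------------

def write_cohort(cohort: Cohort, truth: TruthSet | None, directory) -> dict[str, Path]:
    """Write a cohort (and optional truth set) in the cohort_io dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "data_expression.txt",
        "cna": directory / "data_cna.txt",
        "clinical": directory / "data_clinical.txt",
        "mutations": directory / "data_mutations.txt",
    }
    write_matrix(cohort.expression, paths["expression"])
    write_matrix(cohort.cna, paths["cna"])
    if cohort.clinical is not None:
        write_clinical(cohort.clinical, paths["clinical"])
    else:
        paths.pop("clinical")
    if cohort.mutations is not None:
        write_mutations(cohort.mutations, paths["mutations"])
    else:
        paths.pop("mutations")
    if truth is not None:
        paths["truth_genes"] = directory / "truth_genes.tsv"
        paths["truth_burdens"] = directory / "truth_burdens.tsv"
        truth.genes.to_csv(paths["truth_genes"], sep="\t")
        truth.burdens.to_csv(paths["truth_burdens"], sep="\t")
    return paths


def read_cohort(directory) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    expr = read_matrix(directory / "data_expression.txt", "expression")
    cna = read_matrix(directory / "data_cna.txt", "cna")
    clin_path = directory / "data_clinical.txt"
    mut_path = directory / "data_mutations.txt"
    clinical = read_clinical(clin_path) if clin_path.exists() else None
    mutations = read_mutations(mut_path) if mut_path.exists() else None
    if mutations is not None:
        # the long TSV stores only positive flags; restore the full
        # gene x patient grid of the cohort
        mutations = mutations.reindex(
            index=cna.genes, columns=cna.patients, fill_value=False
        )
    return align_cohort(expr, cna, clinical, mutations)


def read_truth(directory) -> TruthSet:
    directory = Path(directory)
    genes = pd.read_csv(
        directory / "truth_genes.tsv", sep="\t", index_col=0, keep_default_na=False,
        na_values=[],
    )
    genes["delta"] = genes["delta"].astype(float)
    genes["beta"] = genes["beta"].astype(float)
    burdens = pd.read_csv(directory / "truth_burdens.tsv", sep="\t", index_col=0)
    return TruthSet(genes=genes, burdens=burdens)


def verify_burden_conservation(cohort: Cohort, truth: TruthSet, m: int = 1) -> bool:
    """Check amp + del == total for every patient and that realized nonzero
    call counts match the truth set's latent burdens (at m=1)."""
    table = burden_table(cohort.cna, m=m)
    ok = (table["amp"] + table["del"] == table["total"]).all()
    if m == 1:
        aligned = truth.burdens.loc[table.index]
        ok &= (table["total"] == aligned["total"]).all()
        ok &= (table["amp"] == aligned["amp"]).all()
        ok &= (table["del"] == aligned["del"]).all()
    return bool(ok)
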