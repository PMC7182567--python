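"""Seeded synthetic cohorts with the structure the pipeline assumes.

Generates complete cohorts — panel counts, qPCR Cts, lesion and mutation
flags, and competing-risks outcomes — with a planted Ph-like subgroup, so
every pipeline stage can be exercised and calibrated without patient data.

The expression model is negative-binomial counts with log-normally
distributed library sizes (median 150,000 reads/sample, the panel's design
depth).  Each gene has a baseline relative abundance; in the planted
subgroup the up-markers (ECM1, ENAM, IGJ, CRLF2) are shifted by +2 log2
fold-changes and MDFIC by -2, while housekeeping genes have fold-change 1
and low dispersion.  Two amplicons (SCHIP1, IFITM1) are given near-zero
abundance so that gene-level QC has something real to remove.  Outcomes
are latent cause-specific exponential times for relapse and
death-without-relapse with independent exponential censoring; the planted
group gets an elevated relapse hazard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import DEFAULT_PANEL, ExpressionMatrix, PanelDefinition

__all__ = ["SimulationConfig", "SyntheticCohort", "simulate_expression", "simulate_outcomes", "simulate_cohort", "end_to_end_fixture"]

#: genes deliberately simulated at near-zero depth (unmeasurable amplicons)
LOW_READ_GENES = ("SCHIP1", "IFITM1")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions: 80 patients, 25% planted Ph-like
    prevalence, |log2 FC| = 2 marker effects, ~150,000 reads/sample.
    Hazard rates are per year; the planted group's relapse hazard is its
    hazard ratio times the baseline.
    """

    n_samples: int = 80
    prevalence: float = 0.25
    log2_fc_up: float = 2.0
    log2_fc_down: float = -2.0
    dispersion: float = 20.0  # NB size parameter for informative genes
    housekeeping_dispersion: float = 500.0  # near-Poisson control genes
    library_size_median: float = 150_000.0
    library_size_sigma: float = 0.35  # sd of log library size
    relapse_hazard: float = 0.15  # baseline, per year
    relapse_hazard_ratio: float = 3.0  # planted vs baseline
    death_hazard: float = 0.05
    censoring_hazard: float = 0.15
    max_follow_up_years: float = 10.0
    # qPCR dCt (CRLF2 - GAPDH): planted group centered below the positivity
    # threshold equivalent log2(1000) ~ 9.97 cycles, rest above it
    dct_mean_phlike: float = 7.0
    dct_mean_other: float = 12.0
    dct_sd: float = 1.5
    gapdh_ct_mean: float = 20.0
    gapdh_ct_sd: float = 1.0
    # per-group feature prevalences (planted, other)
    mutation_prevalence: dict = field(
        default_factory=lambda: {"JAK2": (0.64, 0.11), "KRAS": (0.3, 0.2), "PAX5": (0.25, 0.15)}
    )
    ikzf1_del_prevalence: tuple[float, float] = (0.5, 0.2)
    cdkn2ab_del_prevalence: tuple[float, float] = (0.45, 0.3)
    mrd_positive_prevalence: tuple[float, float] = (0.73, 0.33)

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence < 1.0:
            raise ValueError("prevalence must be in [0, 1)")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        for name in ("dispersion", "housekeeping_dispersion", "library_size_median",
                     "relapse_hazard", "death_hazard"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SyntheticCohort:
    counts: ExpressionMatrix
    true_labels: dict[str, bool]  # sample -> planted Ph-like
    clinical: pd.DataFrame
    mutations: pd.DataFrame
    panel: PanelDefinition
    seed: int


def _baseline_profile(panel: PanelDefinition) -> np.ndarray:
    """Per-gene baseline relative abundances (fixed, not cohort-random).

    A log-spaced ladder deterministically permuted across informative
    genes, high stable levels for housekeeping genes, and near-zero levels
    for the unmeasurable amplicons.
    """
    genes = list(panel.panel_genes)
    informative = [g for g in genes if g not in panel.housekeeping_candidates]
    ladder = np.logspace(0.5, 3.0, len(informative))
    perm = np.random.default_rng(20200413).permutation(len(informative))
    levels = dict(zip(informative, ladder[perm]))
    for g in LOW_READ_GENES:
        if g in levels:
            levels[g] = 0.02
    for g in panel.housekeeping_candidates:
        levels[g] = 400.0
    p = np.array([levels[g] for g in genes])
    return p / p.sum()


def simulate_expression(
    cfg: SimulationConfig, seed: int, panel: PanelDefinition = DEFAULT_PANEL
) -> tuple[ExpressionMatrix, dict[str, bool]]:
    """Negative-binomial panel counts with a planted marker signature."""
    rng = np.random.default_rng(seed)
    n = cfg.n_samples
    sample_ids = [f"P{i + 1:03d}" for i in range(n)]
    n_planted = int(round(cfg.prevalence * n))
    planted = np.zeros(n, dtype=bool)
    planted[rng.choice(n, size=n_planted, replace=False)] = True

    base = _baseline_profile(panel)
    lib = np.exp(rng.normal(np.log(cfg.library_size_median), cfg.library_size_sigma, size=n))
    genes = list(panel.panel_genes)
    fc = np.ones((len(genes), n))
    for gi, g in enumerate(genes):
        if g in panel.markers_up:
            fc[gi, planted] = 2.0**cfg.log2_fc_up
        elif g in panel.markers_down:
            fc[gi, planted] = 2.0**cfg.log2_fc_down
    # reads are allocated to amplicons proportionally within each sample's
    # library: fold-changes reshape the composition, not the total depth
    comp = base[:, None] * fc
    comp = comp / comp.sum(axis=0, keepdims=True)
    mean = comp * lib[None, :]
    counts = np.empty_like(mean, dtype=np.int64)
    for gi, g in enumerate(genes):
        r = cfg.housekeeping_dispersion if g in panel.housekeeping_candidates else cfg.dispersion
        mu = mean[gi]
        if np.isinf(r):
            counts[gi] = rng.poisson(mu)
        else:
            counts[gi] = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    labels = dict(zip(sample_ids, planted.tolist()))
    return ExpressionMatrix(values=df, stage="counts"), labels


def simulate_outcomes(labels: dict[str, bool], cfg: SimulationConfig, seed: int) -> pd.DataFrame:
    """Latent cause-specific exponential times under independent censoring.

    Returns a table with columns patient_id, time_years, cause
    (0 censored / 1 relapse / 2 death-without-relapse) and group.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pid, is_planted in labels.items():
        lam1 = cfg.relapse_hazard * (cfg.relapse_hazard_ratio if is_planted else 1.0)
        t1 = rng.exponential(1.0 / lam1)
        t2 = rng.exponential(1.0 / cfg.death_hazard)
        tc = (
            rng.exponential(1.0 / cfg.censoring_hazard)
            if cfg.censoring_hazard > 0
            else np.inf
        )
        tc = min(tc, cfg.max_follow_up_years)
        t = min(t1, t2, tc)
        cause = 0 if t == tc else (1 if t1 <= t2 else 2)
        rows.append(
            {
                "patient_id": pid,
                "time_years": float(t),
                "cause": cause,
                "group": "planted" if is_planted else "other",
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(
    cfg: SimulationConfig, seed: int, panel: PanelDefinition = DEFAULT_PANEL
) -> SyntheticCohort:
    """A complete cohort: counts, clinical/qPCR/lesion table, mutations."""
    counts, labels = simulate_expression(cfg, seed, panel)
    outcomes = simulate_outcomes(labels, cfg, np.random.default_rng([seed, 1]).integers(2**31))
    rng = np.random.default_rng([seed, 2])
    planted = np.array([labels[p] for p in counts.sample_ids])

    def per_group(prev: tuple[float, float]) -> np.ndarray:
        p = np.where(planted, prev[0], prev[1])
        return rng.random(len(p)) < p

    gapdh = rng.normal(cfg.gapdh_ct_mean, cfg.gapdh_ct_sd, size=len(planted))
    dct = rng.normal(
        np.where(planted, cfg.dct_mean_phlike, cfg.dct_mean_other), cfg.dct_sd
    )
    ikzf1 = per_group(cfg.ikzf1_del_prevalence)
    cdkn = per_group(cfg.cdkn2ab_del_prevalence)
    mrd = per_group(cfg.mrd_positive_prevalence)

    out_idx = outcomes.set_index("patient_id")
    clin = pd.DataFrame(
        {
            "patient_id": counts.sample_ids,
            "age": rng.integers(16, 60, size=len(planted)),
            "sex": rng.choice(["F", "M"], size=len(planted)),
            "wbc_e9_l": np.round(np.exp(rng.normal(np.log(8), 1.0, size=len(planted))
                                        + 0.6 * planted), 2),
            "pb_blasts_pct": np.round(np.clip(rng.normal(40 + 25 * planted, 20), 0, 100), 1),
            "bm_blasts_pct": np.round(np.clip(rng.normal(75, 15, size=len(planted)), 5, 100), 1),
            "mrd_induction": np.where(mrd, "positive", "negative"),
            "mrd_consolidation": np.where(mrd & (rng.random(len(planted)) < 0.6),
                                          "positive", "negative"),
            "os_time_years": out_idx.loc[counts.sample_ids, "time_years"].to_numpy(),
            "os_event": (out_idx.loc[counts.sample_ids, "cause"] == 2).astype(int).to_numpy(),
            "dfs_time_years": out_idx.loc[counts.sample_ids, "time_years"].to_numpy(),
            "dfs_event": (out_idx.loc[counts.sample_ids, "cause"] != 0).astype(int).to_numpy(),
            "cir_time_years": out_idx.loc[counts.sample_ids, "time_years"].to_numpy(),
            "cir_cause": out_idx.loc[counts.sample_ids, "cause"].to_numpy(),
            "crlf2_ct": np.round(gapdh + dct, 3),
            "gapdh_ct": np.round(gapdh, 3),
            "ikzf1_del": ikzf1.astype(int),
            "cdkn2ab_del": cdkn.astype(int),
        }
    )
    mut_rows = []
    for gene, prev in cfg.mutation_prevalence.items():
        flags = per_group(prev)
        for pid, fl in zip(counts.sample_ids, flags):
            mut_rows.append({"patient_id": pid, "gene": gene, "flag": int(fl), "annotation": ""})
    mutations = pd.DataFrame(mut_rows)
    return SyntheticCohort(
        counts=counts, true_labels=labels, clinical=clin, mutations=mutations,
        panel=panel, seed=seed,
    )


def end_to_end_fixture(cfg: SimulationConfig, outdir: str | Path, seed: int) -> SyntheticCohort:
    """Write a cohort to disk in the canonical TSV/JSON formats.

    Produces ``counts.tsv``, ``panel.json``, ``clinical.tsv``,
    ``mutations.tsv`` and ``manifest.json`` (seed, config and truth
    labels); the files are accepted unchanged by the pipeline readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(cfg, seed)
    cohort.counts.to_tsv(outdir / "counts.tsv")
    cohort.panel.to_json(outdir / "panel.json")
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    cohort.mutations.to_csv(outdir / "mutations.tsv", sep="\t", index=False)
    manifest = {
        "seed": seed,
        "config": _config_dict(cfg),
        "true_labels": cohort.true_labels,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return cohort


def _config_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["ikzf1_del_prevalence"] = list(cfg.ikzf1_del_prevalence)
    d["cdkn2ab_del_prevalence"] = list(cfg.cdkn2ab_del_prevalence)
    d["mrd_positive_prevalence"] = list(cfg.mrd_positive_prevalence)
    d["mutation_prevalence"] = {k: list(v) for k, v in cfg.mutation_prevalence.items()}
    return d
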