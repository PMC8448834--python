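"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators emulate the assay's study designs with planted ground
truth, so every downstream caller can be scored for recovery:

* ``simulate_bulk`` — a NanoString-style count matrix with mock and
  injured replicate arms; injury shifts poor-prognosis genes up and
  good-prognosis genes down on the log2 scale while housekeeping genes
  stay untouched.
* ``simulate_screen`` — an injured control arm plus per-compound arms, a
  subset of which are planted signature reversers.
* ``simulate_cells`` — a single-cell count matrix with a viral-load
  covariate coupled to the signature genes, plus planted QC failures
  (low-total, high-mito, poorly aligned cells; artifact-correlated
  transcripts).
* ``simulate_perturbation_reference`` — a LINCS-like collection of
  per-compound z-score profiles with landmark/inferred probe classes and
  one planted reverser.

All generators are pure functions of their configuration (including the
seed) and return a truth record sufficient to compute sensitivity and
specificity without re-reading the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import PerturbationProfile, ProbeEntry
from .signature import ExpressionMatrix, GeneSet, PrognosticSignature, build_signature
from .single_cell import CellStats

__all__ = [
    "SimulationConfig",
    "ScreenConfig",
    "CellConfig",
    "ProfileConfig",
    "simulate_bulk",
    "simulate_screen",
    "simulate_cells",
    "simulate_perturbation_reference",
    "default_signature",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Compound-screen design: 25 arms with 11 planted reversers."""

    n_compounds: int = 25
    n_reversers: int = 11
    reversal_strength: float = 1.5
    reverser_ids: tuple[str, ...] | None = None


@dataclass(frozen=True)
class CellConfig:
    """Single-cell design: 40 analysed cells (23 infected / 17 not).

    ``coupling_beta`` is the log2 expression change per unit viral load
    applied to poor-prognosis genes (+) and good-prognosis genes (−); at
    the defaults it is sized so the correlation between mean poor-gene
    expression and viral load is ~0.5 by design (see the methods note).
    ``cell_effect_sd`` adds a shared per-cell technical effect so that
    set-mean noise does not average away, as in real data.
    """

    n_cells: int = 40
    infected_fraction: float = 23 / 40
    viral_load_mu: float = 2.0
    viral_load_sd: float = 1.0
    coupling_beta: float = 0.14
    cell_effect_sd: float = 0.3
    n_mito_genes: int = 10
    n_artifact_genes: int = 3
    artifact_gene: str = "KCNQ1OT1"
    plant_qc_failures: bool = True


@dataclass(frozen=True)
class ProfileConfig:
    """Perturbation-reference design: one planted reverser among nulls."""

    n_perturbagens: int = 20
    reverser_strength: float = 4.0
    landmark_fraction: float = 0.5
    multi_probe_fraction: float = 0.2


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped defaults: 186 signature genes, 6 housekeepers, 3 reps."""

    seed: int = 0
    n_background: int = 500
    n_poor: int = 93
    n_good: int = 93
    n_housekeeping: int = 6
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0
    sigma_noise: float = 0.5
    delta_poor: float = 1.5
    delta_good: float = 1.5
    n_replicates: int = 3
    count_model: str = "lognormal_rounded"  # or "negative_binomial"
    nb_dispersion: float = 0.1
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    cells: CellConfig = field(default_factory=CellConfig)
    profiles: ProfileConfig = field(default_factory=ProfileConfig)

    def __post_init__(self) -> None:
        if min(self.n_background, self.n_poor, self.n_good, self.n_housekeeping) <= 0:
            raise ValueError("gene-group sizes must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.count_model not in ("lognormal_rounded", "negative_binomial"):
            raise ValueError(f"unknown count model {self.count_model!r}")
        if not 0 < self.cells.infected_fraction <= 1:
            raise ValueError("infected_fraction must lie in (0, 1]")
        if self.screen.n_reversers > self.screen.n_compounds:
            raise ValueError("more reversers than compounds")


def _gene_names(cfg: SimulationConfig) -> dict[str, list[str]]:
    return {
        "poor": [f"POOR{i:03d}" for i in range(1, cfg.n_poor + 1)],
        "good": [f"GOOD{i:03d}" for i in range(1, cfg.n_good + 1)],
        "hk": [f"HK{i}" for i in range(1, cfg.n_housekeeping + 1)],
        "background": [f"BG{i:04d}" for i in range(1, cfg.n_background + 1)],
    }


def default_signature(cfg: SimulationConfig = SimulationConfig()) -> PrognosticSignature:
    """The signature matching the simulated gene namespace."""
    names = _gene_names(cfg)
    version = "full-186" if cfg.n_poor + cfg.n_good == 186 else "custom"
    return build_signature(
        GeneSet("PLS_poor", tuple(names["poor"]), "poor-prognosis genes"),
        GeneSet("PLS_good", tuple(names["good"]), "good-prognosis genes"),
        GeneSet("PLS_housekeeping", tuple(names["hk"]), "housekeeping panel"),
        version=version,
    )


def _emit_counts(log2_expr: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.count_model == "lognormal_rounded":
        return np.maximum(np.round(2.0**log2_expr), 0.0)
    mean = 2.0**log2_expr
    r = 1.0 / cfg.nb_dispersion
    return rng.negative_binomial(r, r / (r + mean)).astype(float)


def _baselines(cfg: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)


def simulate_bulk(cfg: SimulationConfig = SimulationConfig()) -> tuple[ExpressionMatrix, dict]:
    """Mock + injured replicate arms with the planted injury effect."""
    rng = np.random.default_rng(cfg.seed)
    names = _gene_names(cfg)
    genes = names["poor"] + names["good"] + names["hk"] + names["background"]
    base = _baselines(cfg, rng, len(genes))
    effect = np.zeros(len(genes))
    effect[: cfg.n_poor] = cfg.delta_poor
    effect[cfg.n_poor : cfg.n_poor + cfg.n_good] = -cfg.delta_good

    cols, data, cond = [], [], []
    for arm, shift in (("mock", 0.0), ("injured", 1.0)):
        for r in range(1, cfg.n_replicates + 1):
            noise = rng.normal(0, cfg.sigma_noise, size=len(genes))
            log2v = base + shift * effect + noise
            data.append(_emit_counts(log2v, cfg, rng))
            cols.append(f"{arm}_{r}")
            cond.append(arm)
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    meta = pd.DataFrame({"condition": cond}, index=cols)
    truth = {
        "poor_genes": names["poor"],
        "good_genes": names["good"],
        "housekeeping_genes": names["hk"],
        "delta_poor": cfg.delta_poor,
        "delta_good": cfg.delta_good,
        "sigma_noise": cfg.sigma_noise,
    }
    return ExpressionMatrix(values=values, scale="counts", sample_meta=meta), truth


def simulate_screen(
    cfg: SimulationConfig = SimulationConfig(),
) -> tuple[ExpressionMatrix, dict[str, ExpressionMatrix], dict]:
    """Injured control plus compound arms, some planted as reversers.

    Reverser arms shift poor genes by −reversal_strength and good genes
    by +reversal_strength relative to the injured control; the other arms
    redraw replicate noise around the injured baseline.
    """
    rng = np.random.default_rng(cfg.seed)
    names = _gene_names(cfg)
    genes = names["poor"] + names["good"] + names["hk"] + names["background"]
    base = _baselines(cfg, rng, len(genes))
    injury = np.zeros(len(genes))
    injury[: cfg.n_poor] = cfg.delta_poor
    injury[cfg.n_poor : cfg.n_poor + cfg.n_good] = -cfg.delta_good
    reversal = np.zeros(len(genes))
    reversal[: cfg.n_poor] = -cfg.screen.reversal_strength
    reversal[cfg.n_poor : cfg.n_poor + cfg.n_good] = cfg.screen.reversal_strength

    compound_ids = [f"cmpd{i:02d}" for i in range(1, cfg.screen.n_compounds + 1)]
    if cfg.screen.reverser_ids is not None:
        reversers = list(cfg.screen.reverser_ids)
        unknown = set(reversers) - set(compound_ids)
        if unknown:
            raise ValueError(f"unknown reverser ids: {sorted(unknown)}")
    else:
        reversers = list(rng.choice(compound_ids, size=cfg.screen.n_reversers, replace=False))

    def make_arm(arm_name: str, shift: np.ndarray) -> ExpressionMatrix:
        cols, data = [], []
        for r in range(1, cfg.n_replicates + 1):
            noise = rng.normal(0, cfg.sigma_noise, size=len(genes))
            data.append(_emit_counts(base + shift + noise, cfg, rng))
            cols.append(f"{arm_name}_{r}")
        values = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
        meta = pd.DataFrame({"condition": [arm_name] * len(cols)}, index=cols)
        return ExpressionMatrix(values=values, scale="counts", sample_meta=meta)

    control = make_arm("CTRL", injury)
    arms = {
        cid: make_arm(cid, injury + (reversal if cid in reversers else 0.0))
        for cid in compound_ids
    }
    truth = {
        "reversers": sorted(reversers),
        "non_reversers": sorted(set(compound_ids) - set(reversers)),
        "reversal_strength": cfg.screen.reversal_strength,
    }
    return control, arms, truth


def simulate_cells(
    cfg: SimulationConfig = SimulationConfig(),
) -> tuple[ExpressionMatrix, list[CellStats], dict]:
    """Single-cell counts with viral-load coupling and planted QC failures.

    Infected cells draw a positive viral load; poor-prognosis genes gain
    ``coupling_beta`` log2 units per load unit and good-prognosis genes
    lose the same.  A shared per-cell effect (``cell_effect_sd``) models
    technical cell-to-cell scale variation.  When ``plant_qc_failures``
    is set, four extra cells (low alignment rate, few aligned pairs,
    high mitochondrial fraction, low total) and ``n_artifact_genes``
    transcripts tracking the artifact gene are appended and recorded in
    the truth.
    """
    rng = np.random.default_rng(cfg.seed)
    cc = cfg.cells
    names = _gene_names(cfg)
    mito = [f"MT-{i}" for i in range(1, cc.n_mito_genes + 1)]
    artifacts = [f"ARTIF{i}" for i in range(1, cc.n_artifact_genes + 1)]
    genes = (
        names["poor"] + names["good"] + names["hk"] + names["background"]
        + mito + [cc.artifact_gene] + artifacts
    )
    n_genes = len(genes)
    gi = {g: i for i, g in enumerate(genes)}
    base = _baselines(cfg, rng, n_genes)

    n_inf = int(round(cc.n_cells * cc.infected_fraction))
    cell_ids = [f"cell{i:03d}" for i in range(1, cc.n_cells + 1)]
    infected = np.zeros(cc.n_cells, dtype=bool)
    infected[:n_inf] = True
    loads = np.zeros(cc.n_cells)
    loads[infected] = np.maximum(
        rng.normal(cc.viral_load_mu, cc.viral_load_sd, size=n_inf), 0.1
    )

    coupling = np.zeros(n_genes)
    coupling[: cfg.n_poor] = cc.coupling_beta
    coupling[cfg.n_poor : cfg.n_poor + cfg.n_good] = -cc.coupling_beta

    cell_effects = rng.normal(0, cc.cell_effect_sd, size=cc.n_cells)
    # artifact transcripts: technical, no cell effect, correlated with each other
    art_signal = rng.normal(0, 1.0, size=cc.n_cells)

    log2v = (
        base[:, None]
        + coupling[:, None] * loads[None, :]
        + cell_effects[None, :]
        + rng.normal(0, cfg.sigma_noise, size=(n_genes, cc.n_cells))
    )
    for g in [cc.artifact_gene] + artifacts:
        i = gi[g]
        log2v[i] = base[i] + art_signal + rng.normal(0, 0.2, size=cc.n_cells)

    counts = _emit_counts(log2v, cfg, rng)

    stats = [
        CellStats(
            cell_id=cid,
            align_rate=float(np.clip(rng.normal(0.8, 0.05), 0.55, 0.99)),
            aligned_pairs=int(rng.integers(200_000, 2_000_000)),
            viral_load=float(loads[i]),
        )
        for i, cid in enumerate(cell_ids)
    ]

    truth = {
        "poor_genes": names["poor"],
        "good_genes": names["good"],
        "infected_cells": [c for c, f in zip(cell_ids, infected) if f],
        "viral_loads": dict(zip(cell_ids, map(float, loads))),
        "coupling_beta": cc.coupling_beta,
        "artifact_genes": artifacts,
        "artifact_reference": cc.artifact_gene,
        "mito_genes": mito,
        "qc_fail_alignment": [],
        "qc_fail_pairs": [],
        "qc_fail_mito": [],
        "qc_fail_total": [],
    }

    if cc.plant_qc_failures:
        extra_cols = []
        for tag, kind in (
            ("fail_align", "alignment"),
            ("fail_pairs", "pairs"),
            ("fail_mito", "mito"),
            ("fail_total", "total"),
        ):
            col = _emit_counts(
                base + rng.normal(0, cfg.sigma_noise, size=n_genes), cfg, rng
            )
            align_rate, pairs = 0.8, 500_000
            if kind == "alignment":
                align_rate = 0.40
                truth["qc_fail_alignment"].append(tag)
            elif kind == "pairs":
                pairs = 50_000
                truth["qc_fail_pairs"].append(tag)
            elif kind == "mito":
                mito_idx = [gi[g] for g in mito]
                col[mito_idx] = 10 * col.sum()  # mito dominate: fraction >> 0.8
                truth["qc_fail_mito"].append(tag)
            elif kind == "total":
                col = np.floor(col * (1000.0 / max(col.sum(), 1.0)))
                truth["qc_fail_total"].append(tag)
            extra_cols.append(col)
            stats.append(
                CellStats(
                    cell_id=tag,
                    align_rate=align_rate,
                    aligned_pairs=pairs,
                    viral_load=0.0,
                )
            )
        counts = np.column_stack([counts] + extra_cols)
        cell_ids = cell_ids + ["fail_align", "fail_pairs", "fail_mito", "fail_total"]

    values = pd.DataFrame(counts, index=genes, columns=cell_ids)
    meta = pd.DataFrame(
        {
            "condition": [
                "infected" if (i < cc.n_cells and infected[i]) else "uninfected"
                for i in range(len(cell_ids))
            ],
            "viral_load": [s.viral_load for s in stats],
        },
        index=cell_ids,
    )
    return ExpressionMatrix(values=values, scale="counts", sample_meta=meta), stats, truth


def simulate_perturbation_reference(
    cfg: SimulationConfig = SimulationConfig(),
) -> tuple[list[PerturbationProfile], dict]:
    """A LINCS-like profile collection with one planted signature reverser.

    The reverser's z-scores oppose the injury signature (poor genes
    strongly negative, good genes strongly positive); the other profiles
    are standard-normal noise.  A fraction of genes carry two probes with
    mixed landmark/inferred classes so the collapse rules are exercised.
    """
    rng = np.random.default_rng(cfg.seed)
    pc = cfg.profiles
    if pc.n_perturbagens < 2:
        raise ValueError("need at least 2 perturbagens")
    names = _gene_names(cfg)
    genes = names["poor"] + names["good"] + names["background"]
    pert_ids = [f"pert{i:02d}" for i in range(1, pc.n_perturbagens + 1)]
    reverser = str(rng.choice(pert_ids))

    profiles = []
    for pid in pert_ids:
        z = rng.normal(0, 1, size=len(genes))
        if pid == reverser:
            z[: cfg.n_poor] = rng.normal(-pc.reverser_strength, 1, size=cfg.n_poor)
            z[cfg.n_poor : cfg.n_poor + cfg.n_good] = rng.normal(
                pc.reverser_strength, 1, size=cfg.n_good
            )
        entries = []
        for i, g in enumerate(genes):
            n_probes = 2 if rng.random() < pc.multi_probe_fraction else 1
            for k in range(n_probes):
                cls = "landmark" if rng.random() < pc.landmark_fraction else "inferred"
                zz = z[i] if k == 0 else z[i] + rng.normal(0, 0.5)
                entries.append(
                    ProbeEntry(probe=f"{g}_p{k}", gene=g, z=float(zz), probe_class=cls)
                )
        profiles.append(PerturbationProfile(perturbagen=pid, entries=tuple(entries)))
    truth = {
        "reverser": reverser,
        "poor_genes": names["poor"],
        "good_genes": names["good"],
    }
    return profiles, truth
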