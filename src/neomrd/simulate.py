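"""Synthetic cohort generation for the MRD / immune-profiling pipeline.

Everything downstream of sequencing is driven by four kinds of input, all of
which can be generated here with the statistical structure the analysis
assumes:

* tracked-variant panels with per-site background error rates (log-normal)
  and ultra-deep consensus depths (negative binomial around a mean);
* plasma samples whose alt molecule counts are Poisson with rate
  ``d_i * (e_i + c_i * f)`` for a true ctDNA fraction ``f``;
* 10x-style TCR contig tables with power-law clone-size distributions;
* bulk expression matrices with an embedded marker-gene signature effect
  linked to exponential survival times.

Determinism contract: all randomness flows from integer seeds through
``numpy.random.default_rng``; per-patient streams are derived by hashing
``(seed, patient_id)`` with CRC-32 so that adding a patient never perturbs
the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mrd import MrdSample, SiteObservation, TrackedPanel, TrackedVariant

__all__ = [
    "DepthModel",
    "ErrorModel",
    "FractionModel",
    "CloneSizeModel",
    "ExpressionModel",
    "SurvivalModel",
    "SimulationConfig",
    "SimulatedPanel",
    "LongitudinalCohort",
    "SimulatedRepertoire",
    "ExpressionCohort",
    "patient_rng",
    "gen_tracked_panel",
    "simulate_mrd_sample",
    "simulate_longitudinal_cohort",
    "simulate_clonotype_table",
    "simulate_expression_cohort",
]

TIMEPOINTS = (
    "baseline",
    "after-cycle-1",
    "after-cycle-2",
    "after-cycle-3",
    "pre-surgery",
    "post-surgery",
)

_CHROMS = [str(i) for i in range(1, 23)] + ["X"]
_BASES = "ACGT"


@dataclass(frozen=True)
class DepthModel:
    """Consensus (post-UMI) molecule depth per tracked site.

    Negative binomial with mean ``mean`` and dispersion ``size`` (larger =
    closer to Poisson).  Depths are modeled directly at the molecule level;
    raw-read/UMI collapse is out of scope since the caller consumes
    consensus molecule counts.
    """

    mean: float = 5000.0
    size: float = 20.0


@dataclass(frozen=True)
class ErrorModel:
    """Per-site background error rate e_i, log-normal.

    Defaults give a median of 1e-4 with a log-sd of 1.0, spanning roughly
    1e-6 to 1e-3 across sites (duplex-to-UMI error regimes).
    """

    log_mean: float = float(np.log(1e-4))
    log_sd: float = 1.0


@dataclass(frozen=True)
class FractionModel:
    """True ctDNA fraction trajectories by response group.

    ``baseline_log_mean``/``baseline_log_sd`` set the log-normal baseline
    fraction; the two multiplier tuples scale it at each named timepoint.
    Responders clear ctDNA entirely by pre-surgery (multiplier 0);
    nonresponders also drop substantially but less deeply.
    """

    baseline_log_mean: float = float(np.log(1e-3))
    baseline_log_sd: float = 0.5
    timepoints: tuple[str, ...] = TIMEPOINTS
    responder_multipliers: tuple[float, ...] = (1.0, 0.1, 0.01, 1e-3, 0.0, 0.0)
    nonresponder_multipliers: tuple[float, ...] = (1.0, 0.5, 0.2, 0.1, 0.05, 0.01)

    def __post_init__(self) -> None:
        if len(self.responder_multipliers) != len(self.timepoints) or len(
            self.nonresponder_multipliers
        ) != len(self.timepoints):
            raise ValueError("one multiplier per timepoint required")


@dataclass(frozen=True)
class CloneSizeModel:
    """Power-law clone sizes for the TCR repertoire simulator.

    Clone sizes are drawn from a zeta (discrete power-law) distribution with
    exponent ``exponent``; ``exponent=None`` is the all-singletons limit.
    ``subtype_cells`` maps cell-subtype annotation to its number of cells.
    ``dominant_clone_size`` optionally forces one clone of that many cells in
    the first subtype.
    """

    exponent: float | None = 2.5
    subtype_cells: dict[str, int] = field(
        default_factory=lambda: {
            "CD8T_Tex_CXCL13": 400,
            "CD4T_Treg_CCR8": 250,
            "CD4T_Treg_FOXP3": 250,
            "CD8T_Teff_FGFBP2": 400,
            "CD8T_Trm_ZNF683": 300,
        }
    )
    max_clone_size: int = 200
    dominant_clone_size: int | None = None


@dataclass(frozen=True)
class ExpressionModel:
    """Bulk expression cohort with an embedded signature effect.

    ``effect_size`` is the mean shift (in log-expression sd units) added to
    signature genes in signature-high samples; ``noise_sd`` the residual sd.
    """

    n_genes: int = 2000
    n_samples: int = 200
    effect_size: float = 2.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect size must be nonnegative")


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential survival with a hazard ratio for the signature-high group.

    ``baseline_hazard`` is events per unit time in the low stratum;
    ``hazard_ratio`` multiplies the hazard in the high stratum;
    ``censoring_rate`` is the hazard of independent exponential censoring.
    """

    baseline_hazard: float = 0.1
    hazard_ratio: float = 2.5
    censoring_rate: float = 0.02


@dataclass(frozen=True)
class SimulationConfig:
    """Root configuration: one seed, all sub-models."""

    seed: int = 0
    n_patients: int = 20
    n_sites_per_panel: int = 50
    allele_factor: float = 0.5
    response_mix: float = 0.5
    depth_model: DepthModel = field(default_factory=DepthModel)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    fraction_model: FractionModel = field(default_factory=FractionModel)
    clone_size_model: CloneSizeModel = field(default_factory=CloneSizeModel)
    expression_model: ExpressionModel = field(default_factory=ExpressionModel)
    survival_model: SurvivalModel = field(default_factory=SurvivalModel)

    def __post_init__(self) -> None:
        if self.n_sites_per_panel < 1:
            raise ValueError(
                f"n_sites_per_panel must be >= 1, got {self.n_sites_per_panel}"
            )
        if not (0.0 <= self.response_mix <= 1.0):
            raise ValueError("response_mix must be in [0, 1]")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def patient_rng(seed: int, patient_id: str, stream: str = "") -> np.random.Generator:
    """Child RNG for one patient, stable under cohort-composition changes."""
    key = zlib.crc32(f"{patient_id}|{stream}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


# ---------------------------------------------------------------------------
# Tracked panels and MRD samples
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedPanel:
    """A tracked panel together with its nominal consensus depths."""

    panel: TrackedPanel
    depths: np.ndarray

    def __len__(self) -> int:
        return len(self.panel)


def _nb_depths(rng: np.random.Generator, model: DepthModel, n: int) -> np.ndarray:
    # negative binomial parameterized by size (r) and mean: p = r / (r + mu)
    p = model.size / (model.size + model.mean)
    d = rng.negative_binomial(model.size, p, size=n)
    return np.maximum(d, 1)


def gen_tracked_panel(config: SimulationConfig, patient_id: str) -> SimulatedPanel:
    """Generate one patient's tracked panel (sites, error rates, depths)."""
    n = config.n_sites_per_panel
    rng = patient_rng(config.seed, patient_id, "panel")
    chroms = rng.choice(_CHROMS, size=n)
    pos = rng.integers(1, 250_000_000, size=n)
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    vafs = np.clip(rng.beta(2.0, 6.0, size=n), 0.03, 1.0)
    errors = np.exp(rng.normal(config.error_model.log_mean,
                               config.error_model.log_sd, size=n))
    errors = np.clip(errors, 1e-12, 0.999)
    depths = _nb_depths(rng, config.depth_model, n)
    variants = tuple(
        TrackedVariant(
            site_id=f"{patient_id}_s{i:03d}",
            chrom=str(chroms[i]),
            pos=int(pos[i]),
            ref=_BASES[ref_idx[i]],
            alt=_BASES[(ref_idx[i] + alt_shift[i]) % 4],
            tumor_vaf=float(vafs[i]),
            error_rate=float(errors[i]),
            allele_factor=config.allele_factor,
        )
        for i in range(n)
    )
    return SimulatedPanel(
        panel=TrackedPanel(patient_id=patient_id, variants=variants),
        depths=depths,
    )


def simulate_mrd_sample(
    panel: TrackedPanel | SimulatedPanel,
    true_fraction: float,
    seed: int | np.random.Generator = 0,
    depths=None,
    timepoint: str = "sample",
) -> MrdSample:
    """Draw one plasma sample: k_i ~ Poisson(d_i (e_i + c_i f))."""
    if not (0.0 <= true_fraction <= 1.0):
        raise ValueError(f"true_fraction must be in [0, 1], got {true_fraction}")
    if isinstance(panel, SimulatedPanel):
        if depths is None:
            depths = panel.depths
        panel = panel.panel
    if depths is None:
        raise ValueError("depths required when panel carries none")
    d = np.broadcast_to(np.asarray(depths, dtype=float), (len(panel),))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = d * (panel.error_rates() + panel.allele_factors() * true_fraction)
    k = rng.poisson(lam)
    k = np.minimum(k, d.astype(int))  # alt molecules cannot exceed depth
    obs = tuple(
        SiteObservation(site_id=s, depth=int(di), alt_count=int(ki))
        for s, di, ki in zip(panel.site_ids, d, k)
    )
    return MrdSample(patient_id=panel.patient_id, timepoint=timepoint,
                     observations=obs)


@dataclass(frozen=True)
class LongitudinalCohort:
    """Simulated longitudinal samples plus the ground truth behind them."""

    panels: dict[str, SimulatedPanel]
    samples: dict[str, dict[str, MrdSample]]  # patient -> timepoint -> sample
    truth: pd.DataFrame  # patient_id, responder, timepoint, true_fraction


def simulate_longitudinal_cohort(
    config: SimulationConfig, timepoints: tuple[str, ...] | None = None
) -> LongitudinalCohort:
    """Simulate a cohort of longitudinal MRD samples with known truth.

    Response labels are assigned deterministically (the first
    ``round(response_mix * n)`` patients respond) so a fixed seed fixes
    group sizes exactly; per-patient baseline fractions and counts come from
    the patient's own child RNG stream.
    """
    fm = config.fraction_model
    if timepoints is None:
        timepoints = fm.timepoints
    unknown = [t for t in timepoints if t not in fm.timepoints]
    if unknown:
        raise ValueError(f"unknown timepoints {unknown}; known: {list(fm.timepoints)}")
    n_resp = int(round(config.response_mix * config.n_patients))
    panels: dict[str, SimulatedPanel] = {}
    samples: dict[str, dict[str, MrdSample]] = {}
    truth_rows = []
    for idx in range(config.n_patients):
        pid = f"P{idx + 1:03d}"
        responder = idx < n_resp
        sp = gen_tracked_panel(config, pid)
        panels[pid] = sp
        rng = patient_rng(config.seed, pid, "longitudinal")
        baseline_f = float(
            np.exp(rng.normal(fm.baseline_log_mean, fm.baseline_log_sd))
        )
        baseline_f = min(baseline_f, 1.0)
        mult = dict(zip(
            fm.timepoints,
            fm.responder_multipliers if responder else fm.nonresponder_multipliers,
        ))
        samples[pid] = {}
        for tp in timepoints:
            f = min(baseline_f * mult[tp], 1.0)
            samples[pid][tp] = simulate_mrd_sample(sp, f, seed=rng, timepoint=tp)
            truth_rows.append(
                {"patient_id": pid, "responder": responder,
                 "timepoint": tp, "true_fraction": f}
            )
    return LongitudinalCohort(
        panels=panels, samples=samples, truth=pd.DataFrame(truth_rows)
    )


# ---------------------------------------------------------------------------
# TCR repertoire
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedRepertoire:
    """10x-style contig rows, barcode annotations, and true clone sizes."""

    contigs: pd.DataFrame
    annotations: pd.DataFrame  # barcode, subtype
    truth: pd.DataFrame  # clonotype_id, subtype, n_cells


def _draw_clone_sizes(
    rng: np.random.Generator, n_cells: int, model: CloneSizeModel
) -> list[int]:
    if model.exponent is None:
        return [1] * n_cells
    sizes: list[int] = []
    remaining = n_cells
    while remaining > 0:
        s = int(rng.zipf(model.exponent))
        s = min(s, model.max_clone_size, remaining)
        sizes.append(s)
        remaining -= s
    return sizes


def _random_cdr3(rng: np.random.Generator, length: int = 39) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def simulate_clonotype_table(config: SimulationConfig) -> SimulatedRepertoire:
    """Simulate paired alpha/beta contigs with power-law clone sizes.

    Each clonotype gets a distinct alpha and beta (V gene, J gene, CDR3nt)
    pair; each member cell contributes one productive, high-confidence,
    full-length contig row per chain.  Subtypes with zero configured cells
    yield an empty stratum, not an error.
    """
    model = config.clone_size_model
    rng = np.random.default_rng(np.random.SeedSequence([config.seed,
                                                        zlib.crc32(b"tcr")]))
    contig_rows = []
    ann_rows = []
    truth_rows = []
    clone_counter = 0
    barcode_counter = 0
    for subtype, n_cells in model.subtype_cells.items():
        if n_cells == 0:
            continue
        sizes = _draw_clone_sizes(rng, n_cells, model)
        if (
            model.dominant_clone_size is not None
            and subtype == next(iter(model.subtype_cells))
        ):
            forced = min(model.dominant_clone_size, n_cells)
            sizes = [forced] + _draw_clone_sizes(rng, n_cells - forced, model)
        for size in sizes:
            clone_counter += 1
            cid = f"clonotype{clone_counter}"
            alpha = (f"TRAV{rng.integers(1, 42)}", f"TRAJ{rng.integers(1, 62)}",
                     _random_cdr3(rng))
            beta = (f"TRBV{rng.integers(1, 31)}", f"TRBJ{rng.integers(1, 3)}-{rng.integers(1, 8)}",
                    _random_cdr3(rng))
            truth_rows.append({"clonotype_id": cid, "subtype": subtype,
                               "n_cells": size})
            for _ in range(size):
                barcode_counter += 1
                bc = f"BC{barcode_counter:06d}-1"
                ann_rows.append({"barcode": bc, "subtype": subtype})
                for chain, (v, j, cdr3) in (("TRA", alpha), ("TRB", beta)):
                    contig_rows.append({
                        "barcode": bc,
                        "is_cell": True,
                        "contig_id": f"{bc}_contig_{chain}",
                        "high_confidence": True,
                        "length": 500 + len(cdr3),
                        "chain": chain,
                        "v_gene": v,
                        "j_gene": j,
                        "cdr3": "C" + cdr3[:12] + "F",
                        "cdr3_nt": cdr3,
                        "reads": int(rng.integers(100, 5000)),
                        "umis": int(rng.integers(2, 50)),
                        "productive": True,
                        "full_length": True,
                    })
    return SimulatedRepertoire(
        contigs=pd.DataFrame(contig_rows),
        annotations=pd.DataFrame(ann_rows),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Expression cohort with survival
# ---------------------------------------------------------------------------

DEFAULT_SIGNATURES = {
    "CCR8_Treg": ("FOXP3", "IL2RA", "CCR8"),
    "CXCL13_Tex": ("HAVCR2", "PDCD1", "LAG3", "CXCL13",
                   "TIGIT", "CTLA4", "ENTPD1", "LAYN"),
}


@dataclass(frozen=True)
class ExpressionCohort:
    """Genes x samples matrix, survival table, and true stratum labels."""

    expression: pd.DataFrame  # genes x samples
    survival: pd.DataFrame  # id, time, event, group
    truth: pd.DataFrame  # sample_id, signature_high


def simulate_expression_cohort(
    config: SimulationConfig, signature_genes: tuple[str, ...] | None = None
) -> ExpressionCohort:
    """Simulate a bulk-RNA cohort with a marker-gene signature effect.

    Half the samples (alternating) are signature-high: their signature genes
    are shifted upward by ``effect_size`` noise-sd units in log expression.
    Survival is exponential with the configured hazard ratio for the high
    stratum and independent exponential censoring.
    """
    em = config.expression_model
    sm = config.survival_model
    if signature_genes is None:
        signature_genes = tuple(
            g for genes in DEFAULT_SIGNATURES.values() for g in genes
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed,
                                                        zlib.crc32(b"expression")]))
    n_bg = em.n_genes - len(signature_genes)
    if n_bg < 0:
        raise ValueError("n_genes smaller than the signature itself")
    genes = list(signature_genes) + [f"GENE{i:05d}" for i in range(n_bg)]
    sample_ids = [f"S{i + 1:04d}" for i in range(em.n_samples)]
    high = np.arange(em.n_samples) % 2 == 0  # alternating: balanced strata
    base = rng.normal(5.0, 1.0, size=(em.n_genes, 1))
    x = base + rng.normal(0.0, em.noise_sd, size=(em.n_genes, em.n_samples))
    x[: len(signature_genes), high] += em.effect_size * em.noise_sd
    expression = pd.DataFrame(x, index=genes, columns=sample_ids)

    hazard = sm.baseline_hazard * np.where(high, sm.hazard_ratio, 1.0)
    event_t = rng.exponential(1.0 / hazard)
    if sm.censoring_rate > 0:
        cens_t = rng.exponential(1.0 / sm.censoring_rate, size=em.n_samples)
    else:
        cens_t = np.full(em.n_samples, np.inf)
    time = np.minimum(event_t, cens_t)
    event = (event_t <= cens_t).astype(int)
    survival = pd.DataFrame({
        "id": sample_ids,
        "time": time,
        "event": event,
        "group": np.where(high, "high", "low"),
    })
    truth = pd.DataFrame({"sample_id": sample_ids, "signature_high": high})
    return ExpressionCohort(expression=expression, survival=survival, truth=truth)
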