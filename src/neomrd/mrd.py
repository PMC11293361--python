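"""Tumor-informed ctDNA minimal-residual-disease detection.

A patient-specific panel tracks up to 50 somatic variants (chosen from
tumor/normal exome calls by descending tumor VAF) in ultra-deep consensus
sequencing of plasma cell-free DNA.  At tracked site *i* with consensus
depth ``d_i``, per-molecule background error rate ``e_i`` and allele factor
``c_i`` (0.5 for a heterozygous diploid variant), the alt molecule count is
modeled as

    k_i ~ Poisson(d_i * (e_i + c_i * f))

where ``f`` is the ctDNA fraction.  Detection combines two tests:

* per-site upper-tail Poisson p-value under the background-only rate
  ``d_i * e_i`` (sites with p < 0.05 are "significant sites");
* a sample-level likelihood-ratio test of f > 0 against f = 0, with the
  one-sided boundary null (a 50:50 mixture of a point mass at 0 and
  chi-square with 1 df).

A sample is called MRD-positive iff it has two or more significant sites AND
a sample-level p-value below 0.005.  The limit of detection of a panel is
estimated by Monte Carlo: the smallest fraction on a log grid at which the
detection probability reaches a target (default 95%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, poisson

__all__ = [
    "TrackedVariant",
    "TrackedPanel",
    "SiteObservation",
    "MrdSample",
    "MrdCall",
    "LodEstimate",
    "filter_somatic_variants",
    "select_tracking_variants",
    "site_significance",
    "estimate_ctdna_fraction",
    "sample_level_test",
    "call_mrd",
    "estimate_lod",
    "summarize_longitudinal",
    "tmb",
]

SITE_ALPHA = 0.05          # per-site significance threshold
SAMPLE_ALPHA = 0.005       # sample-level p threshold
MIN_SIGNIFICANT_SITES = 2  # positivity requires at least this many sites
ERROR_FLOOR = 1e-9         # floor for e_i = 0 with observed alt molecules


@dataclass(frozen=True)
class TrackedVariant:
    """One tracked somatic variant with its background error profile."""

    site_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    tumor_vaf: float
    error_rate: float
    allele_factor: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.tumor_vaf <= 1.0):
            raise ValueError(f"tumor_vaf must be in [0,1], got {self.tumor_vaf}")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError(f"error_rate must be in [0,1), got {self.error_rate}")
        if self.allele_factor <= 0:
            raise ValueError(f"allele_factor must be > 0, got {self.allele_factor}")


@dataclass(frozen=True)
class TrackedPanel:
    """A patient's tracked-variant panel."""

    patient_id: str
    variants: tuple[TrackedVariant, ...]

    def __post_init__(self) -> None:
        ids = [v.site_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site_ids in panel")
        if len(self.variants) == 0:
            raise ValueError(
                f"empty panel for patient {self.patient_id}: no trackable variants"
            )

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def site_ids(self) -> list[str]:
        return [v.site_id for v in self.variants]

    def error_rates(self) -> np.ndarray:
        return np.array([v.error_rate for v in self.variants])

    def allele_factors(self) -> np.ndarray:
        return np.array([v.allele_factor for v in self.variants])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(v) for v in self.variants])


@dataclass(frozen=True)
class SiteObservation:
    """Consensus molecule counts at one tracked site."""

    site_id: str
    depth: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_count < 0:
            raise ValueError("depth and alt_count must be nonnegative")
        if self.alt_count > self.depth:
            raise ValueError(
                f"alt_count {self.alt_count} exceeds depth {self.depth} at {self.site_id}"
            )


@dataclass(frozen=True)
class MrdSample:
    """One plasma sample: per-site molecule counts aligned to a panel."""

    patient_id: str
    timepoint: str
    observations: tuple[SiteObservation, ...]

    def aligned_arrays(self, panel: TrackedPanel) -> tuple[np.ndarray, np.ndarray]:
        """Depths and alt counts in panel site order; validates alignment."""
        by_id = {o.site_id: o for o in self.observations}
        if len(by_id) != len(self.observations):
            raise ValueError("duplicate site_ids in sample")
        missing = [s for s in panel.site_ids if s not in by_id]
        extra = set(by_id) - set(panel.site_ids)
        if missing or extra:
            raise ValueError(
                f"sample/panel misalignment: missing={missing[:3]}, extra={sorted(extra)[:3]}"
            )
        d = np.array([by_id[s].depth for s in panel.site_ids], dtype=float)
        k = np.array([by_id[s].alt_count for s in panel.site_ids], dtype=float)
        return d, k


@dataclass(frozen=True)
class MrdCall:
    """Full result of the MRD positivity decision for one sample."""

    patient_id: str
    timepoint: str
    ctdna_fraction: float
    loglik_at_fhat: float
    loglik_at_zero: float
    lrt_statistic: float
    sample_p: float
    site_p: dict[str, float]
    n_significant_sites: int
    positive: bool
    mean_alt_molecules: float


@dataclass(frozen=True)
class LodEstimate:
    """Monte-Carlo limit-of-detection estimate for a panel."""

    lod: float | None  # None = detection never reached target ("above grid")
    detect_prob_target: float
    n_reps: int
    grid: np.ndarray = field(repr=False)
    detection_prob: np.ndarray = field(repr=False)

    @property
    def lod_percent(self) -> float | None:
        return None if self.lod is None else 100.0 * self.lod

    @property
    def above_grid(self) -> bool:
        return self.lod is None


# ---------------------------------------------------------------------------
# Variant selection
# ---------------------------------------------------------------------------

_FILTER_COLUMNS = ["supporting_reads", "vaf", "tumor_af", "normal_af", "popfreq_flag"]


def filter_somatic_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Somatic-variant filters applied to tumor/normal exome calls.

    Keeps variants with at least 5 supporting reads, VAF >= 3%, no elevated
    population frequency, and a tumor/normal allele-frequency pattern
    consistent with a somatic origin: excluded are variants with
    tumor_af/normal_af < 3 or with both tumor and normal AF above 10%.
    ``normal_af == 0`` counts as an infinite ratio (kept).
    """
    missing = [c for c in _FILTER_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    v = variants
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            v["normal_af"].to_numpy(dtype=float) == 0.0,
            np.inf,
            v["tumor_af"].to_numpy(dtype=float) / v["normal_af"].to_numpy(dtype=float),
        )
    germline_like = (ratio < 3.0) | (
        (v["tumor_af"].to_numpy(dtype=float) > 0.10)
        & (v["normal_af"].to_numpy(dtype=float) > 0.10)
    )
    keep = (
        (v["supporting_reads"] >= 5)
        & (v["vaf"] >= 0.03)
        & (~v["popfreq_flag"].astype(bool))
        & (~germline_like)
    )
    return v.loc[keep].copy()


def select_tracking_variants(
    filtered: pd.DataFrame,
    max_sites: int = 50,
    patient_id: str = "patient",
    error_rates=None,
    allele_factor: float = 0.5,
    min_vaf: float = 0.03,
) -> TrackedPanel:
    """Design a tracking panel: highest-VAF variants, VAF >= 3%, up to 50.

    Ties in VAF are broken by (chrom, pos) ascending.  Panels smaller than
    ``max_sites`` are allowed; zero eligible variants raises (the patient
    has no designable panel).  ``error_rates`` supplies per-site background
    error rates aligned to the selected rows (scalar or sequence); if omitted
    the frame must carry an ``error_rate`` column.
    """
    if "tumor_vaf" not in filtered.columns:
        if "vaf" in filtered.columns:
            filtered = filtered.rename(columns={"vaf": "tumor_vaf"})
        else:
            raise ValueError("missing required column: tumor_vaf")
    eligible = filtered[filtered["tumor_vaf"] >= min_vaf].copy()
    if len(eligible) == 0:
        raise ValueError(
            f"no variants with VAF >= {min_vaf}: panel undesignable for {patient_id}"
        )
    eligible = eligible.sort_values(
        by=["tumor_vaf", "chrom", "pos"], ascending=[False, True, True],
        kind="mergesort",
    ).head(max_sites)
    if error_rates is None:
        if "error_rate" not in eligible.columns:
            raise ValueError("supply error_rates or an error_rate column")
        rates = eligible["error_rate"].to_numpy(dtype=float)
    else:
        rates = np.broadcast_to(np.asarray(error_rates, dtype=float), (len(eligible),))
    variants = tuple(
        TrackedVariant(
            site_id=f"{row.chrom}:{row.pos}:{row.ref}>{row.alt}",
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            tumor_vaf=float(row.tumor_vaf),
            error_rate=float(e),
            allele_factor=allele_factor,
        )
        for row, e in zip(eligible.itertuples(index=False), rates)
    )
    return TrackedPanel(patient_id=patient_id, variants=variants)


# ---------------------------------------------------------------------------
# Detection model
# ---------------------------------------------------------------------------


def site_significance(obs: SiteObservation, variant: TrackedVariant) -> float:
    """Upper-tail Poisson p-value P(X >= k_i) under the background rate.

    X ~ Poisson(d_i * e_i).  k = 0 gives p = 1 (inclusive tail); a zero
    background rate with observed alt molecules gives p = 0.
    """
    rate = obs.depth * variant.error_rate
    k = obs.alt_count
    if k == 0:
        return 1.0
    if rate == 0.0:
        return 0.0
    return float(poisson.sf(k - 1, rate))


def _site_pvalues(d: np.ndarray, k: np.ndarray, e: np.ndarray) -> np.ndarray:
    rate = d * e
    p = np.ones_like(rate)
    pos = k > 0
    with np.errstate(divide="ignore"):
        p[pos] = poisson.sf(k[pos] - 1, rate[pos])
    p[pos & (rate == 0.0)] = 0.0
    return p


def _loglik(f, d, k, e, c):
    """Poisson log-likelihood in f, dropping the k-independent ln(k!) term."""
    lam = d * (e + c * f)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(k > 0, k * np.log(lam), 0.0)
    # lam == 0 with k > 0 would be -inf; callers floor e beforehand
    return float(np.sum(term - lam))


def _floored_errors(e: np.ndarray, k: np.ndarray) -> np.ndarray:
    bad = (e == 0.0) & (k > 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} sites have zero error rate but observed alt "
            f"molecules; flooring e_i at {ERROR_FLOOR}"
        )
        e = np.where(bad, ERROR_FLOOR, e)
    return e


def estimate_ctdna_fraction(
    sample: MrdSample, panel: TrackedPanel, tol: float = 1e-12
) -> tuple[float, float, float]:
    """Maximum-likelihood ctDNA fraction on [0, 1].

    Maximizes  l(f) = sum_i [k_i ln(d_i (e_i + c_i f)) - d_i (e_i + c_i f)],
    which is concave in f, via the root of the monotone score function with
    boundary checks at f = 0 and f = 1.  Returns (f_hat, l(f_hat), l(0)).
    """
    d, k = sample.aligned_arrays(panel)
    if np.all(d == 0):
        raise ValueError("all depths zero: sample is uninformative")
    e = _floored_errors(panel.error_rates(), k)
    c = panel.allele_factors()

    def score(f):
        lam_unit = e + c * f
        return float(np.sum(k * c / lam_unit) - np.sum(d * c))

    if score(0.0) <= 0.0:
        fhat = 0.0
    elif score(1.0) >= 0.0:
        fhat = 1.0
    else:
        fhat = float(optimize.brentq(score, 0.0, 1.0, xtol=tol))
    return fhat, _loglik(fhat, d, k, e, c), _loglik(0.0, d, k, e, c)


def sample_level_test(
    sample: MrdSample, panel: TrackedPanel, boundary_mixture: bool = True
) -> tuple[float, float]:
    """Likelihood-ratio test of ctDNA fraction > 0: returns (Lambda, p).

    Lambda = 2 (l(f_hat) - l(0)) >= 0.  Because f is constrained to [0, 1],
    the null distribution of Lambda is the 50:50 mixture of a point mass at
    0 and chi-square(1); ``boundary_mixture=False`` uses plain chi-square(1)
    instead.  f_hat = 0 gives p = 1.
    """
    fhat, ll_hat, ll_0 = estimate_ctdna_fraction(sample, panel)
    lam = max(0.0, 2.0 * (ll_hat - ll_0))
    if fhat == 0.0 or lam == 0.0:
        return 0.0, 1.0
    p = float(chi2.sf(lam, df=1))
    if boundary_mixture:
        p *= 0.5
    return lam, p


def call_mrd(
    sample: MrdSample,
    panel: TrackedPanel,
    site_alpha: float = SITE_ALPHA,
    sample_alpha: float = SAMPLE_ALPHA,
    min_significant_sites: int = MIN_SIGNIFICANT_SITES,
    boundary_mixture: bool = True,
) -> MrdCall:
    """MRD positivity call: >= 2 significant sites AND sample p < 0.005."""
    d, k = sample.aligned_arrays(panel)
    e = panel.error_rates()
    site_p = _site_pvalues(d, k, e)
    n_sig = int(np.sum(site_p < site_alpha))
    fhat, ll_hat, ll_0 = estimate_ctdna_fraction(sample, panel)
    lam = max(0.0, 2.0 * (ll_hat - ll_0))
    if fhat == 0.0 or lam == 0.0:
        lam, sample_p = 0.0, 1.0
    else:
        sample_p = float(chi2.sf(lam, df=1))
        if boundary_mixture:
            sample_p *= 0.5
    return MrdCall(
        patient_id=sample.patient_id,
        timepoint=sample.timepoint,
        ctdna_fraction=fhat,
        loglik_at_fhat=ll_hat,
        loglik_at_zero=ll_0,
        lrt_statistic=lam,
        sample_p=sample_p,
        site_p=dict(zip(panel.site_ids, site_p.tolist())),
        n_significant_sites=n_sig,
        positive=(n_sig >= min_significant_sites) and (sample_p < sample_alpha),
        mean_alt_molecules=float(np.mean(k)),
    )


# ---------------------------------------------------------------------------
# Limit of detection
# ---------------------------------------------------------------------------


def _detection_prob_vectorized(
    panel: TrackedPanel,
    depths: np.ndarray,
    fraction: float,
    n_reps: int,
    rng: np.random.Generator,
) -> float:
    """Fraction of simulated samples at ``fraction`` called MRD-positive.

    Vectorized over replicates: draws an (n_reps, n_sites) Poisson count
    matrix and applies the per-site and sample-level tests per row.
    """
    e = panel.error_rates()
    c = panel.allele_factors()
    d = depths
    lam = d * (e + c * fraction)
    k = rng.poisson(lam, size=(n_reps, len(d))).astype(float)

    bg = d * e
    site_p = np.ones_like(k)
    pos = k > 0
    site_p[pos] = poisson.sf((k - 1)[pos], np.broadcast_to(bg, k.shape)[pos])
    site_p[pos & (np.broadcast_to(bg, k.shape) == 0.0)] = 0.0
    n_sig = np.sum(site_p < SITE_ALPHA, axis=1)

    candidates = n_sig >= MIN_SIGNIFICANT_SITES
    detected = np.zeros(n_reps, dtype=bool)
    e_f = np.where(e == 0.0, ERROR_FLOOR, e)
    for i in np.nonzero(candidates)[0]:
        ki = k[i]

        def score(f):
            return float(np.sum(ki * c / (e_f + c * f)) - np.sum(d * c))

        if score(0.0) <= 0.0:
            continue
        fhat = 1.0 if score(1.0) >= 0.0 else float(
            optimize.brentq(score, 0.0, 1.0, xtol=1e-10)
        )
        lam0 = 2.0 * (_loglik(fhat, d, ki, e_f, c) - _loglik(0.0, d, ki, e_f, c))
        if lam0 <= 0.0:
            continue
        detected[i] = 0.5 * chi2.sf(lam0, df=1) < SAMPLE_ALPHA
    return float(np.mean(detected))


def estimate_lod(
    panel: TrackedPanel,
    depths,
    detect_prob: float = 0.95,
    n_reps: int = 200,
    seed: int = 0,
    grid=None,
) -> LodEstimate:
    """Monte-Carlo limit of detection of a panel at given consensus depths.

    Simulates samples across a log grid of candidate fractions (default 25
    points in [1e-7, 1e-3]) with a common seed across grid points (paired
    replicates reduce grid-to-grid MC noise) and reports the smallest grid
    fraction whose detection probability reaches ``detect_prob``.  Returns an
    "above grid" sentinel (lod=None) if the target is never reached — e.g.
    a one-site panel can never satisfy the two-significant-sites rule.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a stable LoD estimate")
    if grid is None:
        grid = np.logspace(-7, -3, 25)
    grid = np.asarray(grid, dtype=float)
    depths = np.broadcast_to(
        np.asarray(depths, dtype=float), (len(panel),)
    ).copy()
    probs = np.empty(len(grid))
    for gi, f in enumerate(grid):
        rng = np.random.default_rng(seed)  # paired seeds across grid points
        probs[gi] = _detection_prob_vectorized(panel, depths, f, n_reps, rng)
    hit = np.nonzero(probs >= detect_prob)[0]
    lod = float(grid[hit[0]]) if hit.size else None
    return LodEstimate(
        lod=lod,
        detect_prob_target=detect_prob,
        n_reps=n_reps,
        grid=grid,
        detection_prob=probs,
    )


# ---------------------------------------------------------------------------
# Longitudinal summaries
# ---------------------------------------------------------------------------


def summarize_longitudinal(
    calls: list[MrdCall],
    baseline: str = "baseline",
    presurgery: str = "pre-surgery",
    floor: float = 1e-7,
) -> pd.DataFrame:
    """Per-patient trajectory summary with baseline-to-presurgery fold change.

    ``fold_reduction = f(baseline) / max(f(presurgery), floor)``; the floor
    (default 1e-7, intended as panel LoD / 10) keeps fold changes finite when
    the pre-surgery fraction is estimated as exactly zero.  Patients lacking
    a baseline call are skipped with a warning.
    """
    rows = []
    by_patient: dict[str, dict[str, MrdCall]] = {}
    for c in calls:
        by_patient.setdefault(c.patient_id, {})[c.timepoint] = c
    for pid, tp_calls in by_patient.items():
        if baseline not in tp_calls:
            warnings.warn(f"patient {pid} lacks a {baseline!r} call; skipped")
            continue
        base = tp_calls[baseline]
        row = {
            "patient_id": pid,
            "baseline_fraction": base.ctdna_fraction,
            "mean_alt_molecules_baseline": base.mean_alt_molecules,
        }
        if presurgery in tp_calls:
            pre = tp_calls[presurgery]
            row["presurgery_fraction"] = pre.ctdna_fraction
            row["fold_reduction"] = base.ctdna_fraction / max(
                pre.ctdna_fraction, floor
            )
            row["presurgery_positive"] = pre.positive
        rows.append(row)
    return pd.DataFrame(rows)


def group_fold_reduction_ratio(
    summary: pd.DataFrame, groups: pd.Series | dict
) -> float:
    """Ratio of group median fold-reductions (responders over nonresponders).

    ``groups`` maps patient_id -> True for responders.
    """
    g = pd.Series(groups)
    s = summary.set_index("patient_id")["fold_reduction"]
    resp = s[g.reindex(s.index).astype(bool)]
    nonresp = s[~g.reindex(s.index).astype(bool)]
    if resp.empty or nonresp.empty:
        raise ValueError("both responder and nonresponder groups required")
    return float(resp.median() / nonresp.median())


def tmb(n_nonsynonymous: int, panel_size_mb: float) -> float:
    """Tumor mutational burden: nonsynonymous mutations per megabase."""
    if panel_size_mb <= 0:
        raise ValueError("panel size must be positive")
    if n_nonsynonymous < 0:
        raise ValueError("mutation count must be nonnegative")
    return n_nonsynonymous / panel_size_mb
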