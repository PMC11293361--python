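"""Plain-text readers/writers for panels, samples, repertoires and cohorts.

All formats are tab- or comma-separated text so that simulated cohorts can
be round-tripped and inspected.  A minimal VCF reader (CHROM, POS, REF, ALT
plus a VAF INFO tag) is provided for variant lists coming from standard
callers; it uses cyvcf2 when available.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mrd import MrdSample, SiteObservation, TrackedPanel, TrackedVariant
from .simulate import SimulatedPanel

__all__ = [
    "write_panel_tsv",
    "read_panel_tsv",
    "write_sample_tsv",
    "read_sample_tsv",
    "read_variants_vcf",
]

_PANEL_COLS = ["site_id", "chrom", "pos", "ref", "alt",
               "tumor_vaf", "error_rate", "allele_factor", "depth"]


def write_panel_tsv(panel: TrackedPanel | SimulatedPanel, path) -> None:
    """Write a tracked panel (with nominal depths if available) as TSV."""
    depths = None
    if isinstance(panel, SimulatedPanel):
        depths = panel.depths
        panel = panel.panel
    df = panel.to_frame()
    df["depth"] = depths if depths is not None else -1
    df[_PANEL_COLS].to_csv(path, sep="\t", index=False)


def read_panel_tsv(path, patient_id: str | None = None) -> SimulatedPanel:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    variants = tuple(
        TrackedVariant(
            site_id=str(r.site_id), chrom=str(r.chrom), pos=int(r.pos),
            ref=str(r.ref), alt=str(r.alt), tumor_vaf=float(r.tumor_vaf),
            error_rate=float(r.error_rate), allele_factor=float(r.allele_factor),
        )
        for r in df.itertuples(index=False)
    )
    pid = patient_id or Path(path).stem
    return SimulatedPanel(
        panel=TrackedPanel(patient_id=pid, variants=variants),
        depths=df["depth"].to_numpy(),
    )


def write_sample_tsv(sample: MrdSample, panel: TrackedPanel, path) -> None:
    """Write one plasma sample as TSV with full site context."""
    by_id = {v.site_id: v for v in panel.variants}
    rows = [
        {
            "site_id": o.site_id,
            "chrom": by_id[o.site_id].chrom,
            "pos": by_id[o.site_id].pos,
            "ref": by_id[o.site_id].ref,
            "alt": by_id[o.site_id].alt,
            "depth": o.depth,
            "alt_count": o.alt_count,
            "error_rate": by_id[o.site_id].error_rate,
        }
        for o in sample.observations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_tsv(path, patient_id: str, timepoint: str) -> MrdSample:
    df = pd.read_csv(path, sep="\t")
    obs = tuple(
        SiteObservation(site_id=str(r.site_id), depth=int(r.depth),
                        alt_count=int(r.alt_count))
        for r in df.itertuples(index=False)
    )
    return MrdSample(patient_id=patient_id, timepoint=timepoint, observations=obs)


def read_variants_vcf(path, vaf_tag: str = "VAF") -> pd.DataFrame:
    """Read a minimal VCF variant list into a frame with a tumor_vaf column."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires cyvcf2") from exc
    rows = []
    for rec in VCF(str(path)):
        vaf = rec.INFO.get(vaf_tag)
        for alt in rec.ALT:
            rows.append({
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": alt,
                "tumor_vaf": float(vaf) if vaf is not None else np.nan,
            })
    return pd.DataFrame(rows)
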