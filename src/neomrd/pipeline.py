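"""End-to-end synthetic MRD run: simulate, call, summarize, report.

The pipeline mirrors the longitudinal monitoring workflow: a cohort with
known response labels is simulated, every plasma sample is MRD-called,
per-patient trajectories are summarized, and diagnostic performance of the
pre-surgery call against response is computed.  All outputs are plain text
and byte-identical under a fixed seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import mrd
from .simulate import SimulationConfig, simulate_longitudinal_cohort
from .stats import diagnostic_performance

__all__ = ["run_longitudinal_pipeline"]


def run_longitudinal_pipeline(
    config: SimulationConfig, out_dir, presurgery: str = "pre-surgery"
) -> dict:
    """Simulate a longitudinal cohort, call MRD, and write a report.

    Writes ``calls.tsv`` (one row per sample), ``trajectories.tsv`` (one row
    per patient) and ``report.json`` (diagnostics of the pre-surgery call
    against non-response plus run metadata) under ``out_dir``.  Returns the
    report dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_longitudinal_cohort(config)

    calls: list[mrd.MrdCall] = []
    for pid, by_tp in sorted(cohort.samples.items()):
        panel = cohort.panels[pid].panel
        for tp, sample in by_tp.items():
            calls.append(mrd.call_mrd(sample, panel))

    calls_df = pd.DataFrame(
        {
            "patient_id": c.patient_id,
            "timepoint": c.timepoint,
            "ctdna_fraction": c.ctdna_fraction,
            "lrt_statistic": c.lrt_statistic,
            "sample_p": c.sample_p,
            "n_significant_sites": c.n_significant_sites,
            "positive": c.positive,
            "mean_alt_molecules": c.mean_alt_molecules,
        }
        for c in calls
    )
    calls_df.to_csv(out / "calls.tsv", sep="\t", index=False, float_format="%.10g")

    summary = mrd.summarize_longitudinal(calls, presurgery=presurgery)
    summary.to_csv(out / "trajectories.tsv", sep="\t", index=False,
                   float_format="%.10g")

    responder = (
        cohort.truth.drop_duplicates("patient_id")
        .set_index("patient_id")["responder"]
    )
    pre = calls_df[calls_df["timepoint"] == presurgery].set_index("patient_id")
    pre = pre.loc[responder.index]
    # condition-positive = non-response: ctDNA persistence predicts nMPR
    diag = diagnostic_performance(
        pre["positive"].to_numpy(), (~responder).to_numpy()
    )
    report = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "n_sites_per_panel": config.n_sites_per_panel,
        "n_calls": len(calls),
        "n_positive_presurgery": int(pre["positive"].sum()),
        "diagnostics_presurgery": {
            "tp": diag.tp, "fp": diag.fp, "fn": diag.fn, "tn": diag.tn,
            **diag.describe(),
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
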