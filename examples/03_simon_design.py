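"""Evaluate and re-derive the trial's Simon two-stage design.

With a null MPR rate of 10% and an alternative of 30%, the optimal design
at alpha 5% / power 90% enrolls 18 patients in stage 1 (continue only if
at least 3 respond) and declares the regimen active if more than 6 of 35
respond.  The script prints the exact operating characteristics and then
recovers the same design by exhaustive search.
"""

from neomrd import datasets
from neomrd.design import SimonDesign, search_optimal, summarize

design = SimonDesign(**datasets.simon_design_parameters())
s = summarize(design)
print(f"design: stage 1 {design.r1}/{design.n1}, final {design.r}/{design.n}")
print(f"  PET(p0={design.p0})        = {s['pet_p0']:.4f}  ({s['pet_p0'] * 100:.1f}%)")
print(f"  EN(p0)              = {s['en_p0']:.2f} patients")
print(f"  attained alpha      = {s['attained_alpha']:.4f}  (<= 0.05)")
print(f"  attained power      = {s['attained_power']:.4f}  (>= 0.90)")

found = search_optimal(0.10, 0.30, alpha_max=0.05, beta_max=0.10, n_max=40)
print(f"\noptimal search recovers: stage 1 {found.r1}/{found.n1}, "
      f"final {found.r}/{found.n}")
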