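"""Score one stained/isotype pair under the three gating schemes.

Simulates a tumour sample (true cancer-cell Ki67 fraction 20%), locates the
2n DNA peak, reports dissociation QC rates, and prints Ki67 positivity with
no population gate (dapi_only), with the cytokeratin gate (ck), and with the
biomarker-free AreaX ellipse (areax).
"""

from ki67flow import (
    DnaGate,
    dna_partition,
    find_2n_peak,
    ki67_positivity,
    qc_rates,
    simulate_pair,
)
from ki67flow.simulate import default_tumor_populations

pair, truth = simulate_pair(default_tumor_populations(true_li=0.20),
                            n_events=50_000, seed=1)

peak = find_2n_peak(pair.stained)
gate = DnaGate(peak)
rates = qc_rates(dna_partition(pair.stained, gate))
print(f"2n peak at {peak:.1f} a.u.; analysis window "
      f"[{gate.lower:.1f}, {gate.upper:.1f}]")
print(f"QC: recovery {rates.cell_recovery_rate:.1f}%  "
      f"debris {rates.debris_rate:.3f}  "
      f"single-cell {rates.single_cell_rate:.1f}%")

for scheme in ("dapi_only", "ck", "areax"):
    res = ki67_positivity(pair, scheme=scheme)
    stages = ", ".join(f"{k}={v}" for k, v in res.stage_counts.items())
    print(f"{scheme:10s} positivity {res.positivity:5.2f}%   ({stages})")

print("\nThe true fraction is 20%; the 95th-percentile cutoff adds ~5% of the")
print("negatives, so a pure cancer readout sits near 24%.  Without a")
print("population gate, Ki67-negative lymphocytes dilute the estimate.")
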