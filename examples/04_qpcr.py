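"""Standard-curve efficiency and Pfaffl relative expression from a Ct table.

Simulates a qRT-PCR validation: two target genes (4-fold induced and 4-fold
repressed) plus a TUB4 reference across four treatments at 0/1/3 h with
3 replicates and 0.2-cycle Ct noise, then recovers relative expression
against the 0-h control calibrator.
"""

from txfootprint import (
    SimulationConfig,
    StandardCurve,
    efficiency_from_slope,
    generate_ct_table,
    pfaffl_ratio,
    relative_expression_table,
)

# a slope of -3.32 cycles per 10-fold dilution means perfect doubling
for slope in (-3.3219, -3.6, -3.1):
    print(f"slope {slope:7.4f} -> efficiency {efficiency_from_slope(StandardCurve(slope)):6.1f}%")

print("\ncalibrator vs itself:", pfaffl_ratio(90.0, 100.0, 0.0, 0.0))

cfg = SimulationConfig(seed=1)
ct, truth = generate_ct_table(cfg)
res = relative_expression_table(
    ct, list(cfg.qpcr.target_genes), cfg.qpcr.reference_gene, cfg.qpcr.calibrator
)
merged = res.merge(truth, on=["gene", "condition", "timepoint_h"])
print(merged[merged["condition"] == "PQ"].to_string(index=False))
# Er_mean is the efficiency-corrected expression relative to the untreated
# 0-h calibrator (defined as 1), averaged over replicates with its SEM;
# true_fold is the value the simulation planted, so the two should agree
# within the Ct noise.
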