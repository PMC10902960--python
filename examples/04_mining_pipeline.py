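"""Full synthetic pipeline: simulate -> value -> trend -> joinpoint -> compare.

Simulates a 100 x 100 grassland landscape (1-ha pixels, 1990-2020) in
which two mining concessions expand from 2002, runs every analysis stage,
and prints the headline numbers. All outputs are also written to
./scratch/example_run/.
"""

from esvtrend import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(outdir="scratch/example_run", seed=0))

acc = res.accounts
print(f"dynamic ESV, {int(acc.year.iloc[0])}: {acc.esv_dynamic.iloc[0]:,.0f} CNY")
print(f"dynamic ESV, {int(acc.year.iloc[-1])}: {acc.esv_dynamic.iloc[-1]:,.0f} CNY")

print("\ntrend-class shares of the study area:")
print(res.trend_summary.to_string(index=False))

print("\njoinpoint summaries of the regional mean dynamic ESV per hectare:")
for grp, rep in res.joinpoint_report.items():
    lo, hi = rep["aapc_ci"]
    print(
        f"  {grp:8s} AAPC = {rep['aapc']:+.2f}%/yr "
        f"(95% CI {lo:+.2f} to {hi:+.2f}), breakpoints {rep['breakpoints']}"
    )

mw = res.comparison.query("test == 'mann_whitney'")
for _, row in mw.iterrows():
    print(
        f"\nMann-Whitney, {int(row.year)}: mining median {row.median_a:,.0f} vs "
        f"control {row.median_b:,.0f} CNY/ha, p = {row.p:.4f}"
        f" ({'significant' if row.significant else 'not significant'} at 0.05)"
    )

print("\nThe concessions' mean value declines once mining outpaces the")
print("willingness-to-pay growth, while the control area rises steadily -")
print("the contrast the comparison stage is designed to detect.")
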