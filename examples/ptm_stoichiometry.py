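"""PTM stoichiometry from extracted ion chromatograms.

Simulates an MS1 run in which the TAD-peptide proteoforms elute as
separated chromatographic peaks at the wild-type composition, then
re-quantifies the run from scratch: theoretical m/z per isoform, XIC at
10 ppm, baseline-subtracted trapezoidal area, fractions of total signal.
"""

from ptmkit import gen_ms1_run, quantify_isoforms
from ptmkit.reference import WT_TAD_FRACTIONS, WT_TAD_RT_CENTERS, tad_isoforms

isoforms = tad_isoforms(WT_TAD_FRACTIONS)
run, truth = gen_ms1_run(
    isoforms, WT_TAD_FRACTIONS, WT_TAD_RT_CENTERS, noise_cv=0.01, seed=1
)
table = quantify_isoforms(run, isoforms, tolerance_ppm=10.0, rt_windows=truth["rt_windows"])

print(f"simulated MS1 run: {len(run)} scans")
print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print()
for row in table.itertuples(index=False):
    true_pct = 100 * truth["fractions"][row.label]
    print(f"  {row.label:<28s} recovered {100 * row.fraction:5.1f}%  (truth {true_pct:5.1f}%)")
print(
    "\nEach fraction is that proteoform's share of total TAD-peptide XIC "
    "area; rows under 1% of total would be flagged below the limit of "
    "quantitation."
)
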