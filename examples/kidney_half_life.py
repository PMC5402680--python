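"""Elimination half-life across molecular weight and kidney function.

Half-life is ln2 * V_blood / (GFR * C_F(MW)): it grows with molecular
weight (sieving falls) and as kidney health declines (GFR falls). Markers
above the sieving cutoff (e.g. IgG, 140 kDa) are never renally cleared.
"""

from neuropk import run_kidney_sweep

table = run_kidney_sweep(
    mw_grid=[10700.0, 21000.0, 26000.0, 46000.0, 140000.0],
    gfr_function_grid=[1.0, 0.5, 0.25, 0.1],
)
print("elimination half-life (minutes); columns = kidney-health fraction")
print(table.to_string(float_format=lambda v: f"{v:10.4g}"))

# Each halving of kidney function doubles every finite half-life; the
# *absolute* increase is largest for heavy markers, which is why renal
# failure distorts large-marker serum levels the most.
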