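"""Substrate concentration versus enzyme binding sites.

With one binding site per catalytic subunit, the binding-site
concentration of each CBC enzyme equals its subunit concentration in the
chloroplast. Comparing metabolite pools against these binding sites
classifies each enzyme's substrate as below the sites (fold < 1),
slightly above (< 4.5-fold) or in clear excess — the enzymes whose
substrates are scarcest relative to their sites are the interesting
overexpression candidates.
"""

from qconpipe import occupancy_table
from qconpipe import reference
from qconpipe.occupancy import records_to_frame

table2 = reference.table2_method_comparison()
subunit_uM = dict(zip(table2["protein"], table2["um_chloroplast_qconcat"]))
metabolites = reference.synthetic_metabolites()  # synthetic test table

records = occupancy_table(metabolites, subunit_uM)
df = records_to_frame(records).sort_values("fold")

print(f"{'enzyme':8s} {'metabolite':10s} {'role':10s} "
      f"{'substrate uM':>12s} {'sites uM':>9s} {'fold':>7s}  regime")
for r in df.itertuples():
    print(f"{r.enzyme:8s} {r.substrate:10s} {r.role:10s} "
          f"{r.substrate_uM:12.1f} {r.binding_site_uM:9.1f} {r.fold:7.1f}  {r.regime}")

below = df[df["regime"] == "below-sites"]
print(f"\n{len(below)} enzyme-substrate pairs sit below their binding-site "
      "concentration — those enzymes cannot be substrate-saturated.")
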