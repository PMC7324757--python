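"""From per-cell amounts to mass fractions and chloroplast molarity.

Takes the published per-cell amounts of the 12 CBC subunits and runs the
unit-conversion chain: a 27.6 pg-protein cell of 270 fL with half its
volume occupied by the chloroplast. The mass fractions sum to ~12% of
total cell protein, and the concentration column reproduces the
published chloroplast molarities.
"""

from qconpipe import CellModel, contextualize
from qconpipe import reference

cell = CellModel()  # 27.6 pg protein, 270 fL, chloroplast fraction 0.5
table2 = reference.table2_method_comparison()
abundances = table2.rename(columns={"amol_per_cell_qconcat": "amol_per_cell"})[
    ["protein", "amol_per_cell"]
]
out = contextualize(abundances, cell, reference.mature_molecular_weights())

print(f"{'protein':8s} {'amol/cell':>10s} {'% protein':>10s} {'uM chloroplast':>15s}")
for row in out.itertuples():
    print(f"{row.protein:8s} {row.amol_per_cell:10.2f} "
          f"{row.mass_fraction_percent:10.2f} {row.chloroplast_uM:15.1f}")
total = out["mass_fraction_percent"].sum()
print(f"\nCBC panel totals {total:.1f}% of cell protein; concentrations span "
      f"{out['chloroplast_uM'].max() / out['chloroplast_uM'].min():.0f}-fold.")
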