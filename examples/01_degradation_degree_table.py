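"""Degradation degree from tensile elongation at break.

Loads the packaged tensile grid (pre-stretch 0/20/40% x 3/10/20/30 days),
derives the pristine reference elongation L0 from the anchor assumption
(degree 0.1 at 3 days, 0% pre-stretch) and tabulates D = 1 - L/L0 for
every cell.
"""

from stentdeg import load_table1, tabulate_degrees

dataset = load_table1()
print(f"reference elongation L0 = {dataset.reference_elongation:.6f}")
table = tabulate_degrees(dataset)
print(table.to_string(index=False))
print(
    "\nEach 'degree' is the fraction of ductility lost relative to the"
    "\npristine material: 0 = virgin PLLA, 1 = complete degradation."
    "\nHolding strain during degradation (pre_stretch) accelerates the loss."
)
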