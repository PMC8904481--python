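"""Render the numbered plot family on the packaged expression table.

Writes one image per kind plus a sidecar CSV of the plotted values into
./gallery/; the sidecar is the contract (pixel output is never asserted).
"""

import qpcrmine as q
from qpcrmine.relquant import delta_ct, delta_delta_ct, fold_profile
from qpcrmine.viz import PlotRequest, render_plot

table2 = q.load_fixture("table2")

spec = q.SynthSpec(true_folds={"TPS27": {("10", "15"): 16.0}}, seed=1)
wells, _ = q.simulate_ct_experiment(spec)
estimates, _ = q.relative_expression(wells, spec.design())
records, _ = delta_ct(wells, "actin")
folds = fold_profile(delta_delta_ct(records, spec.control))

for kind in range(1, 11):
    img, sidecar = render_plot(
        PlotRequest(
            kind=kind,
            out_path=f"gallery/plot_{kind:02d}.png",
            estimates=estimates,
            table=table2,
            folds=folds,
            wells=wells,
        )
    )
    print(f"kind {kind:2d}: {img}  (+ {sidecar.name})")

print()
print("Kinds 1-6 compare treatments (bars, dots, boxes, lines, radar);")
print("7-9 are the mining views (correlation plot, clustered heatmap, biplot);")
print("10 is a QC view of the raw Ct distributions per gene.")
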