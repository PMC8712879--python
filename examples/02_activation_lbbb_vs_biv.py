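"""Simulate LBBB and biventricular-pacing activation on one anatomy.

In left bundle branch block the RV Purkinje tree drives activation and the
LV free wall finishes last; biventricular pacing adds an LV lateral source
and resynchronizes the chambers.  The script prints total activation time
(TAT) and the interventricular dyssynchrony index AT_RVLV for both modes.
"""

import numpy as np

from crtpredict import (ConductionModel, build_ventricles, grow_rv_tree,
                        late_activation_zone, lbbb_sources,
                        place_pacing_sites, solve_activation)
from crtpredict.biomarkers import at_rvlv, tat
from crtpredict.vtkio import write_vtk

mesh = build_ventricles(edge_length=4.0)
model = ConductionModel()          # v0 = 0.6 mm/ms, 4:1 anisotropy
tree = grow_rv_tree(mesh, seed=1)
print(f"Purkinje surrogate: {len(tree.pmjs)} junctions, onsets "
      f"{min(o for _, o in tree.pmjs):.1f}-{max(o for _, o in tree.pmjs):.1f} ms")

lbbb = solve_activation(mesh, model, lbbb_sources(tree), mode="lbbb")
pacing = place_pacing_sites(mesh)
biv = solve_activation(mesh, model,
                       [(pacing.rv_site, 0.0), (pacing.lv_site, 0.0)],
                       mode="biv")

for amap in (lbbb, biv):
    print(f"{amap.mode:5s}  TAT = {tat(amap):6.1f} ms   "
          f"AT_RVLV = {at_rvlv(amap, mesh):6.1f} ms")
print("positive AT_RVLV = LV activates later than RV (the LBBB signature);")
print("BiV pacing shortens TAT and collapses the interventricular delay.")

zone = late_activation_zone(lbbb, mesh)
print(f"late-activation zone (LV lead target): {len(zone)} nodes")
write_vtk(mesh, "activation.vtk",
          point_data={"AT_lbbb": lbbb.at, "AT_biv": biv.at})
print("wrote activation.vtk with both activation-time fields")
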