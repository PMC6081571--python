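"""Lagrangian aerosol transport: lobar distribution vs particle size.

Releases ensembles of 2.5, 5 and 10 um particles (reduced counts for a
quick demonstration; the study protocol is 9 x 10,000) into a healthy and
a severe phenotype and compares the upper-to-lower distribution ratio
U/(M+L)|dist with the ventilation ratio U/(M+L)|v.
"""

import warnings

from aerotree import (
    ReleaseSpec,
    TransportConfig,
    TurbulenceSurrogate,
    flow_solution,
    generate_tree,
    generate_volume_change,
    run_ensemble,
)
from aerotree.synthetic_data import PHENOTYPES

warnings.filterwarnings("ignore")

rs = ReleaseSpec(n_particles=3000, n_releases=3, diameters=(2.5e-6, 5e-6, 10e-6),
                 rng_seed=1)
cfg = TransportConfig(turbulence=TurbulenceSurrogate(seed=1))

for name in ("healthy_1", "severe_cr"):
    spec = PHENOTYPES[name]
    tree = generate_tree(spec)
    dv = generate_volume_change(spec)
    flow = flow_solution(tree, dv)
    summary = run_ensemble(tree, flow, rs, cfg)
    print(f"\n{name}:  U/(M+L)|v = {dv.uml_ratio:.3f}")
    for d in rs.diameters:
        print(f"  {d*1e6:4.1f} um: U/(M+L)|dist = {summary.uml_dist(d):.3f}")

print(
    "\nSmall particles follow the flow, so their distribution ratio tracks"
    "\nthe ventilation ratio; inertia carries larger particles past the"
    "\nupper-lobe takeoffs toward the lower lobes, and the apically-shifted"
    "\nsevere phenotype sends more of every size to the upper lobes."
    "\n(At this reduced demonstration scale, sampling scatter can blur the"
    "\nsmall 2.5->5 um step; study-scale ensembles resolve the ordering.)"
)
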