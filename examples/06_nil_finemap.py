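"""Fine-map a chromosome-5 locus with reciprocal NIL panels.

NILs recombine on a single chromosome in an otherwise uniform background,
so per-marker regression localises a QTL below whole-chromosome
resolution and reciprocal panels expose background-dependent effects.
"""

import numpy as np
import pandas as pd

from cslmap import CslGenotype, MarkerMap, nil_panel, nil_scan

rng = np.random.default_rng(3)
marker_map = MarkerMap.default()

col_parent = CslGenotype(("Col",) * 5)
ler_parent = CslGenotype(("Ler",) * 5)
panels = {
    "Col": nil_panel(CslGenotype(("Col", "Col", "Col", "Col", "Ler")),
                     col_parent, 60, marker_map, rng),
    "Ler": nil_panel(CslGenotype(("Ler", "Ler", "Ler", "Ler", "Col")),
                     ler_parent, 60, marker_map, rng),
}

# truth: a locus at 45 cM on chromosome 5, stronger in the Col background
idx5 = marker_map.marker_index(5)
cms = marker_map.frame["cM"].to_numpy()[idx5]
j45 = idx5[int(np.argmin(np.abs(cms - 45.0)))]
phenos = {}
for bg, panel in panels.items():
    effect = -7.4 if bg == "Col" else 4.5  # flowering-time style asymmetry
    dos = np.array([l.dosage()[j45] for l in panel])
    y = 60.0 + effect * dos + rng.normal(0, 1.5, size=len(panel))
    phenos[bg] = pd.Series(y, index=[l.line_id for l in panel])

table = nil_scan(panels, phenos, marker_map, target_chrom=5)
for bg, grp in table.groupby("background"):
    peak = grp.loc[grp["minus_log10_p"].idxmax()]
    print(f"{bg} background: peak at {peak['cM']:.0f} cM, "
          f"effect {peak['effect']:+.2f} days, "
          f"support interval [{peak['si_left_cM']:.0f}, "
          f"{peak['si_right_cM']:.0f}] cM")
print(f"\nmarkers tested per background: "
      f"{int(table.groupby('background')['tested'].sum().iloc[0])}")
# Both support intervals should bracket 45 cM; the effect signs differ by
# construction, mirroring a background-dependent (epistatic) QTL.
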