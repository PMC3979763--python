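"""Histone-mark footprints around TSS and silenced/control ratios.

Builds the average H3K4me3 profile around all active TSS (the signal bump
sits ~120 bp downstream), then compares normalized silenced/control window
ratios of up-regulated versus non-DE genes with the Mann-Whitney test.
"""

import numpy as np

from silencescan.histone import footprint
from silencescan.pipeline import run_pipeline
from silencescan.simulate import SAMPLES, SimulationConfig, simulate_study

config = SimulationConfig(n_genes=300, library_sizes={s: 500_000 for s in SAMPLES})
study = simulate_study(config, seed=5)

truth = study.truth.genes
anchors = [(r.chrom, int(r.tss), r.strand) for _g, r in truth.iterrows()]
prof = footprint(anchors, study.histone[("H3K4me3", "control")],
                 half_window=1750, bin_width=50, mark="H3K4me3")
peak_offset = prof.bin_centers[np.argmax(prof.mean_signal)]
print(f"H3K4me3 profile over {prof.anchor_count} TSS: "
      f"maximum at {peak_offset:+.0f} bp from TSS")

result = run_pipeline(study)
u, p = result.histone_mw["H3K9ac"]
print(f"H3K9ac silenced/control ratios, up-regulated vs non-DE: "
      f"U={u:.0f}, p={p:.2g}")
# The profile maximum downstream of the TSS reflects the +1 nucleosome
# region; the tiny Mann-Whitney p shows the planted coupling between
# expression change and histone-mark change is recovered.
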