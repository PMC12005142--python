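"""Full selection scan: SAF -> 2D-SFS -> FST components -> PBS windows -> peaks.

A sweep is implanted in the focal population; the scan should recover it as
the single candidate peak. Window FST is the ratio of summed per-site
Hudson components, with posterior expectations taken under the EM-estimated
2D-SFS prior — no genotype calling anywhere.
"""

import numpy as np

from pbscan import gl as glmod
from pbscan import scan, sfs
from pbscan.simdata import SimulationConfig, Sweep, simulate_dataset

config = SimulationConfig(
    n_sites=10_000, chrom_length=10_000_000,
    n_individuals=(15, 15, 15), drift=(0.068, 0.020, 0.012),
    mean_depth=2.0, error_rate=0.01,
    sweep=Sweep(population=0, start=4_000_001, end=4_100_000, delta=0.8),
    seed=1,
)
truth, pileup = simulate_dataset(config)
table = glmod.compute_gl_table(pileup)

safs = [sfs.saf_table(table.gl[:, truth.pop_slice(k), :]) for k in range(3)]
components = {}
for key, (x, y) in {"ij": (0, 1), "ik": (0, 2), "jk": (1, 2)}.items():
    joint = sfs.estimate_sfs_em(safs[x], safs[y], tol=1e-5, max_iter=80)
    a, d = scan.fst_site_components(safs[x], safs[y], joint.eta, 15, 15)
    components[key] = (a, d)
    print(f"genome-wide FST pop{x}-pop{y}: {scan.genome_fst(a, d):.4f}")

windows = scan.sliding_scan(truth.positions, components,
                            window=20_000, step=10_000,
                            chrom_length=config.chrom_length)
valid = windows.dropna(subset=["pbs"])
print(f"\n{len(valid)} windows; genome-wide mean PBS {valid['pbs'].mean():.4f}")

peaks = scan.call_peaks(windows, top_fraction=0.01, min_windows=6,
                        merge_distance=1_000_000)
for p in peaks:
    print(f"peak at {p.start/1e6:.2f} Mb: best PBS {p.best_pbs:.3f}, "
          f"{p.n_top_windows} top windows")
print(f"true sweep interval: {truth.sweep_interval[0]/1e6:.2f}-"
      f"{truth.sweep_interval[1]/1e6:.2f} Mb")
print("The called peak's best window should fall inside the true interval;")
print("its PBS is an order of magnitude above the genome-wide mean.")
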