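"""The PBS worked example: from three genome-wide FST values to one PBS.

The population branch statistic for a focal population i against references
j and k is PBS_i = (T_ij + T_ik - T_jk) / 2 with T = -log(1 - FST). Applied
to the genome-wide pairwise FST trio of a focal South American population
against two related reference populations, it gives the genome-wide PBS
level against which selection peaks are judged.
"""

from pbscan.scan import branch_length, pbs

fst_focal_ref1 = 0.044
fst_focal_ref2 = 0.040
fst_ref1_ref2 = 0.016

for name, fst in [("focal-ref1", fst_focal_ref1),
                  ("focal-ref2", fst_focal_ref2),
                  ("ref1-ref2", fst_ref1_ref2)]:
    print(f"T({name}) = -log(1 - {fst}) = {branch_length(fst):.6f}")

value = pbs(fst_focal_ref1, fst_focal_ref2, fst_ref1_ref2)
print(f"\nPBS(focal) = {value:.6f}")
print("This is the branch length private to the focal population: how much")
print("allele-frequency drift it accumulated that neither reference shares.")
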