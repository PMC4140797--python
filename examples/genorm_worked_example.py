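"""geNorm stability on a tiny hand-checkable relative-quantity matrix.

Genes A and B rise perfectly in step (their expression ratio is constant
across samples), while C is flat.  Because A/B never deviate from each
other, their mutual log-ratio SD is 0 and each gene's M is driven only
by its disagreement with C.
"""

import pandas as pd

from refstab import genorm_m, genorm_rank, pairwise_variation

rq = pd.DataFrame(
    [[1.0, 2.0, 4.0],   # A
     [1.0, 2.0, 4.0],   # B — proportional to A
     [1.0, 1.0, 1.0]],  # C — flat
    index=["A", "B", "C"], columns=["s1", "s2", "s3"],
)

res = genorm_m(rq)
print("stability measure M (lower = more stable):")
print(res.m.round(4).to_string())

ranking = genorm_rank(rq)
print(f"\nstepwise exclusion order (least stable first): {ranking.exclusion_order}")
print(f"final, most stable pair: {ranking.final_pair}")

pv = pairwise_variation(rq, ranking)
print(f"\npairwise variation V_2/3 = {pv.v[2]:.4f} (exactly 1/3)")
print(f"optimal number of reference genes at cutoff {pv.cutoff}: {pv.optimal_n}"
      + (" (no V fell below the cutoff)" if pv.no_v_below_cutoff else ""))
print("\nM_A = M_B = 0.5: each stable gene's only disagreement is with C;")
print("M_C = 1.0: C disagrees with both, so it is excluded first.")
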