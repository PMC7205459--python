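"""The per-gene fitness score and what its values mean.

W compares a gene's share of transposon reads before (N_t1) and after
(N_t2) growth, normalised by the 2^10 expansion of the whole population:
W = 1 means the gene's mutants kept pace, W < 1 a fitness defect, W = 0 a
lineage that never divided, W > 1 an advantage.
"""

from tnprof import fitness_score

cases = [
    ("unchanged proportion (neutral)", 0.001, 0.001),
    ("proportion doubled (advantage)", 0.001, 0.002),
    ("proportion halved (mild defect)", 0.001, 0.0005),
    ("diluted 1024-fold (no growth)", 0.001, 0.001 / 1024),
]

for label, n1, n2 in cases:
    w = fitness_score(n1, n2, generations=10)
    print(f"{label:35s} N_t1={n1:.6f}  N_t2={n2:.7f}  W = {w:.4f}")
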