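"""Pairwise K2P distances on a small alignment, undefined state included.

Builds five short aligned sequences (one of them mostly N) and prints the
distance matrix.  NaN cells are *undefined* distances: either no comparable
site was left after pairwise deletion, or the K2P logarithm saturated.
"""

import numpy as np

from coithresh import distance_matrix, k2p_distance, p_distance

sequences = [
    ("bee1", "ATGGCTCGTATTAACGGTCAACTAATCGGA"),
    ("bee2", "ATGGCTCGTATCAACGGTCAACTAATCGGA"),   # one transition vs bee1
    ("bee3", "ATGGCACGTATCAACGGACAACTTATCGGA"),   # a few more changes
    ("wasp", "ATAGCCCGAATTAATGGCCAATTAATTGGG"),
    ("dud",  "NNNNNNNNNNNNNNNNNNNNNNNNNNNNGA"),   # almost no usable sites
]

matrix = distance_matrix(sequences, model="K2P")
np.set_printoptions(precision=4, suppress=True)
print("labels:", matrix.labels)
print(matrix.values)
print()
d_k2p = k2p_distance(sequences[0][1], sequences[3][1])
d_p = p_distance(sequences[0][1], sequences[3][1])
print(f"bee1 vs wasp: K2P = {d_k2p:.4f}, p = {d_p:.4f}")
print("The K2P value exceeds the raw mismatch fraction because it corrects")
print("for multiple substitutions at one site; NaN rows involve 'dud', whose")
print("N-runs leave too few comparable sites for a defined distance.")
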