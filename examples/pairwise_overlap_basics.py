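"""Pairwise overlap from first principles on a six-plant pollination module.

Two pollinators visit overlapping sets of plants.  The standardized overlap
compares the observed number of shared plants O with the hypergeometric
expectation E = d_i * d_j / n and maps the outcome onto [-1, +1].
"""

from nshare import Network, PermittedInteractions, mean_overlap, pair_overlap

plants = [f"plant{k}" for k in range(1, 7)]
pollinators = ["bee", "moth", "fly"]
visits = [
    ("plant1", "bee"), ("plant2", "bee"), ("plant3", "bee"), ("plant4", "bee"),
    ("plant1", "moth"), ("plant2", "moth"), ("plant3", "moth"),
    ("plant5", "fly"), ("plant6", "fly"),
]
web = Network(plants + pollinators, visits, directed=False,
              bipartite_sides=(plants, pollinators))

# naive specification: every pollinator could visit every plant (n = 6)
naive = PermittedInteractions.fully_permissive(web)

for a, b in [("bee", "moth"), ("bee", "fly")]:
    rec = pair_overlap(web, naive, a, b, direction="undirected")
    print(f"{a}-{b}: n={rec.n} d_i={rec.d_i} d_j={rec.d_j} O={rec.observed} "
          f"E={rec.expected:.2f} value={rec.value:+.2f}")

summary = mean_overlap(web, naive, scope="cols")
print(f"pollinator-side mean overlap N-bar = {summary.mean_overlap:+.3f} "
      f"({summary.n_pairs_included} pairs included)")

# bee-moth share 3 of an expected 2 plants (overlap, value near +1);
# bee-fly share none (segregation, value -1); the mean summarizes the guild.
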