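# nshare — node overlap and segregation under permitted interactions

`nshare` measures the tendency of species in an ecological network to share
interaction partners — nestedness when they share more than chance predicts,
segregation when they share less — while letting the analyst declare which
interactions are *ecologically possible* in the first place.  It works on
bipartite webs (plant–pollinator, host–parasite) and on unimode directed
food webs alike.

## The statistic

For a pair of nodes *i*, *j*, let **A_ij** be the set of partners the two
could *possibly* share (the shareable set), **n = |A_ij|**, and let
**d_i**, **d_j** be their realized partner counts inside A_ij and **O** the
number of shared realized partners.  Under the hypergeometric sampling
distribution — every member of A_ij equally likely to be linked — the
expected overlap is

    E = d_i · d_j / n,    s_min = max(0, d_i + d_j − n),    s_max = min(d_i, d_j)

and the standardized pairwise overlap maps {s_min, E, s_max} linearly onto
{−1, 0, +1}:

    Ɲ_ij = (O − E) / (s_max − E)   if O ≥ E
    Ɲ_ij = (O − E) / (E − s_min)   if O < E

The network index **N̄** is the mean of Ɲ_ij over all candidate pairs with a
defined value (pairs with an empty shareable set, a zero degree, or a forced
outcome are counted and reported separately).

The parameter **n** is the scientific crux.  The naive choice — every node of
the opposite guild, or all N−2 other species in a food web — assumes all
interactions are possible.  `nshare` instead builds *permitted-interaction*
relations from ecological rules and restricts every pair's shareable set to
them:

* **Trophic rule** (food webs): a link is permitted only from a resource to a
  consumer at a strictly higher trophic level, with levels defined as the
  minimum path distance from a basal species (one with no prey).
* **Task matching** (host–parasite): a parasite can use a host only if their
  trait/task repertoires intersect.
* **Arbitrary matrices**: any labeled 0/1 table.

Synthetic generators (Bernoulli, nested, modular bipartite webs; layered food
webs; task-matching host–parasite worlds) let every analysis run without
external data, and a batch pipeline compares constrained vs unconstrained N̄
across groups of networks with 95% confidence intervals and Spearman
diversity correlations.

## Worked example

```python
from nshare import (gen_layered_foodweb, trophic_permitted, mean_overlap,
                    reduction_report)

web, _ = gen_layered_foodweb(levels=4, species_per_level=8, seed=42)
perm = trophic_permitted(web)
print(reduction_report(web, perm, "out").mean_ratio)
print(mean_overlap(web, None, scope="unimode-out").mean_overlap)
print(mean_overlap(web, perm, scope="unimode-out").mean_overlap)
```

prints

```
0.3024193548387097
-0.36246510369479357
-0.20694526602911698
```

Reading: the trophic rule shrinks the average potential-prey set to ~30% of
all other species; under the naive n the web looks strongly segregated
(N̄ ≈ −0.36), while within ecologically permitted prey sets much of that
apparent segregation disappears (N̄ ≈ −0.21).  The `examples/` directory has
one short script per capability (pairwise decomposition, trophic constraint,
task matching, batch group comparison), each printing and explaining its
numbers.

A thin CLI mirrors the library:

```bash
nshare compute web.csv --format incidence --scope rows
nshare compute web.txt --constraint trophic --per-pair
nshare simulate --config world.yaml --out-dir out/
nshare batch --manifest manifest.csv --out-dir report/
```

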