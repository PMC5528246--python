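"""Group comparison across a batch of synthetic food webs.

Builds two groups of layered webs — deep 'persistent'-style webs and shallow
'ephemeral'-style webs — runs the constrained/unconstrained comparison on
each, and prints group means with 95% confidence intervals, writing the full
machine-readable report (CSV + JSON + plots) to a temporary directory.
"""

import tempfile

from nshare import (
    BatchEntry,
    batch_overlap,
    gen_layered_foodweb,
    group_summary,
    write_report,
)

entries = []
for k in range(12):  # deep webs: four trophic levels
    net, _ = gen_layered_foodweb(4, 6, seed=100 + k)
    entries.append(BatchEntry(id=f"deep{k}", group="deep", network=net,
                              constraint="trophic"))
for k in range(12):  # shallow webs: two levels only
    net, _ = gen_layered_foodweb(2, 12, seed=200 + k)
    entries.append(BatchEntry(id=f"shallow{k}", group="shallow", network=net,
                              constraint="trophic"))

records = batch_overlap(entries, scope="unimode-out")
summaries = []
for group in ("deep", "shallow"):
    for which in ("unconstrained", "constrained"):
        s = group_summary(records, group, which=which)
        summaries.append(s)
        print(f"{group:8s} {which:13s} N-bar = {s.mean_nbar:+.3f} "
              f"± {s.ci95_halfwidth:.3f} (95% CI, k={s.n_networks})")

out_dir = tempfile.mkdtemp(prefix="nshare_report_")
paths = write_report(out_dir, records, summaries, plots=True)
print("report written to:", sorted(str(p) for p in paths.values()))

# In the deep webs the paired difference (constrained - unconstrained) is
# positive: the naive n dilutes within-level prey sharing into apparent
# segregation.  In the two-level webs it is negative: with only 12 true prey,
# n = 22 inflates the apparent overlap, and the constraint corrects it back
# toward randomness.  Both directions are the same lesson - N-bar is only
# interpretable relative to an ecologically defensible n.
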