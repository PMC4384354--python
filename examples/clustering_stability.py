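"""Cutoff scan and run-to-run stability of the greedy clustering.

Plants 10 distinct fragment-pair geometries with 30 noisy members each
(sigma 0.3 A), then (a) scans the clustering cutoff — at 0.1 A every
pair is its own cluster, at 4 A the 10 planted groups reappear, at 100 A
everything merges — and (b) repeats the 4 A clustering under five
shuffled visiting orders to show the partition does not depend on the
order.
"""

from ifplib import cutoff_scan, stability_runs
from ifplib.fixtures import make_planted_pair_dataset

pairs, labels = make_planted_pair_dataset(K=10, members_per=30,
                                          noise_sigma=0.3, seed=11)
print(f"{len(pairs)} pairs from 10 planted geometries, 30 members each")

print("\ncutoff scan (cutoff_A -> n_clusters):")
for cutoff, n in cutoff_scan(pairs, [0.1, 1.0, 4.0, 10.0, 100.0],
                             order_seed=0):
    print(f"  {cutoff:6.1f} -> {n:4d}")

print("\nfive shuffled clustering runs at 4 A:")
for run in stability_runs(pairs, cutoff=4.0, n_runs=5,
                          seeds=[0, 1, 2, 3, 4], min_members=20):
    print(f"  seed {run['seed']}: {run['n_clusters']} clusters, "
          f"{run['n_abundant']} with >20 members, "
          f"largest sizes {run['ranked_sizes'][:3]}")
print("identical counts and size profiles across runs indicate a stable "
      "cluster topology")
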