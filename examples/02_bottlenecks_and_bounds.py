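"""Bottlenecks, cycle clusters and critical-number bounds on a planted fixture.

A 4-clique with self-loops feeding a 3-node tail is a hysteretic bottleneck:
no single node controls it, but forcing ceil(4/2) = 2 clique nodes flips the
whole cluster and its downstream cone.
"""

from attractorctl import (
    critical_set_search,
    efficiencies,
    size1_bottlenecks,
    size_k_bottlenecks,
    theorem_bounds,
)
from attractorctl.synth import make_clique_cluster

net, attr, spec = make_clique_cluster(4, self_loops=True, tail=3)
cluster = set(spec.truth["cluster"])
print("planted cluster:", sorted(cluster), " planted N_c:", spec.truth["n_c"])

print("size-1 bottlenecks:", size1_bottlenecks(net))

rec = size_k_bottlenecks(net)[0]
print(f"cluster bottleneck: members={rec.members} impact={rec.impact}")

b = theorem_bounds(net, cluster, seed=0)
print(f"N_c bounds: [{b.lower}, {b.upper}]  (z={b.inputs.z}, "
      f"overestimate used: {b.eq_overestimate_used})")

res = critical_set_search(net, cluster, replicates=30, seed=0)
print(f"exact N_c by enumeration: {res.n_c}  "
      f"({len(res.sets)} minimal sets, {res.tested} subsets verified)")

rec = efficiencies(rec, net, replicates=20, seed=0)
print(f"critical efficiency: impact/N_c = {rec.impact}/{res.n_c} "
      f"= {rec.impact / res.n_c:.1f}")
print(f"optimal efficiency: {rec.e_opt:.1f} at prefix {rec.e_opt_subset}")
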