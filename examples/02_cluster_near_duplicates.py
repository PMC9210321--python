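"""Group near-duplicate peptides and collapse them to pseudo-datapoints.

Near-identical sequences carry no independent information about the
sequence-fitness relationship, so they are clustered by Hamming distance
(single link) and each cluster becomes one weighted pseudo-datapoint:
fitness = weighted mean, weight = summed weights. The partition here is
identical over a wide window of cutoffs because planted mutants sit at
distance 1-2 while unrelated random peptides differ at ~47 of 50 sites.
"""

from pepfit import (
    SimulationConfig,
    collapse_clusters,
    fit_experiment,
    simulate,
    single_link_clusters,
)

cfg = SimulationConfig(n_lineages=80, depth=50_000, seed=7, n_duplicate_clusters=6)
sim = simulate(cfg)
fit = fit_experiment(sim["experiment"], model="poisson")

peps = [(r.id, r.aa_seq) for r in sim["records"]]
for cutoff in (2, 6, 20, 29):
    print(f"cutoff {cutoff:2d}: {len(single_link_clusters(peps, cutoff))} clusters")

fits = {f.id: f for f in fit.fits}
fitted = [(pid, seq) for pid, seq in peps if pid in fits]
clusters = collapse_clusters(single_link_clusters(fitted, 6), fits)

multi = [c for c in clusters if len(c.members) > 1]
print(f"\n{len(clusters)} clusters from {len(fitted)} fitted peptides; "
      f"{len(multi)} clusters have >1 member")
print("largest cluster, collapsed to one weighted pseudo-datapoint:")
big = max(clusters, key=lambda c: len(c.members))
print(f"  members: {big.members}")
print(f"  representative (max weight): {big.representative}")
print(f"  pseudo fitness {big.pseudo_fitness:.3f}, pseudo weight "
      f"{big.pseudo_weight:.1f} (= sum of member weights)")
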