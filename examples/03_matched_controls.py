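"""Generate length/GC/CpG/GpC-matched non-G4 control sequences.

For each detected G4 the search anchors at a random same-chromosome
position and shifts a window of identical length +/-1 bp until the GC
fraction and CpG/GpC counts match within the 10% reciprocal tolerance.
Prints the success rate and a sample matched pair.
"""

import g4topo as g

spec = g.SimulationSpec(seed=3, chrom_lengths={"chr1": 400_000}, n_g4=100)
genome, _ = g.simulate_genome(spec)
union = g.merged_sets_union(g.detect_genome(genome, method="both"))

controls = g.generate_controls(genome, union, union, per_g4=2, tol=0.10, seed=3)
n_found = sum(controls.success_counts.values())
print(f"{len(union)} G4s -> {n_found} accepted controls "
      f"(target 2 per G4; none overlap any G4)")

gid = next(i for i, c in controls.pairs.items() if c)
src, ctrl = union[gid], controls.pairs[gid][0]
ms = g.sequence_metrics(genome[src.chrom][src.start:src.end])
mc = g.sequence_metrics(genome[ctrl.chrom][ctrl.start:ctrl.end])
print(f"example pair (G4 #{gid}):")
print(f"  G4      {src.chrom}:{src.start}-{src.end}  gc={ms.gc:.3f} cpg={ms.cpg} gpc={ms.gpc}")
print(f"  control {ctrl.chrom}:{ctrl.start}-{ctrl.end}  gc={mc.gc:.3f} cpg={mc.cpg} gpc={mc.gpc}")
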