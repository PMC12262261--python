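"""Emit a complete synthetic input bundle to ./scratch/bundle.

Writes the FASTA genome with planted G4s, the truth BED, a VCF with a
known variant class mixture, a per-CpG methylation BED, MAF alignment
blocks for simulated haplotypes, and a peak BED — everything the pipeline
consumes, with ground truth recorded in the manifest. Equivalent to
`g4topo simulate --seed 0 --out-dir scratch/bundle`.
"""

import json
from pathlib import Path

import g4topo as g

out = Path("scratch/bundle")
out.mkdir(parents=True, exist_ok=True)
spec = g.SimulationSpec(seed=0)

genome, truth = g.simulate_genome(spec)
g.write_genome(genome, out / "genome.fa")
g.write_intervals(truth, out / "truth_g4.bed")
variants = g.simulate_variants(spec, genome, truth)
g.write_vcf(variants, genome, out / "variants.vcf")
calls, _ = g.simulate_methylation(spec, truth)
g.write_methylation_bed(calls, out / "methylation.bed")
g.write_maf(g.simulate_maf(spec, genome), out / "alignment.maf")
peaks = g.simulate_peaks(spec, truth, {c: len(s) for c, s in genome.items()})
g.write_intervals(peaks, out / "peaks.bed")
(out / "truth_manifest.json").write_text(json.dumps({
    "seed": spec.seed, "n_g4": len(truth), "n_variants": len(variants),
    "rho_mut": spec.rho_mut, "meth_mixture": list(spec.meth_mixture),
    "divergence": spec.divergence, "colocalization_q": spec.colocalization_q,
}, indent=2))
print(f"bundle written to {out}: {len(truth)} planted G4s, "
      f"{len(variants)} variants, {len(calls)} methylation calls, {len(peaks)} peaks")
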