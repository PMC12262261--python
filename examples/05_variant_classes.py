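"""Classify germline variants and measure mutation enrichment near G4s.

Simulates a VCF with a known class mixture and a 5x mutation-rate
enrichment within 50 bp of planted G4s, classifies every record through
the sequential rule table (splitting multi-allelic rows first), and
recovers the planted enrichment factor from the classified records.
"""

import tempfile
from collections import Counter
from pathlib import Path

import g4topo as g
from g4topo.variants import mutation_rate_enrichment

spec = g.SimulationSpec(seed=5, chrom_lengths={"chr1": 500_000}, n_g4=150,
                        n_variants=8000, rho_mut=5.0)
genome, truth = g.simulate_genome(spec)
variants = g.simulate_variants(spec, genome, truth)

with tempfile.TemporaryDirectory() as d:
    vcf = Path(d) / "sim.vcf"
    g.write_vcf(variants, genome, vcf)
    records = g.classify_variants(g.load_variants(vcf), exclude_chroms=("chrY",))

print("class counts after multi-allelic splitting:")
for cls, n in Counter(r.mut_class for r in records).most_common():
    print(f"  {cls:16s} {n}")

sizes = {c: len(s) for c, s in genome.items()}
ratio = mutation_rate_enrichment(records, truth, sizes, half_width=50)
print(f"mutation rate in G4 +/- 50 bp vs background: {ratio:.2f}x (planted 5x)")
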