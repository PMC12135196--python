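"""Two routes to the number of independent chromosome segments (Me).

Me caps genomic prediction accuracy: acc = sqrt(N h2 / (N h2 + Me)).  It can
be set from population parameters (4 Ne L) or read off the eigenvalue
spectrum of the genomic relationship matrix.
"""

import numpy as np

import predslice as ps

print("Me = 4 Ne L:")
for label, ne, length in [("cattle-like", 125, 30.0), ("pig/chicken-like", 42, 30.0)]:
    print(f"  {label:<18} Ne={ne:<4} L={length} M ->", ps.me_from_ne_l(ne, length).me)

# spectral route on a simulated population with a known nucleus size
cfg = ps.SimConfig(
    genome=ps.GenomeSpec(n_chromosomes=2, markers_per_chromosome=150,
                         qtn_per_chromosome=5),
    scheme=ps.SelectionScheme(n_sires=5, n_dams=40,
                              offspring_per_generation=320, select=False),
    n_generations=0, burn_in_generations=12, burn_in_size=16)
pop, _ = ps.run_generations(cfg, seed=21)
grm = ps.build_grm(pop.genotypes, blend_alpha=0.0)
est = ps.me_from_grm_eigenvalues(grm, fraction=0.98)
print(f"\nsimulated nucleus (Ne={cfg.burn_in_size}, L="
      f"{cfg.genome.genome_length_morgans} M):")
print("  eigenvalue count explaining 98% of G:", est.me)
print("  4 Ne L nominal:                      ",
      ps.me_from_ne_l(cfg.burn_in_size, cfg.genome.genome_length_morgans).me)
# the two estimates agree to within a small factor; both grow with Ne and
# with genome length, and either can feed the heritability estimator.
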