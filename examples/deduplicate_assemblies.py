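"""Deduplicate assemblies by nested-MD5 fingerprint and filter by size.

Public repositories hold many byte-identical copies of the same assembly
under different names and contig orders. The fingerprint — MD5 over the
sorted per-contig MD5 digests — collapses them regardless of naming or
contig order, and the size filter flags entries too small to be a
prokaryotic genome (stray plasmids) or too large (eukaryotes).
"""

from genoscore import (
    Contig,
    GenomeAssembly,
    classify_by_size,
    dedupe_cohort,
    genome_fingerprint,
    simulate_assembly,
)
from genoscore.simulate import SimulationParams

base = simulate_assembly(SimulationParams(seed=5, genome_size=200_000, contig_count=3),
                         name="strain_A")
renamed = GenomeAssembly(
    "strain_A_mirror",
    [Contig(f"scf{i}", c.sequence) for i, c in enumerate(reversed(base.contigs))],
)
other = simulate_assembly(SimulationParams(seed=6, genome_size=200_000), name="strain_B")
plasmid = simulate_assembly(SimulationParams(seed=7, genome_size=60_000), name="orphan_plasmid")

cohort = [base, renamed, other, plasmid]
unique, duplicates = dedupe_cohort(cohort)

print(f"{'name':<18}{'fingerprint':<36}{'size':>9}  size_class")
for assembly in cohort:
    print(f"{assembly.name:<18}{genome_fingerprint(assembly):<36}"
          f"{assembly.total_size:>9,}  {classify_by_size(assembly.total_size).value}")
print()
print(f"unique assemblies: {[a.name for a in unique]}")
for fingerprint, names in duplicates.items():
    print(f"duplicate group {fingerprint[:8]}...: {names}")
print()
print("The mirror shares strain_A's fingerprint despite renamed, reordered contigs;")
print("the 60 kb entry is below the 138,500 bp floor and would be dropped as a plasmid.")
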