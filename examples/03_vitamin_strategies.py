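"""Classify B-vitamin acquisition strategies and enumerate the
configuration space.

For each of vitamins B1, B7 and B12 a genome is a *consumer* (transporter
but no biosynthesis), *independent* (biosynthesis but no transporter),
*flexible* (both) or *none*; the three vitamins jointly span a 4^3 = 64
cell configuration space.
"""

from traitatlas import SyntheticSpec, classify_vitamins, enumerate_configurations, gen_trait_matrix

matrix, truth = gen_trait_matrix(SyntheticSpec(n_genomes=120, n_traits=60, seed=3))
profiles = classify_vitamins(matrix)

for vit in ("B1", "B7", "B12"):
    counts = profiles[f"{vit}_strategy"].value_counts().to_dict()
    print(f"{vit}: {counts}")

table = enumerate_configurations(profiles)
print(f"\nconfiguration space: {table.attrs['n_possible']} cells, "
      f"{table.attrs['n_observed']} observed in {len(profiles)} genomes")
print("\nmost common configurations (B1, B7, B12 -> genomes):")
top = table.sort_values("n_genomes", ascending=False).head(5)
for _, row in top.iterrows():
    print(f"  {row['B1_strategy']:>11} / {row['B7_strategy']:>11} / "
          f"{row['B12_strategy']:>11} -> {row['n_genomes']}")
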