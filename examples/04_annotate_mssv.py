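"""Classify MSSVs into gene-region categories and type exonic consequences.

Each MSSV lands in exactly one category (exonic, splicing, UTRs, intronic,
the ncRNA counterparts, upstream/downstream within 2 kb, or intergenic);
exonic insertions/deletions are frameshift when their length is not a
multiple of 3.
"""

from collections import Counter

from gynotrace import (
    AnnotateParams,
    SimConfig,
    classify_region,
    detect_dsv,
    detect_mssv,
    simulate_cohort,
    tally_annotations,
)

cohort = simulate_cohort(SimConfig(seed=1))
male = detect_dsv(cohort.callsets["PM"], cohort.maternal, cohort.maternal_coverage)
off = detect_dsv(cohort.callsets["PP1"], cohort.maternal, cohort.maternal_coverage)
mssv = detect_mssv(off.dsv, male.dsv).mssv

calls = [classify_region(r, cohort.gene_model, AnnotateParams()) for r in mssv]
t = tally_annotations(calls, cohort.gene_model)

print(f"PP1: {t.total} MSSVs classified")
for cat, n in sorted(t.per_category.items(), key=lambda kv: -kv[1]):
    if n:
        print(f"  {cat.value:20s} {n}")
print(
    f"gene-associated: {t.n_gene_associated} ({100 * t.gene_associated_fraction:.1f}%), "
    f"intergenic: {t.n_intergenic}"
)
print("distinct genes hit per biotype:",
      {b.value: n for b, n in t.genes_per_biotype.items()})

exonic = [c for c in calls if c.consequence is not None]
if exonic:
    print("\nexonic consequences (net length change mod 3):")
    for c in Counter(x.consequence.value for x in exonic).items():
        print(f"  {c[0]}: {c[1]}")
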