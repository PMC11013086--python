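"""Census cis-regulatory elements in 1500-bp promoter regions.

Generates promoters with planted elements (2x ABRE, 1x MBS, 1x LTR,
1x GCN4_motif per gene), scans them against the shipped IUPAC catalog on
both strands, and aggregates occurrences and gene-level presences per
element and per functional category.
"""

from kincascade.promoters import category_rollup, default_catalog, scan_elements
from kincascade.synthetic import SynthesisConfig, gen_promoters

catalog = default_catalog()
records, truth = gen_promoters(SynthesisConfig(seed=1, n_promoters=20),
                               catalog)
results = [scan_elements(rec, catalog) for rec in records]
per_element, per_category = category_rollup(results, catalog)

hits = per_element[per_element["total_occurrences"] > 0]
print(hits.to_string(index=False))
print()
print(per_category.to_string(index=False))
print("\nABRE marks ABA response, MBS drought (MYB binding), LTR low "
      "temperature, GCN4_motif endosperm expression; totals count every "
      "occurrence, gene counts each promoter once.")
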