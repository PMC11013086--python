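"""Tabulate length, molecular weight, pI and GRAVY for family members.

The same four descriptors a gene-family survey reports per protein:
length in residues, average molecular weight in kDa, the isoelectric
point (pH of zero net charge), and the grand average of hydropathicity
(mean Kyte-Doolittle index; negative = hydrophilic).
"""

from kincascade.properties import property_report
from kincascade.synthetic import SynthesisConfig, gen_proteome

cfg = SynthesisConfig(
    seed=1,
    tier_counts={"MAPK": 3, "MAP2K": 2, "MEKK": 2, "RAF": 2, "ZIK": 1,
                 "MAP4K": 2},
    decoy_count=0,
)
records, _ = gen_proteome(cfg)
df = property_report(records)
print(df.to_string(index=False,
                   formatters={"MW_kDa": "{:.2f}".format,
                               "pI": "{:.2f}".format,
                               "GRAVY": "{:+.3f}".format}))
print("\nKinases are soluble cytoplasmic/nuclear proteins: GRAVY is "
      "typically negative and pI spreads widely with surface charge.")
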