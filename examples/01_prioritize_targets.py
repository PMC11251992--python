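"""Select shared cancer mutations and prevalent HLA alleles from frequency tables.

Builds a small mutation-prevalence table and an allele-frequency/typing pair
in memory, applies the standard thresholds (2% case prevalence; 5% overall
allele frequency, 10% carrier frequency, 1% floor) and prints the ranked
selections.
"""

import numpy as np
import pandas as pd

from neoscreen import select_alleles, select_mutations

prevalence = pd.DataFrame(
    [
        ("KRAS", "G12D", "PAAD", 0.32),
        ("KRAS", "G12D", "COAD", 0.10),
        ("KRAS", "G12V", "PAAD", 0.20),
        ("BRAF", "V600E", "SKCM", 0.40),
        ("EGFR", "L858R", "LUAD", 0.04),
        ("IDH1", "R132H", "LGG", 0.70),
        ("RARE", "X999Y", "PAAD", 0.004),  # below threshold everywhere
    ],
    columns=["gene", "protein_change", "indication", "case_prevalence"],
)

mutations = select_mutations(prevalence, threshold=0.02)
print("Selected mutations (max per-indication case prevalence >= 2%):")
print(mutations.to_string(index=False))

freq = pd.DataFrame(
    [
        ("A*02:01", "EUR", 0.27), ("A*02:01", "API", 0.16),
        ("A*01:01", "EUR", 0.16), ("A*01:01", "API", 0.06),
        ("B*07:02", "EUR", 0.14), ("B*07:02", "API", 0.04),
        ("C*17:01", "EUR", 0.008), ("C*17:01", "API", 0.006),  # rare everywhere
    ],
    columns=["allele", "population", "allele_frequency"],
)

rng = np.random.default_rng(0)
carrier_rates = {"A*02:01": 0.45, "A*01:01": 0.28, "B*07:02": 0.22, "C*17:01": 0.02}
typing = pd.DataFrame(
    [
        {"subject": f"s{i:03d}", "allele": allele}
        for i in range(200)
        for allele, rate in carrier_rates.items()
        if rng.random() < rate
    ]
)

alleles = select_alleles(freq, typing)
print("\nSelected alleles (overall AF >= 5%, carrier >= 10%, floor 1%):")
print(alleles.to_string(index=False))
print(
    "\noverall_af is the unweighted mean across populations; carrier_frequency"
    "\ncounts typed subjects carrying >= 1 copy (homozygotes once). C*17:01 is"
    "\nremoved by the 1% floor before either threshold applies."
)
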