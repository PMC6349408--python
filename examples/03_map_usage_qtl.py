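"""Permutation-based usage-QTL discovery.

Simulates a noisy planted usage QTL for one gene plus seven unlinked
variants in the cis window, runs the permutation pass (minimum nominal
p over all variant x event pairs, sample labels shuffled jointly) and
reports the lead variant with its empirical p-value.
"""

import numpy as np
import pandas as pd

from txevents import GenotypeMatrix, inverse_normal_transform, permutation_pass, relative_usage
from txevents.simulate import UsageQtlSpec, simulate_usage_qtl

rng = np.random.default_rng(1234)
dosage, abundance = simulate_usage_qtl(
    UsageQtlSpec(n_samples=84, maf=0.3, shift=0.10, noise_sd=0.05, seed=5)
)
pheno = inverse_normal_transform(relative_usage(abundance)).usage

n = dosage.size
ids = [f"null{i}" for i in range(7)] + ["causal"]
dosages = np.vstack([rng.binomial(2, 0.3, (7, n)).astype(float), dosage])
geno = GenotypeMatrix(
    ids,
    pd.DataFrame(
        {"chrom": "1", "pos": 1000 * np.arange(8), "ref": "A", "alt": "G"}, index=ids
    ),
    list(pheno.columns),
    dosages,
)

result = permutation_pass(pheno, geno, n_perm=1000, rng=np.random.default_rng(99))
print(f"scope: {result.n_features} events x {result.n_variants} variants")
print(f"lead variant:    {result.lead_variant}")
print(f"lead event:      {result.lead_feature}")
print(f"min nominal p:   {result.p_nominal_min:.3e}")
print(f"empirical p:     {result.p_empirical:.4f}  (floor 1/{result.n_perm + 1})")
print(
    "\nThe planted variant is recovered as the lead and its empirical "
    "p-value sits at the permutation floor — far below any FDR threshold."
)
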