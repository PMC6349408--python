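"""Classify a QTL as condition-specific (response) or shared.

Two candidate QTLs are simulated for 40 donors profiled in paired
naive and stimulated states: one whose genotype effect exists only
after stimulation, and one whose effect is identical in both
conditions.  Each is scored with the genotype-by-condition interaction
likelihood-ratio test (mixed model with a donor random intercept) and
with the random-effects variance decomposition that yields
sigma2_relative, the share of genetic variance explained by the
interaction.  A response QTL needs interaction FDR < 10% AND
sigma2_relative > 0.5.
"""

import numpy as np

from txevents import LongPhenotypeTable, classify_response
from txevents.simulate import ConditionSimSpec, simulate_conditions

tables = {}

# QTL active only after stimulation
tab, _ = simulate_conditions(ConditionSimSpec(n_donors=40, seed=70))
d = tab.data.copy()
d["phenotype"] += np.where(d.condition == "stimulated", 1.5 * d.dosage, 0.0)
tables["stimulated_only_qtl"] = LongPhenotypeTable(d)

# QTL with the same additive effect in both conditions
tab2, _ = simulate_conditions(
    ConditionSimSpec(n_donors=40, var_genotype=2.0, additive=True, seed=71)
)
tables["shared_qtl"] = LongPhenotypeTable(tab2.data)

for result in classify_response(tables):
    flag = "RESPONSE" if result.is_response else "shared"
    print(
        f"{result.feature_id:>20}: interaction LRT p={result.lrt_p:.2e} "
        f"(FDR={result.fdr:.2e}), sigma2_relative={result.sigma2_relative:.2f} "
        f"-> {flag}"
    )

print(
    "\nOnly the stimulation-dependent QTL passes both rules; the shared QTL "
    "has most of its genetic variance in the main genotype component."
)
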