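"""From event-level TPM to relative usage.

Simulates the textbook scenario: each copy of the alternative allele
increases the usage of the second promoter event by 10 percentage
points.  TPMs are written as per-sample quantifier tables, imported
back, and normalised within the event block; ordinary least squares on
the relative usage recovers the planted slope exactly because no noise
was added.
"""

import tempfile

import numpy as np

from txevents import import_abundance, relative_usage
from txevents.simulate import UsageQtlSpec, simulate_usage_qtl, write_abundance_tables

spec = UsageQtlSpec(n_samples=84, maf=0.3, shift=0.10, noise_sd=0.0, seed=17)
dosage, abundance = simulate_usage_qtl(spec)

with tempfile.TemporaryDirectory() as tmp:
    files = write_abundance_tables(abundance, tmp)
    matrix = import_abundance(files, abundance.feature_meta)

usage = relative_usage(matrix).usage
target = usage.iloc[1]  # the promoter event carrying the planted shift

slope = np.polyfit(dosage, target.to_numpy(), 1)[0]
for d in (0, 1, 2):
    mean = target.to_numpy()[dosage == d].mean()
    print(f"dosage {d}: mean relative usage {mean:.3f}")
print(f"OLS slope: {slope:.4f} per alternative allele")
print(
    "\nThe slope equals the simulated effect (0.10): one allele shifts the "
    "event's share of its block by ten percentage points."
)
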