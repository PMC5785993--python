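"""Success rates of the three orthotopic tumour implantation methods.

Summarises the fixed reference outcome counts (success fraction per method,
rounded half-up to one decimal) and, for contrast, a random Bernoulli cohort
drawn at the same underlying rates.
"""

from enafl import (ImplantOutcomeParams, gen_implantation_outcomes,
                   implantation_summary, reference_outcome_table)

print("reference counts:")
print(implantation_summary(reference_outcome_table()).to_string(index=False))
print()
table, truth = gen_implantation_outcomes(ImplantOutcomeParams(seed=0))
print("one random cohort at the same underlying success probabilities "
      f"{truth['probabilities']}:")
print(implantation_summary(table).to_string(index=False))
print()
print("Endoscopic implantation succeeds most often and needs the shortest")
print("follow-up, which is why it is the method of choice for building the")
print("orthotopic colon tumour model.")
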