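# Starter exclusion list: preferred terms with no pharmacovigilance reference
# value, terms reflecting the disease under treatment, and medication-error
# terms. Extend per study; this list only seeds the categories.
# -- no reference value
Inability to afford medication
Insurance issues
# -- disease-of-indication
Acute myocardial infarction
Unstable angina
Acute coronary syndrome
# -- medication error
Product name confusion
Intentional product misuse
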