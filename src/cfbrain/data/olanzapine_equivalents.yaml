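# Olanzapine-equivalence factors: mg of olanzapine per mg of drug.
# Derived from published expert-consensus antipsychotic dose equivalents
# (daily doses equivalent to olanzapine 20 mg/day). Editable config data:
# add or adjust entries to match the consensus table in use.
olanzapine: 1.0
risperidone: 3.333
paliperidone: 2.222
haloperidol: 2.0
quetiapine: 0.0267
clozapine: 0.05
aripiprazole: 0.667
ziprasidone: 0.125
amisulpride: 0.0286
chlorpromazine: 0.0333
perphenazine: 0.667
fluphenazine: 2.0
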