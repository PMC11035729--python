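# Curated respiratory, thoracic and mediastinal preferred terms (subgroup view)
Dyspnea
Epistaxis
Asphyxia
Exertional dyspnea
Hemoptysis
Pulmonary edema
Sleep apnea syndrome
A feeling of suffocation
Pulmonary hemorrhage
Tachypnea
Bronchospasm
Orthopnea
Hyperventilation
Dyspnea at rest
Pulmonary alveolar hemorrhage
Respiration abnormal
Apnea
Cheyne-stokes respiration
Acute pulmonary edema
Nocturnal dyspnea
Paroxysmal nocturnal dyspnea
Irregular breathing
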