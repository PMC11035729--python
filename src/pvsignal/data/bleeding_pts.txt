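# Curated haemorrhage-related preferred terms (subgroup view)
Contusion
Hemorrhage
Gastrointestinal hemorrhage
Epistaxis
Anemia
Cerebral hemorrhage
Hemoglobin decreased
Intracranial hemorrhage
Melaena
Rectal hemorrhage
Hematuria
Faces discolored
Hematochezia
Hematoma
Hemoptysis
Upper gastrointestinal hemorrhage
Subdural hematoma
Hemorrhagic stroke
Gastric hemorrhage
Internal hemorrhage
Pulmonary hemorrhage
Pulmonary alveolar hemorrhage
Traumatic intracranial hemorrhage
Retroperitoneal hematoma
Subcutaneous hematoma
Ear hemorrhage
Cerebellar hemorrhage
Gastrointestinal polyp hemorrhage
Spinal cord hematoma
Occult blood
Bleeding time prolonged
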