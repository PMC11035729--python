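# Curated cardiac-disorder preferred terms (subgroup view)
Cardiac arrest
Bradycardia
Atrial fibrillation
Cardio-respiratory arrest
Complete atrioventricular block
Atrioventricular block
Cardiogenic shock
Sinus arrest
Coronary artery stenosis
Pericardial effusion
Ventricular fibrillation
Myocardial ischemia
Ventricular tachycardia
Sinoatrial block
Atrioventricular block second degree
Sinus bradycardia
Ventricular asystole
Cardiac ventricular thrombosis
Cardiac tamponade
Cardiac failure acute
Bradyarrhythmia
Idioventricular rhythm
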