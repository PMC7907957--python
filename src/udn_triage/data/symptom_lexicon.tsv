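weakness	objective
contracture	objective
clonus	objective
hyperreflexia	objective
areflexia	objective
macrocephaly	objective
microcephaly	objective
scoliosis	objective
kyphosis	objective
cyanosis	objective
jaundice	objective
rash	objective
alopecia	objective
clubbing	objective
murmur	objective
bradycardia	objective
tachycardia	objective
hypertension	objective
proteinuria	objective
hematuria	objective
anemia	objective
eosinophilia	objective
hypoglycemia	objective
acidosis	objective
pain	subjective
headache	subjective
dizziness	subjective
nausea	subjective
insomnia	subjective
malaise	subjective
brain fog	subjective
numbness	subjective
tingling	subjective
palpitations	subjective
tinnitus	subjective
photophobia	subjective
pruritus	subjective
anorexia	subjective
weight loss	subjective
night sweats	subjective
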