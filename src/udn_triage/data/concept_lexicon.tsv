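seizures	sign_or_symptom
ataxia	sign_or_symptom
hypotonia	sign_or_symptom
dystonia	sign_or_symptom
tremor	sign_or_symptom
nystagmus	sign_or_symptom
spasticity	sign_or_symptom
dysarthria	sign_or_symptom
dysphagia	sign_or_symptom
fatigue	sign_or_symptom
myalgia	sign_or_symptom
arthralgia	sign_or_symptom
paresthesia	sign_or_symptom
syncope	sign_or_symptom
vertigo	sign_or_symptom
hepatomegaly	sign_or_symptom
splenomegaly	sign_or_symptom
lymphadenopathy	sign_or_symptom
petechiae	sign_or_symptom
edema	sign_or_symptom
biopsy	procedure
electromyography	procedure
echocardiogram	procedure
colonoscopy	procedure
endoscopy	procedure
bronchoscopy	procedure
electroencephalogram	procedure
angiography	procedure
karyotype	procedure
spirometry	procedure
audiometry	procedure
polysomnography	procedure
immunoassay	procedure
tomography	procedure
venipuncture	procedure
lumbar puncture	procedure
exome sequencing	procedure
muscle biopsy	procedure
nerve conduction	procedure
bone scan	procedure
epilepsy	disease_or_syndrome
neuropathy	disease_or_syndrome
myopathy	disease_or_syndrome
cardiomyopathy	disease_or_syndrome
leukodystrophy	disease_or_syndrome
vasculitis	disease_or_syndrome
encephalopathy	disease_or_syndrome
dysautonomia	disease_or_syndrome
osteogenesis	disease_or_syndrome
amyloidosis	disease_or_syndrome
sarcoidosis	disease_or_syndrome
scleroderma	disease_or_syndrome
thrombocytopenia	disease_or_syndrome
pancytopenia	disease_or_syndrome
mastocytosis	disease_or_syndrome
lymphedema	disease_or_syndrome
glycogenosis	disease_or_syndrome
porphyria	disease_or_syndrome
dysplasia	disease_or_syndrome
achalasia	disease_or_syndrome
cerebellum	body_part
brainstem	body_part
hippocampus	body_part
thalamus	body_part
myocardium	body_part
pericardium	body_part
duodenum	body_part
esophagus	body_part
pancreas	body_part
thyroid	body_part
adrenal gland	body_part
spinal cord	body_part
optic nerve	body_part
retina	body_part
cornea	body_part
cochlea	body_part
femur	body_part
vertebrae	body_part
diaphragm	body_part
synovium	body_part
mecp2	gene_or_genome
scn1a	gene_or_genome
pten	gene_or_genome
fbn1	gene_or_genome
col1a1	gene_or_genome
dmd	gene_or_genome
smn1	gene_or_genome
nf1	gene_or_genome
tsc2	gene_or_genome
gba	gene_or_genome
pmp22	gene_or_genome
mitochondrial dna	gene_or_genome
trinucleotide repeat	gene_or_genome
copy number variant	gene_or_genome
de novo mutation	gene_or_genome
missense variant	gene_or_genome
frameshift	gene_or_genome
heterozygous	gene_or_genome
homozygous	gene_or_genome
exon deletion	gene_or_genome
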