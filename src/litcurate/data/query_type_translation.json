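{
  "antihypertensive agent": "treatment",
  "cardiovascular agent": "treatment",
  "drug therapy": "treatment",
  "therapeutic procedure": "treatment",
  "therapeutic or preventive procedure": "treatment",
  "pharmacologic substance": "treatment",
  "diagnostic procedure": "diagnosis",
  "laboratory procedure": "diagnosis",
  "imaging procedure": "diagnosis",
  "diagnostic aid": "diagnosis",
  "prognostic factor": "prognosis",
  "survival analysis": "prognosis",
  "follow-up assessment": "prognosis",
  "risk factor": "etiology",
  "causative agent": "etiology",
  "environmental exposure": "etiology"
}
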