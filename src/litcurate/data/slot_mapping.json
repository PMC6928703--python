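{
  "semantic_types": {
    "population group": "P",
    "age group": "P",
    "patient or disabled group": "P",
    "disease or syndrome": "P",
    "sign or symptom": "P",
    "finding": "P",
    "mental or behavioral dysfunction": "P",
    "anatomical structure": "P",
    "pharmacologic substance": "I",
    "clinical drug": "I",
    "antibiotic": "I",
    "therapeutic or preventive procedure": "I",
    "diagnostic procedure": "I",
    "qualitative concept": "O",
    "quantitative concept": "O",
    "outcome": "O"
  },
  "entity_types": {
    "population": "P",
    "disorder": "P",
    "finding": "P",
    "chemical and drugs": "I",
    "procedure": "I",
    "device": "I",
    "outcome": "O",
    "qualifier": "O"
  },
  "fallback": "P"
}
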