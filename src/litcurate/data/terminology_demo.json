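[
  {
    "entity_type": "population",
    "id": "C0001",
    "name": "female",
    "parents": [],
    "semantic_types": [
      "population group"
    ],
    "synonyms": [
      "woman"
    ]
  },
  {
    "entity_type": "finding",
    "id": "C0002",
    "name": "blood pressure",
    "parents": [],
    "semantic_types": [
      "finding"
    ],
    "synonyms": [
      "arterial tension"
    ]
  },
  {
    "entity_type": "chemical and drugs",
    "id": "C0003",
    "name": "beta-blocker",
    "parents": [
      "C0100"
    ],
    "semantic_types": [
      "pharmacologic substance"
    ],
    "synonyms": [
      "beta adrenergic blocking agent"
    ]
  },
  {
    "entity_type": "chemical and drugs",
    "id": "C0004",
    "name": "angiotensin-converting-enzyme inhibitor",
    "parents": [
      "C0100"
    ],
    "semantic_types": [
      "pharmacologic substance"
    ],
    "synonyms": [
      "ACE inhibitor"
    ]
  },
  {
    "entity_type": "chemical and drugs",
    "id": "C0100",
    "name": "antihypertensive agent",
    "parents": [],
    "semantic_types": [
      "pharmacologic substance"
    ],
    "synonyms": []
  },
  {
    "entity_type": "procedure",
    "id": "C0101",
    "name": "diagnostic procedure",
    "parents": [],
    "semantic_types": [
      "diagnostic procedure"
    ],
    "synonyms": []
  },
  {
    "entity_type": "qualifier",
    "id": "C0102",
    "name": "risk factor",
    "parents": [],
    "semantic_types": [
      "qualitative concept"
    ],
    "synonyms": []
  },
  {
    "entity_type": "qualifier",
    "id": "C0103",
    "name": "prognostic factor",
    "parents": [],
    "semantic_types": [
      "qualitative concept"
    ],
    "synonyms": []
  },
  {
    "entity_type": "disorder",
    "id": "C0200",
    "name": "hypertension",
    "parents": [],
    "semantic_types": [
      "disease or syndrome"
    ],
    "synonyms": [
      "hypertensive disorder"
    ]
  },
  {
    "entity_type": "disorder",
    "id": "C0201",
    "name": "type 2 diabetes mellitus",
    "parents": [],
    "semantic_types": [
      "disease or syndrome"
    ],
    "synonyms": []
  },
  {
    "entity_type": "disorder",
    "id": "C0202",
    "name": "myocardial infarction",
    "parents": [],
    "semantic_types": [
      "disease or syndrome"
    ],
    "synonyms": [
      "heart attack"
    ]
  },
  {
    "entity_type": "disorder",
    "id": "C0203",
    "name": "asthma",
    "parents": [],
    "semantic_types": [
      "disease or syndrome"
    ],
    "synonyms": []
  },
  {
    "entity_type": "disorder",
    "id": "C0204",
    "name": "atrial fibrillation",
    "parents": [],
    "semantic_types": [
      "disease or syndrome"
    ],
    "synonyms": []
  },
  {
    "entity_type": "disorder",
    "id": "C0205",
    "name": "stroke",
    "parents": [],
    "semantic_types": [
      "disease or syndrome"
    ],
    "synonyms": [
      "cerebrovascular accident"
    ]
  },
  {
    "entity_type": "disorder",
    "id": "C0206",
    "name": "chronic kidney disease",
    "parents": [],
    "semantic_types": [
      "disease or syndrome"
    ],
    "synonyms": []
  },
  {
    "entity_type": "disorder",
    "id": "C0207",
    "name": "osteoporosis",
    "parents": [],
    "semantic_types": [
      "disease or syndrome"
    ],
    "synonyms": []
  },
  {
    "entity_type": "disorder",
    "id": "C0208",
    "name": "major depressive disorder",
    "parents": [],
    "semantic_types": [
      "disease or syndrome"
    ],
    "synonyms": []
  },
  {
    "entity_type": "chemical and drugs",
    "id": "C0210",
    "name": "aspirin",
    "parents": [
      "C0211"
    ],
    "semantic_types": [
      "pharmacologic substance"
    ],
    "synonyms": []
  },
  {
    "entity_type": "chemical and drugs",
    "id": "C0211",
    "name": "cardiovascular agent",
    "parents": [],
    "semantic_types": [
      "pharmacologic substance"
    ],
    "synonyms": []
  },
  {
    "entity_type": "chemical and drugs",
    "id": "C0212",
    "name": "metformin",
    "parents": [],
    "semantic_types": [
      "pharmacologic substance"
    ],
    "synonyms": []
  },
  {
    "entity_type": "chemical and drugs",
    "id": "C0213",
    "name": "atorvastatin",
    "parents": [],
    "semantic_types": [
      "pharmacologic substance"
    ],
    "synonyms": []
  },
  {
    "entity_type": "chemical and drugs",
    "id": "C0214",
    "name": "warfarin",
    "parents": [
      "C0211"
    ],
    "semantic_types": [
      "pharmacologic substance"
    ],
    "synonyms": []
  },
  {
    "entity_type": "chemical and drugs",
    "id": "C0215",
    "name": "amoxicillin",
    "parents": [],
    "semantic_types": [
      "pharmacologic substance"
    ],
    "synonyms": []
  },
  {
    "entity_type": "chemical and drugs",
    "id": "C0216",
    "name": "albuterol",
    "parents": [],
    "semantic_types": [
      "pharmacologic substance"
    ],
    "synonyms": [
      "salbutamol"
    ]
  },
  {
    "entity_type": "chemical and drugs",
    "id": "C0217",
    "name": "bisphosphonate",
    "parents": [],
    "semantic_types": [
      "pharmacologic substance"
    ],
    "synonyms": []
  },
  {
    "entity_type": "procedure",
    "id": "C0220",
    "name": "electrocardiography",
    "parents": [
      "C0101"
    ],
    "semantic_types": [
      "diagnostic procedure"
    ],
    "synonyms": [
      "ecg"
    ]
  },
  {
    "entity_type": "procedure",
    "id": "C0221",
    "name": "colonoscopy",
    "parents": [
      "C0101"
    ],
    "semantic_types": [
      "diagnostic procedure"
    ],
    "synonyms": []
  },
  {
    "entity_type": "procedure",
    "id": "C0222",
    "name": "mammography",
    "parents": [
      "C0101"
    ],
    "semantic_types": [
      "diagnostic procedure"
    ],
    "synonyms": []
  },
  {
    "entity_type": "procedure",
    "id": "C0223",
    "name": "serum creatinine measurement",
    "parents": [
      "C0101"
    ],
    "semantic_types": [
      "diagnostic procedure"
    ],
    "synonyms": []
  },
  {
    "entity_type": "finding",
    "id": "C0230",
    "name": "chest pain",
    "parents": [],
    "semantic_types": [
      "finding"
    ],
    "synonyms": []
  },
  {
    "entity_type": "finding",
    "id": "C0231",
    "name": "body mass index",
    "parents": [],
    "semantic_types": [
      "finding"
    ],
    "synonyms": [
      "bmi"
    ]
  },
  {
    "entity_type": "procedure",
    "id": "C0232",
    "name": "smoking cessation",
    "parents": [],
    "semantic_types": [
      "therapeutic or preventive procedure"
    ],
    "synonyms": []
  },
  {
    "entity_type": "procedure",
    "id": "C0233",
    "name": "influenza vaccination",
    "parents": [],
    "semantic_types": [
      "therapeutic or preventive procedure"
    ],
    "synonyms": [
      "flu shot"
    ]
  }
]
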