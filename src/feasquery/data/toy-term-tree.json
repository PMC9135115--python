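[
 {
  "termCode": {
   "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
   "code": "E11",
   "display": "Diabetes mellitus, Type 2"
  },
  "children": [
   {
    "termCode": {
     "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
     "code": "E11.0",
     "display": "Diabetes mellitus, Type 2: with coma"
    },
    "children": []
   },
   {
    "termCode": {
     "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
     "code": "E11.1",
     "display": "Diabetes mellitus, Type 2: with ketoacidosis"
    },
    "children": []
   },
   {
    "termCode": {
     "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
     "code": "E11.2",
     "display": "Diabetes mellitus, Type 2: with kidney complications"
    },
    "children": []
   },
   {
    "termCode": {
     "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
     "code": "E11.3",
     "display": "Diabetes mellitus, Type 2: with ophthalmic complications"
    },
    "children": []
   },
   {
    "termCode": {
     "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
     "code": "E11.4",
     "display": "Diabetes mellitus, Type 2: with neurological complications"
    },
    "children": []
   },
   {
    "termCode": {
     "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
     "code": "E11.5",
     "display": "Diabetes mellitus, Type 2: with peripheral circulatory complications"
    },
    "children": []
   },
   {
    "termCode": {
     "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
     "code": "E11.6",
     "display": "Diabetes mellitus, Type 2: with other specified complications"
    },
    "children": []
   },
   {
    "termCode": {
     "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
     "code": "E11.7",
     "display": "Diabetes mellitus, Type 2: with multiple complications"
    },
    "children": []
   },
   {
    "termCode": {
     "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
     "code": "E11.8",
     "display": "Diabetes mellitus, Type 2: with unspecified complications"
    },
    "children": []
   },
   {
    "termCode": {
     "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
     "code": "E11.9",
     "display": "Diabetes mellitus, Type 2: without complications"
    },
    "children": []
   }
  ]
 },
 {
  "termCode": {
   "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
   "code": "C50",
   "display": "Malignant neoplasm of breast"
  },
  "children": [
   {
    "termCode": {
     "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
     "code": "C50.0",
     "display": "Malignant neoplasm of breast, part 0"
    },
    "children": []
   },
   {
    "termCode": {
     "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
     "code": "C50.1",
     "display": "Malignant neoplasm of breast, part 1"
    },
    "children": []
   },
   {
    "termCode": {
     "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
     "code": "C50.2",
     "display": "Malignant neoplasm of breast, part 2"
    },
    "children": []
   }
  ]
 },
 {
  "termCode": {
   "system": "http://fhir.de/CodeSystem/bfarm/ops",
   "code": "5-78",
   "display": "Operations on bones"
  },
  "children": [
   {
    "termCode": {
     "system": "http://fhir.de/CodeSystem/bfarm/ops",
     "code": "5-787",
     "display": "Removal of osteosynthesis material"
    },
    "children": [
     {
      "termCode": {
       "system": "http://fhir.de/CodeSystem/bfarm/ops",
       "code": "5-787.ex",
       "display": "Removal of osteosynthesis material, example site"
      },
      "children": []
     }
    ]
   }
  ]
 },
 {
  "termCode": {
   "system": "http://loinc.org",
   "code": "55782-7",
   "display": "Beta-2-Microglobulin [Mass/volume] in Serum"
  },
  "children": []
 },
 {
  "termCode": {
   "system": "http://loinc.org",
   "code": "2160-0",
   "display": "Creatinine [Mass/volume] in Serum or Plasma"
  },
  "children": []
 },
 {
  "termCode": {
   "system": "http://hl7.org/fhir/administrative-gender",
   "code": "female",
   "display": "Female"
  },
  "children": []
 },
 {
  "termCode": {
   "system": "http://hl7.org/fhir/administrative-gender",
   "code": "male",
   "display": "Male"
  },
  "children": []
 },
 {
  "termCode": {
   "system": "http://hl7.org/fhir/administrative-gender",
   "code": "other",
   "display": "Other"
  },
  "children": []
 },
 {
  "termCode": {
   "system": "http://hl7.org/fhir/administrative-gender",
   "code": "unknown",
   "display": "Unknown"
  },
  "children": []
 }
]
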