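[
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
   "code": "E11",
   "display": "Diabetes mellitus, Type 2"
  },
  "fhirResourceType": "Condition",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "recorded-date"
 },
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
   "code": "E11.0",
   "display": "Diabetes mellitus, Type 2: with coma"
  },
  "fhirResourceType": "Condition",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "recorded-date"
 },
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
   "code": "E11.1",
   "display": "Diabetes mellitus, Type 2: with ketoacidosis"
  },
  "fhirResourceType": "Condition",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "recorded-date"
 },
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
   "code": "E11.2",
   "display": "Diabetes mellitus, Type 2: with kidney complications"
  },
  "fhirResourceType": "Condition",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "recorded-date"
 },
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
   "code": "E11.3",
   "display": "Diabetes mellitus, Type 2: with ophthalmic complications"
  },
  "fhirResourceType": "Condition",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "recorded-date"
 },
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
   "code": "E11.4",
   "display": "Diabetes mellitus, Type 2: with neurological complications"
  },
  "fhirResourceType": "Condition",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "recorded-date"
 },
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
   "code": "E11.5",
   "display": "Diabetes mellitus, Type 2: with peripheral circulatory complications"
  },
  "fhirResourceType": "Condition",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "recorded-date"
 },
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
   "code": "E11.6",
   "display": "Diabetes mellitus, Type 2: with other specified complications"
  },
  "fhirResourceType": "Condition",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "recorded-date"
 },
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
   "code": "E11.7",
   "display": "Diabetes mellitus, Type 2: with multiple complications"
  },
  "fhirResourceType": "Condition",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "recorded-date"
 },
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
   "code": "E11.8",
   "display": "Diabetes mellitus, Type 2: with unspecified complications"
  },
  "fhirResourceType": "Condition",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "recorded-date"
 },
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
   "code": "E11.9",
   "display": "Diabetes mellitus, Type 2: without complications"
  },
  "fhirResourceType": "Condition",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "recorded-date"
 },
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
   "code": "C50",
   "display": "Malignant neoplasm of breast"
  },
  "fhirResourceType": "Condition",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "recorded-date"
 },
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
   "code": "C50.0",
   "display": "Malignant neoplasm of breast, part 0"
  },
  "fhirResourceType": "Condition",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "recorded-date"
 },
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
   "code": "C50.1",
   "display": "Malignant neoplasm of breast, part 1"
  },
  "fhirResourceType": "Condition",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "recorded-date"
 },
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
   "code": "C50.2",
   "display": "Malignant neoplasm of breast, part 2"
  },
  "fhirResourceType": "Condition",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "recorded-date"
 },
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/ops",
   "code": "5-78",
   "display": "Operations on bones"
  },
  "fhirResourceType": "Procedure",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "date"
 },
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/ops",
   "code": "5-787",
   "display": "Removal of osteosynthesis material"
  },
  "fhirResourceType": "Procedure",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "date"
 },
 {
  "key": {
   "system": "http://fhir.de/CodeSystem/bfarm/ops",
   "code": "5-787.ex",
   "display": "Removal of osteosynthesis material, example site"
  },
  "fhirResourceType": "Procedure",
  "termCodeSearchParameter": "code",
  "timeRestrictionParameter": "date"
 },
 {
  "key": {
   "system": "http://loinc.org",
   "code": "55782-7",
   "display": "Beta-2-Microglobulin [Mass/volume] in Serum"
  },
  "fhirResourceType": "Observation",
  "termCodeSearchParameter": "code",
  "valueSearchParameter": "value-quantity",
  "timeRestrictionParameter": "date"
 },
 {
  "key": {
   "system": "http://loinc.org",
   "code": "2160-0",
   "display": "Creatinine [Mass/volume] in Serum or Plasma"
  },
  "fhirResourceType": "Observation",
  "termCodeSearchParameter": "code",
  "valueSearchParameter": "value-quantity",
  "timeRestrictionParameter": "date"
 },
 {
  "key": {
   "system": "http://hl7.org/fhir/administrative-gender",
   "code": "female",
   "display": "Female"
  },
  "fhirResourceType": "Patient",
  "termCodeSearchParameter": "gender",
  "tokenForm": "code"
 },
 {
  "key": {
   "system": "http://hl7.org/fhir/administrative-gender",
   "code": "male",
   "display": "Male"
  },
  "fhirResourceType": "Patient",
  "termCodeSearchParameter": "gender",
  "tokenForm": "code"
 },
 {
  "key": {
   "system": "http://hl7.org/fhir/administrative-gender",
   "code": "other",
   "display": "Other"
  },
  "fhirResourceType": "Patient",
  "termCodeSearchParameter": "gender",
  "tokenForm": "code"
 },
 {
  "key": {
   "system": "http://hl7.org/fhir/administrative-gender",
   "code": "unknown",
   "display": "Unknown"
  },
  "fhirResourceType": "Patient",
  "termCodeSearchParameter": "gender",
  "tokenForm": "code"
 }
]
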