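{
  "scenario": 1,
  "synthetic": true,
  "note": "synthetic reconstruction of a screening scenario: criteria met through the proband's own history",
  "pedigree": {
    "proband_id": "R01",
    "persons": [
      {
        "person_id": "R01",
        "sex": "female",
        "alive": "alive",
        "age_years": 45,
        "mother_id": "R07",
        "father_id": "R06",
        "diagnoses": [
          {
            "site": "breast",
            "age_at_diagnosis": 43,
            "primary_index": 1
          }
        ],
        "is_proband": true
      },
      {
        "person_id": "R02",
        "sex": "male",
        "alive": "deceased",
        "age_years": 84,
        "mother_id": null,
        "father_id": null,
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R03",
        "sex": "female",
        "alive": "deceased",
        "age_years": 88,
        "mother_id": null,
        "father_id": null,
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R04",
        "sex": "male",
        "alive": "deceased",
        "age_years": 79,
        "mother_id": null,
        "father_id": null,
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R05",
        "sex": "female",
        "alive": "deceased",
        "age_years": 91,
        "mother_id": null,
        "father_id": null,
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R06",
        "sex": "male",
        "alive": "alive",
        "age_years": 72,
        "mother_id": "R03",
        "father_id": "R02",
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R07",
        "sex": "female",
        "alive": "alive",
        "age_years": 70,
        "mother_id": "R05",
        "father_id": "R04",
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R08",
        "sex": "female",
        "alive": "alive",
        "age_years": 48,
        "mother_id": "R07",
        "father_id": "R06",
        "diagnoses": [],
        "is_proband": false
      }
    ]
  },
  "expected": {
    "overall": true,
    "met_criteria": [
      "A1"
    ]
  },
  "answers": [
    "female",
    "45",
    "deceased",
    "84",
    "deceased",
    "88",
    "deceased",
    "79",
    "deceased",
    "91",
    "alive",
    "72",
    "alive",
    "70",
    "0",
    "0",
    "1",
    "female",
    "alive",
    "48",
    "0",
    "0",
    "yes",
    "breast",
    "43",
    "no",
    "no",
    "no",
    "no",
    "no",
    "no",
    "no",
    "no"
  ]
}
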