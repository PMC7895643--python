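{
  "scenario": 2,
  "synthetic": true,
  "note": "synthetic reconstruction of a screening scenario: criteria met through family history only",
  "pedigree": {
    "proband_id": "R01",
    "persons": [
      {
        "person_id": "R01",
        "sex": "female",
        "alive": "alive",
        "age_years": 52,
        "mother_id": "R07",
        "father_id": "R06",
        "diagnoses": [],
        "is_proband": true
      },
      {
        "person_id": "R02",
        "sex": "male",
        "alive": "deceased",
        "age_years": 86,
        "mother_id": null,
        "father_id": null,
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R03",
        "sex": "female",
        "alive": "alive",
        "age_years": 94,
        "mother_id": null,
        "father_id": null,
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R04",
        "sex": "male",
        "alive": "deceased",
        "age_years": 81,
        "mother_id": null,
        "father_id": null,
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R05",
        "sex": "female",
        "alive": "deceased",
        "age_years": 77,
        "mother_id": null,
        "father_id": null,
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R06",
        "sex": "male",
        "alive": "alive",
        "age_years": 78,
        "mother_id": "R03",
        "father_id": "R02",
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R07",
        "sex": "female",
        "alive": "alive",
        "age_years": 74,
        "mother_id": "R05",
        "father_id": "R04",
        "diagnoses": [
          {
            "site": "ovarian",
            "age_at_diagnosis": 61,
            "primary_index": 1
          }
        ],
        "is_proband": false
      },
      {
        "person_id": "R08",
        "sex": "female",
        "alive": "alive",
        "age_years": 75,
        "mother_id": "R03",
        "father_id": "R02",
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R09",
        "sex": "male",
        "alive": "alive",
        "age_years": 49,
        "mother_id": "R07",
        "father_id": "R06",
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R10",
        "sex": "female",
        "alive": "alive",
        "age_years": 26,
        "mother_id": "R01",
        "father_id": null,
        "diagnoses": [],
        "is_proband": false
      }
    ]
  },
  "expected": {
    "overall": true,
    "met_criteria": [
      "A7"
    ]
  },
  "answers": [
    "female",
    "52",
    "deceased",
    "86",
    "alive",
    "94",
    "deceased",
    "81",
    "deceased",
    "77",
    "alive",
    "78",
    "alive",
    "74",
    "1",
    "female",
    "alive",
    "75",
    "0",
    "0",
    "1",
    "male",
    "alive",
    "49",
    "1",
    "female",
    "alive",
    "26",
    "0",
    "no",
    "no",
    "no",
    "no",
    "no",
    "no",
    "yes",
    "ovarian",
    "61",
    "no",
    "no",
    "no",
    "no"
  ]
}
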