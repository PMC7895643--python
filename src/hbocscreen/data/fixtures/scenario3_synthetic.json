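{
  "scenario": 3,
  "synthetic": true,
  "note": "synthetic reconstruction of a screening scenario: sporadic-looking history; no active criterion met",
  "pedigree": {
    "proband_id": "R01",
    "persons": [
      {
        "person_id": "R01",
        "sex": "female",
        "alive": "alive",
        "age_years": 55,
        "mother_id": "R07",
        "father_id": "R06",
        "diagnoses": [
          {
            "site": "breast",
            "age_at_diagnosis": 54,
            "primary_index": 1
          }
        ],
        "is_proband": true
      },
      {
        "person_id": "R02",
        "sex": "male",
        "alive": "deceased",
        "age_years": 82,
        "mother_id": null,
        "father_id": null,
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R03",
        "sex": "female",
        "alive": "alive",
        "age_years": 92,
        "mother_id": null,
        "father_id": null,
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R04",
        "sex": "male",
        "alive": "deceased",
        "age_years": 85,
        "mother_id": null,
        "father_id": null,
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R05",
        "sex": "female",
        "alive": "deceased",
        "age_years": 85,
        "mother_id": null,
        "father_id": null,
        "diagnoses": [
          {
            "site": "other",
            "age_at_diagnosis": 80,
            "primary_index": 1
          }
        ],
        "is_proband": false
      },
      {
        "person_id": "R06",
        "sex": "male",
        "alive": "alive",
        "age_years": 80,
        "mother_id": "R03",
        "father_id": "R02",
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R07",
        "sex": "female",
        "alive": "alive",
        "age_years": 78,
        "mother_id": "R05",
        "father_id": "R04",
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R08",
        "sex": "female",
        "alive": "alive",
        "age_years": 77,
        "mother_id": "R03",
        "father_id": "R02",
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R09",
        "sex": "male",
        "alive": "alive",
        "age_years": 74,
        "mother_id": "R05",
        "father_id": "R04",
        "diagnoses": [],
        "is_proband": false
      },
      {
        "person_id": "R10",
        "sex": "male",
        "alive": "alive",
        "age_years": 28,
        "mother_id": "R01",
        "father_id": null,
        "diagnoses": [],
        "is_proband": false
      }
    ]
  },
  "expected": {
    "overall": false,
    "met_criteria": []
  },
  "answers": [
    "female",
    "55",
    "deceased",
    "82",
    "alive",
    "92",
    "deceased",
    "85",
    "deceased",
    "85",
    "alive",
    "80",
    "alive",
    "78",
    "1",
    "female",
    "alive",
    "77",
    "1",
    "male",
    "alive",
    "74",
    "0",
    "0",
    "0",
    "1",
    "male",
    "alive",
    "28",
    "yes",
    "breast",
    "54",
    "no",
    "no",
    "no",
    "no",
    "yes",
    "other",
    "80",
    "no",
    "no",
    "no",
    "no",
    "no",
    "no"
  ]
}
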