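{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://example.org/hbocscreen/pedigree.schema.json",
  "title": "Pedigree document",
  "description": "Proband-anchored family graph for HBOC preliminary screening. Unknown values are encoded as null.",
  "type": "object",
  "required": ["proband_id", "persons"],
  "properties": {
    "proband_id": {"type": "string"},
    "persons": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["person_id", "sex", "alive", "age_years", "mother_id", "father_id", "diagnoses", "is_proband"],
        "properties": {
          "person_id": {"type": "string"},
          "sex": {"enum": ["female", "male", "unknown"]},
          "alive": {"enum": ["alive", "deceased", "unknown"]},
          "age_years": {"type": ["integer", "null"], "minimum": 0, "maximum": 130},
          "mother_id": {"type": ["string", "null"]},
          "father_id": {"type": ["string", "null"]},
          "is_proband": {"type": "boolean"},
          "cancer_history_known": {"type": "boolean"},
          "diagnoses": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["site", "age_at_diagnosis", "primary_index"],
              "properties": {
                "site": {"enum": ["breast", "ovarian", "pancreatic", "prostate", "other"]},
                "age_at_diagnosis": {"type": ["integer", "null"], "minimum": 0, "maximum": 130},
                "primary_index": {"type": "integer", "minimum": 1}
              }
            }
          }
        }
      }
    }
  }
}
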