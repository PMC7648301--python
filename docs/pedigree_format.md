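# Pedigree interchange format (`fhh-pedigree/1`)

One JSON document per proband. The schema is enforced by the pydantic
models in `fhhrisk.pedigree` (`parse_pedigree` raises a `ParseError`
naming the offending path, or a `VocabularyError` for unknown relation or
condition codes); unknown extra fields are preserved through a
parse → serialise round trip.

```json
{
  "schema_version": "fhh-pedigree/1",
  "proband": {
    "relation_code": "self",
    "sex": "female",
    "alive": true,
    "current_age": 45,
    "race_ethnicity": "white",
    "ashkenazi": false,
    "consanguinity": false,
    "conditions": []
  },
  "relatives": [
    {
      "relation_code": "mother",
      "alive": true,
      "current_age": 70,
      "twin_status": "none",
      "history_known": true,
      "conditions": [
        {"condition_code": "breast_cancer", "age_of_onset": 41}
      ]
    }
  ]
}
```

## Fields

| Field | Type | Notes |
|---|---|---|
| `relation_code` | string | closed vocabulary below; determines degree, side of family and (mostly) sex |
| `sex` | `male` / `female` / `unknown` | required for entered relatives where the code does not imply it (cousins); codes that imply a sex are enforced |
| `alive` | bool | if true, `current_age` must be set and `age_at_death` absent; if false, `age_at_death` (+ `cause_of_death` for full quality) |
| `current_age`, `age_at_death` | years, 0–120 | exactly one populated when vital status is known |
| `twin_status` | `none` / `identical` / `fraternal` | stored and exported; not modelled in the likelihood |
| `history_known` | bool | false ⇒ the relative contributes structure but no phenotype information |
| `conditions[]` | list | `condition_code` from the loaded catalog (27 risk-assessed codes) or `other:<free text>`; `age_of_onset` optional, must not exceed the current/death age |

Proband extras: `race_ethnicity`, `ashkenazi` (selects the Ashkenazi
allele-frequency stratum), `consanguinity` (stored and surfaced; loops are
not modelled).

## Relation vocabulary

`self`; `mother`, `father`, `sister`, `brother`, `daughter`, `son` (first
degree); `maternal/paternal grandmother/grandfather`, `maternal/paternal
aunt/uncle`, `niece`, `nephew`, `granddaughter`, `grandson`,
`maternal/paternal half-sister/half-brother` (second degree);
`maternal/paternal cousin` (third degree). Singleton slots (`self`,
parents, the four grandparents) may appear at most once. Relatives outside
this list are rejected rather than guessed — Mendelian expansion requires
unambiguous codes.

## PED export

`write_ped` emits LINKAGE/PED text: `family_id individual_id father_id
mother_id sex affection` per row, whitespace-delimited, `0` for missing
parents, sex `1`=male / `2`=female / `0`=unknown, affection `0`=unknown
(history not known), `1`=unaffected, `2`=affected for the chosen condition.
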