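{
  "form_id": "pneumonia_v1",
  "condition_label": "pediatric pneumonia",
  "sections": [
    {
      "section_kind": "true_false_I",
      "elements": [
        {
          "element_id": "tf1_fever",
          "label": "Patient had fever",
          "element_kind": "true_false",
          "source_doc_type": "admission_record",
          "binding": {"concept_id": "SYN:0105"}
        },
        {
          "element_id": "tf1_wheezing",
          "label": "Patient had wheezing",
          "element_kind": "true_false",
          "source_doc_type": "admission_record",
          "binding": {"concept_id": "SYN:0108"}
        },
        {
          "element_id": "tf1_feeding",
          "label": "Patient had feeding difficulty",
          "element_kind": "true_false",
          "source_doc_type": "admission_record",
          "binding": {"concept_id": "SYN:0107"}
        }
      ]
    },
    {
      "section_kind": "true_false_II",
      "elements": [
        {
          "element_id": "tf2_consolidation",
          "label": "Pulmonary consolidation present on imaging",
          "element_kind": "true_false",
          "source_doc_type": "imaging_report",
          "binding": {"concept_id": "SYN:0109"}
        },
        {
          "element_id": "tf2_effusion",
          "label": "Pleural effusion present on imaging",
          "element_kind": "true_false",
          "source_doc_type": "imaging_report",
          "binding": {"concept_id": "SYN:0110"}
        }
      ]
    },
    {
      "section_kind": "multiple_choice",
      "elements": [
        {
          "element_id": "mc_chief",
          "label": "Chief complaints of the patient",
          "element_kind": "multiple_choice",
          "source_doc_type": "admission_record",
          "binding": {
            "options": [
              ["cough", "SYN:0106"],
              ["dyspnea", "SYN:0104"],
              ["cyanosis", "SYN:0103"]
            ]
          }
        }
      ]
    }
  ]
}
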