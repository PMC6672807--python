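{
  "form_id": "chd_v1",
  "condition_label": "pediatric congenital heart disease",
  "sections": [
    {
      "section_kind": "true_false_I",
      "elements": [
        {
          "element_id": "tf1_consciousness",
          "label": "Patient had a disturbance of consciousness",
          "element_kind": "true_false",
          "source_doc_type": "admission_record",
          "binding": {"concept_id": "SCT:3006004"}
        },
        {
          "element_id": "tf1_fever",
          "label": "Patient had fever",
          "element_kind": "true_false",
          "source_doc_type": "admission_record",
          "binding": {"concept_id": "SYN:0105"}
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
          "element_id": "tf2_vsd",
          "label": "Ventricular septal defect present on imaging",
          "element_kind": "true_false",
          "source_doc_type": "imaging_report",
          "binding": {"concept_id": "RID3277"}
        },
        {
          "element_id": "tf2_asd",
          "label": "Atrial septal defect present on imaging",
          "element_kind": "true_false",
          "source_doc_type": "imaging_report",
          "binding": {"concept_id": "SYN:0101"}
        },
        {
          "element_id": "tf2_pda",
          "label": "Patent ductus arteriosus present on imaging",
          "element_kind": "true_false",
          "source_doc_type": "imaging_report",
          "binding": {"concept_id": "SYN:0102"}
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
              ["cardiac murmur", "SCT:42842009"],
              ["cyanosis", "SYN:0103"],
              ["dyspnea", "SYN:0104"]
            ]
          }
        }
      ]
    },
    {
      "section_kind": "fill_in_blank",
      "elements": [
        {
          "element_id": "fib_vsd_size",
          "label": "The lesion size of ventricular septal defect is ___ cm",
          "element_kind": "fill_in_blank",
          "source_doc_type": "imaging_report",
          "binding": {
            "observable_concept_id": "SCT:246116008",
            "related_problem_concept_id": "RID3277",
            "expected_unit": "cm"
          }
        }
      ]
    }
  ]
}
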