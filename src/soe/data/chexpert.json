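{
  "name": "CheXpert",
  "is_label": false,
  "children": [
    {"name": "No Finding", "is_label": true},
    {"name": "Support Devices", "is_label": true},
    {"name": "Fracture", "is_label": true},
    {
      "name": "Enlarged Cardiomediastinum",
      "is_label": true,
      "children": [
        {"name": "Cardiomegaly", "is_label": true}
      ]
    },
    {
      "name": "Lung Opacity",
      "is_label": true,
      "children": [
        {"name": "Lung Lesion", "is_label": true},
        {"name": "Edema", "is_label": true},
        {"name": "Consolidation", "is_label": true},
        {"name": "Pneumonia", "is_label": true},
        {"name": "Atelectasis", "is_label": true},
        {"name": "Pneumothorax", "is_label": true},
        {"name": "Pleural Effusion", "is_label": true},
        {"name": "Pleural Other", "is_label": true}
      ]
    }
  ]
}
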