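{
  "allergies": ["allergy", "allergies", "allergic"],
  "alzheimers": ["alzheimer", "alzheimers"],
  "anemia": ["anemia", "anemic"],
  "arthritis": ["arthritis"],
  "asthma": ["asthma"],
  "bronchitis": ["bronchitis"],
  "cancer": ["cancer", "cancers"],
  "cholesterol": ["cholesterol"],
  "dementia": ["dementia"],
  "depression": ["depression", "depressed"],
  "diabetes": ["diabetes", "diabetic"],
  "down_syndrome": ["down syndrome", "downs syndrome"],
  "epilepsy": ["epilepsy", "epileptic"],
  "heart_attack": ["heart attack", "heart attacks"],
  "heart_disease": ["heart disease"],
  "hiv": ["hiv"],
  "hypertension": ["hypertension", "high blood pressure"],
  "influenza": ["flu", "influenza"],
  "insomnia": ["insomnia"],
  "kidney_stones": ["kidney stone", "kidney stones"],
  "leukemia": ["leukemia"],
  "lymphoma": ["lymphoma"],
  "malaria": ["malaria"],
  "migraine": ["migraine", "migraines"],
  "miscarriage": ["miscarriage", "miscarriages"],
  "obesity": ["obesity", "obese"],
  "parkinsons": ["parkinson", "parkinsons"],
  "pneumonia": ["pneumonia"],
  "schizophrenia": ["schizophrenia", "schizophrenic"],
  "smallpox": ["smallpox"],
  "stroke": ["stroke", "strokes"],
  "thyroid": ["thyroid"],
  "tuberculosis": ["tuberculosis"],
  "ulcer": ["ulcer", "ulcers"]
}
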