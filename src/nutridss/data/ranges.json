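{
 "version": "1.0",
 "provenance": "Default adult reference intervals assembled from commonly used laboratory standards; replace per local laboratory. The 1600 kcal/day intake reference is the minimum recommended for adequate macro- and micronutrient intake after bariatric surgery.",
 "intake_threshold_kcal": 1600,
 "portion_kcal": {
  "grains": 150,
  "vegetables": 25,
  "fruits": 60,
  "dairy": 120,
  "meat_beans": 150,
  "fats_oils": 45,
  "sweets": 110
 },
 "surgery_time_bands": [
  {"state": "under_6mo", "min_months": 0, "max_months": 6},
  {"state": "6mo_to_2y", "min_months": 6, "max_months": 24},
  {"state": "over_2y", "min_months": 24, "max_months": null}
 ],
 "markers": {
  "hemoglobin": {"unit": "g/dL", "bounds": {"female": [12.0, 16.0], "male": [13.5, 17.5]}},
  "hematocrit": {"unit": "%", "bounds": {"female": [36.0, 46.0], "male": [41.0, 53.0]}},
  "mcv": {"unit": "fL", "bounds": {"any": [80.0, 100.0]}},
  "albumin": {"unit": "g/dL", "bounds": {"any": [3.5, 5.2]}},
  "ferritin": {"unit": "ng/mL", "bounds": {"female": [12.0, 150.0], "male": [15.0, 200.0]}},
  "vitamin_b12": {"unit": "pg/mL", "bounds": {"any": [200.0, 900.0]}},
  "folic_acid": {"unit": "ng/mL", "bounds": {"any": [3.0, 17.0]}}
 }
}
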