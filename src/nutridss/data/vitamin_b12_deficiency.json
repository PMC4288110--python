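{
 "name": "vitamin_b12_deficiency",
 "version": "1.0",
 "nodes": [
  {
   "name": "intake",
   "states": [
    "adequate",
    "inadequate"
   ],
   "parents": [],
   "cpt": [
    {
     "given": {},
     "dist": {
      "adequate": 0.55,
      "inadequate": 0.45
     }
    }
   ]
  },
  {
   "name": "surgery_time",
   "states": [
    "under_6mo",
    "6mo_to_2y",
    "over_2y"
   ],
   "parents": [],
   "cpt": [
    {
     "given": {},
     "dist": {
      "under_6mo": 0.2,
      "6mo_to_2y": 0.4,
      "over_2y": 0.4
     }
    }
   ]
  },
  {
   "name": "vitamin_b12_deficiency",
   "states": [
    "present",
    "at_risk",
    "absent"
   ],
   "parents": [
    "intake",
    "surgery_time"
   ],
   "cpt": [
    {
     "given": {
      "intake": "adequate",
      "surgery_time": "under_6mo"
     },
     "dist": {
      "present": 0.02,
      "at_risk": 0.1,
      "absent": 0.88
     }
    },
    {
     "given": {
      "intake": "adequate",
      "surgery_time": "6mo_to_2y"
     },
     "dist": {
      "present": 0.05,
      "at_risk": 0.2,
      "absent": 0.75
     }
    },
    {
     "given": {
      "intake": "adequate",
      "surgery_time": "over_2y"
     },
     "dist": {
      "present": 0.1,
      "at_risk": 0.3,
      "absent": 0.6
     }
    },
    {
     "given": {
      "intake": "inadequate",
      "surgery_time": "under_6mo"
     },
     "dist": {
      "present": 0.05,
      "at_risk": 0.2,
      "absent": 0.75
     }
    },
    {
     "given": {
      "intake": "inadequate",
      "surgery_time": "6mo_to_2y"
     },
     "dist": {
      "present": 0.12,
      "at_risk": 0.33,
      "absent": 0.55
     }
    },
    {
     "given": {
      "intake": "inadequate",
      "surgery_time": "over_2y"
     },
     "dist": {
      "present": 0.25,
      "at_risk": 0.4,
      "absent": 0.35
     }
    }
   ]
  },
  {
   "name": "vitamin_b12",
   "states": [
    "low",
    "normal",
    "high"
   ],
   "parents": [
    "vitamin_b12_deficiency"
   ],
   "cpt": [
    {
     "given": {
      "vitamin_b12_deficiency": "present"
     },
     "dist": {
      "low": 0.85,
      "normal": 0.14,
      "high": 0.01
     }
    },
    {
     "given": {
      "vitamin_b12_deficiency": "at_risk"
     },
     "dist": {
      "low": 0.3,
      "normal": 0.67,
      "high": 0.03
     }
    },
    {
     "given": {
      "vitamin_b12_deficiency": "absent"
     },
     "dist": {
      "low": 0.03,
      "normal": 0.94,
      "high": 0.03
     }
    }
   ]
  },
  {
   "name": "mcv",
   "states": [
    "low",
    "normal",
    "high"
   ],
   "parents": [
    "vitamin_b12_deficiency"
   ],
   "cpt": [
    {
     "given": {
      "vitamin_b12_deficiency": "present"
     },
     "dist": {
      "low": 0.06,
      "normal": 0.76,
      "high": 0.18
     }
    },
    {
     "given": {
      "vitamin_b12_deficiency": "at_risk"
     },
     "dist": {
      "low": 0.07,
      "normal": 0.81,
      "high": 0.12
     }
    },
    {
     "given": {
      "vitamin_b12_deficiency": "absent"
     },
     "dist": {
      "low": 0.08,
      "normal": 0.84,
      "high": 0.08
     }
    }
   ]
  },
  {
   "name": "paresthesia",
   "states": [
    "absent",
    "present"
   ],
   "parents": [
    "vitamin_b12_deficiency"
   ],
   "cpt": [
    {
     "given": {
      "vitamin_b12_deficiency": "present"
     },
     "dist": {
      "absent": 0.7,
      "present": 0.3
     }
    },
    {
     "given": {
      "vitamin_b12_deficiency": "at_risk"
     },
     "dist": {
      "absent": 0.78,
      "present": 0.22
     }
    },
    {
     "given": {
      "vitamin_b12_deficiency": "absent"
     },
     "dist": {
      "absent": 0.85,
      "present": 0.15
     }
    }
   ]
  }
 ],
 "metadata": {
  "provenance": "All conditional probabilities are placeholders: weakly informative, literature-plausible values authored for this implementation and marked for replacement by expert-elicited or literature-derived numbers. They are not calibrated to any clinical dataset.",
  "cpt_provenance": "placeholder",
  "description": "Vitamin B12 deficiency: body stores deplete over years after bypass of the terminal-ileum absorption pathway; risk grows with time since surgery and inadequate intake; read off serum B12, macrocytosis (MCV) and paresthesia."
 }
}
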