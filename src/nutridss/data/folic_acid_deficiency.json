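{
 "name": "folic_acid_deficiency",
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
   "name": "folic_acid_deficiency",
   "states": [
    "present",
    "at_risk",
    "absent"
   ],
   "parents": [
    "intake"
   ],
   "cpt": [
    {
     "given": {
      "intake": "adequate"
     },
     "dist": {
      "present": 0.04,
      "at_risk": 0.16,
      "absent": 0.8
     }
    },
    {
     "given": {
      "intake": "inadequate"
     },
     "dist": {
      "present": 0.18,
      "at_risk": 0.42,
      "absent": 0.4
     }
    }
   ]
  },
  {
   "name": "folic_acid",
   "states": [
    "low",
    "normal",
    "high"
   ],
   "parents": [
    "folic_acid_deficiency"
   ],
   "cpt": [
    {
     "given": {
      "folic_acid_deficiency": "present"
     },
     "dist": {
      "low": 0.85,
      "normal": 0.14,
      "high": 0.01
     }
    },
    {
     "given": {
      "folic_acid_deficiency": "at_risk"
     },
     "dist": {
      "low": 0.3,
      "normal": 0.67,
      "high": 0.03
     }
    },
    {
     "given": {
      "folic_acid_deficiency": "absent"
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
    "folic_acid_deficiency"
   ],
   "cpt": [
    {
     "given": {
      "folic_acid_deficiency": "present"
     },
     "dist": {
      "low": 0.06,
      "normal": 0.76,
      "high": 0.18
     }
    },
    {
     "given": {
      "folic_acid_deficiency": "at_risk"
     },
     "dist": {
      "low": 0.07,
      "normal": 0.81,
      "high": 0.12
     }
    },
    {
     "given": {
      "folic_acid_deficiency": "absent"
     },
     "dist": {
      "low": 0.08,
      "normal": 0.84,
      "high": 0.08
     }
    }
   ]
  }
 ],
 "metadata": {
  "provenance": "All conditional probabilities are placeholders: weakly informative, literature-plausible values authored for this implementation and marked for replacement by expert-elicited or literature-derived numbers. They are not calibrated to any clinical dataset.",
  "cpt_provenance": "placeholder",
  "description": "Folic acid deficiency: dominated by dietary adequacy (folate stores last only months); read off serum folate and macrocytosis."
 }
}
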