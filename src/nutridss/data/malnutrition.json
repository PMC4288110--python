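{
 "name": "malnutrition",
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
   "name": "diarrhea",
   "states": [
    "absent",
    "present"
   ],
   "parents": [],
   "cpt": [
    {
     "given": {},
     "dist": {
      "absent": 0.75,
      "present": 0.25
     }
    }
   ]
  },
  {
   "name": "malnutrition",
   "states": [
    "present",
    "at_risk",
    "absent"
   ],
   "parents": [
    "intake",
    "diarrhea"
   ],
   "cpt": [
    {
     "given": {
      "intake": "adequate",
      "diarrhea": "absent"
     },
     "dist": {
      "present": 0.03,
      "at_risk": 0.12,
      "absent": 0.85
     }
    },
    {
     "given": {
      "intake": "adequate",
      "diarrhea": "present"
     },
     "dist": {
      "present": 0.08,
      "at_risk": 0.27,
      "absent": 0.65
     }
    },
    {
     "given": {
      "intake": "inadequate",
      "diarrhea": "absent"
     },
     "dist": {
      "present": 0.15,
      "at_risk": 0.4,
      "absent": 0.45
     }
    },
    {
     "given": {
      "intake": "inadequate",
      "diarrhea": "present"
     },
     "dist": {
      "present": 0.3,
      "at_risk": 0.45,
      "absent": 0.25
     }
    }
   ]
  },
  {
   "name": "albumin",
   "states": [
    "low",
    "normal",
    "high"
   ],
   "parents": [
    "malnutrition"
   ],
   "cpt": [
    {
     "given": {
      "malnutrition": "present"
     },
     "dist": {
      "low": 0.8,
      "normal": 0.19,
      "high": 0.01
     }
    },
    {
     "given": {
      "malnutrition": "at_risk"
     },
     "dist": {
      "low": 0.3,
      "normal": 0.67,
      "high": 0.03
     }
    },
    {
     "given": {
      "malnutrition": "absent"
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
   "name": "hair_loss",
   "states": [
    "absent",
    "present"
   ],
   "parents": [
    "malnutrition"
   ],
   "cpt": [
    {
     "given": {
      "malnutrition": "present"
     },
     "dist": {
      "absent": 0.25,
      "present": 0.75
     }
    },
    {
     "given": {
      "malnutrition": "at_risk"
     },
     "dist": {
      "absent": 0.5,
      "present": 0.5
     }
    },
    {
     "given": {
      "malnutrition": "absent"
     },
     "dist": {
      "absent": 0.7,
      "present": 0.3
     }
    }
   ]
  },
  {
   "name": "nail_skin_changes",
   "states": [
    "absent",
    "present"
   ],
   "parents": [
    "malnutrition"
   ],
   "cpt": [
    {
     "given": {
      "malnutrition": "present"
     },
     "dist": {
      "absent": 0.35,
      "present": 0.65
     }
    },
    {
     "given": {
      "malnutrition": "at_risk"
     },
     "dist": {
      "absent": 0.65,
      "present": 0.35
     }
    },
    {
     "given": {
      "malnutrition": "absent"
     },
     "dist": {
      "absent": 0.88,
      "present": 0.12
     }
    }
   ]
  },
  {
   "name": "weakness",
   "states": [
    "absent",
    "present"
   ],
   "parents": [
    "malnutrition"
   ],
   "cpt": [
    {
     "given": {
      "malnutrition": "present"
     },
     "dist": {
      "absent": 0.55,
      "present": 0.45
     }
    },
    {
     "given": {
      "malnutrition": "at_risk"
     },
     "dist": {
      "absent": 0.65,
      "present": 0.35
     }
    },
    {
     "given": {
      "malnutrition": "absent"
     },
     "dist": {
      "absent": 0.75,
      "present": 0.25
     }
    }
   ]
  }
 ],
 "metadata": {
  "provenance": "All conditional probabilities are placeholders: weakly informative, literature-plausible values authored for this implementation and marked for replacement by expert-elicited or literature-derived numbers. They are not calibrated to any clinical dataset.",
  "cpt_provenance": "placeholder",
  "description": "Protein-energy malnutrition: inadequate intake and losses (diarrhea) drive it; read off serum albumin, hair loss, nail/skin changes and weakness."
 }
}
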