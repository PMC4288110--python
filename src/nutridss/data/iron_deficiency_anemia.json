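{
 "name": "iron_deficiency_anemia",
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
   "name": "blood_loss",
   "states": [
    "absent",
    "present"
   ],
   "parents": [],
   "cpt": [
    {
     "given": {},
     "dist": {
      "absent": 0.85,
      "present": 0.15
     }
    }
   ]
  },
  {
   "name": "iron_deficiency_anemia",
   "states": [
    "present",
    "at_risk",
    "absent"
   ],
   "parents": [
    "intake",
    "blood_loss"
   ],
   "cpt": [
    {
     "given": {
      "intake": "adequate",
      "blood_loss": "absent"
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
      "blood_loss": "present"
     },
     "dist": {
      "present": 0.2,
      "at_risk": 0.35,
      "absent": 0.45
     }
    },
    {
     "given": {
      "intake": "inadequate",
      "blood_loss": "absent"
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
      "blood_loss": "present"
     },
     "dist": {
      "present": 0.35,
      "at_risk": 0.4,
      "absent": 0.25
     }
    }
   ]
  },
  {
   "name": "hemoglobin",
   "states": [
    "low",
    "normal",
    "high"
   ],
   "parents": [
    "iron_deficiency_anemia"
   ],
   "cpt": [
    {
     "given": {
      "iron_deficiency_anemia": "present"
     },
     "dist": {
      "low": 0.85,
      "normal": 0.14,
      "high": 0.01
     }
    },
    {
     "given": {
      "iron_deficiency_anemia": "at_risk"
     },
     "dist": {
      "low": 0.3,
      "normal": 0.67,
      "high": 0.03
     }
    },
    {
     "given": {
      "iron_deficiency_anemia": "absent"
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
   "name": "hematocrit",
   "states": [
    "low",
    "normal",
    "high"
   ],
   "parents": [
    "iron_deficiency_anemia"
   ],
   "cpt": [
    {
     "given": {
      "iron_deficiency_anemia": "present"
     },
     "dist": {
      "low": 0.8,
      "normal": 0.19,
      "high": 0.01
     }
    },
    {
     "given": {
      "iron_deficiency_anemia": "at_risk"
     },
     "dist": {
      "low": 0.28,
      "normal": 0.69,
      "high": 0.03
     }
    },
    {
     "given": {
      "iron_deficiency_anemia": "absent"
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
    "iron_deficiency_anemia"
   ],
   "cpt": [
    {
     "given": {
      "iron_deficiency_anemia": "present"
     },
     "dist": {
      "low": 0.7,
      "normal": 0.28,
      "high": 0.02
     }
    },
    {
     "given": {
      "iron_deficiency_anemia": "at_risk"
     },
     "dist": {
      "low": 0.25,
      "normal": 0.7,
      "high": 0.05
     }
    },
    {
     "given": {
      "iron_deficiency_anemia": "absent"
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
   "name": "ferritin",
   "states": [
    "low",
    "normal",
    "high"
   ],
   "parents": [
    "iron_deficiency_anemia"
   ],
   "cpt": [
    {
     "given": {
      "iron_deficiency_anemia": "present"
     },
     "dist": {
      "low": 0.9,
      "normal": 0.09,
      "high": 0.01
     }
    },
    {
     "given": {
      "iron_deficiency_anemia": "at_risk"
     },
     "dist": {
      "low": 0.45,
      "normal": 0.52,
      "high": 0.03
     }
    },
    {
     "given": {
      "iron_deficiency_anemia": "absent"
     },
     "dist": {
      "low": 0.05,
      "normal": 0.9,
      "high": 0.05
     }
    }
   ]
  },
  {
   "name": "paleness",
   "states": [
    "absent",
    "present"
   ],
   "parents": [
    "iron_deficiency_anemia"
   ],
   "cpt": [
    {
     "given": {
      "iron_deficiency_anemia": "present"
     },
     "dist": {
      "absent": 0.3,
      "present": 0.7
     }
    },
    {
     "given": {
      "iron_deficiency_anemia": "at_risk"
     },
     "dist": {
      "absent": 0.65,
      "present": 0.35
     }
    },
    {
     "given": {
      "iron_deficiency_anemia": "absent"
     },
     "dist": {
      "absent": 0.9,
      "present": 0.1
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
    "iron_deficiency_anemia"
   ],
   "cpt": [
    {
     "given": {
      "iron_deficiency_anemia": "present"
     },
     "dist": {
      "absent": 0.25,
      "present": 0.75
     }
    },
    {
     "given": {
      "iron_deficiency_anemia": "at_risk"
     },
     "dist": {
      "absent": 0.6,
      "present": 0.4
     }
    },
    {
     "given": {
      "iron_deficiency_anemia": "absent"
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
  "description": "Iron deficiency anemia after Roux-en-Y gastric bypass: driven by inadequate intake and blood loss; read off hemoglobin, hematocrit, MCV, ferritin, paleness and weakness."
 }
}
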