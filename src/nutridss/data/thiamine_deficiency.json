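{
 "name": "thiamine_deficiency",
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
   "name": "vomiting",
   "states": [
    "absent",
    "present"
   ],
   "parents": [],
   "cpt": [
    {
     "given": {},
     "dist": {
      "absent": 0.8,
      "present": 0.2
     }
    }
   ]
  },
  {
   "name": "thiamine_deficiency",
   "states": [
    "present",
    "at_risk",
    "absent"
   ],
   "parents": [
    "intake",
    "surgery_time",
    "vomiting"
   ],
   "cpt": [
    {
     "given": {
      "intake": "adequate",
      "surgery_time": "under_6mo",
      "vomiting": "absent"
     },
     "dist": {
      "present": 0.03,
      "at_risk": 0.17,
      "absent": 0.8
     }
    },
    {
     "given": {
      "intake": "adequate",
      "surgery_time": "under_6mo",
      "vomiting": "present"
     },
     "dist": {
      "present": 0.4,
      "at_risk": 0.4,
      "absent": 0.2
     }
    },
    {
     "given": {
      "intake": "adequate",
      "surgery_time": "6mo_to_2y",
      "vomiting": "absent"
     },
     "dist": {
      "present": 0.01,
      "at_risk": 0.09,
      "absent": 0.9
     }
    },
    {
     "given": {
      "intake": "adequate",
      "surgery_time": "6mo_to_2y",
      "vomiting": "present"
     },
     "dist": {
      "present": 0.25,
      "at_risk": 0.45,
      "absent": 0.3
     }
    },
    {
     "given": {
      "intake": "adequate",
      "surgery_time": "over_2y",
      "vomiting": "absent"
     },
     "dist": {
      "present": 0.01,
      "at_risk": 0.05,
      "absent": 0.94
     }
    },
    {
     "given": {
      "intake": "adequate",
      "surgery_time": "over_2y",
      "vomiting": "present"
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
      "surgery_time": "under_6mo",
      "vomiting": "absent"
     },
     "dist": {
      "present": 0.06,
      "at_risk": 0.29,
      "absent": 0.65
     }
    },
    {
     "given": {
      "intake": "inadequate",
      "surgery_time": "under_6mo",
      "vomiting": "present"
     },
     "dist": {
      "present": 0.55,
      "at_risk": 0.35,
      "absent": 0.1
     }
    },
    {
     "given": {
      "intake": "inadequate",
      "surgery_time": "6mo_to_2y",
      "vomiting": "absent"
     },
     "dist": {
      "present": 0.03,
      "at_risk": 0.17,
      "absent": 0.8
     }
    },
    {
     "given": {
      "intake": "inadequate",
      "surgery_time": "6mo_to_2y",
      "vomiting": "present"
     },
     "dist": {
      "present": 0.35,
      "at_risk": 0.45,
      "absent": 0.2
     }
    },
    {
     "given": {
      "intake": "inadequate",
      "surgery_time": "over_2y",
      "vomiting": "absent"
     },
     "dist": {
      "present": 0.02,
      "at_risk": 0.1,
      "absent": 0.88
     }
    },
    {
     "given": {
      "intake": "inadequate",
      "surgery_time": "over_2y",
      "vomiting": "present"
     },
     "dist": {
      "present": 0.25,
      "at_risk": 0.45,
      "absent": 0.3
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
    "thiamine_deficiency"
   ],
   "cpt": [
    {
     "given": {
      "thiamine_deficiency": "present"
     },
     "dist": {
      "absent": 0.2,
      "present": 0.8
     }
    },
    {
     "given": {
      "thiamine_deficiency": "at_risk"
     },
     "dist": {
      "absent": 0.6,
      "present": 0.4
     }
    },
    {
     "given": {
      "thiamine_deficiency": "absent"
     },
     "dist": {
      "absent": 0.94,
      "present": 0.06
     }
    }
   ]
  }
 ],
 "metadata": {
  "provenance": "All conditional probabilities are placeholders: weakly informative, literature-plausible values authored for this implementation and marked for replacement by expert-elicited or literature-derived numbers. They are not calibrated to any clinical dataset.",
  "cpt_provenance": "placeholder",
  "description": "Thiamine deficiency: thiamine stores last weeks, so persistent vomiting in the early post-operative months is the classic precipitant; read off paresthesia."
 }
}
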