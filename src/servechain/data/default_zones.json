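{
 "_comment": "SYNTHETIC default target-zone geometry (not from any published protocol): rectangular 9/6/3 regions near each aiming target; uncovered in-box area scores 1; second-serve zones shifted 0.5 m toward the net for net clearance. Replace with coach-defined polygons for real analyses.",
 "frame": {
  "origin": "T of the receiving service box",
  "x_axis": "toward the net along the centre service line",
  "y_axis": "toward the singles sideline"
 },
 "service_box": {
  "depth_m": 6.4,
  "width_m": 4.115
 },
 "zones": {
  "first": {
   "T": [
    {
     "id": "first_T_9",
     "points": 9,
     "polygon": [
      [
       0.0,
       0.0
      ],
      [
       1.0,
       0.0
      ],
      [
       1.0,
       1.0
      ],
      [
       0.0,
       1.0
      ]
     ]
    },
    {
     "id": "first_T_6",
     "points": 6,
     "polygon": [
      [
       1.0,
       0.0
      ],
      [
       2.0,
       0.0
      ],
      [
       2.0,
       1.0
      ],
      [
       1.0,
       1.0
      ]
     ]
    },
    {
     "id": "first_T_3",
     "points": 3,
     "polygon": [
      [
       0.0,
       1.0
      ],
      [
       2.0,
       1.0
      ],
      [
       2.0,
       2.0
      ],
      [
       0.0,
       2.0
      ]
     ]
    }
   ],
   "wide": [
    {
     "id": "first_wide_9",
     "points": 9,
     "polygon": [
      [
       0.0,
       3.115
      ],
      [
       1.0,
       3.115
      ],
      [
       1.0,
       4.115
      ],
      [
       0.0,
       4.115
      ]
     ]
    },
    {
     "id": "first_wide_6",
     "points": 6,
     "polygon": [
      [
       1.0,
       3.115
      ],
      [
       2.0,
       3.115
      ],
      [
       2.0,
       4.115
      ],
      [
       1.0,
       4.115
      ]
     ]
    },
    {
     "id": "first_wide_3",
     "points": 3,
     "polygon": [
      [
       0.0,
       2.115
      ],
      [
       2.0,
       2.115
      ],
      [
       2.0,
       3.115
      ],
      [
       0.0,
       3.115
      ]
     ]
    }
   ],
   "body": [
    {
     "id": "first_body_9",
     "points": 9,
     "polygon": [
      [
       0.0,
       1.5575
      ],
      [
       1.0,
       1.5575
      ],
      [
       1.0,
       2.5575
      ],
      [
       0.0,
       2.5575
      ]
     ]
    },
    {
     "id": "first_body_6",
     "points": 6,
     "polygon": [
      [
       1.0,
       1.5575
      ],
      [
       2.0,
       1.5575
      ],
      [
       2.0,
       2.5575
      ],
      [
       1.0,
       2.5575
      ]
     ]
    },
    {
     "id": "first_body_3",
     "points": 3,
     "polygon": [
      [
       2.0,
       1.5575
      ],
      [
       3.0,
       1.5575
      ],
      [
       3.0,
       2.5575
      ],
      [
       2.0,
       2.5575
      ]
     ]
    }
   ]
  },
  "second": {
   "T": [
    {
     "id": "second_T_9",
     "points": 9,
     "polygon": [
      [
       0.5,
       0.0
      ],
      [
       1.5,
       0.0
      ],
      [
       1.5,
       1.0
      ],
      [
       0.5,
       1.0
      ]
     ]
    },
    {
     "id": "second_T_6",
     "points": 6,
     "polygon": [
      [
       1.5,
       0.0
      ],
      [
       2.5,
       0.0
      ],
      [
       2.5,
       1.0
      ],
      [
       1.5,
       1.0
      ]
     ]
    },
    {
     "id": "second_T_3",
     "points": 3,
     "polygon": [
      [
       0.5,
       1.0
      ],
      [
       2.5,
       1.0
      ],
      [
       2.5,
       2.0
      ],
      [
       0.5,
       2.0
      ]
     ]
    }
   ],
   "wide": [
    {
     "id": "second_wide_9",
     "points": 9,
     "polygon": [
      [
       0.5,
       3.115
      ],
      [
       1.5,
       3.115
      ],
      [
       1.5,
       4.115
      ],
      [
       0.5,
       4.115
      ]
     ]
    },
    {
     "id": "second_wide_6",
     "points": 6,
     "polygon": [
      [
       1.5,
       3.115
      ],
      [
       2.5,
       3.115
      ],
      [
       2.5,
       4.115
      ],
      [
       1.5,
       4.115
      ]
     ]
    },
    {
     "id": "second_wide_3",
     "points": 3,
     "polygon": [
      [
       0.5,
       2.115
      ],
      [
       2.5,
       2.115
      ],
      [
       2.5,
       3.115
      ],
      [
       0.5,
       3.115
      ]
     ]
    }
   ],
   "body": [
    {
     "id": "second_body_9",
     "points": 9,
     "polygon": [
      [
       0.5,
       1.5575
      ],
      [
       1.5,
       1.5575
      ],
      [
       1.5,
       2.5575
      ],
      [
       0.5,
       2.5575
      ]
     ]
    },
    {
     "id": "second_body_6",
     "points": 6,
     "polygon": [
      [
       1.5,
       1.5575
      ],
      [
       2.5,
       1.5575
      ],
      [
       2.5,
       2.5575
      ],
      [
       1.5,
       2.5575
      ]
     ]
    },
    {
     "id": "second_body_3",
     "points": 3,
     "polygon": [
      [
       2.5,
       1.5575
      ],
      [
       3.5,
       1.5575
      ],
      [
       3.5,
       2.5575
      ],
      [
       2.5,
       2.5575
      ]
     ]
    }
   ]
  }
 }
}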