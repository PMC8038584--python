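{
  "lit-01": {
    "expected": {
      "physiological": ["hagma", "met_alk"],
      "chemical": ["hagma", "met_alk"]
    }
  },
  "lit-02": {
    "expected": {
      "physiological": ["hagma", "met_alk"],
      "chemical": ["hagma", "met_alk"]
    }
  },
  "lit-03": {
    "expected": {
      "physiological": ["resp_alk", "hagma", "met_alk?"],
      "chemical": ["resp_alk", "hagma", "met_alk?"]
    }
  },
  "lit-04": {
    "expected": {
      "physiological": ["hagma", "resp_acid", "met_alk?"],
      "chemical": ["hagma", "resp_acid", "met_alk?"]
    }
  },
  "lit-05": {
    "expected": {
      "physiological": ["met_alk", "resp_alk"],
      "chemical": ["met_alk", "resp_alk"]
    }
  },
  "lit-06": {
    "expected": {
      "physiological": ["resp_acid", "met_alk"],
      "chemical": ["resp_acid", "met_alk"]
    }
  },
  "lit-07": {
    "expected": {
      "physiological": ["resp_alk/chronic", "hagma", "met_alk"],
      "chemical": ["resp_alk/chronic", "hagma", "met_alk"]
    }
  },
  "lit-08": {
    "expected": {
      "physiological": ["hagma", "resp_acid", "met_alk?"],
      "chemical": ["hagma", "resp_acid", "met_alk?"]
    }
  },
  "lit-09": {
    "expected": {
      "physiological": ["nagma", "resp_acid"],
      "physiological_agc": ["hagma", "resp_acid", "nagma?"],
      "chemical": ["nagma", "resp_acid"],
      "chemical_agc": ["hagma", "resp_acid", "nagma?"]
    },
    "compliance": 50
  },
  "survey-01": {
    "expected": {
      "physiological": ["resp_alk", "hagma"],
      "physiological_agc": ["resp_alk", "hagma"],
      "chemical": ["resp_alk", "hagma"],
      "chemical_agc": ["resp_alk", "hagma"]
    }
  },
  "survey-02": {
    "expected": {
      "physiological": ["hagma", "met_alk"],
      "physiological_agc": ["hagma", "met_alk"],
      "chemical": ["hagma", "met_alk"],
      "chemical_agc": ["hagma", "met_alk"]
    }
  },
  "survey-03": {
    "expected": {
      "physiological": ["resp_alk", "hagma", "met_alk"],
      "physiological_agc": ["resp_alk", "hagma", "met_alk"],
      "chemical": ["resp_alk", "hagma", "met_alk"],
      "chemical_agc": ["resp_alk", "hagma", "met_alk"]
    }
  },
  "survey-04": {
    "expected": {
      "physiological": ["resp_acid", "hagma", "met_alk"],
      "physiological_agc": ["resp_acid", "hagma", "met_alk"],
      "chemical": ["resp_acid", "hagma", "met_alk"],
      "chemical_agc": ["resp_acid", "hagma", "met_alk"]
    }
  },
  "survey-05": {
    "expected": {
      "physiological": ["nagma"],
      "physiological_agc": ["hagma"]
    },
    "known_divergent": ["chemical", "chemical_agc"]
  },
  "survey-06": {
    "reject": true
  },
  "survey-07": {
    "expected": {
      "physiological": ["resp_alk", "met_alk"],
      "physiological_agc": ["resp_alk", "met_alk"],
      "chemical": ["resp_alk", "met_alk"],
      "chemical_agc": ["resp_alk", "met_alk"]
    }
  },
  "survey-08": {
    "expected": {
      "physiological": ["resp_alk/acute"],
      "physiological_agc": ["resp_alk/acute"],
      "chemical": ["resp_alk/acute"],
      "chemical_agc": ["resp_alk/acute"]
    }
  },
  "survey-09": {
    "expected": {
      "physiological": ["resp_acid", "nagma"],
      "physiological_agc": ["resp_acid", "nagma"],
      "chemical": ["resp_acid", "nagma"],
      "chemical_agc": ["resp_acid", "nagma"]
    }
  },
  "survey-10": {
    "expected": {
      "physiological": ["resp_acid/acute"],
      "physiological_agc": ["resp_acid/acute"],
      "chemical": ["resp_acid/acute"],
      "chemical_agc": ["resp_acid/acute"]
    }
  },
  "worked-1": {
    "expected": {
      "physiological": [],
      "physiological_agc": [],
      "chemical": [],
      "chemical_agc": []
    },
    "compliance": 100
  },
  "worked-2": {
    "expected": {
      "physiological": ["met_alk", "resp_alk"],
      "chemical": ["met_alk", "resp_alk"]
    },
    "compliance": 100
  },
  "worked-3": {
    "expected": {
      "physiological": ["nagma", "resp_acid"],
      "physiological_agc": ["hagma", "resp_acid", "nagma?"],
      "chemical": ["nagma", "resp_acid"],
      "chemical_agc": ["hagma", "resp_acid", "nagma?"]
    },
    "compliance": 50
  },
  "appcmp-elevated": {
    "expected": {
      "physiological": ["hagma", "met_alk"],
      "physiological_agc": ["hagma", "met_alk"],
      "chemical": ["hagma", "met_alk"],
      "chemical_agc": ["hagma", "met_alk"]
    },
    "compliance": 100
  },
  "appcmp-normal": {
    "expected": {
      "physiological": [],
      "physiological_agc": [],
      "chemical": [],
      "chemical_agc": []
    },
    "compliance": 100
  },
  "fourway-discordant": {
    "expected": {
      "physiological": ["hagma"],
      "physiological_agc": ["hagma", "met_alk?"]
    },
    "known_divergent": ["chemical", "chemical_agc"]
  }
}
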