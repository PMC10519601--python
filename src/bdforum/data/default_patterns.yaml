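# Default diagnosis-statement pattern set (regular expressions, matched
# case-insensitively at word boundaries over whitespace-normalised text).
#
# The production pattern set behind published cohorts is far larger (74
# exclusion patterns alone) and not public; this shipped default is an
# honest, documented seed built from the canonical quoted examples. Supply
# a pattern file with the same keys to use a full set as the source of truth.
inclusion:
  - "i (was|am|have been|'?ve been|got|just got) (recently |officially |finally |just )?(diagnosed|dx'?d) (with|as having) bipolar( disorder| [12]| ii?| type [12])?"
  - "(they|my (doctor|psychiatrist|therapist)) diagnosed me with bipolar( disorder| [12]| ii?)?"
  - "my bipolar( disorder)? diagnosis"
  - "diagnosis of bipolar( disorder| [12]| ii?)?"
exclusion:
  - "not officially diagnosed"
  - "never (been )?(officially )?diagnosed"
  - "self[- ]diagnosed"
  - "self[- ]diagnosis"
  - "not (yet )?(been )?diagnosed"
  - "undiagnosed"
  - "(haven'?t|have not) been diagnosed"
  - "without (an? )?(official )?diagnosis"
  - "no (official |formal )?diagnosis"
  - "if i (was|were|got) diagnosed"
  - "think i (might|may|could) (be|have) bipolar"
  - "pretty sure i'?m bipolar"
other_diagnoses:
  psychotic_disorder:
    - "diagnosed (with|as having) (schizophrenia|schizoaffective( disorder)?|psychosis|a psychotic disorder)"
    - "my (schizophrenia|schizoaffective|psychosis) diagnosis"
  major_depressive_disorder:
    - "diagnosed (with|as having) (major depress(ion|ive disorder)|mdd|clinical depression)"
    - "my (mdd|major depression) diagnosis"
  anxiety_disorder:
    - "diagnosed (with|as having) ((generalized |generalised )?anxiety( disorder)?|gad)"
  ptsd:
    - "diagnosed (with|as having) (ptsd|post[- ]traumatic stress( disorder)?)"
  adhd:
    - "diagnosed (with|as having) (adhd|add|attention deficit)"
  ocd:
    - "diagnosed (with|as having) (ocd|obsessive[- ]compulsive( disorder)?)"
  eating_disorder:
    - "diagnosed (with|as having) (anorexia|bulimia|an eating disorder)"
  borderline_pd:
    - "diagnosed (with|as having) (bpd|borderline( personality( disorder)?)?)"
  substance_use_disorder:
    - "diagnosed (with|as having) (alcoholism|substance (use|abuse) disorder|addiction)"
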