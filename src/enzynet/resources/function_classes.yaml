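# Function-class scheme for enriched GO terms.
#
# Classes are matched in the order listed: the most specific disease
# classes first, the broad metabolic catch-all last. Within the pass over
# classes, explicit term ids take precedence over keyword matches; the
# keywords are case-insensitive substrings of the term name. Edit or
# replace this file (config key `function_classes`) to change the scheme.
death:
  term_ids: []
  keywords:
    - programmed cell death
    - cell death
    - apoptosis
    - apoptotic
    - autophagy
    - autophagic
    - necrosis
    - necrotic
chd:
  term_ids: []
  keywords:
    - coronary
    - cardiac
    - cardio
    - heart
    - atheroscler
    - angiogenesis
    - inflammatory
    - inflammation
    - vascular
    - vasculature
    - blood vessel
lipid:
  term_ids: []
  keywords:
    - lipid
    - sterol
    - cholesterol
    - fatty acid
    - lipoprotein
    - triglyceride
    - phospholipid
    - steroid
basic_metabolic:
  term_ids: []
  keywords:
    - metabolic
    - metabolism
    - biosynthe
    - catabol
    - glycolysis
    - tricarboxylic
    - oxidation
    - translation
    - trna aminoacylation
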