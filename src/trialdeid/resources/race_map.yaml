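# Source-vocabulary -> FDA race category mapping.
#
# Targets are the five FDA-recommended categories; common CDISC/CDASH
# collected spellings are listed as sources.  Editable: data holders add
# their own collected terms here.  Unmapped values are routed to a review
# list and set missing, never guessed.
categories:
  - American Indian or Alaska Native
  - Asian
  - Black or African American
  - Native Hawaiian or Other Pacific Islander
  - White
other_label: Other/Multiple
map:
  AMERICAN INDIAN OR ALASKA NATIVE: American Indian or Alaska Native
  AMERICAN INDIAN: American Indian or Alaska Native
  ALASKA NATIVE: American Indian or Alaska Native
  NATIVE AMERICAN: American Indian or Alaska Native
  ASIAN: Asian
  ASIAN INDIAN: Asian
  CHINESE: Asian
  JAPANESE: Asian
  KOREAN: Asian
  FILIPINO: Asian
  VIETNAMESE: Asian
  BLACK OR AFRICAN AMERICAN: Black or African American
  BLACK: Black or African American
  AFRICAN AMERICAN: Black or African American
  AFRICAN: Black or African American
  NATIVE HAWAIIAN OR OTHER PACIFIC ISLANDER: Native Hawaiian or Other Pacific Islander
  NATIVE HAWAIIAN: Native Hawaiian or Other Pacific Islander
  PACIFIC ISLANDER: Native Hawaiian or Other Pacific Islander
  GUAMANIAN: Native Hawaiian or Other Pacific Islander
  SAMOAN: Native Hawaiian or Other Pacific Islander
  WHITE: White
  CAUCASIAN: White
  MULTIPLE: Other/Multiple
  MULTIRACIAL: Other/Multiple
  OTHER: Other/Multiple
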