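# HIPAA Safe Harbor direct-identifier registry.
#
# The Safe Harbor route de-identifies data by removing eighteen enumerated
# classes of direct identifier (45 CFR 164.514(b)(2)), lettered A-R.  The
# closing condition of the rule -- that the data holder has no actual
# knowledge that the remaining information could identify an individual --
# is a governance attestation, not a computable rule; it is recorded in
# reports as an attestation line (see `safe_harbor_condition`).
#
# `detection` names the value-pattern family the cell scanner can use to
# spot stray instances of the identifier inside free text; `none` means the
# class is handled purely by variable-level declaration (no reliable value
# pattern exists, and name detection is deliberately heuristic-free).
identifiers:
  - code: A
    label: Names
    detection: name-like
  - code: B
    label: Geographic subdivisions smaller than a state
    detection: zip
  - code: C
    label: Elements of dates (except year) directly related to an individual
    detection: date-like
  - code: D
    label: Telephone numbers
    detection: phone
  - code: E
    label: Fax numbers
    detection: fax
  - code: F
    label: Email addresses
    detection: email
  - code: G
    label: Social security numbers
    detection: ssn-like
  - code: H
    label: Medical record numbers
    detection: account-like
  - code: I
    label: Health plan beneficiary numbers
    detection: account-like
  - code: J
    label: Account numbers
    detection: account-like
  - code: K
    label: Certificate/licence numbers
    detection: account-like
  - code: L
    label: Vehicle identifiers and serial numbers
    detection: none
  - code: M
    label: Device identifiers and serial numbers
    detection: none
  - code: N
    label: Web Universal Resource Locators (URLs)
    detection: url
  - code: O
    label: Internet Protocol (IP) addresses
    detection: ip
  - code: P
    label: Biometric identifiers
    detection: none
  - code: Q
    label: Full-face photographs and any comparable images
    detection: none
  - code: R
    label: Any other unique identifying number, characteristic, or code
    detection: none
safe_harbor_condition: >-
  S. The data holder attests to having no actual knowledge that the
  information could be used alone or in combination with other information
  to identify an individual who is a subject of the information.
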