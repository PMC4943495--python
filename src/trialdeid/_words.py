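"""Small deterministic word lists for the synthetic-trial generator.

Shipped in-package so fixture generation needs no download and plants are
reproducible.  All names are common-word inventions, not real people.
"""

FIRST_NAMES = [
    "Alice", "Brian", "Carla", "David", "Elena", "Frank", "Grace", "Henry",
    "Irene", "James", "Karen", "Louis", "Maria", "Nolan", "Olive", "Peter",
    "Quinn", "Rosa", "Simon", "Tessa", "Umar", "Vera", "Walter", "Yusuf",
]

LAST_NAMES = [
    "Abbott", "Barnes", "Carter", "Dalton", "Ellis", "Foster", "Gibson",
    "Hardy", "Ingram", "Jensen", "Keller", "Lawson", "Mercer", "Norris",
    "Osborn", "Parker", "Quimby", "Reeves", "Sutton", "Turner", "Upton",
    "Vaughn", "Weaver", "Yates",
]

AE_TERMS = [
    # (dictionary-coded preferred term, verbatim phrasing)
    ("Headache", "throbbing headache"),
    ("Nausea", "feeling of nausea"),
    ("Fatigue", "persistent tiredness"),
    ("Dizziness", "dizzy spells"),
    ("Rash", "itchy skin rash"),
    ("Pyrexia", "raised temperature"),
    ("Cough", "dry cough"),
    ("Insomnia", "trouble sleeping"),
    ("Diarrhoea", "loose stools"),
    ("Arthralgia", "aching joints"),
]

SEVERITIES = ["mild", "moderate", "severe"]

COUNTRIES = ["USA", "GBR", "DEU", "FRA", "JPN", "CAN", "ESP", "ITA"]

RACES = [
    "WHITE", "BLACK OR AFRICAN AMERICAN", "ASIAN", "AMERICAN INDIAN OR ALASKA NATIVE",
    "NATIVE HAWAIIAN OR OTHER PACIFIC ISLANDER", "OTHER",
]

ETHNICITIES = ["HISPANIC OR LATINO", "NOT HISPANIC OR LATINO", "NOT REPORTED"]

ARMS = ["PLACEBO", "ACTIVE 10MG", "ACTIVE 20MG"]
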