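"""Diagnose metabolic syndrome on single exam records.

The rule: three or more of {abdominal obesity, hyperglycemia, hypertension,
high triglycerides, low HDL-C}, with the guideline's inclusive thresholds
(WC >= 90/85 cm male/female, FGLU >= 6.1, BP >= 130/85, TG >= 1.70,
HDL-C <= 1.04).
"""

from metsflow import CONDITIONS, diagnose_mets, evaluate_condition

records = {
    "healthy male": {
        "sex": "male", "WC": 80.0, "FGLU": 5.0, "SBP": 115.0, "DBP": 70.0,
        "TG": 1.0, "HDL-C": 1.5,
    },
    "borderline male (2 of 5)": {
        "sex": "male", "WC": 92.0, "FGLU": 5.5, "SBP": 120.0, "DBP": 80.0,
        "TG": 1.9, "HDL-C": 1.2,
    },
    "incident case, female": {
        "sex": "female", "WC": 86.0, "FGLU": 6.3, "SBP": 128.0, "DBP": 86.0,
        "TG": 1.5, "HDL-C": 1.1,
    },
}

for label, record in records.items():
    mets, n = diagnose_mets(record)
    met = [c for c in CONDITIONS if evaluate_condition(record, c)]
    print(f"{label}: MetS={mets} ({n} conditions met: {', '.join(met) or 'none'})")

# A diagnosis of 1 means the person-year meets >= 3 of the 5 guideline
# conditions; this is the label the 5-year windows predict one year ahead.
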