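"""Shared feature generators for hand-built simulation scenarios."""

BASIC_GENERATORS = {
    "age": {"kind": "uniform_int", "low": 25, "high": 65},
    "gender": {"kind": "categorical", "levels": {"M": 0.6, "F": 0.4}},
    "year": {"kind": "uniform_int", "low": 2016, "high": 2020},
    "occupation_class": {
        "kind": "categorical",
        "levels": {"1": 0.3, "2": 0.4, "3": 0.2, "4": 0.1},
    },
}
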