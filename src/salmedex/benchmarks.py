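"""Published comparison scores for nine saliency models on an expert
eye-tracking benchmark of DME fundus images.

These are reference numbers from the published evaluation this package's
method descends from: eight general-purpose saliency models plus the learned
fundus-specific model ("Ours"), scored with 10x 10-fold cross-validation on
100 expert-annotated images.  They are kept here as data so consistency
arithmetic (Youden from sensitivity/specificity, cross-model averages) can
be checked, and as context for users comparing their own runs.  Absolute
EMD values depend on the original, unpublished transport configuration and
are not reproducible by this package.
"""

from __future__ import annotations

MODELS = ("Ours", "AIM", "AWS", "GBVS", "ITTI", "STB", "Judd", "SUN", "Torralba")

#: Saliency-map scores (Table-style comparison; cross-validated means).
PUBLISHED_SCORES = {
    "auc": {
        "Ours": 0.8275, "AIM": 0.5610, "AWS": 0.6081, "GBVS": 0.6748,
        "ITTI": 0.6419, "STB": 0.4723, "Judd": 0.7945, "SUN": 0.6449,
        "Torralba": 0.6235,
    },
    "emd": {
        "Ours": 8.1524, "AIM": 13.4767, "AWS": 13.2513, "GBVS": 12.3116,
        "ITTI": 12.8744, "STB": 17.9996, "Judd": 12.3079, "SUN": 12.4320,
        "Torralba": 12.701,
    },
    "ss": {
        "Ours": 0.1930, "AIM": 0.0853, "AWS": 0.0987, "GBVS": 0.1066,
        "ITTI": 0.1044, "STB": 0.0055, "Judd": 0.1033, "SUN": 0.0932,
        "Torralba": 0.0988,
    },
}

#: Published cross-model averages for the scores above.
PUBLISHED_AVERAGES = {"auc": 0.6498, "emd": 12.8341}

#: Detection rates at a 50% salient region (percent) and Youden's J.
PUBLISHED_RATES = {
    "sensitivity_pct": {
        "Ours": 83.7, "AIM": 50.7, "AWS": 57.0, "GBVS": 80.1, "ITTI": 69.6,
        "STB": 81.6, "Judd": 37.2, "SUN": 65.6, "Torralba": 63.7,
    },
    "specificity_pct": {
        "Ours": 77.7, "AIM": 59.2, "AWS": 64.5, "GBVS": 57.0, "ITTI": 58.1,
        "STB": 74.1, "Judd": 60.1, "SUN": 60.0, "Torralba": 55.4,
    },
    "youden": {
        "Ours": 0.614, "AIM": 0.099, "AWS": 0.215, "GBVS": 0.371,
        "ITTI": 0.277, "STB": 0.557, "Judd": -0.027, "SUN": 0.256,
        "Torralba": 0.191,
    },
}

#: Published cross-model averages for the rates above.
PUBLISHED_RATE_AVERAGES = {"sensitivity_pct": 65.5, "specificity_pct": 62.9}
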