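"""Published summary tables from the red deer tick survey (south-central Spain,
2004-2010) that the synthetic cohort generator and the descriptive checks use as
inputs.

The original individual-level records are not public; what is public are the
study's marginal tables: annual ungulate censuses, sex x age-class morphometric
moments, parasitisation counts by sex and age class, and per-year sample sizes.
Those margins are transcribed here and serve two purposes:

* they parameterise the synthetic cohort generator (age-class mix, morphometric
  moments, per-year sample sizes), and
* they are the inputs to the recomputable descriptive statistics (prevalence
  Wald CIs, mean burdens, census means).

Morphometric dispersion is published as standard errors; ``morphometric_sd``
converts SE -> SD using the per-class sample sizes.
"""

from __future__ import annotations

import math

import pandas as pd

#: Annual ungulate censuses (head counts at feeders during the rut).
#: Two pre-study years are included so that t-1 / t-2 lags exist for 2004.
CENSUS = pd.DataFrame(
    {
        "year": [2002, 2003, 2004, 2005, 2006, 2007, 2008, 2009, 2010],
        "deer": [363, 365, 286, 400, 392, 425, 418, 434, 332],
        "boar": [160, 60, 40, 140, 100, 200, 150, 16, 48],
        "total_ungulates": [600, 504, 395, 626, 559, 693, 636, 514, 458],
    }
)

#: Deer necropsied per study year (study total 306).
N_PER_YEAR = {2004: 12, 2005: 36, 2006: 56, 2007: 64, 2008: 40, 2009: 60, 2010: 38}

#: Number of deer per sex and age class (1 fawn ... 5 old).  The single hind of
#: unknown age is excluded, as in the modelling dataset.
AGE_CLASS_COUNTS = {
    "male": {1: 20, 2: 24, 3: 11, 4: 118, 5: 9},
    "female": {1: 16, 2: 10, 3: 13, 4: 72, 5: 12},
}

#: Hosts observed per meteorological season over the whole study
#: (winter Dec-Feb, spring Mar-May, summer Jun-Aug, autumn Sep-Nov).
SEASON_COUNTS = {"winter": 87, "spring": 2, "summer": 63, "autumn": 154}

#: Morphometric moments by sex and age class: mean and standard error of total
#: length TL (cm), thoracic perimeter TP (cm), hind foot length HF (cm) and
#: kidney fat index KFI (%).  The male-yearling KFI mean is printed as 4.3 in
#: the source table, below its own range minimum (4.6-107.7); 43.0 is used as a
#: plausible mid-range value.
MORPHOMETRIC_MOMENTS = {
    ("male", 1): {"TL": (133.8, 2.7), "TP": (93.4, 2.6), "HF": (45.3, 0.9), "KFI": (88.0, 21.3)},
    ("male", 2): {"TL": (165.8, 1.3), "TP": (115.0, 1.9), "HF": (51.8, 0.4), "KFI": (43.0, 6.4)},
    ("male", 3): {"TL": (174.9, 2.4), "TP": (115.9, 1.7), "HF": (53.1, 1.7), "KFI": (41.6, 7.8)},
    ("male", 4): {"TL": (187.7, 1.1), "TP": (125.8, 0.7), "HF": (53.3, 0.2), "KFI": (65.7, 8.5)},
    ("male", 5): {"TL": (188.8, 2.6), "TP": (125.0, 1.9), "HF": (52.8, 0.7), "KFI": (48.9, 14.0)},
    ("female", 1): {"TL": (128.5, 3.5), "TP": (86.1, 2.6), "HF": (44.3, 0.8), "KFI": (78.0, 19.3)},
    ("female", 2): {"TL": (148.4, 2.9), "TP": (108.0, 6.5), "HF": (49.1, 0.7), "KFI": (122.2, 23.2)},
    ("female", 3): {"TL": (160.6, 2.3), "TP": (105.2, 2.0), "HF": (49.3, 0.3), "KFI": (74.7, 17.6)},
    ("female", 4): {"TL": (162.4, 1.1), "TP": (110.3, 0.9), "HF": (48.7, 0.2), "KFI": (93.8, 8.4)},
    ("female", 5): {"TL": (166.6, 1.7), "TP": (110.2, 1.7), "HF": (48.7, 0.4), "KFI": (119.7, 25.0)},
}

#: Parasitisation margins: tick-positive / examined by sex, and tick totals.
PARASITISM = {
    "male": {"positive": 146, "examined": 182},
    "female": {"positive": 36, "examined": 124},
    "total": {"positive": 182, "examined": 306},
    "ticks_counted": 4009,
    "ticks_collected": 1772,
    "adults_collected": 1761,
    "hyalomma_adults": 1750,
}

#: Mean counted burden per sex (ticks/deer), used to calibrate the generator.
MEAN_BURDEN = {"male": 20.4, "female": 2.4, "total": 13.1}


def morphometric_sd(sex: str, age_class: int) -> dict[str, tuple[float, float]]:
    """Return ``{trait: (mean, sd)}`` for one sex x age class, converting the
    published standard errors to standard deviations with the class sample size."""
    n = AGE_CLASS_COUNTS[sex][age_class]
    out = {}
    for trait, (mean, se) in MORPHOMETRIC_MOMENTS[(sex, age_class)].items():
        out[trait] = (mean, se * math.sqrt(n))
    return out


def default_samples_per_year() -> dict[str, dict[int, int]]:
    """Per-year sample sizes by sex.

    The published per-year totals are split by the overall sex ratio
    (182 M / 124 F), rounding half away from zero; the rounding happens to
    return exactly 182 males and 124 females over the seven years.
    """
    male_frac = PARASITISM["male"]["examined"] / PARASITISM["total"]["examined"]
    males = {y: int(math.floor(n * male_frac + 0.5)) for y, n in N_PER_YEAR.items()}
    females = {y: N_PER_YEAR[y] - males[y] for y in N_PER_YEAR}
    return {"male": males, "female": females}
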