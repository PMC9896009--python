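"""Small bundled worked-example tables.

These are published summary means from two tropical maize half-diallel
trials (105 hybrids from 15 parents; 55 hybrids from 11 parents) evaluated
under artificial fall-armyworm infestation, reduced to the ten best hybrids
per experiment plus the best commercial check.  They exercise the ranking
and percent-advantage operations on real numbers without shipping any plot
data.
"""

from __future__ import annotations

import pandas as pd

from .tables import TraitMeta

#: Grain yield (t/ha) of the ten best experimental hybrids under artificial
#: fall-armyworm infestation, experiment I (15-parent diallel).
TOP10_GY_FAW_EXP1 = {
    "CKDHL164260/CML567": 7.50,
    "CML567/KS23-6": 7.33,
    "CML312/CKDHL164288": 6.99,
    "CML567/CKDHL166068": 6.79,
    "CML312/CML488": 6.55,
    "CKDHL164288/CML567": 6.45,
    "CML488/CML567": 6.43,
    "CML312/CKDHL166062": 6.42,
    "CML312/CKDHL164271": 6.37,
    "CML567/CKDHL164271": 6.34,
}

#: Same, experiment II (11-parent diallel).
TOP10_GY_FAW_EXP2 = {
    "CKDHL120348/CKDHL166087": 8.18,
    "CKDHL121320/CLRCY039": 8.17,
    "CKDHL166087/CLRCY039": 7.69,
    "CKDHL89/CKLMLN140377": 7.63,
    "CKDHL121320/CKLMLN140538": 7.49,
    "CKLMLN140377/CKLMLN140538": 7.40,
    "CKDHL89/CKDHL166091": 7.37,
    "CKDHL120668/CKDHL166087": 7.24,
    "CKDHL120348/CKDHL166091": 7.07,
    "CKDHL166091/CML494": 6.99,
}

#: Best commercial check under fall-armyworm infestation and its yield.
BEST_CHECK_FAW = ("DUMA43", 5.04)

GY_META = {"GY": TraitMeta(scale="continuous", direction="higher")}


def top_hybrid_table(experiment: int, include_check: bool = True) -> pd.DataFrame:
    """Entry x trait frame of the worked-example grain yields.

    Parameters
    ----------
    experiment:
        1 (15-parent trial) or 2 (11-parent trial).
    include_check:
        Append the best commercial check as an extra entry.
    """
    if experiment == 1:
        vals = dict(TOP10_GY_FAW_EXP1)
    elif experiment == 2:
        vals = dict(TOP10_GY_FAW_EXP2)
    else:
        raise ValueError("experiment must be 1 or 2")
    if include_check:
        name, gy = BEST_CHECK_FAW
        vals[name] = gy
    return pd.DataFrame({"GY": pd.Series(vals)})
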