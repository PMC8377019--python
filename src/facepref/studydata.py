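"""Published summary inputs of the cross-cultural study this package re-analyses.

The study recruited 1606 raters from 47 countries; after excluding
predominantly homosexual raters (Kinsey 4-6), raters identifying as neither
male nor female, and countries with fewer than 10 raters, 1371 raters from
12 countries remained.  For each judgement (attractiveness, femininity) and
each of five fertility-cue prototype sets they made a three-alternative
forced choice among the low/medium/high-cue composite faces.  The published
report prints only the percentage of choices per cell, not the raw counts;
:func:`facepref.pipeline.reproduce_table1` converts these percentages back
to counts at n = 1371 by largest-remainder rounding and re-runs the
centroid randomisation test on them.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["FINAL_SAMPLE_SIZE", "REPORTED_CHOICE_PROPORTIONS"]

#: raters retained after all exclusion rules
FINAL_SAMPLE_SIZE = 1371

#: published percentage of low/medium/high choices per judgement x cue set
REPORTED_CHOICE_PROPORTIONS = pd.DataFrame(
    [
        ("attractiveness", "all_cycles", 33.03, 32.88, 34.09),
        ("attractiveness", "textbook", 29.64, 31.01, 39.35),
        ("attractiveness", "E", 35.20, 32.25, 32.55),
        ("attractiveness", "P", 34.07, 34.60, 31.34),
        ("attractiveness", "EP_ratio", 36.09, 30.17, 33.74),
        ("femininity", "all_cycles", 34.72, 32.64, 32.64),
        ("femininity", "textbook", 30.51, 33.36, 36.13),
        ("femininity", "E", 33.44, 34.90, 31.67),
        ("femininity", "P", 34.72, 33.03, 32.26),
        ("femininity", "EP_ratio", 37.41, 30.56, 32.02),
    ],
    columns=["judgement", "cue_set", "low_pct", "medium_pct", "high_pct"],
)
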