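"""Bundled example data: published site-environment summary statistics.

`load_site_covariates` returns the biophysical, environmental, and
human-impact covariate summaries of a five-site Kenyan coral-reef fishery
study, split into the group of sites with a significant cross-level
closure effect versus those without.  Columns give the group summary
triples (n, mean, sd) together with the originally reported test values
(t, df, p, Cohen's D) and which t-test variant reproduces them.  The
``recomputable`` flag marks rows whose printed test statistics can be
recovered exactly from the rounded summaries (sea-surface temperature,
rugosity, and human gravity cannot be).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_site_covariates"]

_ROWS = [
    # metric, years, n1, mean1, sd1, n2, mean2, sd2,
    #   t, df, p, D, variant, recomputable
    ("sst", "2010-2015", 18, 27.33, 0.14, 12, 27.26, 0.13,
     1.34, 28.0, 0.19, 0.50, "pooled", False),
    ("npp", "2002-2013", 3, 1021.75, 83.04, 2, 951.77, 0.0,
     1.46, 2.0, 0.28, 1.03, "welch", True),
    ("coral_cover", "2009-2016", 26, 29.98, 14.69, 45, 32.68, 9.30,
     -0.84, 36.8, 0.41, -0.23, "welch", True),
    ("rugosity", "2009-2016", 26, 1.22, 0.07, 45, 1.22, 0.08,
     -0.03, 69.0, 0.98, -0.01, "pooled", False),
    ("human_gravity", "2014", 3, 1940.33, 1538.97, 2, 4471.5, 5609.48,
     -0.72, 3.0, 0.53, -0.65, "pooled", False),
    ("fishing_pressure", "2015", 3, 119.0, 98.88, 2, 153.5, 21.92,
     -0.46, 3.0, 0.68, -0.42, "pooled", True),
]

_COLUMNS = ["metric", "years", "n1", "mean1", "sd1", "n2", "mean2", "sd2",
            "t_reported", "df_reported", "p_reported", "d_reported",
            "variant", "recomputable"]


def load_site_covariates() -> pd.DataFrame:
    """Site-group covariate summaries (group 1: with closure; group 2: without)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
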